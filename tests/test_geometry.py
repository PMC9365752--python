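"""Branch-unit parameterisation: the s-tilde laws and their inverses."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acinusim import geometry
from acinusim.geometry import (
    alveoli_count,
    build_model_spec,
    flow_from_stilde,
    split_stilde,
    stilde_from_flow,
    stilde_from_volume,
    unit_length,
    unit_volume,
    unit_volume_sum,
    volume_ratio,
)


class TestStructureParameter:
    def test_reference_flow_gives_reference_stilde(self, constants):
        st_ref = stilde_from_flow(constants.q_m, constants)
        assert st_ref == pytest.approx(3.99, rel=5e-3)

    def test_single_bre_flow_gives_zero(self, constants):
        q_min = constants.m_bar_alv * constants.q_alv
        assert stilde_from_flow(q_min, constants) == pytest.approx(0.0, abs=1e-12)

    def test_small_study_flow(self, constants):
        # Table value 3.41e-5 ml/s, the smallest daughter flow in the study
        assert stilde_from_flow(3.41e-5, constants) == pytest.approx(0.7092, abs=2e-3)

    def test_below_minimum_flow_names_the_minimum(self, constants):
        with pytest.raises(ValueError, match="minimum"):
            stilde_from_flow(1e-6, constants)

    @given(s_tilde=st.floats(min_value=0.0, max_value=8.0))
    @settings(derandomize=True, max_examples=60)
    def test_flow_round_trip(self, s_tilde, constants):
        q = flow_from_stilde(s_tilde, constants)
        assert stilde_from_flow(q, constants) == pytest.approx(s_tilde, abs=1e-10)

    @given(s_tilde=st.floats(min_value=0.0, max_value=8.0))
    @settings(derandomize=True, max_examples=60)
    def test_volume_round_trip(self, s_tilde, constants):
        v = unit_volume(s_tilde, 0.0, constants)
        assert stilde_from_volume(v, constants) == pytest.approx(s_tilde, abs=1e-10)

    def test_split_integer(self):
        assert split_stilde(2.0) == (2, 0.0, 0.0)

    def test_split_fractional(self):
        s, a, b = split_stilde(3.98)
        assert (s, b) == (3, pytest.approx(0.98))
        assert a == pytest.approx(2**0.98 - 1, rel=1e-12)

    def test_split_rejects_negative(self):
        with pytest.raises(ValueError):
            split_stilde(-0.1)


class TestLengthsCountsVolumes:
    def test_unit_length_examples(self, constants):
        assert unit_length(3, 0.972, 0.089) == pytest.approx(0.4425, abs=2e-4)
        assert unit_length(0, 0.0, 0.089) == pytest.approx(0.089)

    def test_alveoli_count_single_bre(self):
        assert alveoli_count(0.0, 18) == pytest.approx(18.0)

    def test_alveoli_count_doubling_recursion(self):
        # adding one full generation doubles the subtree and adds one BrE
        m = 18
        for s_tilde in (0.0, 1.3, 2.75):
            assert alveoli_count(s_tilde + 1, m) == pytest.approx(
                2 * alveoli_count(s_tilde, m) + m, rel=1e-12
            )

    def test_single_bre_volume(self, constants):
        v = unit_volume(0.0, 0.0, constants)
        expected = constants.a_m * constants.l_m + 18 * constants.v_alv
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(2.54e-4, rel=2e-3)

    def test_reference_volume(self, constants):
        v = unit_volume(constants.s_tilde_ref, 0.0, constants)
        assert v == pytest.approx(7.76e-3, rel=1e-2)

    @pytest.mark.parametrize("s", range(7))
    @pytest.mark.parametrize("a", [0.0, 0.25, 0.5, 0.99])
    def test_explicit_sum_matches_closed_form(self, s, a, constants):
        s_tilde = s + math.log2(1.0 + a)
        for t in (0.0, 12.5):
            assert unit_volume_sum(s, a, t, constants) == pytest.approx(
                unit_volume(s_tilde, t, constants), rel=1e-12
            )

    def test_volume_grows_at_the_unit_input_flow(self, constants):
        for s_tilde in (0.0, 2.4, 5.5):
            v0 = unit_volume(s_tilde, 0.0, constants)
            v1 = unit_volume(s_tilde, 10.0, constants)
            assert (v1 - v0) / 10.0 == pytest.approx(
                flow_from_stilde(s_tilde, constants), rel=1e-12
            )


class TestModelSpec:
    def test_volume_implies_tabulated_flow(self, symmetric_small_spec):
        # 5.76e-4 ml at t=0 must reproduce the tabulated 3.41e-5 ml/s
        assert symmetric_small_spec.bru1.q_in == pytest.approx(3.41e-5, rel=5e-3)

    def test_flow_to_volume_ratio_is_unit_independent(self, asym_spec):
        r1 = asym_spec.bru1.q_in / asym_spec.bru1.v0
        r2 = asym_spec.bru2.q_in / asym_spec.bru2.v0
        r0 = asym_spec.bru0.q_in / asym_spec.bru0.v0
        assert r1 == pytest.approx(r2, rel=1e-12)
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_bru0_with_chamber_volume(self, symmetric_small_spec):
        assert symmetric_small_spec.bru0_volume_with_chamber == pytest.approx(
            3.31e-4, rel=1e-2
        )

    def test_volume_ratios_match_study_table(self, constants):
        spec1 = build_model_spec(constants, v_bru1=5.76e-4, v_bru2=7.76e-3)
        f, _ = volume_ratio(spec1)
        assert f == pytest.approx(0.074, abs=5e-4)
        spec6 = build_model_spec(constants, v_bru1=2.30e-2, v_bru2=7.76e-3)
        f6, _ = volume_ratio(spec6)
        assert f6 == pytest.approx(2.963, abs=2e-3)

    def test_reference_geometry_has_unit_fsym(self, constants):
        spec = build_model_spec(
            constants, v_bru1=constants.v_ref, v_bru2=constants.v_ref
        )
        _, f_sym = volume_ratio(spec)
        assert f_sym == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("t", [0.0, 5.0, 30.0])
    def test_volume_ratio_is_time_independent(self, asym_spec, t):
        c = asym_spec.constants
        ratio = unit_volume(asym_spec.bru1.s_tilde, t, c) / unit_volume(
            asym_spec.bru2.s_tilde, t, c
        )
        assert ratio == pytest.approx(asym_spec.f, rel=1e-12)

    def test_inconsistent_volume_flow_pair_rejected(self, constants):
        with pytest.raises(ValueError, match="inconsistent"):
            geometry.branch_unit("BrU1", constants, volume=5.76e-4, flow=4.6e-4)

    def test_unphysical_diffusion_coefficient_warns(self, constants):
        with pytest.warns(UserWarning, match="physical"):
            build_model_spec(constants, v_bru1=7.76e-3, v_bru2=7.76e-3,
                             diffusion_coefficient=1.5)

    def test_config_file_round_trip(self, asym_spec):
        buf = io.StringIO()
        geometry.write_config(geometry.spec_to_config(asym_spec, t_end=12.0), buf)
        buf.seek(0)
        spec2, dx, t_end = geometry.spec_from_config(geometry.read_config(buf))
        assert spec2.bru1.s_tilde == pytest.approx(asym_spec.bru1.s_tilde, rel=1e-9)
        assert spec2.bru2.v0 == pytest.approx(asym_spec.bru2.v0, rel=1e-9)
        assert (dx, t_end) == (10e-4, 12.0)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            geometry.read_config(io.StringIO("bogus = 1\n"))
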