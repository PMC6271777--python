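import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import monofilm as mf
from monofilm.constants import KT_23C
from monofilm.errors import InsufficientDataError
from monofilm.features import (
    FeatureConfig,
    compute_compressibility,
    detect_collapse,
    detect_liftoff,
    detect_transition,
    dipole_moment_profile,
    extract_features,
    max_surface_potential,
    modulus_summary,
    phase_label,
    surface_pressure_from_tension,
)
from monofilm.smoothing import prepare_for_derivative
from monofilm.synthetic import _solve_backbone


@pytest.mark.parametrize(
    "gamma0,gamma,expected",
    [(72.8, 72.8, 0.0), (72.8, 42.8, 30.0), (72.8, 14.8, 58.0)],
)
def test_surface_pressure_from_tension(gamma0, gamma, expected):
    assert surface_pressure_from_tension(gamma0, gamma) == pytest.approx(expected)


class TestCompressibility:
    def test_volmer_closed_form_at_60(self):
        """C_s⁻¹ on a Volmer branch with ω=40 at A=60 is A·kT/(A−ω)² = 61.34."""
        spec = mf.SyntheticIsothermSpec(
            area_max=120, area_min=30, n_points=2000, liftoff_area=90,
            volmer_coarea=40.0, lc_elasticity=240, collapse_pressure=58,
            noise_sd_pressure=0.0,
        )
        iso = mf.generate_isotherm(spec)
        curve = compute_compressibility(iso)
        i = np.argmin(np.abs(curve.area - 60.0))
        oracle = 60.0 * KT_23C / (60.0 - 40.0) ** 2
        assert oracle == pytest.approx(61.335)
        assert curve.modulus[i] == pytest.approx(oracle, rel=0.01)

    def test_constant_elasticity_branch(self, noiseless_lc_iso, noiseless_lc_spec):
        bb = _solve_backbone(noiseless_lc_spec)
        curve = compute_compressibility(noiseless_lc_iso)
        sel = (curve.area < bb.lc_start_area - 0.5) & (curve.area > bb.collapse_area + 0.5)
        np.testing.assert_allclose(curve.modulus[sel], 240.0, rtol=0.005)

    def test_constant_pressure_segment_is_zero(self):
        """A constant-π stretch between two rises has exactly zero modulus."""
        area = np.linspace(100.0, 40.0, 601)
        pressure = np.where(
            area > 70, 15.0 * (100.0 - area) / 30.0,
            np.where(area > 55, 15.0, 15.0 + 25.0 * (55.0 - area) / 15.0),
        )
        iso = mf.CompressionIsotherm(area=area, pressure=pressure)
        curve = compute_compressibility(iso)
        flat = (curve.area < 69) & (curve.area > 56)
        np.testing.assert_allclose(curve.modulus[flat], 0.0, atol=1e-9)

    def test_too_few_samples_above_threshold(self, gas_only_iso):
        with pytest.raises(InsufficientDataError):
            compute_compressibility(gas_only_iso)


class TestLiftoff:
    def test_noiseless_injected_liftoff_recovered(self):
        spec = mf.SyntheticIsothermSpec(
            area_max=160, area_min=30, n_points=1500, liftoff_area=120,
            volmer_coarea=95, lc_elasticity=240, collapse_pressure=55,
            noise_sd_pressure=0.0,
        )
        iso = mf.generate_isotherm(spec)
        res = detect_liftoff(prepare_for_derivative(iso))
        assert res.liftoff_area == pytest.approx(120.0, abs=1.0)

    def test_noisy_dppg_water_liftoff(self):
        spec, psi = mf.preset_spec("DPPG", "water", seed=3)
        iso = mf.generate_isotherm(spec, psi)
        res = detect_liftoff(prepare_for_derivative(iso))
        assert res.liftoff_area == pytest.approx(90.0, abs=2.0)

    def test_all_zero_trace_absent(self):
        iso = mf.CompressionIsotherm(
            area=np.linspace(100, 20, 200), pressure=np.zeros(200)
        )
        res = detect_liftoff(iso)
        assert res.liftoff_area is None


class TestCollapse:
    def test_noiseless_clip_recovers_injected_point(
        self, noiseless_lc_iso, noiseless_lc_spec
    ):
        bb = _solve_backbone(noiseless_lc_spec)
        s = prepare_for_derivative(noiseless_lc_iso)
        curve = compute_compressibility(s)
        res = detect_collapse(s, curve)
        h = (noiseless_lc_spec.area_max - noiseless_lc_spec.area_min) / (
            noiseless_lc_spec.n_points - 1
        )
        assert res.collapse_pressure == pytest.approx(58.0, abs=0.05)
        assert res.collapse_area == pytest.approx(bb.collapse_area, abs=h)

    def test_monotone_truncated_run_absent(self):
        # run ends at ~36 mN/m while still on the LC branch: no collapse
        spec = mf.SyntheticIsothermSpec(
            area_max=120, area_min=75, n_points=1000, liftoff_area=90,
            volmer_coarea=70.5, lc_elasticity=240, collapse_pressure=58,
            noise_sd_pressure=0.0,
        )
        iso = mf.generate_isotherm(spec)
        s = prepare_for_derivative(iso)
        curve = compute_compressibility(s)
        res = detect_collapse(s, curve)
        assert res.collapse_pressure is None

    def test_monotone_kink_route(self):
        # pressure keeps creeping up after collapse: no local maximum, the
        # two-segment fit must locate the kink
        spec = mf.SyntheticIsothermSpec(
            area_max=120, area_min=30, n_points=2000, liftoff_area=90,
            volmer_coarea=70.5, lc_elasticity=240, collapse_pressure=58,
            post_collapse_slope=-0.02, noise_sd_pressure=0.0,
        )
        iso = mf.generate_isotherm(spec)
        s = prepare_for_derivative(iso)
        curve = compute_compressibility(s)
        res = detect_collapse(s, curve)
        assert res.collapse_pressure == pytest.approx(58.0, abs=1.0)

    def test_never_condensed_absent(self):
        area = np.linspace(150, 50, 300)
        pressure = np.linspace(0, 8, 300)  # modulus ~ A*8/100 < 30
        iso = mf.CompressionIsotherm(area=area, pressure=pressure)
        curve = compute_compressibility(iso)
        assert detect_collapse(iso, curve).collapse_pressure is None


@pytest.fixture(scope="module")
def plateau_curve():
    spec = mf.SyntheticIsothermSpec(
        area_max=120, area_min=20, n_points=2000, liftoff_area=90,
        volmer_coarea=45, plateau_enabled=True,
        plateau_onset_pressure=15, plateau_end_pressure=22,
        plateau_slope=-0.25, lc_elasticity=150, collapse_pressure=40,
        noise_sd_pressure=0.05, seed=3,
    )
    iso = mf.generate_isotherm(spec)
    return compute_compressibility(prepare_for_derivative(iso))


class TestTransition:
    def test_injected_plateau_bounds_recovered(self, plateau_curve):
        res = detect_transition(plateau_curve)
        assert res.present
        assert res.onset_pressure == pytest.approx(15.0, abs=1.0)
        assert res.end_pressure == pytest.approx(22.0, abs=1.0)

    def test_no_plateau_is_absent(self, noiseless_lc_iso):
        curve = compute_compressibility(prepare_for_derivative(noiseless_lc_iso))
        assert not detect_transition(curve).present


class TestModulusSummary:
    def test_constant_elasticity_curve(self):
        spec = mf.SyntheticIsothermSpec(
            area_max=140, area_min=25, n_points=2000, liftoff_area=100,
            volmer_coarea=55, lc_elasticity=100, collapse_pressure=45,
            noise_sd_pressure=0.0,
        )
        iso = mf.generate_isotherm(spec)
        s = prepare_for_derivative(iso)
        curve = compute_compressibility(s)
        summ = modulus_summary(curve, collapse_pressure=45.0)
        assert summ.max_modulus == pytest.approx(100.0, rel=0.01)
        assert summ.modulus_at_reference == pytest.approx(100.0, rel=0.01)
        assert summ.phase_label == "liquid-condensed"

    def test_reference_outside_range_absent(self):
        spec = mf.SyntheticIsothermSpec(
            area_max=120, area_min=75, n_points=1000, liftoff_area=90,
            volmer_coarea=70.5, lc_elasticity=240, collapse_pressure=58,
            noise_sd_pressure=0.0,
        )
        iso = mf.generate_isotherm(spec)
        curve = compute_compressibility(prepare_for_derivative(iso))
        summ = modulus_summary(curve, reference_pressure=50.0)
        assert summ.modulus_at_reference is None

    def test_phase_bands(self):
        assert phase_label(5) == "gaseous/LE-LC"
        assert phase_label(50) == "liquid-expanded"
        assert phase_label(150) == "liquid-condensed"
        assert phase_label(300) == "solid"


class TestSurfacePotential:
    def test_dppe_water_condensed_state(self):
        spec, psi = mf.preset_spec("DPPE", "water", seed=2)
        iso = mf.generate_isotherm(spec, psi)
        s = prepare_for_derivative(iso)
        res = max_surface_potential(s, area_window=(30, 40))
        assert res.max_potential == pytest.approx(600.0, abs=10.0)
        assert 30 <= res.area_at_max <= 40

    def test_negative_running_potential_keeps_sign(self):
        spec, psi = mf.preset_spec("cardiolipin", "geraniol", seed=2)
        iso = mf.generate_isotherm(spec, psi)
        s = prepare_for_derivative(iso)
        res = max_surface_potential(s, area_window=(50, 100))
        assert res.max_potential == pytest.approx(-100.0, abs=10.0)

    def test_zero_trace_returns_zero(self):
        iso = mf.CompressionIsotherm(
            area=np.linspace(100, 20, 100),
            pressure=np.linspace(0, 40, 100),
            potential=np.zeros(100),
        )
        res = max_surface_potential(iso)
        assert res.max_potential == 0.0

    def test_missing_channel_is_absent(self, gas_only_iso):
        assert max_surface_potential(gas_only_iso).max_potential is None

    def test_disjoint_window_raises(self):
        iso = mf.CompressionIsotherm(
            area=np.linspace(100, 50, 100),
            pressure=np.linspace(0, 40, 100),
            potential=np.linspace(0, 300, 100),
        )
        with pytest.raises(InsufficientDataError):
            max_surface_potential(iso, area_window=(10, 20))


class TestDipole:
    def test_unit_conversion_constant(self):
        """1 mV at A = 12π Å² is exactly 1 mD."""
        a = 12 * math.pi
        iso = mf.CompressionIsotherm(
            area=np.array([a + 1e-9, a, a - 1e-9]),
            pressure=np.zeros(3),
            potential=np.ones(3),
        )
        prof = dipole_moment_profile(iso)
        assert prof.dipole[1] == pytest.approx(1.0, abs=1e-6)

    def test_condensed_dppe_scale(self):
        iso = mf.CompressionIsotherm(
            area=np.array([41.0, 40.0, 39.0]),
            pressure=np.zeros(3),
            potential=np.array([0.0, 600.0, 600.0]),
        )
        prof = dipole_moment_profile(iso)
        assert prof.dipole[0] == 0.0
        assert prof.dipole[1] == pytest.approx(636.62, abs=0.01)

    @given(c=st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_scaling_in_potential_is_exact(self, c):
        rng = np.random.default_rng(1)
        area = np.linspace(100, 30, 50)
        psi = rng.uniform(-100, 500, size=50)
        base = dipole_moment_profile(
            mf.CompressionIsotherm(area=area, pressure=np.zeros(50), potential=psi)
        )
        scaled = dipole_moment_profile(
            mf.CompressionIsotherm(area=area, pressure=np.zeros(50), potential=c * psi)
        )
        np.testing.assert_allclose(scaled.dipole, c * base.dipole, atol=1e-9)

    def test_missing_channel_raises(self, gas_only_iso):
        with pytest.raises(InsufficientDataError):
            dipole_moment_profile(gas_only_iso)


class TestExtractFeatures:
    def test_dppe_carvacrol_recovery(self):
        spec, psi = mf.preset_spec("DPPE", "carvacrol", seed=1)
        iso = mf.generate_isotherm(spec, psi, metadata=mf.preset_metadata("DPPE", "carvacrol"))
        fs = extract_features(iso)
        assert fs.liftoff_area == pytest.approx(120.0, abs=3.0)
        assert fs.collapse_pressure == pytest.approx(38.0, abs=1.0)
        assert fs.max_modulus == pytest.approx(50.0, rel=0.05)

    def test_noiseless_run_yields_all_features(self):
        spec, psi = mf.preset_spec("DPPG", "water", noise_sd_pressure=0.0,
                                   noise_sd_potential=0.0)
        iso = mf.generate_isotherm(spec, psi, metadata=mf.preset_metadata("DPPG", "water"))
        fs = extract_features(iso)
        for field in ("liftoff_area", "collapse_pressure", "collapse_area",
                      "max_modulus", "modulus_at_reference", "max_potential"):
            assert getattr(fs, field) is not None, field

    def test_gas_only_trace_all_absent(self, gas_only_iso):
        fs = extract_features(gas_only_iso)
        assert fs.liftoff_area is None
        assert fs.collapse_pressure is None
        assert fs.max_modulus is None
        assert fs.max_potential is None

    def test_deterministic_given_input(self, dppe_water):
        a = extract_features(dppe_water)
        b = extract_features(dppe_water)
        assert a == b

    @pytest.mark.parametrize("seed", [2, 11])
    def test_feature_ordering_invariant(self, seed):
        """liftoff area > collapse area whenever both are present."""
        for lipid, sub in mf.list_presets():
            spec, psi = mf.preset_spec(lipid, sub, seed=seed)
            iso = mf.generate_isotherm(spec, psi, metadata=mf.preset_metadata(lipid, sub))
            fs = extract_features(iso)
            if fs.liftoff_area is not None and fs.collapse_area is not None:
                assert fs.liftoff_area > fs.collapse_area

    def test_increasing_elasticity_increases_max_modulus(self):
        previous = 0.0
        for k in (80.0, 150.0, 240.0):
            spec = mf.SyntheticIsothermSpec(
                area_max=120, area_min=25, n_points=1500, liftoff_area=90,
                volmer_coarea=68, lc_elasticity=k, collapse_pressure=50,
                noise_sd_pressure=0.0,
            )
            iso = mf.generate_isotherm(spec)
            fs = extract_features(iso)
            assert fs.max_modulus is not None and fs.max_modulus > previous
            previous = fs.max_modulus

    def test_serialization_has_units(self, dppe_water):
        d = extract_features(dppe_water).to_dict()
        assert "liftoff_area_A2_per_molecule" in d
        assert "max_modulus_mN_per_m" in d
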