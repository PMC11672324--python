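"""Hole-energetics model and tether-plateau extraction."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from woundsight import (
    ForceTrace,
    MembraneParams,
    NoTetherError,
    PlateauParams,
    barrier_height,
    critical_radius,
    enthalpy,
    enthalpy_components,
    generate_force_trace,
    hole_fate,
    plateau_force,
    tension_scan,
)

DEFAULTS = MembraneParams()  # λ = 1 pN, σ = 1e-5 N/m


class TestEnthalpy:
    def test_closed_hole_costs_twice_the_baseline_energy(self):
        p = MembraneParams(system_energy=3.5e-19)
        assert enthalpy(0.0, p) == pytest.approx(2 * 3.5e-19)

    def test_components_sum_to_total(self):
        for R in (0.0, 1e-8, 5e-7, 2e-6):
            h_line, h_tension = enthalpy_components(R, DEFAULTS)
            assert h_line + h_tension == pytest.approx(enthalpy(R, DEFAULTS), rel=1e-12)

    def test_barrier_height_is_pi_lambda_sq_over_sigma(self):
        # H(R_c) − H(0) = πλ²/σ; defaults give π × 1e−19 J
        rc = critical_radius(DEFAULTS)
        assert enthalpy(rc, DEFAULTS) - enthalpy(0.0, DEFAULTS) == pytest.approx(
            math.pi * 1e-19, rel=1e-12
        )
        assert barrier_height(DEFAULTS) == pytest.approx(math.pi * 1e-19, rel=1e-12)

    def test_derivative_vanishes_at_critical_radius(self):
        # central finite differences straddling R_c
        rc = critical_radius(DEFAULTS)
        h = rc * 1e-6
        dH = (enthalpy(rc + h, DEFAULTS) - enthalpy(rc - h, DEFAULTS)) / (2 * h)
        scale = enthalpy(rc, DEFAULTS) / rc
        assert abs(dH) < 1e-8 * abs(scale)

    def test_negative_radius_refused(self):
        with pytest.raises(ValueError):
            enthalpy(-1e-9, DEFAULTS)

    @pytest.mark.parametrize("lam", np.logspace(-13, -11, 5))
    @pytest.mark.parametrize("sigma", np.logspace(-6, -4, 5))
    def test_numeric_stationary_point_matches_lambda_over_sigma(self, lam, sigma):
        """Bracketed root of dH/dR agrees with λ/σ to relative 1e-10."""
        p = MembraneParams(line_tension=lam, membrane_tension=sigma)
        rc = critical_radius(p)

        def dHdR(R):
            return 2 * math.pi * lam - 2 * math.pi * R * sigma

        root = brentq(dHdR, rc * 1e-3, rc * 1e3, xtol=rc * 1e-14, rtol=1e-14)
        assert root == pytest.approx(rc, rel=1e-10)

    def test_concavity_everywhere(self):
        # d²H/dR² = −2πσ < 0: H is a barrier, never a well
        for R in np.linspace(1e-9, 5e-6, 7):
            h = 1e-9
            d2 = (enthalpy(R + h, DEFAULTS) - 2 * enthalpy(R, DEFAULTS)
                  + enthalpy(R - h, DEFAULTS)) / h**2
            assert d2 == pytest.approx(-2 * math.pi * DEFAULTS.membrane_tension, rel=1e-3)


class TestCriticalRadius:
    def test_standard_values_give_100_nm(self):
        assert critical_radius(DEFAULTS) == pytest.approx(100e-9, rel=1e-12)

    def test_tenfold_tension_drop_gives_1_um(self):
        p = MembraneParams(membrane_tension=1e-6)
        assert critical_radius(p) == pytest.approx(1e-6, rel=1e-12)

    def test_zero_line_tension_means_any_hole_grows(self):
        assert critical_radius(MembraneParams(line_tension=0.0)) == 0.0
        assert hole_fate(1e-9, MembraneParams(line_tension=0.0)) == "grow"

    def test_nonpositive_tension_refused(self):
        with pytest.raises(ValueError):
            critical_radius(MembraneParams(membrane_tension=0.0))

    @pytest.mark.parametrize("decade", [1e-2, 1e-1, 1e1, 1e2])
    def test_linearity_in_lambda_and_inverse_in_sigma(self, decade):
        base = critical_radius(DEFAULTS)
        scaled_lam = MembraneParams(line_tension=DEFAULTS.line_tension * decade)
        scaled_sig = MembraneParams(membrane_tension=DEFAULTS.membrane_tension * decade)
        assert critical_radius(scaled_lam) == pytest.approx(base * decade, rel=1e-12)
        assert critical_radius(scaled_sig) == pytest.approx(base / decade, rel=1e-12)


def _gradient_flow_fate(R0: float, p: MembraneParams, steps: int = 20000) -> str:
    """Independent oracle: explicit-Euler descent of H from R0.

    dR/dt ∝ −dH/dR; the trajectory either collapses to 0 (reseal) or
    escapes past several R_c (grow).
    """
    rc = critical_radius(p)
    R = R0
    eta = rc * 1e-3 / (2 * math.pi * p.membrane_tension * rc)  # step ~1e-3 R_c
    for _ in range(steps):
        grad = 2 * math.pi * p.line_tension - 2 * math.pi * R * p.membrane_tension
        R = R - eta * grad
        if R <= 0:
            return "reseal"
        if R >= 10 * rc:
            return "grow"
    raise RuntimeError("gradient flow did not resolve a fate")


class TestHoleFate:
    def test_small_hole_reseals_large_hole_grows(self):
        assert hole_fate(50e-9, DEFAULTS) == "reseal"
        assert hole_fate(200e-9, DEFAULTS) == "grow"
        assert _gradient_flow_fate(50e-9, DEFAULTS) == "reseal"
        assert _gradient_flow_fate(200e-9, DEFAULTS) == "grow"

    def test_exactly_critical(self):
        assert hole_fate(critical_radius(DEFAULTS), DEFAULTS) == "critical"

    def test_sign_rule_agrees_with_gradient_flow_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            lam = 10 ** rng.uniform(-13, -11)
            sigma = 10 ** rng.uniform(-6, -4)
            p = MembraneParams(line_tension=lam, membrane_tension=sigma)
            R = critical_radius(p) * 10 ** rng.uniform(-1, 1)
            if math.isclose(R, critical_radius(p), rel_tol=1e-9):
                continue
            assert hole_fate(R, p) == _gradient_flow_fate(R, p)


class TestTensionScan:
    def test_micron_hole_rescued_by_tension_reduction(self):
        # R = 1 µm: resting tension grows it, a 10× drop is exactly critical,
        # a 20× drop reseals it
        fates = tension_scan(1e-6, DEFAULTS, [1.0, 0.1, 0.05])
        assert fates == ["grow", "critical", "reseal"]

    def test_fates_monotone_along_descending_factors(self):
        factors = np.logspace(0, -2, 9)  # descending
        fates = tension_scan(1e-6, DEFAULTS, factors)
        order = {"grow": 0, "critical": 1, "reseal": 2}
        ranks = [order[f] for f in fates]
        assert ranks == sorted(ranks)

    def test_subcritical_hole_reseals_at_any_reduced_tension(self):
        assert set(tension_scan(50e-9, DEFAULTS, [1.0, 0.5, 0.1])) == {"reseal"}

    def test_nonpositive_factor_refused(self):
        with pytest.raises(ValueError):
            tension_scan(1e-6, DEFAULTS, [1.0, 0.0])


class TestPlateauForce:
    def test_noise_free_plateau_recovered_exactly(self):
        trace, _ = generate_force_trace(40.0, 20.0, noise_sd=0.0, n_samples=1000, seed=0)
        peak, plateau = plateau_force(trace)
        assert peak == pytest.approx(40.0, abs=1e-9)
        assert plateau == pytest.approx(20.0, abs=1e-9)

    def test_noisy_plateau_within_clt_bound(self):
        """Mean over a ≥500-sample plateau at σ = 1 pN lands within 3σ/√500."""
        errs = []
        for i in range(20):
            plateau = 10.0 + i
            trace, gt = generate_force_trace(plateau + 15, plateau, noise_sd=1.0,
                                             n_samples=850, seed=100 + i)
            _, est = plateau_force(trace, PlateauParams(subtract_baseline=False))
            errs.append(abs(est - gt.force_gt[1]))
        assert max(errs) <= 3.0 / math.sqrt(500)

    def test_flat_zero_trace_is_no_tether(self):
        trace = ForceTrace(time=np.arange(200) / 1000.0, force=np.zeros(200))
        with pytest.raises(NoTetherError):
            plateau_force(trace)

    def test_offset_invariance_with_baseline_estimation(self):
        trace, _ = generate_force_trace(40.0, 20.0, noise_sd=0.0, n_samples=1000, seed=0)
        shifted = ForceTrace(time=trace.time, force=trace.force + 7.5)
        assert plateau_force(trace) == pytest.approx(plateau_force(shifted), abs=1e-9)

    def test_short_trace_refused(self):
        trace = ForceTrace(time=np.arange(20) / 1000.0, force=np.ones(20) * 30)
        with pytest.raises(ValueError):
            plateau_force(trace)
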