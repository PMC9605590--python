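"""Ten-Gaussian OH-stretch deconvolution and water-state ratios."""

import math

import numpy as np
import pytest

from ramanclear.exceptions import CoverageError, NormalizationError
from ramanclear.spectra import RamanSpectrum, Region
from ramanclear.synth import SyntheticExperimentSpec, synth_hwn_experiment
from ramanclear.water import (
    ComponentRole,
    GaussianComponent,
    NOMINAL_CENTERS,
    NOMINAL_SIGMAS,
    WATER_ROLES,
    component_auc,
    deconvolve_hwn,
    subtract_hwn_baseline,
    water_kinetics,
    water_profile,
)


def clean_spec(seed=0, **kw):
    kw.setdefault("noise_cv", 0.0)
    kw.setdefault("noise_floor", 0.0)
    kw.setdefault("baseline_coeffs", ())
    kw.setdefault("depths_um", (50.0,))
    return SyntheticExperimentSpec(seed=seed, **kw)


def hwn_with_ratios(ratios, seed=0, **kw):
    spec = clean_spec(seed=seed, **kw)
    return synth_hwn_experiment(
        spec, water_ratios={50.0: {k: (v, v) for k, v in ratios.items()}}
    )


TABLE_RATIOS = {"tight": 0.20, "strong": 6.00, "weak": 3.49, "free": 0.73}


class TestComponentAuc:
    def test_unit_gaussian(self):
        g = GaussianComponent(ComponentRole.PROTEIN_2940, 2940, 1.0, 1.0)
        assert component_auc(g) == pytest.approx(math.sqrt(2 * math.pi))

    def test_zero_amplitude(self):
        g = GaussianComponent(ComponentRole.PROTEIN_2940, 2940, 5.0, 0.0)
        assert component_auc(g) == 0.0

    def test_matches_quadrature_over_eight_sigma(self):
        g = GaussianComponent(ComponentRole.WATER_WEAK_3458, 3458, 10.0, 2.0)
        x = np.linspace(3458 - 80, 3458 + 80, 20001)
        numeric = np.trapezoid(g.evaluate(x), x)
        assert numeric == pytest.approx(g.auc, rel=1e-6)


class TestDeconvolveHwn:
    def test_noise_free_aucs_recovered_within_two_percent(self):
        hwn = hwn_with_ratios(TABLE_RATIOS)
        res = deconvolve_hwn(hwn.untreated[50.0][0])
        assert res.converged
        prof = water_profile(res, 50.0, None)
        for state, truth in TABLE_RATIOS.items():
            assert abs(prof.ratio(state) - truth) / truth < 0.02

    def test_zero_water_amplitudes(self):
        hwn = hwn_with_ratios({k: 1e-9 for k in TABLE_RATIOS})
        res = deconvolve_hwn(hwn.untreated[50.0][0])
        prof = water_profile(res, 50.0, None)
        protein = res.by_role()[ComponentRole.PROTEIN_2940]
        assert protein.auc > 0
        for state in TABLE_RATIOS:
            assert prof.ratio(state) < 1e-3

    def test_noisy_recovery_median_error(self, rng):
        """2% noise, 15 seeds: median ratio error well under 5% per state."""
        errs = {s: [] for s in TABLE_RATIOS}
        for seed in range(15):
            truth = {
                "tight": rng.uniform(0.1, 0.25), "strong": rng.uniform(3, 7),
                "weak": rng.uniform(1.5, 3.5), "free": rng.uniform(0.3, 1.3),
            }
            hwn = hwn_with_ratios(truth, seed=seed, noise_cv=0.02)
            prof = water_profile(deconvolve_hwn(hwn.untreated[50.0][0]), 50.0, None)
            for s, t in truth.items():
                errs[s].append(abs(prof.ratio(s) - t) / t)
        for s, e in errs.items():
            assert np.median(e) <= 0.05, s

    def test_insufficient_coverage_rejected(self):
        wn = np.arange(2800.0, 3500.0, 2.0)
        s = RamanSpectrum(wn, np.ones_like(wn), Region.HWN)
        with pytest.raises(CoverageError):
            deconvolve_hwn(s)

    def test_components_sorted_and_within_bounds(self):
        hwn = hwn_with_ratios(TABLE_RATIOS)
        res = deconvolve_hwn(hwn.untreated[50.0][0])
        centers = [c.center_cm1 for c in res.components]
        assert centers == sorted(centers)
        for c in res.components:
            assert abs(c.center_cm1 - NOMINAL_CENTERS[c.role]) <= 5.0 + 1e-9
            assert abs(c.sigma_cm1 - NOMINAL_SIGMAS[c.role]) <= 20.0 + 1e-9


class TestWaterProfile:
    def _components(self, water_ratios, protein_amp=10.0):
        comps = []
        protein_sigma = NOMINAL_SIGMAS[ComponentRole.PROTEIN_2940]
        protein_area = protein_amp * protein_sigma
        for role in NOMINAL_CENTERS:
            name = next((n for n, r in WATER_ROLES.items() if r is role), None)
            if name is not None:
                sigma = NOMINAL_SIGMAS[role]
                amp = water_ratios[name] * protein_area / sigma
            elif role is ComponentRole.PROTEIN_2940:
                amp, sigma = protein_amp, protein_sigma
            else:
                amp, sigma = 1.0, NOMINAL_SIGMAS[role]
            comps.append(GaussianComponent(role, NOMINAL_CENTERS[role], sigma, amp))
        return comps

    def test_total_water_is_sum_of_reported_state_ratios(self):
        prof = water_profile(self._components(TABLE_RATIOS), 50.0, None)
        assert prof.total_water == pytest.approx(10.42, abs=1e-10)

    def test_sum_rule_exact_identity(self):
        prof = water_profile(self._components(TABLE_RATIOS), 50.0, None)
        assert prof.total_water == pytest.approx(
            prof.tight + prof.strong + prof.weak + prof.free, abs=1e-12
        )

    def test_zero_water(self):
        prof = water_profile(
            self._components({k: 0.0 for k in TABLE_RATIOS}), 50.0, None
        )
        assert prof.total_water == 0.0

    def test_scale_invariance(self):
        comps = self._components(TABLE_RATIOS)
        doubled = [
            GaussianComponent(c.role, c.center_cm1, c.sigma_cm1, 2 * c.amplitude)
            for c in comps
        ]
        a = water_profile(comps, 50.0, None)
        b = water_profile(doubled, 50.0, None)
        assert b.strong == pytest.approx(a.strong, rel=1e-12)
        assert b.total_water == pytest.approx(a.total_water, rel=1e-12)

    def test_zero_protein_rejected(self):
        comps = self._components(TABLE_RATIOS, protein_amp=0.0)
        with pytest.raises(NormalizationError):
            water_profile(comps, 50.0, None)


class TestWaterKinetics:
    def _profile(self, depth, t, ratios):
        comps = TestWaterProfile()._components(ratios)
        return water_profile(comps, depth, t)

    def test_constant_profiles_give_flat_kinetics(self):
        profiles = [self._profile(50.0, t, TABLE_RATIOS) for t in (0.0, 30.0, 90.0)]
        kin = water_kinetics(profiles)
        strong = kin.table[kin.table.state == "strong"]["ratio"]
        assert strong.nunique() == 1
        assert not kin.insufficient

    def test_decaying_ratios_preserve_ordering(self):
        times = np.arange(0.0, 120.0, 30.0)
        profiles = [
            self._profile(
                50.0, t, {k: v * math.exp(-t / 60.0) for k, v in TABLE_RATIOS.items()}
            )
            for t in times
        ]
        kin = water_kinetics(profiles, after_time_s=90.0)
        strong = kin.table[kin.table.state == "strong"].sort_values("time_s")["ratio"]
        assert np.all(np.diff(strong) < 0)
        row = kin.summary[(kin.summary.state == "strong")].iloc[0]
        assert row.before > row.after

    def test_single_time_point_flagged_insufficient(self):
        kin = water_kinetics([self._profile(50.0, 30.0, TABLE_RATIOS)])
        assert kin.insufficient
        assert len(kin.summary) > 0  # summary still produced (before == after)


def test_edge_anchored_baseline_preserves_broad_bands():
    """Polynomial drift is removed without swallowing the OH envelope."""
    spec = SyntheticExperimentSpec(
        seed=3, depths_um=(50.0,), noise_cv=0.0, noise_floor=0.0,
        baseline_coeffs=(20.0, 10.0, -5.0),
    )
    hwn = synth_hwn_experiment(
        spec, water_ratios={50.0: {k: (v, v) for k, v in TABLE_RATIOS.items()}}
    )
    s = subtract_hwn_baseline(hwn.untreated[50.0][0])
    prof = water_profile(deconvolve_hwn(s), 50.0, None)
    for state, truth in TABLE_RATIOS.items():
        assert abs(prof.ratio(state) - truth) / truth < 0.05, state
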