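import math

import numpy as np
import pytest
from scipy.optimize import brentq

from cspscreen import (
    BindingParams,
    FragmentClass,
    SimulationConfig,
    bound_fraction,
    classify_fragment,
    fit_global,
    fit_residue,
    predict_csp,
    simulate_titration,
)
from cspscreen.csp import CSPProfile

from conftest import make_annotation15


def equilibrium_bound_fraction(p_total, l_total, kd):
    """Independent oracle: solve the mass balance for free ligand by root
    finding, then return [PL]/P_total."""
    if l_total == 0:
        return 0.0

    def balance(l_free):
        # L_total = L_free + P_total * L_free / (Kd + L_free)
        return l_free + p_total * l_free / (kd + l_free) - l_total

    l_free = brentq(balance, 0.0, l_total, xtol=1e-14, rtol=1e-15)
    return (l_free / (kd + l_free))


class TestBoundFraction:
    def test_zero_ligand_means_zero_binding(self):
        assert bound_fraction(100.0, 0.0, 105.0) == 0.0

    def test_stoichiometric_limit_saturates(self):
        assert bound_fraction(100.0, 400.0, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_equal_concentrations(self):
        # P = L = Kd = 100: (300 - sqrt(50000)) / 200
        expected = (300.0 - math.sqrt(50000.0)) / 200.0
        assert bound_fraction(100.0, 100.0, 100.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.381966, abs=1e-6)

    def test_agrees_with_equilibrium_root_finder_on_grid(self):
        grid = np.geomspace(1.0, 1000.0, 10)
        for p in grid:
            for l in grid:
                for kd in grid:
                    assert abs(
                        bound_fraction(p, l, kd) - equilibrium_bound_fraction(p, l, kd)
                    ) < 1e-9

    def test_hyperbolic_limit_at_negligible_protein(self):
        kd = 100.0
        p = kd * 1e-5
        for l in (10.0, 100.0, 1000.0):
            hyper = l / (l + kd)
            assert bound_fraction(p, l, kd) == pytest.approx(hyper, rel=1e-4)

    def test_monotone_in_ligand_and_kd(self):
        ls = np.linspace(0, 1000, 50)
        f = bound_fraction(100.0, ls, 105.0)
        assert np.all(np.diff(f) > 0)
        kds = np.geomspace(1, 1e4, 50)
        g = np.array([bound_fraction(100.0, 400.0, k) for k in kds])
        assert np.all(np.diff(g) < 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction(-1.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            bound_fraction(100.0, -1.0, 10.0)
        with pytest.raises(ValueError):
            bound_fraction(100.0, 10.0, 0.0)


class TestPredictCSP:
    def test_zero_ligand_gives_zero_csp(self):
        assert predict_csp(BindingParams(kd=105.0, dmax=0.05), 100.0, 0.0) == 0.0

    def test_saturation_reaches_dmax(self):
        val = predict_csp(BindingParams(kd=1e-9, dmax=0.05), 100.0, 400.0)
        assert val == pytest.approx(0.05, rel=1e-6)

    def test_scales_bound_fraction(self):
        val = predict_csp(BindingParams(kd=100.0, dmax=0.05), 100.0, 100.0)
        assert val == pytest.approx(0.05 * 0.3819660, rel=1e-6)
        assert val == pytest.approx(0.0190983, abs=1e-7)


class TestFitResidue:
    def test_noiseless_recovery_is_exact(self, clean_series):
        series, truth = clean_series
        res = sorted(truth.responsive_residues)[0]
        fit = fit_residue(series, res)
        assert fit.ok
        assert fit.params.kd == pytest.approx(105.0, rel=1e-6)
        assert fit.params.dmax == pytest.approx(truth.dmax[res], rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_residue_rejected_at_dmax_boundary(self, clean_series):
        series, truth = clean_series
        silent = sorted(set(range(1, 41)) - set(truth.responsive_residues))[0]
        fit = fit_residue(series, silent)
        assert not fit.ok
        assert "dmax" in fit.reason

    def test_grid_search_oracle_agrees_with_fit(self, clean_series):
        series, truth = clean_series
        res = sorted(truth.responsive_residues)[1]
        from cspscreen import extract_residue_csps

        concs, csps = extract_residue_csps(series, res)
        kd_grid = np.geomspace(1.0, 4000.0, 200)
        dmax_grid = np.geomspace(1e-3, 1.0, 200)
        sse = np.full((200, 200), np.inf)
        for i, kd in enumerate(kd_grid):
            model_frac = bound_fraction(series.protein_conc, concs, kd)
            for j, dmax in enumerate(dmax_grid):
                sse[i, j] = np.sum((dmax * model_frac - csps) ** 2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        fit = fit_residue(series, res)
        # fit optimum within one log-grid cell of the brute-force minimum
        assert abs(np.log(fit.params.kd) - np.log(kd_grid[i])) <= np.log(kd_grid[1] / kd_grid[0])
        assert abs(np.log(fit.params.dmax) - np.log(dmax_grid[j])) <= np.log(
            dmax_grid[1] / dmax_grid[0]
        )

    def test_too_few_points_raises(self):
        cfg = SimulationConfig(seed=3, ligand_concs=(0.0, 400.0), noise_h=0.0, noise_n=0.0)
        series, truth = simulate_titration(cfg)
        with pytest.raises(ValueError, match="3"):
            fit_residue(series, sorted(truth.responsive_residues)[0])


class TestFitGlobal:
    def test_single_residue_reduces_to_individual_fit(self, clean_series):
        series, truth = clean_series
        res = sorted(truth.responsive_residues)[0]
        single = fit_residue(series, res)
        result = fit_global(series, {res})
        assert result.kd == pytest.approx(single.params.kd, rel=1e-9)

    def test_five_noiseless_residues_shared_kd(self, clean_series):
        series, truth = clean_series
        result = fit_global(series, set(truth.responsive_residues))
        assert result.kd == pytest.approx(105.0, rel=1e-6)
        assert result.residues_used == set(truth.responsive_residues)
        assert not result.residues_rejected
        for res, dmax in result.per_residue_dmax.items():
            assert dmax == pytest.approx(truth.dmax[res], rel=1e-6)

    def test_noise_residue_rejected_kd_stable(self):
        rng_cfg = SimulationConfig(
            seed=11,
            noise_h=0.002,
            noise_n=0.01,
            responsive_residues=set(
                sorted(SimulationConfig(seed=0).functional_residues)[:4]
            ),
        )
        series, truth = simulate_titration(rng_cfg)
        clean = set(truth.responsive_residues)
        noise_res = sorted(set(range(1, 41)) - clean)[0]  # pure noise trace
        with_noise = fit_global(series, clean | {noise_res})
        assert noise_res in with_noise.residues_rejected
        clean_only = fit_global(series, clean)
        assert abs(with_noise.kd - clean_only.kd) <= 2 * max(
            with_noise.kd_stderr, clean_only.kd_stderr, 1e-9
        )

    def test_r2_cutoff_inclusive_at_boundary(self):
        # R^2 exactly at the cutoff is retained; strictly below is rejected
        cfg = SimulationConfig(
            seed=5,
            noise_h=0.004,
            noise_n=0.02,
            responsive_residues=set(
                sorted(SimulationConfig(seed=0).functional_residues)[:3]
            ),
        )
        series, truth = simulate_titration(cfg)
        residues = set(truth.responsive_residues)
        fits = {r: fit_residue(series, r) for r in residues}
        r2_values = sorted(fit.r_squared for fit in fits.values())
        boundary = r2_values[0]  # lowest observed R^2
        at = fit_global(series, residues, r2_cutoff=boundary)
        assert len(at.residues_used) == len(residues)
        just_above = fit_global(series, residues, r2_cutoff=boundary + 1e-12)
        assert len(just_above.residues_rejected) == 1

    def test_order_invariance(self, clean_series):
        series, truth = clean_series
        residues = sorted(truth.responsive_residues)
        a = fit_global(series, set(residues))
        b = fit_global(series, set(reversed(residues)))
        assert a.kd == pytest.approx(b.kd, rel=1e-12)
        assert a.per_residue_dmax == b.per_residue_dmax

    def test_all_rejected_raises(self):
        cfg = SimulationConfig(seed=9, scenario="nonbinder", noise_h=0.0, noise_n=0.0)
        series, _ = simulate_titration(cfg)
        with pytest.raises(ValueError, match="no fit-worthy"):
            fit_global(series, {1, 2, 3})


class TestClassifyFragment:
    def _fit(self, kd):
        from cspscreen import GlobalFitResult

        return GlobalFitResult(
            fragment_id="f",
            kd=kd,
            kd_stderr=kd * 0.1,
            per_residue_dmax={1: 0.05},
            residues_used={1},
        )

    def _profile(self, shifter_residues, background_residues):
        values = {r: 0.08 for r in shifter_residues}
        values.update({r: 0.002 for r in background_residues})
        return CSPProfile(fragment_id="f", ligand_conc=400.0, values=values)

    def test_localized_tight_binder_is_hit(self):
        ann = make_annotation15()
        prof = self._profile({1, 2, 3, 4, 5}, set(range(21, 40)))
        assert classify_fragment(self._fit(105.0), prof, ann) is FragmentClass.HIT

    def test_localized_weak_binder(self):
        ann = make_annotation15()
        prof = self._profile({1, 2, 3, 4, 5}, set(range(21, 40)))
        assert classify_fragment(self._fit(2500.0), prof, ann) is FragmentClass.WEAK

    def test_delocalized_shifters_are_nonspecific(self):
        ann = make_annotation15()
        # 1 of 5 shifters in the interface region -> locality 0.2
        prof = self._profile({1, 31, 32, 33, 34}, set(range(21, 28)))
        assert classify_fragment(self._fit(300.0), prof, ann) is FragmentClass.NONSPECIFIC

    def test_missing_fit_raises(self):
        ann = make_annotation15()
        prof = self._profile({1, 2}, {30, 31})
        with pytest.raises(ValueError):
            classify_fragment(None, prof, ann)


class TestParameterRecovery:
    def test_median_kd_and_stderr_coverage(self):
        """Recovery across seeded noisy titrations at the standard design."""
        responsive = set(sorted(SimulationConfig(seed=0).functional_residues)[:5])
        kds, covered = [], 0
        n = 40
        for seed in range(n):
            cfg = SimulationConfig(seed=seed, responsive_residues=responsive)
            series, _ = simulate_titration(cfg)
            result = fit_global(series, responsive)
            kds.append(result.kd)
            if abs(result.kd - 105.0) <= 2.0 * result.kd_stderr:
                covered += 1
        assert abs(np.median(kds) - 105.0) / 105.0 < 0.20
        assert covered / n >= 0.90
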