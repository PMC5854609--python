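"""Assay analysis: ELISpot rule, ICS decomposition, EC50 fit, lysis."""

import itertools

import numpy as np
import pytest
from scipy import stats

from neoscreen.assays import (
    COMBINATIONS,
    CYTOKINES,
    DoseResponseSeries,
    ElispotPlate,
    KillingAssay,
    call_elispot,
    compare_avidity,
    decompose_polyfunctionality,
    fit_ec50,
    four_pl,
    specific_lysis,
)


def _plate(label, counts):
    return ElispotPlate(condition_label=label, replicate_spot_counts=tuple(counts))


class TestElispot:
    def test_printed_worked_rule(self):
        # neg [10,12,14]: mean 12, sample sd 2, threshold 18; mean 20 is positive
        calls = call_elispot([_plate("No Ag", [10, 12, 14]), _plate("pep", [19, 20, 21])])
        call = calls[0]
        assert call.neg_mean == 12 and call.neg_sd == 2 and call.threshold == 18
        assert call.mean_spots == 20 and call.positive

    def test_degenerate_zero_sd_strict_inequality(self):
        calls = call_elispot([_plate("No Ag", [0, 0, 0]), _plate("pep", [0, 0, 0])])
        assert calls[0].threshold == 0 and not calls[0].positive

    def test_missing_negative_errors(self):
        with pytest.raises(ValueError, match="No Ag"):
            call_elispot([_plate("pep", [1, 2, 3])])

    def test_single_replicate_flagged(self):
        calls = call_elispot([_plate("No Ag", [1, 2, 3]), _plate("pep", [50])])
        assert calls[0].warning and calls[0].positive

    def test_pha_reported_not_called(self):
        calls = call_elispot([_plate("No Ag", [1, 2, 3]), _plate("PHA", [900, 950, 1000])])
        pha = [c for c in calls if c.condition_label == "PHA"][0]
        assert not pha.positive and "viability" in pha.warning

    def test_replicate_order_invariance(self):
        a = call_elispot([_plate("No Ag", [10, 12, 14]), _plate("pep", [19, 20, 21])])
        b = call_elispot([_plate("No Ag", [14, 10, 12]), _plate("pep", [21, 19, 20])])
        assert a == b

    def test_common_shift_preserves_decision_pattern(self):
        # adding a constant k to both condition and negative wells shifts
        # means but leaves sd and the decision pattern unchanged
        rng = np.random.default_rng(5)
        for _ in range(20):
            neg = rng.integers(0, 30, size=3)
            cond = rng.integers(0, 60, size=3)
            k = int(rng.integers(1, 50))
            base = call_elispot([_plate("No Ag", neg), _plate("pep", cond)])
            shift = call_elispot([_plate("No Ag", neg + k), _plate("pep", cond + k)])
            assert base[0].positive == shift[0].positive
            assert shift[0].neg_sd == pytest.approx(base[0].neg_sd)


class TestIcs:
    def test_all_triple_positive(self):
        events = np.ones((100, 3), dtype=bool)
        bg = np.zeros((100, 3), dtype=bool)
        summary = decompose_polyfunctionality(events, bg)
        assert summary.frequencies["IFNg+TNFa+IL2"] == pytest.approx(1.0)
        assert not summary.empty
        assert sum(summary.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_stimulated_equals_background_is_empty(self):
        rng = np.random.default_rng(0)
        events = rng.random((200, 3)) < 0.3
        summary = decompose_polyfunctionality(events, events.copy())
        assert summary.empty
        assert all(v == 0.0 for v in summary.frequencies.values())

    def test_random_table_matches_subset_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        stim = rng.random((3000, 3)) < rng.random(3) * 0.6
        bg = rng.random((3000, 3)) < 0.05
        summary = decompose_polyfunctionality(stim, bg)

        # oracle: exhaustively count each of the 8 subsets in both wells
        def counts(events):
            out = {}
            for bits in itertools.product((False, True), repeat=3):
                out[bits] = int(np.sum(np.all(events == np.array(bits), axis=1)))
            return out

        cs, cb = counts(stim), counts(bg)
        adj = {}
        for combo in COMBINATIONS:
            bits = tuple(c in combo for c in CYTOKINES)
            adj[combo] = max(cs[bits] / len(stim) - cb[bits] / len(bg), 0.0)
        total = sum(adj.values())
        for combo in COMBINATIONS:
            key = "+".join(combo)
            assert summary.frequencies[key] == pytest.approx(adj[combo] / total, abs=1e-12)


class TestEc50:
    def _series(self, ec50, hill=1.0, upper=100.0, noise=0.0, rng=None, n_doses=8):
        conc = np.logspace(-3, 3, n_doses) * ec50  # spans 6 logs around ec50
        resp = upper / (1.0 + (ec50 / conc) ** hill)
        if noise:
            resp = np.clip(resp * (1 + noise * rng.standard_normal(len(conc))), 0, None)
        return DoseResponseSeries(concentrations=tuple(conc), responses=tuple(resp))

    def test_noise_free_exact_inversion(self):
        est = fit_ec50(self._series(1.0), n_bootstrap=0)
        assert est.converged and not est.unreliable
        assert est.ec50 == pytest.approx(1.0, rel=1e-6)
        assert est.hill_slope == pytest.approx(1.0, rel=1e-4)

    def test_flat_zero_response_unreliable(self):
        series = DoseResponseSeries(concentrations=(0.01, 0.1, 1.0, 10.0),
                                    responses=(0.0, 0.0, 0.0, 0.0))
        est = fit_ec50(series, n_bootstrap=0)
        assert est.unreliable and est.ec50 is None

    def test_too_few_concentrations_error(self):
        series = DoseResponseSeries(concentrations=(0.1, 1.0, 10.0),
                                    responses=(1.0, 50.0, 99.0))
        with pytest.raises(ValueError, match="4 distinct"):
            fit_ec50(series, n_bootstrap=0)

    def test_scale_equivariance(self):
        base = self._series(0.5)
        scaled = DoseResponseSeries(
            concentrations=tuple(c * 37.0 for c in base.concentrations),
            responses=base.responses)
        a = fit_ec50(base, n_bootstrap=0)
        b = fit_ec50(scaled, n_bootstrap=0)
        assert b.ec50 == pytest.approx(a.ec50 * 37.0, rel=1e-5)

    def test_bootstrap_ci_covers_estimate_and_is_seeded(self):
        rng = np.random.default_rng(3)
        series = self._series(0.2, noise=0.1, rng=rng)
        a = fit_ec50(series, n_bootstrap=50, seed=9)
        b = fit_ec50(series, n_bootstrap=50, seed=9)
        assert a.bootstrap_ci == b.bootstrap_ci
        lo, hi = a.bootstrap_ci
        assert lo <= a.ec50 <= hi

    def test_noisy_recovery_beats_grid_oracle(self):
        # independent oracle: dense grid over (log ec50, hill) with data-driven
        # asymptotes; the refined fit should recover the truth at least as well
        rng = np.random.default_rng(11)
        rel_err_fit, rel_err_grid = [], []
        for _ in range(25):
            ec50 = 10.0 ** rng.uniform(-2, 2)
            series = self._series(ec50, noise=0.1, rng=rng)
            est = fit_ec50(series, n_bootstrap=0)
            rel_err_fit.append(abs(est.ec50 - ec50) / ec50)
            x = np.log10(series.concentrations)
            y = np.asarray(series.responses)
            grid = [(le, h) for le in np.linspace(x.min(), x.max(), 200)
                    for h in (0.5, 1.0, 2.0)]
            sse = [((four_pl(x, y.min(), y.max(), le, h) - y) ** 2).sum() for le, h in grid]
            le_best = grid[int(np.argmin(sse))][0]
            rel_err_grid.append(abs(10 ** le_best - ec50) / ec50)
        assert np.median(rel_err_fit) <= np.median(rel_err_grid) * 1.05


class TestCompareAvidity:
    def test_identical_groups_p_one(self):
        res = compare_avidity({"TIL": [1.0, 2.0, 3.0], "PBL": [1.0, 2.0, 3.0]})
        assert res["pvalue"] == pytest.approx(1.0)
        assert res["median_ratio"] == pytest.approx(1.0)

    def test_tenfold_separation_ratio(self):
        til = [0.1, 0.100001, 0.0999999]
        pbl = [1.0, 1.000001, 0.999999]
        res = compare_avidity({"TIL": til, "PBL": pbl})
        assert res["median_ratio"] == pytest.approx(0.1, rel=1e-4)
        assert res["pvalue"] < 1e-4

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            compare_avidity({"TIL": [1.0], "PBL": [1.0, 2.0]})

    def test_mann_whitney_matches_rank_permutation_enumeration(self):
        # tie-free small samples: enumerate all rank assignments by brute force
        a = [0.11, 0.52, 0.93, 1.7]
        b = [0.27, 3.1, 5.4]
        u_obs = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        pooled = a + b
        n, m = len(a), len(b)
        us = []
        for combo in itertools.combinations(range(n + m), n):
            grp_a = [pooled[i] for i in combo]
            grp_b = [pooled[i] for i in range(n + m) if i not in combo]
            u = sum(1 for x in grp_a for y in grp_b if x > y)
            us.append(u)
        us = np.array(us)
        u = u_obs.statistic
        lo = min(u, n * m - u)
        p_enum = min(1.0, (np.sum(us <= lo) + np.sum(us >= n * m - lo)) / len(us))
        assert u_obs.pvalue == pytest.approx(p_enum, abs=1e-12)


class TestSpecificLysis:
    @pytest.mark.parametrize("exp,spont,total,expected", [
        (1000.0, 100.0, 1000.0, 100.0),
        (100.0, 100.0, 1000.0, 0.0),
        (550.0, 100.0, 1000.0, 50.0),
    ])
    def test_formula(self, exp, spont, total, expected):
        res = specific_lysis(KillingAssay(exp, spont, total))
        assert res.percent == pytest.approx(expected)
        assert not res.out_of_range

    def test_out_of_range_flagged(self):
        res = specific_lysis(KillingAssay(1100.0, 100.0, 1000.0))
        assert res.percent > 100 and res.out_of_range

    def test_invalid_denominator_errors(self):
        with pytest.raises(ValueError):
            KillingAssay(500.0, 1000.0, 1000.0)

    def test_strictly_increasing_in_experimental(self):
        vals = [specific_lysis(KillingAssay(e, 100.0, 1000.0)).percent
                for e in np.linspace(0, 1200, 13)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
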