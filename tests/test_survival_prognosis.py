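import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank
from sklearn.metrics import roc_auc_score

from conftest import make_synthetic
from mhcscreen.io_formats import ClinicalTable, ExpressionMatrix
from mhcscreen.survival_prognosis import (
    combined_stratify,
    expression_tertiles,
    km_estimate,
    logrank,
    prognostic_roc,
    tertile_labels,
)


def brute_force_km(time, event):
    """Independent oracle: recompute the product limit by explicit risk sets."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    out = []
    s = 1.0
    for t in sorted(set(time[event])):
        at_risk = sum(1 for x in time if x >= t)
        deaths = sum(1 for x, e in zip(time, event) if e and x == t)
        s *= 1 - deaths / at_risk
        out.append((t, s))
    return out


def brute_force_logrank(ta, ea, tb, eb):
    """Independent oracle: explicit hypergeometric sums."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, bool)
    tb, eb = np.asarray(tb, float), np.asarray(eb, bool)
    o = e = v = 0.0
    for t in sorted(set(np.r_[ta[ea], tb[eb]])):
        na = np.sum(ta >= t)
        nb = np.sum(tb >= t)
        n = na + nb
        d = np.sum(ea & (ta == t)) + np.sum(eb & (tb == t))
        o += np.sum(ea & (ta == t))
        e += na * d / n
        if n > 1:
            v += d * (n - d) * na * nb / (n * n * (n - 1))
    return (o - e) ** 2 / v


def brute_force_auc(score, y):
    """Pair counting: (concordant + 0.5 * ties) / (cases * controls)."""
    cases = [s for s, yy in zip(score, y) if yy]
    controls = [s for s, yy in zip(score, y) if not yy]
    num = 0.0
    for c in cases:
        for k in controls:
            num += 1.0 if c > k else (0.5 if c == k else 0.0)
    return num / (len(cases) * len(controls))


class TestKM:
    def test_all_censored_survival_is_one(self):
        ct = ClinicalTable(["a", "b", "c"], [1, 2, 3], [0, 0, 0])
        km = km_estimate(ct)
        assert km.event_times.size == 0
        assert km.at(10.0) == 1.0

    def test_three_events_closed_form(self):
        ct = ClinicalTable(["a", "b", "c"], [1, 2, 3], [1, 1, 1])
        km = km_estimate(ct)
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_matches_brute_force_and_lifelines(self, clinical_20):
        km = km_estimate(clinical_20)
        oracle = brute_force_km(clinical_20.time, clinical_20.event)
        np.testing.assert_allclose(km.event_times, [t for t, _ in oracle])
        np.testing.assert_allclose(km.survival, [s for _, s in oracle])
        kmf = KaplanMeierFitter().fit(clinical_20.time, clinical_20.event)
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-10)

    def test_no_censoring_last_point_is_empirical_fraction(self, rng):
        time = rng.exponential(10, size=25)
        ct = ClinicalTable([f"s{i}" for i in range(25)], time, np.ones(25, int))
        km = km_estimate(ct)
        assert km.survival[-1] == pytest.approx(0.0, abs=1e-12)
        t_mid = np.median(time)
        frac_alive = np.mean(time > t_mid)
        assert km.at(t_mid) == pytest.approx(frac_alive, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate(ClinicalTable([], [], []))


class TestLogRank:
    def test_identical_groups_chi_zero(self, clinical_20):
        res = logrank(clinical_20, clinical_20)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_swap_symmetry(self, clinical_20, rng):
        other = ClinicalTable(
            [f"o{i}" for i in range(15)],
            rng.exponential(20, size=15) + 0.5,
            rng.integers(0, 2, size=15) | np.r_[1, np.zeros(14, int)],
        )
        ab = logrank(clinical_20, other)
        ba = logrank(other, clinical_20)
        assert ab.chi_square == pytest.approx(ba.chi_square)
        assert ab.p == pytest.approx(ba.p)

    def test_matches_brute_force_and_lifelines(self, clinical_20, rng):
        other = ClinicalTable(
            [f"o{i}" for i in range(20)],
            np.round(rng.exponential(15, size=20), 0) + 1.0,
            np.r_[np.ones(10, int), rng.integers(0, 2, size=10)],
        )
        res = logrank(clinical_20, other)
        chi_oracle = brute_force_logrank(clinical_20.time, clinical_20.event,
                                         other.time, other.event)
        assert res.chi_square == pytest.approx(chi_oracle, rel=1e-12)
        ref = ll_logrank(clinical_20.time, other.time,
                         clinical_20.event, other.event)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_observed_plus_expected_balance(self, clinical_20, rng):
        other = ClinicalTable(
            [f"o{i}" for i in range(12)],
            rng.exponential(25, size=12) + 0.1,
            np.ones(12, int),
        )
        res = logrank(clinical_20, other)
        assert sum(res.observed) == pytest.approx(sum(res.expected), abs=1e-9)

    def test_zero_variance_errors(self):
        a = ClinicalTable(["a"], [1.0], [1])
        b = ClinicalTable(["b"], [1.0], [1])
        with pytest.raises(ValueError, match="variance"):
            logrank(a, b)

    def test_invariant_under_monotone_time_transform(self, clinical_20, rng):
        other = ClinicalTable(
            [f"o{i}" for i in range(15)],
            rng.exponential(20, size=15) + 0.5,
            np.ones(15, int),
        )
        base = logrank(clinical_20, other)
        sq = logrank(
            ClinicalTable(clinical_20.sample_ids, clinical_20.time**2,
                          clinical_20.event),
            ClinicalTable(other.sample_ids, other.time**2, other.event),
        )
        assert sq.chi_square == pytest.approx(base.chi_square, rel=1e-12)

    def test_power_with_planted_hazard(self):
        """Strong planted effect: tertile log-rank rejects in every tried seed."""
        for seed in range(10):
            _, _, expr, clinical, _ = make_synthetic(
                seed=seed, n_samples=459, n_noise_genes=5, hazard_beta=1.0
            )
            groups = expression_tertiles(expr, ["HLA-A", "HLA-B", "HLA-C"])
            res = logrank(clinical.subset(groups.high), clinical.subset(groups.low))
            assert res.p < 0.05


class TestStratification:
    def test_expression_tertiles_gene_set_mean(self, rng):
        genes = ["A", "B"]
        vals = np.vstack([np.arange(9.0), np.arange(9.0)[::-1]])
        vals[1, 0] = -100  # drags sample 0's mean down
        expr = ExpressionMatrix(genes, [f"S{i}" for i in range(9)], vals)
        groups = expression_tertiles(expr, genes)
        assert "S0" in groups.low

    def test_combined_same_groups_is_identity(self, rng):
        g = tertile_labels([f"S{i}" for i in range(9)], rng.normal(size=9))
        combo = combined_stratify(g, g)
        assert combo.labels == g.labels

    def test_combined_disjoint_highs_errors(self):
        ids = [f"S{i}" for i in range(9)]
        g1 = tertile_labels(ids, np.arange(9.0))
        g2 = tertile_labels(ids, -np.arange(9.0))
        with pytest.raises(ValueError, match="stratum empty"):
            combined_stratify(g1, g2)

    def test_combined_independent_scores_expected_size(self, rng):
        # independent tertiles: |high & high| ~ Binomial(n, 1/9)
        ids = [f"S{i}" for i in range(900)]
        g1 = tertile_labels(ids, rng.normal(size=900))
        g2 = tertile_labels(ids, rng.normal(size=900))
        combo = combined_stratify(g1, g2)
        assert 60 <= len(combo.high) <= 145

    def test_different_universes_error(self, rng):
        g1 = tertile_labels(["a", "b", "c"], [1, 2, 3])
        g2 = tertile_labels(["a", "b", "d"], [1, 2, 3])
        with pytest.raises(ValueError, match="universe"):
            combined_stratify(g1, g2)


class TestPrognosticROC:
    def _clinical(self, time, event):
        ids = [f"s{i}" for i in range(len(time))]
        return ids, ClinicalTable(ids, time, event)

    def test_perfect_separation(self):
        ids, ct = self._clinical([10, 20, 90, 80], [1, 1, 0, 0])
        roc = prognostic_roc(ids, [1.0, 2.0, 9.0, 8.0], ct, horizon_months=60)
        assert roc.auc == pytest.approx(1.0)

    def test_constant_score(self):
        ids, ct = self._clinical([10, 20, 90, 80], [1, 1, 0, 0])
        roc = prognostic_roc(ids, [5.0] * 4, ct, horizon_months=60)
        assert roc.auc == pytest.approx(0.5)

    def test_censored_before_horizon_excluded(self):
        ids, ct = self._clinical([10, 30, 90, 70], [1, 0, 0, 1])
        roc = prognostic_roc(ids, [1.0, 2.0, 3.0, 4.0], ct, horizon_months=60)
        # s1 censored at 30 is dropped; s3's event at 70 is beyond the horizon
        assert roc.n_cases == 1 and roc.n_controls == 2

    def test_no_cases_errors(self):
        ids, ct = self._clinical([90, 80], [0, 0])
        with pytest.raises(ValueError, match="case"):
            prognostic_roc(ids, [1.0, 2.0], ct, horizon_months=60)

    def test_matches_pair_counting_and_sklearn(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            time = r.exponential(50, size=50)
            event = r.integers(0, 2, size=50)
            score = r.normal(size=50) + 0.02 * time
            ids = [f"s{i}" for i in range(50)]
            ct = ClinicalTable(ids, time, event)
            try:
                roc = prognostic_roc(ids, score, ct, horizon_months=40)
            except ValueError:
                continue
            is_case = (event == 1) & (time <= 40)
            keep = is_case | (time > 40)
            oracle = brute_force_auc(-score[keep], is_case[keep])
            assert roc.auc == pytest.approx(oracle, abs=1e-12)
            assert roc.auc == pytest.approx(
                roc_auc_score(is_case[keep], -score[keep]), abs=1e-12
            )

    def test_invariant_under_monotone_score_transform(self, rng):
        time = rng.exponential(50, size=60)
        event = np.ones(60, int)
        score = rng.normal(size=60)
        ids = [f"s{i}" for i in range(60)]
        ct = ClinicalTable(ids, time, event)
        base = prognostic_roc(ids, score, ct, horizon_months=40)
        warped = prognostic_roc(ids, np.exp(score), ct, horizon_months=40)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)

    def test_combined_score_beats_singles_with_planted_hazard(self):
        """Mirrors the qualitative figure claim: combining both planted effects
        should not fall behind either alone in most seeds."""
        wins = 0
        n_seeds = 15
        for seed in range(n_seeds):
            _, _, expr, clinical, _ = make_synthetic(
                seed=seed, n_samples=459, n_noise_genes=5, hazard_beta=0.8
            )
            mhc = expr.subset_genes(["HLA-A", "HLA-B", "HLA-C"]).values.mean(axis=0)
            tap = expr.subset_genes(["TAP1", "TAP2"]).values.mean(axis=0)
            combined = ((mhc - mhc.mean()) / mhc.std()
                        + (tap - tap.mean()) / tap.std())
            ids = expr.sample_ids
            auc_m = prognostic_roc(ids, mhc, clinical, 60).auc
            auc_t = prognostic_roc(ids, tap, clinical, 60).auc
            auc_c = prognostic_roc(ids, combined, clinical, 60).auc
            wins += auc_c >= min(auc_m, auc_t)
        assert wins >= int(0.8 * n_seeds)
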