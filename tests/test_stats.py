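"""Group assignment, test selection, FDR, partial Spearman, edgewise contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dfncstates import (
    assign_groups,
    chi_squared,
    compare_groups,
    edgewise_state_comparison,
    fdr_adjust,
    partial_spearman,
    temporal_metric_comparison,
)


def brute_force_bh(p):
    """Oracle: Benjamini–Hochberg step-up computed literally."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestAssignGroups:
    @pytest.mark.parametrize(
        "ess, expected",
        [(12, "EDS"), (10, "EDS"), (24, "EDS"), (3, "noEDS"), (0, "noEDS"),
         (4, "excluded"), (9, "excluded")],
    )
    def test_grouping_rule(self, ess, expected):
        assert assign_groups([ess])[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_groups([25])
        with pytest.raises(ValueError):
            assign_groups([-1])


class TestCompareGroups:
    def test_normal_data_uses_t_test(self, rng):
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30)])
        g = np.array(["EDS"] * 30 + ["noEDS"] * 30)
        res = compare_groups(x, g)
        assert res.test == "t"

    def test_outlier_contaminated_data_uses_mannwhitney(self, rng):
        a = rng.normal(0, 1, 30)
        a[:5] += 40
        x = np.concatenate([a, rng.normal(0, 1, 30)])
        g = np.array(["EDS"] * 30 + ["noEDS"] * 30)
        res = compare_groups(x, g)
        assert res.test == "mann-whitney"

    def test_identical_constant_samples_degenerate(self):
        x = np.full(20, 3.0)
        g = np.array(["EDS"] * 10 + ["noEDS"] * 10)
        res = compare_groups(x, g)
        assert res.test == "degenerate"
        assert res.p == 1.0 and res.statistic == 0.0
        assert res.flags

    def test_power_at_large_shift(self):
        # 1.5-pooled-SD location shift at n=16/41 is detected > 90% of the time
        g = np.array(["EDS"] * 16 + ["noEDS"] * 41)
        hits = 0
        reps = 500
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            x = np.concatenate([rng.normal(1.5, 1, 16), rng.normal(0, 1, 41)])
            hits += compare_groups(x, g).p < 0.05
        assert hits / reps > 0.9

    def test_excluded_subjects_ignored(self, rng):
        x = np.concatenate([rng.normal(0, 1, 20), [999.0]])
        g = np.array(["EDS"] * 10 + ["noEDS"] * 10 + ["excluded"])
        res = compare_groups(x, g)
        assert res.summaries["EDS"]["n"] == 10
        assert res.summaries["noEDS"]["n"] == 10


class TestFDR:
    def test_hand_computed_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_ones_stay_ones(self):
        assert np.all(fdr_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        for s in range(200):
            rng = np.random.default_rng(s)
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(fdr_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=25)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestPartialSpearman:
    def test_perfect_monotone_association(self, rng):
        ess = rng.integers(0, 25, 40).astype(float)
        rho, p = partial_spearman(ess, ess, covariates=rng.normal(size=(40, 2)))
        assert rho == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-10

    def test_reduces_to_spearman_without_covariates(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        rho, p = partial_spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_confound_removed_by_covariate(self):
        # x and y related only through the shared covariate z; averaging over
        # seeds: residualizing ranks on the raw covariate removes the linear
        # part, leaving a small rank-nonlinearity remainder (~0.2)
        raw, adj = [], []
        for s in range(10):
            rng = np.random.default_rng(s)
            z = rng.normal(size=200)
            x = z + 0.3 * rng.normal(size=200)
            y = z + 0.3 * rng.normal(size=200)
            raw.append(partial_spearman(x, y)[0])
            adj.append(partial_spearman(x, y, covariates=z)[0])
        assert np.mean(raw) > 0.85
        assert abs(np.mean(adj)) < 0.35
        assert abs(np.mean(adj)) < np.mean(raw) / 2

    def test_constant_metric_flagged(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = partial_spearman(np.ones(30), rng.normal(size=30))
        assert np.isnan(rho)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3], [1, 2, 3], covariates=np.ones((3, 2)))


class TestChiSquared:
    def test_reference_contingency_table(self):
        # 13/3 vs 23/18 male/female split
        cat = np.array(["M"] * 13 + ["F"] * 3 + ["M"] * 23 + ["F"] * 18)
        grp = np.array(["EDS"] * 16 + ["noEDS"] * 41)
        res = chi_squared(cat, grp)
        # independent oracle: Pearson chi-square from the closed 2x2 formula
        a, b, c, d = 13, 3, 23, 18
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(chi2, rel=1e-12)
        assert res.p == pytest.approx(sps.chi2.sf(chi2, 1), rel=1e-12)
        assert res.p == pytest.approx(0.077, abs=0.0015)

    def test_balanced_table_is_null(self):
        cat = np.array(["M", "F"] * 20)
        grp = np.array(["EDS"] * 20 + ["noEDS"] * 20)
        res = chi_squared(cat, grp)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association(self):
        cat = np.array(["M"] * 10 + ["F"] * 10)
        grp = np.array(["EDS"] * 10 + ["noEDS"] * 10)
        assert chi_squared(cat, grp).p < 0.001

    def test_empty_category_dropped_with_warning(self):
        cat = pd.Categorical(
            ["M"] * 10 + ["F"] * 10, categories=["M", "F", "other"]
        )
        grp = np.array(["EDS"] * 10 + ["noEDS"] * 10)
        with pytest.warns(UserWarning, match="empty"):
            res = chi_squared(cat, grp)
        assert res.summaries["dof"] == 1


class TestTemporalMetricComparison:
    def _metrics(self, rng, n=30):
        cols = {f"frac_time_s{s}": rng.normal(size=n) for s in range(1, 5)}
        cols |= {f"dwell_s{s}": rng.normal(size=n) for s in range(1, 5)}
        cols |= {f"dwell_sec_s{s}": rng.normal(size=n) for s in range(1, 5)}
        cols["n_transitions"] = rng.normal(size=n)
        cols["subject_id"] = [f"s{i}" for i in range(n)]
        return pd.DataFrame(cols)

    def test_family_is_nine_tests(self, rng):
        df = self._metrics(rng)
        g = np.array(["EDS"] * 15 + ["noEDS"] * 15)
        out = temporal_metric_comparison(df, g)
        assert len(out) == 9  # 4 fractional + 4 dwell + transitions
        assert not out["variable"].str.startswith("dwell_sec").any()
        assert np.all(out["q"] >= out["p"] - 1e-15)

    def test_per_metric_family_option(self, rng):
        df = self._metrics(rng)
        g = np.array(["EDS"] * 15 + ["noEDS"] * 15)
        out = temporal_metric_comparison(df, g, family="per-metric")
        assert out["q"].notna().all()

    def test_battery_familywise_error_controlled(self):
        # 9 null tests with BH at q<0.05: any-false-positive rate stays modest
        g = np.array(["EDS"] * 16 + ["noEDS"] * 41)
        fp = 0
        reps = 500
        for s in range(reps):
            rng = np.random.default_rng(5000 + s)
            df = self._metrics(rng, n=57)
            out = temporal_metric_comparison(df, g)
            fp += (out["q"] < 0.05).any()
        assert fp / reps <= 0.10


class TestEdgewise:
    def _tables(self, rng, delta=0.0, n_edges=60, edges_hit=(), n1=16, n2=41):
        subjects = [f"s{i}" for i in range(n1 + n2)]
        base = rng.normal(0, 0.1, (n1 + n2, n_edges))
        for e in edges_hit:
            base[:n1, e] += delta
        table = pd.DataFrame(base, index=subjects, columns=[f"e{i}" for i in range(n_edges)])
        groups = pd.Series(["EDS"] * n1 + ["noEDS"] * n2, index=subjects)
        return {1: table}, groups

    def test_planted_edges_recovered(self, rng):
        tables, groups = self._tables(rng, delta=0.3, edges_hit=(3, 10, 20, 30, 50))
        out = edgewise_state_comparison(tables, groups)[1]
        top5 = set(out.reindex(out["t"].abs().sort_values(ascending=False).index)["edge"].head(5))
        assert top5 == {"e3", "e10", "e20", "e30", "e50"}
        assert out.set_index("edge").loc[["e3", "e10", "e20", "e30", "e50"], "significant"].all()

    def test_null_groups_yield_few_discoveries(self):
        total = 0
        for s in range(10):
            rng = np.random.default_rng(7000 + s)
            tables, groups = self._tables(rng)
            total += int(edgewise_state_comparison(tables, groups)[1]["significant"].sum())
        assert total <= 5

    def test_single_differing_edge_has_minimum_p(self, rng):
        tables, groups = self._tables(rng, delta=0.5, edges_hit=(17,))
        out = edgewise_state_comparison(tables, groups)[1]
        assert out.loc[out["p"].idxmin(), "edge"] == "e17"

    def test_underpopulated_state_skipped_with_warning(self, rng):
        tables, groups = self._tables(rng, n1=1, n2=10)
        with pytest.warns(UserWarning, match="skipped"):
            out = edgewise_state_comparison(tables, groups)
        assert out == {}


class TestEdgewiseFamilies:
    def test_pooled_family_adjusts_across_states(self, rng):
        subjects = [f"s{i}" for i in range(20)]
        groups = pd.Series(["EDS"] * 10 + ["noEDS"] * 10, index=subjects)
        tables = {
            s: pd.DataFrame(rng.normal(size=(20, 8)), index=subjects,
                            columns=[f"e{i}" for i in range(8)])
            for s in (1, 2)
        }
        per_state = edgewise_state_comparison(tables, groups, family="per-state")
        pooled = edgewise_state_comparison(tables, groups, family="pooled")
        assert np.allclose(per_state[1]["p"], pooled[1]["p"])
        # pooled adjustment must match BH run on the concatenated p-vector
        all_p = np.concatenate([pooled[1]["p"], pooled[2]["p"]])
        want_q = brute_force_bh(all_p)
        got_q = np.concatenate([pooled[1]["q"], pooled[2]["q"]])
        assert np.allclose(got_q, want_q, atol=1e-12)
        assert len(pooled) == 2
        with pytest.raises(ValueError):
            edgewise_state_comparison(tables, groups, family="bonferroni")
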