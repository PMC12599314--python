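"""Unit and property tests for differential calling and profile tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phycovoc.chem import parse_formula
from phycovoc.differential import (
    CompoundRecord,
    aggregate_by_class,
    benjamini_hochberg,
    call_depletion,
    call_production,
    classify_compound,
    correlation_cluster,
    paired_t,
    pca_scores,
    permanova,
)
from phycovoc.signal_table import SignalTable


def nm_table(values: np.ndarray, prefix="s"):
    """values: signals x replicates array -> nM-level SignalTable."""
    values = np.atleast_2d(values)
    df = pd.DataFrame(
        values,
        index=[f"{40 + i}.05" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )
    return SignalTable(df, "nM")


class TestPairedT:
    def test_identical_series_degenerate(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_consistent_shift_significant(self, rng):
        x = np.ones(6) + rng.normal(0, 1e-3, 6)
        t, p = paired_t(x + 1.0, x)
        assert p < 1e-4

    def test_hand_computed_oracle(self):
        # textbook paired t on fixed vectors, computed from the definition
        x = np.array([5.1, 4.9, 5.0, 5.2, 4.8, 5.0])
        y = np.array([4.0, 3.9, 4.2, 4.1, 3.8, 4.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(6))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=5)
        t, p = paired_t(x, y)
        assert t == pytest.approx(t_hand, rel=1e-10)
        assert p == pytest.approx(p_hand, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


def bh_oracle(pvals):
    """Definition-based step-up: q_i = min_{j >= rank(i)} m p_(j) / j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestBenjaminiHochberg:
    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_step_up_hand_case(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_matches_definition_oracle_exhaustively(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9]
        for perm in itertools.permutations(grid):
            assert benjamini_hochberg(list(perm)) == pytest.approx(bh_oracle(perm))

    def test_order_preserving(self, rng):
        p = rng.uniform(size=40)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallProduction:
    def test_no_signal_no_calls(self, rng):
        base = rng.lognormal(0, 0.2, size=(20, 6))
        culture = nm_table(base, "c")
        blank = nm_table(rng.lognormal(0, 0.2, size=(20, 6)), "b")
        res = call_production(culture, blank)
        # a handful of chance calls at most under the null
        assert res["produced"].sum() <= 2

    def test_single_strong_signal_only(self, rng):
        vals = rng.lognormal(0, 0.1, size=(10, 6)) * 0.01
        vals[3] = 50.0 * rng.lognormal(0, 0.1, size=6)
        culture = nm_table(vals, "c")
        blank = nm_table(np.full((10, 6), 0.01), "b")
        res = call_production(culture, blank)
        assert res.loc[res.index[3], "produced"]

    def test_recall_and_fdr_with_planted_truth(self, rng):
        # 40 produced signals at >= 5x the blank level, 32 nulls
        n_sig, n_null, n_rep = 40, 32, 6
        blank_level = 1.0
        culture = np.vstack(
            [
                blank_level * 5 * rng.lognormal(0, 0.2, size=(n_sig, n_rep)),
                blank_level * rng.lognormal(0, 0.2, size=(n_null, n_rep)),
            ]
        )
        blank = blank_level * rng.lognormal(0, 0.2, size=(n_sig + n_null, n_rep))
        res = call_production(nm_table(culture, "c"), nm_table(blank, "b"))
        called = res["produced"].values
        recall = called[:n_sig].mean()
        fdr = called[n_sig:].sum() / max(called.sum(), 1)
        assert recall >= 0.9
        assert fdr <= 0.1


class TestCallDepletion:
    def test_identical_tables_no_calls(self, rng):
        vals = rng.lognormal(0, 0.2, size=(15, 6))
        ax = nm_table(vals, "a")
        co = nm_table(vals, "c")
        res = call_depletion(ax, co, 1e6)
        assert not any(r.significant for r in res)

    def test_inflated_coculture_never_depleted(self, rng):
        ax = nm_table(rng.lognormal(0, 0.1, size=(10, 6)), "a")
        co = nm_table(ax.data.values * 10.0, "c")
        res = call_depletion(ax, co, 1e6)
        assert not any(r.significant for r in res)

    def test_full_consumption_per_cell_amount(self):
        ax = nm_table(np.full((1, 6), 8.0), "a")
        co = nm_table(np.zeros((1, 6)), "c")
        (r,) = call_depletion(ax, co, 2e6)
        # 8 nM depleted across 2e6 cells/ml -> fmol per bacterial cell
        assert r.percell_depletion == pytest.approx(8e-9 * 1e15 / 2e9)
        assert r.significant

    def test_zero_density_rejected(self, rng):
        t = nm_table(rng.lognormal(0, 0.1, size=(3, 6)))
        with pytest.raises(ValueError):
            call_depletion(t, t, 0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "formula,klass",
        [
            ("C11H16", "hydrocarbon"),
            ("C6H6", "hydrocarbon"),
            ("C2H6S", "S-containing"),
            ("C2H3N", "N-containing"),
            ("CH4O", "O-containing"),
            ("C2H5NOS", "S-containing"),  # precedence S > N > O
            ("C3H7NO2", "N-containing"),  # precedence N > O
        ],
    )
    def test_classes(self, formula, klass):
        assert classify_compound(parse_formula(formula)) == klass

    def test_unknown_formula(self):
        assert classify_compound(None) == "unidentified"


class TestAggregateByClass:
    def test_reported_pool_fractions(self):
        # per-cell pools printed for the exponential phase: hydrocarbons
        # 52.4 of 84.9 total -> ~61.7%
        records = [
            CompoundRecord("79.05", parse_formula("C6H6")),
            CompoundRecord("33.03", parse_formula("CH4O")),
        ]
        agg = aggregate_by_class({"79.05": 52.4, "33.03": 84.9 - 52.4}, records)
        assert agg.loc["hydrocarbon", "fraction"] == pytest.approx(52.4 / 84.9)
        assert agg["fraction"].sum() == pytest.approx(1.0)

    def test_single_class(self):
        recs = [CompoundRecord("79.05", parse_formula("C6H6"))]
        agg = aggregate_by_class({"79.05": 5.0}, recs)
        assert agg.loc["hydrocarbon", "fraction"] == 1.0

    def test_empty_values_all_zero(self):
        agg = aggregate_by_class({}, [])
        assert (agg["total"] == 0).all() and (agg["fraction"] == 0).all()

    def test_missing_record_rejected(self):
        with pytest.raises(KeyError):
            aggregate_by_class({"99.99": 1.0}, [])


def average_linkage_oracle(matrix):
    """Brute-force average-linkage merge order on columns (correlation
    distance), for a handful of items."""
    cols = list(matrix.columns)
    clusters = {i: [c] for i, c in enumerate(cols)}
    corr = matrix.corr()
    merges = []
    next_id = len(cols)
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean(
                    [1 - corr.loc[x, y] for x in clusters[a] for y in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((sorted((tuple(sorted(clusters[a])), tuple(sorted(clusters[b]))))))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestCorrelationCluster:
    def _planted(self, rng):
        base1 = rng.normal(size=30)
        base2 = rng.normal(size=30)
        data = pd.DataFrame(
            {
                "A1": base1 + rng.normal(0, 0.05, 30),
                "A2": base1 + rng.normal(0, 0.05, 30),
                "B1": base2 + rng.normal(0, 0.05, 30),
                "B2": base2 + rng.normal(0, 0.05, 30),
            }
        )
        return data

    def test_identical_columns_zero_distance(self, rng):
        x = rng.normal(size=20)
        data = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        Z, labels = correlation_cluster(data)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self, rng):
        x = rng.normal(size=20)
        data = pd.DataFrame({"a": x, "b": -x})
        Z, _ = correlation_cluster(data)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_matches_bruteforce_merge_order(self, rng):
        data = self._planted(rng)
        Z, labels = correlation_cluster(data)
        oracle = average_linkage_oracle(data)
        # first oracle merges must pair A1/A2 and B1/B2 in some order
        first_two = {frozenset(m[0] + m[1]) for m in oracle[:2]}
        assert first_two == {frozenset({"A1", "A2"}), frozenset({"B1", "B2"})}
        # linkage: first two merges join leaves 0+1 and 2+3
        got = {frozenset(map(int, row[:2])) for row in Z[:2]}
        assert got == {frozenset({0, 1}), frozenset({2, 3})}

    def test_zero_variance_column_named(self):
        data = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_cluster(data)


class TestPermanova:
    def test_planted_separation_detected(self, rng):
        n, p = 6, 8
        a = rng.normal(0, 1, size=(n, p))
        b = rng.normal(5, 1, size=(n, p))  # 5 SD apart
        res = permanova(np.vstack([a, b]), ["a"] * n + ["b"] * n,
                        n_permutations=999, seed=42)
        assert res.p <= 0.01

    def test_null_data_not_rejected(self, rng):
        x = rng.normal(size=(12, 5))
        res = permanova(x, ["a"] * 6 + ["b"] * 6, n_permutations=499, seed=0)
        assert res.p > 0.05
        assert np.isfinite(res.statistic)

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(12, 4))
        groups = ["a"] * 6 + ["b"] * 6
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        r1 = permanova(x, groups, n_permutations=299, seed=5)
        r2 = permanova(x @ q, groups, n_permutations=299, seed=5)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        assert r1.p == r2.p

    def test_matches_scikit_bio_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        x = rng.normal(size=(10, 3))
        x[5:] += 1.5
        groups = ["a"] * 5 + ["b"] * 5
        res = permanova(x, groups, n_permutations=99, seed=1)
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(x)))
        sk = sk_permanova(dm, grouping=groups, permutations=99)
        assert res.statistic == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_single_member_group_rejected(self, rng):
        with pytest.raises(ValueError):
            permanova(rng.normal(size=(3, 2)), ["a", "a", "b"], 99, 0)

    def test_p_resolution(self, rng):
        x = rng.normal(size=(8, 3))
        res = permanova(x, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=3)
        assert res.p >= 1 / 100


class TestPca:
    def test_rank_one_single_component(self, rng):
        u = rng.normal(size=10)[:, None]
        v = rng.normal(size=4)[None, :]
        scores, evr = pca_scores(u @ v)
        assert evr[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        _, evr = pca_scores(rng.normal(size=(15, 6)))
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_no_dominant_axis(self, rng):
        _, evr = pca_scores(rng.normal(size=(200, 8)))
        assert evr.max() < 2.0 / 8

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca_scores(np.ones((1, 3)))
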