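import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexpair.stats import bh_fdr
from coexpair.survival import (Subnetwork, build_class_network,
                               cluster_patients_two_groups, combine_and_search,
                               detect_subnetworks, km_curve_table,
                               label_groups_by_survival, logrank_test,
                               normalize_cross_platform, nsc_classify,
                               screen_subnetworks, silhouette_width,
                               validate_signature)
from coexpair.types import ExpressionMatrix, SurvivalCohort
from conftest import make_matrix


def cohort_from(times, events, patients=None):
    patients = patients or [f"P{i}" for i in range(len(times))]
    return SurvivalCohort(pd.DataFrame({"patient": patients, "time": times,
                                        "event": events}))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def set_partitions(items):
    """All set partitions (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_best_modularity(g):
    best = -1.0
    for part in set_partitions(sorted(g.nodes)):
        q = nx.community.modularity(g, [set(c) for c in part])
        best = max(best, q)
    return best


def brute_force_logrank(times, events, groups):
    """Two-group log-rank: sum over event times of (O - E) with
    hypergeometric variance."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    event_times = sorted(df.loc[df["e"] == 1, "t"].unique())
    O_minus_E = 0.0
    V = 0.0
    for t in event_times:
        at_risk = df[df["t"] >= t]
        n = len(at_risk)
        n1 = int((at_risk["g"] == 1).sum())
        d = int(((df["t"] == t) & (df["e"] == 1)).sum())
        d1 = int(((df["t"] == t) & (df["e"] == 1) & (df["g"] == 1)).sum())
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E ** 2 / V


def brute_force_silhouette(D, labels):
    n = len(labels)
    widths = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            widths.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(np.mean([D[i, j] for j in range(n) if labels[j] == lab])
                for lab in set(labels) if lab != labels[i])
        widths.append((b - a) / max(a, b))
    return float(np.mean(widths)), widths


def brute_force_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order):
        q[i] = min(min(m * p[j] / (order.index(j) + 1)
                       for j in order[rank_pos:]), 1.0)
    return q


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class TestClassNetwork:
    def test_triangle(self):
        tbl = pd.DataFrame({"gene_a": ["A", "A", "B"],
                            "gene_b": ["B", "C", "C"],
                            "class": ["shared"] * 3})
        g = build_class_network(tbl, "shared")
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_disjoint_pairs_form_matching(self):
        tbl = pd.DataFrame({"gene_a": ["A", "C"], "gene_b": ["B", "D"],
                            "class": ["sc_specific"] * 2})
        g = build_class_network(tbl, "sc_specific")
        assert sorted(d for _, d in g.degree) == [1, 1, 1, 1]

    def test_empty_class_warns(self):
        tbl = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"],
                            "class": ["shared"]})
        g = build_class_network(tbl, "bulk_specific")
        assert g.number_of_nodes() == 0


class TestDetectSubnetworks:
    def test_two_cliques_joined_by_one_edge(self):
        g = nx.Graph()
        c1 = [f"a{i}" for i in range(5)]
        c2 = [f"b{i}" for i in range(5)]
        for grp in (c1, c2):
            g.add_edges_from(itertools.combinations(grp, 2))
        g.add_edge("a0", "b0")
        subs = detect_subnetworks(g, min_size=3, class_label="x")
        assert sorted(sorted(s.genes) for s in subs) == [sorted(c1), sorted(c2)]
        # greedy result attains the exhaustive-search optimum here
        q = nx.community.modularity(g, [set(c1), set(c2)])
        assert q == pytest.approx(brute_force_best_modularity(g), abs=1e-10)

    def test_single_clique_is_one_community(self):
        g = nx.complete_graph(5)
        subs = detect_subnetworks(g, min_size=3)
        assert len(subs) == 1 and len(subs[0].genes) == 5

    def test_empty_graph(self):
        assert detect_subnetworks(nx.Graph()) == []

    def test_min_size_filter(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        assert detect_subnetworks(g, min_size=3) == []

    def test_modularity_not_below_trivial_partition(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.15, seed=3)
        subs = detect_subnetworks(g, min_size=1)
        part = [set(s.genes) for s in subs]
        covered = set().union(*part) if part else set()
        part += [{n} for n in g.nodes if n not in covered]
        q = nx.community.modularity(g, part)
        assert q >= nx.community.modularity(g, [set(g.nodes)]) - 1e-12


# ---------------------------------------------------------------------------
# patient clustering + log-rank
# ---------------------------------------------------------------------------

def two_block_expr(n_per=6, seed=0, genes=8):
    rng = np.random.default_rng(seed)
    w = np.where(np.arange(genes) % 2 == 0, 1.0, -1.0)
    cols = {}
    for i in range(n_per):
        cols[f"good{i}"] = w + 0.1 * rng.normal(size=genes)
        cols[f"bad{i}"] = -w + 0.1 * rng.normal(size=genes)
    df = pd.DataFrame(cols, index=[f"G{k}" for k in range(genes)])
    return ExpressionMatrix(df, level="bulk", state="quantile_normalized")


class TestClusterPatients:
    def test_recovers_opposite_blocks(self):
        expr = two_block_expr()
        part = cluster_patients_two_groups(expr, expr.genes)
        good = {part[p] for p in part if p.startswith("good")}
        bad = {part[p] for p in part if p.startswith("bad")}
        assert len(good) == 1 and len(bad) == 1 and good != bad

    def test_duplicated_patients_co_assigned(self):
        expr = two_block_expr()
        dup = expr.values.copy()
        dup["good0_twin"] = dup["good0"]
        expr2 = ExpressionMatrix(dup, level="bulk", state="quantile_normalized")
        part = cluster_patients_two_groups(expr2, expr2.genes)
        assert part["good0"] == part["good0_twin"]

    def test_column_order_invariance(self):
        expr = two_block_expr()
        rev = ExpressionMatrix(expr.values.iloc[:, ::-1], level="bulk",
                               state="quantile_normalized")
        p1 = cluster_patients_two_groups(expr, expr.genes)
        p2 = cluster_patients_two_groups(rev, rev.genes)
        agree = np.mean([p1[k] == p2[k] for k in p1])
        assert agree in (0.0, 1.0)  # identical up to label swap

    def test_too_few_patients(self):
        expr = two_block_expr(n_per=1)
        with pytest.raises(ValueError, match="4 patients"):
            cluster_patients_two_groups(expr, expr.genes)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [5, 8, 12, 20]
        events = [1, 1, 0, 1]
        cohort = cohort_from(times * 2, events * 2)
        part = {f"P{i}": (1 if i < 4 else 2) for i in range(8)}
        stat, p = logrank_test(cohort, part)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_table(self):
        times = [3, 5, 7, 9, 11, 13]
        events = [1, 1, 1, 1, 0, 1]
        groups = [1, 2, 1, 2, 1, 2]
        cohort = cohort_from(times, events)
        part = {f"P{i}": groups[i] for i in range(6)}
        stat, _ = logrank_test(cohort, part)
        assert stat == pytest.approx(
            brute_force_logrank(times, events, groups), abs=1e-10)

    def test_one_empty_group_errors(self):
        cohort = cohort_from([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="two non-empty|two"):
            logrank_test(cohort, {f"P{i}": 1 for i in range(4)})


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=8)
        q = bh_fdr(p)
        assert np.allclose(q, brute_force_bh(list(p)), atol=1e-12)
        from statsmodels.stats.multitest import multipletests
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        assert np.all(bh_fdr(p) >= p - 1e-15)


class TestSilhouette:
    def test_matches_brute_force_small_instance(self):
        expr = two_block_expr(n_per=2, seed=1)
        part = cluster_patients_two_groups(expr, expr.genes)
        mean, widths = silhouette_width(expr, expr.genes, part)
        X = expr.values.to_numpy().T
        D = 1 - np.corrcoef(X)
        np.fill_diagonal(D, 0)
        labels = [part[p] for p in expr.samples]
        bf_mean, _ = brute_force_silhouette(D, labels)
        assert mean == pytest.approx(bf_mean, abs=1e-10)

    def test_separated_blocks_high_mean(self):
        expr = two_block_expr(n_per=8, seed=2)
        part = cluster_patients_two_groups(expr, expr.genes)
        mean, _ = silhouette_width(expr, expr.genes, part)
        assert mean > 0.8

    def test_random_partition_of_homogeneous_data_near_zero(self):
        rng = np.random.default_rng(3)
        expr = make_matrix(rng.normal(size=(10, 20)), level="bulk",
                           state="quantile_normalized")
        part = {p: (1 if i % 2 else 2) for i, p in enumerate(expr.samples)}
        mean, _ = silhouette_width(expr, expr.genes, part)
        assert abs(mean) < 0.2


# ---------------------------------------------------------------------------
# screening / combination search
# ---------------------------------------------------------------------------

def survival_scenario(seed=0):
    """One prognostic 4-gene module + one null module, 40 patients."""
    rng = np.random.default_rng(seed)
    n = 40
    groups = np.array([1] * (n // 2) + [2] * (n // 2))
    w = np.array([1.0, -1.0, 1.0, -1.0])
    sign = np.where(groups == 1, 1.0, -1.0)
    prog = np.vstack([w_i * sign * 0.75 + rng.normal(0, 0.4, n)
                      for w_i in w])
    null = rng.normal(size=(4, n))
    X = np.vstack([prog, null])
    patients = [f"P{i}" for i in range(n)]
    em = ExpressionMatrix(pd.DataFrame(X, index=[f"M{k}" for k in range(4)]
                                       + [f"N{k}" for k in range(4)],
                                       columns=patients),
                          level="bulk", state="quantile_normalized")
    lam = np.where(groups == 1, math.log(2) / 200, math.log(2) / 600)
    times = rng.exponential(1 / lam)
    cohort = cohort_from(times, [1] * n, patients)
    subnets = [Subnetwork("shared", frozenset(f"M{k}" for k in range(4)), "mod"),
               Subnetwork("sc_specific", frozenset(f"N{k}" for k in range(4)),
                          "null")]
    return em, cohort, subnets


class TestScreenAndCombine:
    def test_planted_module_retained(self):
        em, cohort, subnets = survival_scenario(seed=4)
        screened = screen_subnetworks(subnets, em, cohort)
        got = screened.set_index("id")
        assert got.loc["mod", "significant"]

    def test_single_significant_wins_as_itself(self):
        em, cohort, subnets = survival_scenario(seed=4)
        screened = screen_subnetworks(subnets, em, cohort)
        screened = screened[screened["id"] == "mod"].copy()
        result = combine_and_search(screened, em, cohort)
        assert result.subnetwork_ids == ("mod",)
        assert set(result.genes) == {f"M{k}" for k in range(4)}
        assert result.q >= result.p
        assert "shared" in result.composition

    def test_empty_screen_returns_none(self):
        em, cohort, subnets = survival_scenario(seed=4)
        screened = screen_subnetworks(subnets, em, cohort)
        screened["significant"] = False
        assert combine_and_search(screened, em, cohort) is None

    def test_fdr_universe_covers_singles_and_combos(self):
        em, cohort, subnets = survival_scenario(seed=4)
        extra = Subnetwork("bulk_specific",
                           frozenset(["M0", "M1", "N0"]), "mix")
        screened = screen_subnetworks(subnets + [extra], em, cohort)
        result = combine_and_search(screened, em, cohort, max_combo=3)
        n_sig = int(screened["significant"].sum())
        expected_units = len(screened) + sum(
            math.comb(n_sig, k) for k in range(2, min(3, n_sig) + 1))
        assert len(result.all_tested) == expected_units


# ---------------------------------------------------------------------------
# cross-platform validation
# ---------------------------------------------------------------------------

class TestCrossPlatform:
    def test_constant_shift_cancels(self):
        rng = np.random.default_rng(7)
        a = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        b = a + 3.7
        na, nb = normalize_cross_platform(a, b, "w")
        pd.testing.assert_frame_equal(na, nb)

    def test_identical_platforms_identical_outputs(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz"))
        na, nb = normalize_cross_platform(a, a.copy(), "x")
        pd.testing.assert_frame_equal(na, nb)

    def test_missing_reference_errors(self):
        a = pd.DataFrame(np.ones((2, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="reference"):
            normalize_cross_platform(a, a, "nope")

    def test_nsc_zero_shrinkage_matches_centroid_distances(self):
        train = pd.DataFrame({"p1": [0.0, 0.0], "p2": [0.2, -0.1],
                              "q1": [3.0, 3.1], "q2": [2.8, 3.0]},
                             index=["g1", "g2"])
        labels = {"p1": "lo", "p2": "lo", "q1": "hi", "q2": "hi"}
        test = pd.DataFrame({"t1": [0.1, 0.0], "t2": [3.2, 2.9]},
                            index=["g1", "g2"])
        pred = nsc_classify(train, labels, test, ["g1", "g2"],
                            thresholds=(0.0,))
        # hand check: centroids lo=(0.1,-0.05), hi=(2.9,3.05)
        assert pred == {"t1": "lo", "t2": "hi"}

    def test_fully_shrunk_predicts_one_class(self):
        rng = np.random.default_rng(9)
        train = pd.DataFrame(rng.normal(size=(3, 10)),
                             columns=[f"p{i}" for i in range(10)],
                             index=["g1", "g2", "g3"])
        labels = {f"p{i}": ("a" if i < 5 else "b") for i in range(10)}
        test = pd.DataFrame(rng.normal(size=(3, 6)),
                            columns=[f"t{i}" for i in range(6)],
                            index=["g1", "g2", "g3"])
        pred = nsc_classify(train, labels, test, ["g1", "g2", "g3"],
                            thresholds=(50.0,))
        assert len(set(pred.values())) == 1

    def test_single_class_training_errors(self):
        train = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="two classes"):
            nsc_classify(train, {c: "x" for c in "abcd"}, train, [0, 1])

    def test_label_groups_by_median_survival(self):
        cohort = cohort_from([10, 20, 400, 500], [1, 1, 1, 1])
        part = {"P0": 1, "P1": 1, "P2": 2, "P3": 2}
        named = label_groups_by_survival(part, cohort)
        assert named["P0"] == "poor" and named["P2"] == "favorable"


class TestKmCurve:
    def test_survival_is_monotone_decreasing(self):
        cohort = cohort_from([3, 6, 9, 12, 15, 18], [1, 1, 0, 1, 1, 1])
        part = {f"P{i}": (1 if i < 3 else 2) for i in range(6)}
        km = km_curve_table(cohort, part)
        for _, sub in km.groupby("group"):
            s = sub.sort_values("time")["survival"].to_numpy()
            assert np.all(np.diff(s) <= 1e-12)
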