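"""Survival-signature search over co-expression class networks.

The three class networks (shared, single-cell specific, bulk specific) are
decomposed into communities by greedy modularity maximization; each
community (and each combination of up to three log-rank-significant
communities) is scored by clustering the bulk patients on its genes and
comparing the survival of the two patient groups with a log-rank test.
The winner is validated on an independent cohort after reference-sample
cross-platform normalization and nearest-shrunken-centroid transfer of the
group labels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

from .stats import bh_fdr
from .types import ExpressionMatrix, SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Subnetwork:
    class_label: str
    genes: frozenset
    community_id: str

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class SignatureResult:
    subnetwork_ids: tuple[str, ...]
    genes: list[str]
    gene_classes: dict[str, str]
    partition: dict[str, int]
    statistic: float
    p: float
    q: float
    silhouette: float
    composition: str
    validation_p: float | None = None
    all_tested: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Networks and communities
# ---------------------------------------------------------------------------

def build_class_network(class_table: pd.DataFrame, cls: str) -> nx.Graph:
    """Graph whose edges are the gene pairs of one co-expression class."""
    sub = class_table[class_table["class"] == cls]
    g = nx.Graph()
    g.add_edges_from(zip(sub["gene_a"], sub["gene_b"]))
    if g.number_of_nodes() == 0:
        logger.warning("class %r has no pairs; empty network", cls)
    return g


def detect_subnetworks(g: nx.Graph, min_size: int = 3,
                       class_label: str = "") -> list[Subnetwork]:
    """Communities by greedy agglomerative modularity maximization.

    Clauset-Newman-Moore scheme (merge the community pair with the largest
    modularity gain) as implemented by networkx.  Output is made
    deterministic by relabeling through sorted nodes and ordering the
    communities by (-size, lexicographically smallest member).  Communities
    smaller than ``min_size`` are discarded.
    """
    if g.number_of_edges() == 0:
        return []
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted((min(u, v), max(u, v)) for u, v in g.edges))
    comms = nx.community.greedy_modularity_communities(h)
    comms = sorted((frozenset(c) for c in comms), key=lambda c: (-len(c), min(c)))
    out = []
    for idx, c in enumerate(comms):
        if len(c) < min_size:
            continue
        out.append(Subnetwork(class_label=class_label, genes=c,
                              community_id=f"{class_label or 'net'}_{idx}"))
    return out


# ---------------------------------------------------------------------------
# Patient partitioning and survival comparison
# ---------------------------------------------------------------------------

def _patient_distance(expr: ExpressionMatrix, genes) -> tuple[list[str], np.ndarray]:
    genes = [g for g in genes if g in set(expr.genes)]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes present in the matrix")
    X = expr.values.loc[genes].to_numpy(dtype=float).T  # patients x genes
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.nan_to_num(R, nan=0.0)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    return expr.samples, D


def cluster_patients_two_groups(expr: ExpressionMatrix, genes) -> dict[str, int]:
    """Split patients into two groups by hierarchical clustering.

    Distance 1 - Pearson r between patient columns restricted to the gene
    set; complete linkage; the tree is cut into k = 2.  Deterministic.
    """
    if expr.n_samples < 4:
        raise ValueError("need at least 4 patients to form two groups")
    patients, D = _patient_distance(expr, genes)
    Z = linkage(squareform(D, checks=False), method="complete")
    labels = fcluster(Z, t=2, criterion="maxclust")
    return {p: int(l) for p, l in zip(patients, labels)}


def logrank_test(cohort: SurvivalCohort, partition: dict[str, int]
                 ) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and p-value."""
    tbl = cohort.table.set_index("patient")
    groups = sorted(set(partition.values()))
    if len(groups) != 2:
        raise ValueError("partition must define exactly two non-empty groups")
    sel = {g: [p for p, l in partition.items() if l == g and p in tbl.index]
           for g in groups}
    if any(len(v) == 0 for v in sel.values()):
        raise ValueError("both groups must contain patients with follow-up")
    a, b = (tbl.loc[sel[g]] for g in groups)
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def screen_subnetworks(subnets: list[Subnetwork], expr: ExpressionMatrix,
                       cohort: SurvivalCohort, alpha: float = 0.05) -> pd.DataFrame:
    """Log-rank screen of every subnetwork; all p-values are recorded."""
    rows = []
    for sn in subnets:
        try:
            part = cluster_patients_two_groups(expr, sn.genes)
            stat, p = logrank_test(cohort, part)
        except ValueError as exc:
            logger.info("subnetwork %s skipped: %s", sn.community_id, exc)
            continue
        rows.append({"id": sn.community_id, "class": sn.class_label,
                     "n_genes": sn.size, "statistic": stat, "p": p,
                     "significant": p < alpha, "subnetwork": sn})
    return pd.DataFrame(rows)


def silhouette_width(expr: ExpressionMatrix, genes, partition: dict[str, int]
                     ) -> tuple[float, pd.Series]:
    """Mean and per-patient silhouette widths under distance 1 - Pearson r.

    Patients in a singleton group get width 0 by convention.
    """
    patients, D = _patient_distance(expr, genes)
    labels = np.array([partition[p] for p in patients])
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs two groups")
    widths = silhouette_samples(D, labels, metric="precomputed")
    s = pd.Series(widths, index=patients)
    return float(s.mean()), s


def combine_and_search(screened: pd.DataFrame, expr: ExpressionMatrix,
                       cohort: SurvivalCohort, max_combo: int = 3
                       ) -> SignatureResult | None:
    """Search all combinations of up to ``max_combo`` significant subnetworks.

    Every combination's union gene set is clustered and log-rank tested.
    BH FDR is computed over the full set of tested units (all screened
    singles plus all combinations).  The best unit has the smallest p;
    ties break toward the smaller gene set, then lexicographic ids.
    """
    if screened.empty:
        return None
    significant = screened[screened["significant"]]
    if significant.empty:
        return None
    sig = list(significant.itertuples())
    units: list[dict] = []
    for row in screened.itertuples():
        units.append({"ids": (row.id,), "genes": frozenset(row.subnetwork.genes),
                      "classes": {g: row.subnetwork.class_label
                                  for g in row.subnetwork.genes},
                      "statistic": row.statistic, "p": row.p})
    for size in range(2, max_combo + 1):
        for combo in itertools.combinations(sig, size):
            genes = frozenset().union(*(r.subnetwork.genes for r in combo))
            classes = {}
            for r in combo:
                classes.update({g: r.subnetwork.class_label
                                for g in r.subnetwork.genes})
            try:
                part = cluster_patients_two_groups(expr, genes)
                stat, p = logrank_test(cohort, part)
            except ValueError:
                continue
            units.append({"ids": tuple(sorted(r.id for r in combo)),
                          "genes": genes, "classes": classes,
                          "statistic": stat, "p": p})
    tested = pd.DataFrame([{"ids": u["ids"], "n_genes": len(u["genes"]),
                            "statistic": u["statistic"], "p": u["p"]}
                           for u in units])
    tested["q"] = bh_fdr(tested["p"].to_numpy())
    sig_ids = set(significant["id"])
    candidates = [i for i, u in enumerate(units)
                  if set(u["ids"]) <= sig_ids]
    best_i = min(candidates, key=lambda i: (units[i]["p"], len(units[i]["genes"]),
                                            units[i]["ids"]))
    best = units[best_i]
    partition = cluster_patients_two_groups(expr, best["genes"])
    sil, _ = silhouette_width(expr, best["genes"], partition)
    comp_counts = pd.Series(list(best["classes"].values())).value_counts()
    composition = " + ".join(f"{int(v)} {k}" for k, v in comp_counts.items())
    return SignatureResult(
        subnetwork_ids=best["ids"], genes=sorted(best["genes"]),
        gene_classes=dict(sorted(best["classes"].items())),
        partition=partition, statistic=best["statistic"], p=best["p"],
        q=float(tested.loc[best_i, "q"]), silhouette=sil,
        composition=composition, all_tested=tested)


# ---------------------------------------------------------------------------
# Cross-platform validation
# ---------------------------------------------------------------------------

def label_groups_by_survival(partition: dict[str, int], cohort: SurvivalCohort
                             ) -> dict[str, str]:
    """Name the two groups 'poor'/'favorable' by median survival time."""
    tbl = cohort.table.set_index("patient")
    medians = {}
    for g in sorted(set(partition.values())):
        pats = [p for p, l in partition.items() if l == g and p in tbl.index]
        medians[g] = float(np.median(tbl.loc[pats, "time"]))
    order = sorted(medians, key=medians.get)
    names = {order[0]: "poor", order[-1]: "favorable"}
    return {p: names[l] for p, l in partition.items()}


def normalize_cross_platform(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                             reference_sample_id: str
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two platforms by subtracting each platform's reference average.

    The reference sample must be measured on both platforms; each matrix is
    shifted by the scalar mean (log scale) of its own reference column, so
    the two reference profiles end up aligned in location.
    """
    out = []
    for expr in (expr_a, expr_b):
        if reference_sample_id not in expr.columns:
            raise ValueError(f"reference sample {reference_sample_id!r} missing")
        out.append(expr - float(expr[reference_sample_id].mean()))
    return out[0], out[1]


def nsc_classify(train_expr: pd.DataFrame, train_labels: dict[str, str],
                 test_expr: pd.DataFrame, genes,
                 thresholds=(0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0)
                 ) -> dict[str, str]:
    """Nearest-shrunken-centroid transfer of group labels to a test cohort.

    The shrinkage threshold is chosen by 5-fold cross-validated training
    accuracy (ties resolved toward less shrinkage); with threshold 0 the
    classifier reduces to plain nearest centroid.
    """
    genes = [g for g in genes if g in train_expr.index and g in test_expr.index]
    if len(genes) < 1:
        raise ValueError("no signature genes shared by both platforms")
    patients = [p for p in train_expr.columns if p in train_labels]
    y = np.array([train_labels[p] for p in patients])
    if len(set(y)) < 2:
        raise ValueError("training labels must contain two classes")
    X = train_expr.loc[genes, patients].to_numpy(dtype=float).T

    def make(thr):
        return NearestCentroid(shrink_threshold=thr if thr else None)

    best_thr, best_acc = thresholds[0], -1.0
    n_splits = min(5, np.bincount(pd.factorize(y)[0]).min())
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=False)
        for thr in thresholds:
            accs = []
            for tr, te in skf.split(X, y):
                clf = make(thr).fit(X[tr], y[tr])
                accs.append(float((clf.predict(X[te]) == y[te]).mean()))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best_thr, best_acc = thr, acc
    clf = make(best_thr).fit(X, y)
    test_pat = list(test_expr.columns)
    Xt = test_expr.loc[genes, test_pat].to_numpy(dtype=float).T
    pred = clf.predict(Xt)
    return {p: str(l) for p, l in zip(test_pat, pred)}


def validate_signature(signature: SignatureResult, train_expr_log2: pd.DataFrame,
                       val_expr_log2: pd.DataFrame, reference_sample_id: str,
                       train_cohort: SurvivalCohort, val_cohort: SurvivalCohort
                       ) -> tuple[float, dict[str, str]]:
    """Validation log-rank p on an independent cohort.

    Both platforms are reference-normalized; training group labels (named by
    median survival) are transferred to the validation patients with the
    nearest-shrunken-centroid classifier and the two predicted groups'
    survival is compared.
    """
    a, b = normalize_cross_platform(train_expr_log2, val_expr_log2,
                                    reference_sample_id)
    named = label_groups_by_survival(signature.partition, train_cohort)
    b_test = b.drop(columns=[reference_sample_id], errors="ignore")
    pred = nsc_classify(a, named, b_test, signature.genes)
    codes = {"poor": 1, "favorable": 2}
    partition = {p: codes[l] for p, l in pred.items()
                 if p in set(val_cohort.patients)}
    if len(set(partition.values())) < 2:
        return 1.0, pred
    _, p = logrank_test(val_cohort, partition)
    return p, pred


def km_curve_table(cohort: SurvivalCohort, partition: dict[str, int | str]
                   ) -> pd.DataFrame:
    """Kaplan-Meier curve per group as a tidy table (time, at-risk, survival)."""
    from lifelines import KaplanMeierFitter

    tbl = cohort.table.set_index("patient")
    frames = []
    for g in sorted(set(partition.values()), key=str):
        pats = [p for p, l in partition.items() if l == g and p in tbl.index]
        sub = tbl.loc[pats]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        ev = kmf.event_table
        frames.append(pd.DataFrame({
            "group": str(g),
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].reindex(ev.index).to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
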