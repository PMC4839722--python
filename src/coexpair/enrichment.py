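"""Enrichment of co-expression classes for protein interactions, complex
co-membership, ontology similarity and term-level function.

Observed fractions are compared against random-pair controls: many sets of
randomly selected gene pairs, each scored the same way as the class of
interest.  Significance is reported both as a one-sample t-test of the
control fractions against the observed value and as an empirical
permutation p (the latter is the more orthodox choice; both are kept)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr
from .types import pair_key

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _as_pairs(pairs) -> list[Pair]:
    return [pair_key(a, b) for a, b in pairs]


# ---------------------------------------------------------------------------
# PPI fractions and random-pair controls
# ---------------------------------------------------------------------------

def ppi_fraction(pairs, ppi: set[frozenset]) -> float:
    """Fraction of the given gene pairs that are known interaction edges."""
    plist = _as_pairs(pairs)
    if not plist:
        raise ValueError("empty pair set")
    hits = sum(1 for p in plist if frozenset(p) in ppi)
    return hits / len(plist)


@dataclass
class ControlResult:
    observed: float
    control_mean: float
    control_sd: float
    fold: float
    t_p: float
    empirical_p: float
    n_sets: int
    set_size: int
    control_fractions: np.ndarray = field(repr=False, default=None)


def random_pair_control(universe, indicator, observed: float,
                        n_sets: int = 1000, set_size: int = 1000,
                        seed: int = 0) -> ControlResult:
    """Score ``n_sets`` random sets of ``set_size`` gene pairs with ``indicator``.

    ``indicator(gene_a, gene_b) -> bool`` is evaluated on pairs drawn
    uniformly from all unordered pairs of ``universe``.  Returns the control
    fractions together with the fold (observed / control mean), a two-sided
    one-sample t-test of the control fractions against the observed value,
    and the empirical two-sided p.
    """
    genes = np.asarray(sorted(universe))
    n = genes.size
    if n * (n - 1) // 2 < set_size:
        raise ValueError("universe has fewer pairs than set_size")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_sets)
    for s in range(n_sets):
        i = rng.integers(0, n, size=int(set_size * 1.2) + 8)
        j = rng.integers(0, n, size=i.size)
        keep = i != j
        i, j = i[keep][:set_size], j[keep][:set_size]
        while i.size < set_size:  # top up after dropping self-pairs
            ii = rng.integers(0, n, size=set_size)
            jj = rng.integers(0, n, size=set_size)
            keep = ii != jj
            i = np.concatenate([i, ii[keep]])[:set_size]
            j = np.concatenate([j, jj[keep]])[:set_size]
        hits = sum(1 for a, b in zip(genes[i], genes[j]) if indicator(a, b))
        fractions[s] = hits / set_size
    mean = float(fractions.mean())
    sd = float(fractions.std(ddof=1))
    fold = observed / mean if mean > 0 else math.inf
    if sd == 0:
        t_p = 1.0 if observed == mean else 0.0
    else:
        t_p = float(sps.ttest_1samp(fractions, observed).pvalue)
    more_extreme = np.abs(fractions - mean) >= abs(observed - mean)
    empirical_p = float((more_extreme.sum() + 1) / (n_sets + 1))
    return ControlResult(observed=observed, control_mean=mean, control_sd=sd,
                         fold=fold, t_p=t_p, empirical_p=empirical_p,
                         n_sets=n_sets, set_size=set_size,
                         control_fractions=fractions)


def ppi_indicator(ppi: set[frozenset]):
    def ind(a: str, b: str) -> bool:
        return frozenset((a, b)) in ppi
    return ind


def binned_fraction_by_r(pairs_with_r: pd.DataFrame, ppi: set[frozenset],
                         bin_width: float = 0.1, min_support: int = 20) -> pd.DataFrame:
    """Per-correlation-bin PPI fractions.

    Bins are half-open ``[k*w, (k+1)*w)`` on the class-defining correlation
    column ``r``; r = 1 is clamped into the top bin.  Bins with fewer than
    ``min_support`` pairs are flagged low-support rather than dropped.
    """
    df = pairs_with_r.dropna(subset=["r"])
    r = df["r"].to_numpy(dtype=float)
    k = np.floor(r / bin_width).astype(int)
    top = int(np.floor(1.0 / bin_width)) - 1
    k = np.minimum(k, top) if bin_width <= 1 else k
    is_edge = np.array([frozenset((a, b)) in ppi
                        for a, b in zip(df["gene_a"], df["gene_b"])])
    rows = []
    for kk in sorted(set(k)):
        sel = k == kk
        rows.append({
            "bin_lo": kk * bin_width, "bin_hi": (kk + 1) * bin_width,
            "n_pairs": int(sel.sum()),
            "fraction": float(is_edge[sel].mean()),
            "low_support": bool(sel.sum() < min_support),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein complexes
# ---------------------------------------------------------------------------

def complex_coexpression_map(class_table: pd.DataFrame,
                             complexes: dict[str, set]) -> pd.DataFrame:
    """Per-complex counts of internal pairs in each co-expression class.

    The dominant class is the one with the largest count among shared /
    sc_specific / bulk_specific (tie -> "mixed"; no co-expressed internal
    pair -> "none").  Complexes with fewer than two members in the gene
    universe are skipped.
    """
    universe = set(class_table["gene_a"]) | set(class_table["gene_b"])
    lookup = {pair_key(a, b): c for a, b, c in
              zip(class_table["gene_a"], class_table["gene_b"], class_table["class"])}
    rows = []
    for cid, members in sorted(complexes.items()):
        inside = sorted(set(members) & universe)
        if len(inside) < 2:
            logger.info("complex %s has <2 members in the universe; skipped", cid)
            continue
        counts = {"shared": 0, "sc_specific": 0, "bulk_specific": 0, "other": 0}
        n_pairs = 0
        for x in range(len(inside)):
            for y in range(x + 1, len(inside)):
                cls = lookup.get(pair_key(inside[x], inside[y]))
                if cls is not None:
                    counts[cls] += 1
                    n_pairs += 1
        coexp = {c: counts[c] for c in ("shared", "sc_specific", "bulk_specific")}
        total_coexp = sum(coexp.values())
        if total_coexp == 0:
            dominant, dom_frac = "none", 0.0
        else:
            best = max(coexp.values())
            winners = [c for c, v in coexp.items() if v == best]
            dominant = winners[0] if len(winners) == 1 else "mixed"
            dom_frac = best / total_coexp
        rows.append({"complex_id": cid, "n_members": len(inside),
                     "n_internal_pairs": n_pairs, **counts,
                     "n_coexpressed": total_coexp,
                     "dominant_class": dominant,
                     "dominant_fraction": dom_frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ontology similarity (Lin measure, best-match average)
# ---------------------------------------------------------------------------

class TermAnnotation:
    """A rooted term DAG with gene annotations and information content.

    ``dag_edges`` are (child, parent) pairs with a single root; ``gene_terms``
    maps genes to their *direct* term annotations.  IC(t) = -ln(f(t)) where
    f(t) is the fraction of annotated genes annotated to t or any of its
    descendants; IC(root) = 0 by construction.
    """

    def __init__(self, dag_edges, gene_terms: dict[str, set]):
        g = nx.DiGraph()
        g.add_edges_from(dag_edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term relationships contain a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root term, found {roots}")
        self.root = roots[0]
        self.graph = g
        self.gene_terms = {gene: set(terms) for gene, terms in gene_terms.items()
                           if terms}
        self._ancestors: dict[str, frozenset] = {}
        for t in g.nodes:
            self._ancestors[t] = frozenset(nx.descendants(g, t)) | {t}
        # propagated annotations: gene -> all terms on paths to the root
        self.propagated: dict[str, frozenset] = {}
        for gene, terms in self.gene_terms.items():
            full = set()
            for t in terms:
                if t not in self._ancestors:
                    raise KeyError(f"gene {gene} annotated to unknown term {t}")
                full |= self._ancestors[t]
            self.propagated[gene] = frozenset(full)
        n_annotated = len(self.propagated)
        counts: dict[str, int] = {t: 0 for t in g.nodes}
        for full in self.propagated.values():
            for t in full:
                counts[t] += 1
        self.ic: dict[str, float] = {}
        for t in g.nodes:
            f = counts[t] / n_annotated if n_annotated else 0.0
            self.ic[t] = -math.log(f) if f > 0 else math.inf
        self.ic[self.root] = 0.0
        self.term_genes = {t: frozenset(g_ for g_, full in self.propagated.items()
                                        if t in full) for t in g.nodes}

    def ancestors(self, term: str) -> frozenset:
        return self._ancestors[term]

    def term_similarity(self, t1: str, t2: str) -> float:
        """Lin similarity: 2*IC(MICA) / (IC(t1) + IC(t2))."""
        if t1 == t2:
            return 1.0
        common = self._ancestors[t1] & self._ancestors[t2]
        ic_mica = max(self.ic[t] for t in common) if common else 0.0
        denom = self.ic[t1] + self.ic[t2]
        if denom == 0 or not math.isfinite(denom):
            return 0.0
        return 2.0 * ic_mica / denom


def go_similarity(gene_a: str, gene_b: str, ann: TermAnnotation) -> float | None:
    """Best-match-average Lin similarity between two genes' term sets.

    Returns None (undefined) if either gene has no annotation.
    """
    ta = ann.gene_terms.get(gene_a)
    tb = ann.gene_terms.get(gene_b)
    if not ta or not tb:
        return None
    sims = [[ann.term_similarity(x, y) for y in tb] for x in ta]
    best_a = [max(row) for row in sims]
    best_b = [max(sims[i][j] for i in range(len(ta))) for j in range(len(tb))]
    return (sum(best_a) + sum(best_b)) / (len(ta) + len(tb))


def go_similarity_fraction(pairs, ann: TermAnnotation, threshold: float = 0.5,
                           universe=None, n_sets: int = 1000,
                           set_size: int = 1000, seed: int = 0):
    """Fraction of annotated pairs with similarity >= threshold, vs control.

    Returns ``(fraction, n_scored, ControlResult | None)``; the control is
    computed over ``universe`` (annotated genes by default) with the same
    random-pair machinery used for interactions.
    """
    cache: dict[frozenset, float | None] = {}

    def sim(a: str, b: str) -> float | None:
        key = frozenset((a, b))
        if key not in cache:
            cache[key] = go_similarity(a, b, ann)
        return cache[key]

    scored = [sim(a, b) for a, b in pairs]
    scored = [s for s in scored if s is not None]
    if not scored:
        raise ValueError("no annotated pairs to score")
    frac = sum(1 for s in scored if s >= threshold) / len(scored)
    control = None
    if universe is None:
        universe = sorted(ann.gene_terms)
    if len(universe) >= 3:
        def indicator(a, b):
            s = sim(a, b)
            return s is not None and s >= threshold
        control = random_pair_control(universe, indicator, frac,
                                      n_sets=n_sets, set_size=set_size, seed=seed)
    return frac, len(scored), control


def term_enrichment(gene_set, ann: TermAnnotation, universe,
                    q_cutoff: float = 0.05) -> tuple[pd.DataFrame, dict[str, str]]:
    """Hypergeometric upper-tail term enrichment with BH correction.

    Annotations are propagated to ancestors.  Returns the per-term table and
    a gene -> module map assigning each gene to the most significant
    enriched term that annotates it.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N = len(universe)
    n = len(gene_set)
    rows = []
    for term in sorted(ann.graph.nodes):
        members = ann.term_genes[term] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & gene_set)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "p": p})
    table = pd.DataFrame(rows)
    if table.empty:
        return table, {}
    table["q"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    enriched = table[table["q"] < q_cutoff]
    assignment: dict[str, str] = {}
    for _, row in enriched.iterrows():  # ordered by significance
        for gene in sorted(ann.term_genes[row["term"]] & gene_set):
            assignment.setdefault(gene, row["term"])
    return table, assignment
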