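"""All-pairs co-expression measures, top-K selection and robustness checks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix


def pearson_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation matrix.

    Zero-variance genes yield NaN rows/columns (flagged undefined) and are
    excluded from downstream ranking and classification rather than forced
    to r = 0.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation analysis")
    if m.state != "quantile_normalized":
        warnings.warn(
            f"correlating a matrix in state {m.state!r}; the standard chain "
            "ends at 'quantile_normalized'", stacklevel=2)
    X = m.values.to_numpy(dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    return pd.DataFrame(R, index=m.genes, columns=m.genes)


def _upper_pairs(genes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(genes), k=1)
    return iu


def pearson_all_pairs(m: ExpressionMatrix) -> pd.DataFrame:
    """Long-format table of all unordered gene pairs with their Pearson r."""
    R = pearson_matrix(m).to_numpy()
    genes = np.asarray(m.genes)
    i, j = _upper_pairs(m.genes)
    return pd.DataFrame({"gene_a": genes[i], "gene_b": genes[j], "r": R[i, j]})


def correlation_table(sc: ExpressionMatrix, bulk: ExpressionMatrix) -> pd.DataFrame:
    """Per-pair correlations at both levels over a shared gene universe.

    Columns: gene_a, gene_b (gene_a < gene_b), r_sc, r_bulk.
    """
    if sc.genes != bulk.genes:
        raise ValueError("single-cell and bulk matrices must share the same "
                         "ordered gene universe; run intersect_genes first")
    R_sc = pearson_matrix(sc).to_numpy()
    R_bulk = pearson_matrix(bulk).to_numpy()
    genes = np.asarray(sc.genes)
    i, j = _upper_pairs(sc.genes)
    tbl = pd.DataFrame({
        "gene_a": genes[i], "gene_b": genes[j],
        "r_sc": R_sc[i, j], "r_bulk": R_bulk[i, j],
    })
    swap = tbl["gene_a"] > tbl["gene_b"]
    tbl.loc[swap, ["gene_a", "gene_b"]] = tbl.loc[swap, ["gene_b", "gene_a"]].to_numpy()
    return tbl


def top_k_pairs(table: pd.DataFrame, level: str, k: int = 1000) -> pd.DataFrame:
    """The k pairs with the largest positive r at ``level``.

    Ties are broken lexicographically on (gene_a, gene_b) so the selection
    is a deterministic function of the table. Undefined correlations are
    excluded.
    """
    col = {"single_cell": "r_sc", "bulk": "r_bulk"}.get(level, level)
    if col not in table.columns:
        raise KeyError(f"no correlation column for level {level!r}")
    avail = table.dropna(subset=[col])
    if k > len(avail):
        raise ValueError(f"requested top {k} pairs but only {len(avail)} available")
    ordered = avail.sort_values(["gene_a", "gene_b"], kind="mergesort")
    ordered = ordered.sort_values(col, ascending=False, kind="mergesort")
    return ordered.head(k).reset_index(drop=True)


def pair_set(table: pd.DataFrame) -> set[tuple[str, str]]:
    return set(zip(table["gene_a"], table["gene_b"]))


def split_half_overlap(m: ExpressionMatrix, k: int, seed: int,
                       level_col: str | None = None) -> int:
    """|top_k(half1) ∩ top_k(half2)| for a seeded random equal sample split.

    With an odd number of samples the extra sample goes to the first half.
    """
    if m.n_samples < 6:
        raise ValueError("need at least 6 samples to split in half")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m.n_samples)
    cut = (m.n_samples + 1) // 2
    halves = []
    for idx in (perm[:cut], perm[cut:]):
        sub = ExpressionMatrix(m.values.iloc[:, sorted(idx)], level=m.level, state=m.state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tbl = pearson_all_pairs(sub)
        halves.append(pair_set(top_k_pairs(tbl, "r", k)))
    return len(halves[0] & halves[1])


def cluster_samples(matrices: list[ExpressionMatrix]):
    """Hierarchical clustering of sample columns (distance 1 - r, complete linkage).

    All matrices must share the same ordered gene universe; their columns
    are pooled. Returns ``(sample_ids, linkage_matrix)``.
    """
    genes = matrices[0].genes
    for m in matrices[1:]:
        if m.genes != genes:
            raise ValueError("matrices must share the same ordered gene universe")
    combined = pd.concat([m.values for m in matrices], axis=1)
    if combined.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers across matrices")
    R = np.corrcoef(combined.to_numpy(dtype=float).T)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    return list(combined.columns), Z


# ---------------------------------------------------------------------------
# MIC: a naive equi-count grid approximation
# ---------------------------------------------------------------------------

def _equicount_labels(x: np.ndarray, bins: int) -> np.ndarray:
    # rank-based equi-count binning; ties broken by original order
    order = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (order * bins) // x.size


def mic(x, y, max_bins: int = 15) -> float:
    """Naive maximal-information-coefficient approximation.

    Searches equi-count grids (a x b bins, a*b <= n**0.6) and reports the
    maximum mutual information normalized by log2(min(a, b)).  This is a
    grid approximation with fixed equi-count cut points, not the MINE
    dynamic-programming algorithm; it saturates at 1 for exact functional
    relationships aligned with rank bins and is adequate as a robustness
    check on the Pearson-based results.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 25:
        raise ValueError("need at least 25 samples for MIC")
    budget = n ** 0.6
    best = 0.0
    for a in range(2, max_bins + 1):
        if a * 2 > budget:
            break
        xb = _equicount_labels(x, a)
        for b in range(2, max_bins + 1):
            if a * b > budget:
                break
            yb = _equicount_labels(y, b)
            joint = np.zeros((a, b))
            np.add.at(joint, (xb, yb), 1.0)
            joint /= n
            px = joint.sum(axis=1, keepdims=True)
            py = joint.sum(axis=0, keepdims=True)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = joint * np.log2(joint / (px * py))
            mi = np.nansum(terms)
            best = max(best, mi / np.log2(min(a, b)))
    return float(min(best, 1.0))


def mic_all_pairs(m: ExpressionMatrix, max_bins: int = 15) -> pd.DataFrame:
    """MIC for every unordered gene pair (quadratic; intended for small universes)."""
    X = m.values.to_numpy(dtype=float)
    genes = np.asarray(m.genes)
    i, j = _upper_pairs(m.genes)
    vals = np.array([mic(X[a], X[b], max_bins=max_bins) for a, b in zip(i, j)])
    return pd.DataFrame({"gene_a": genes[i], "gene_b": genes[j], "mic": vals})
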