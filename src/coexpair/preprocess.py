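"""Gene filtering and normalization of RPKM expression matrices.

The chain applied to each level before correlation analysis is:
filter (level-specific) -> intersect gene universes -> log2(x+1) ->
per-gene centering -> cross-sample quantile normalization.

Boundary semantics are deliberate: a bulk gene with mean exactly equal to
``min_mean`` is kept ("below" excludes), and a single-cell gene that is
zero in exactly two-thirds of the cells is kept ("over two-thirds"
excludes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix


def filter_bulk_genes(m: ExpressionMatrix, min_mean: float = 100.0) -> ExpressionMatrix:
    """Drop bulk genes whose average RPKM is below ``min_mean``."""
    m.require(level="bulk", state="raw_rpkm")
    keep = m.values.mean(axis=1) >= min_mean
    if not keep.any():
        raise ValueError("no genes survive the bulk mean-RPKM filter")
    return ExpressionMatrix(m.values.loc[keep], level=m.level, state=m.state)


def filter_sc_genes(m: ExpressionMatrix, max_zero_fraction: float = 2.0 / 3.0) -> ExpressionMatrix:
    """Drop single-cell genes zero in more than ``max_zero_fraction`` of cells."""
    m.require(level="single_cell", state="raw_rpkm")
    zero_frac = (m.values == 0).sum(axis=1) / m.n_samples
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        raise ValueError("no genes survive the single-cell zero-fraction filter")
    return ExpressionMatrix(m.values.loc[keep], level=m.level, state=m.state)


def intersect_genes(a: ExpressionMatrix, b: ExpressionMatrix
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared gene universe, identically ordered."""
    common = [g for g in a.genes if g in set(b.genes)]
    if not common:
        raise ValueError("no genes are measured at both levels")
    return a.subset_genes(common), b.subset_genes(common)


def log2_plus_one(m: ExpressionMatrix) -> ExpressionMatrix:
    m.require(state="raw_rpkm")
    arr = m.values.to_numpy(dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("negative entries cannot be log2(x+1)-transformed")
    out = pd.DataFrame(np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns)
    return m.advance(out, "log2")


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Global centralization: subtract each gene's mean across samples."""
    m.require(state="log2")
    out = m.values.sub(m.values.mean(axis=1), axis=0)
    return m.advance(out, "centered")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean quantile profile.

    Ties within a column receive the mean of the reference values across
    their rank span, so the output is rank-preserving within columns and
    all columns share one multiset of values (up to tie averaging).
    """
    m.require(state="centered")
    X = m.values.to_numpy(dtype=float)
    n, p = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(p):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # span of each tied group in sorted order
        first = np.searchsorted(sorted_col, sorted_col, side="left")
        last = np.searchsorted(sorted_col, sorted_col, side="right") - 1
        tied_mean = (csum[last + 1] - csum[first]) / (last - first + 1)
        out[order, j] = tied_mean
    frame = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advance(frame, "quantile_normalized")


def preprocess_pair(sc: ExpressionMatrix, bulk: ExpressionMatrix,
                    min_mean: float = 100.0,
                    max_zero_fraction: float = 2.0 / 3.0
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Full preprocessing chain for a matched single-cell/bulk dataset."""
    sc_f = filter_sc_genes(sc, max_zero_fraction)
    bulk_f = filter_bulk_genes(bulk, min_mean)
    sc_f, bulk_f = intersect_genes(sc_f, bulk_f)
    out = []
    for m in (sc_f, bulk_f):
        out.append(quantile_normalize(center_genes(log2_plus_one(m))))
    return out[0], out[1]


def average_cell_profile(m: ExpressionMatrix, cell_to_tumor: dict[str, str]
                         ) -> ExpressionMatrix:
    """Collapse single cells into per-tumor pseudo-bulk columns (gene means)."""
    m.require(level="single_cell")
    missing = [c for c in m.samples if c not in cell_to_tumor]
    if missing:
        raise ValueError(f"cells without a tumor assignment: {missing[:5]}")
    groups = pd.Series({c: cell_to_tumor[c] for c in m.samples})
    pseudo = m.values.T.groupby(groups).mean().T
    pseudo = pseudo[sorted(pseudo.columns)]
    return ExpressionMatrix(pseudo, level="bulk", state=m.state)
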