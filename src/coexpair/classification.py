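"""Shuffled-expression null distributions, correlation cutoffs and the
shared / single-cell-specific / bulk-specific classification of gene pairs.

The positive-correlation cutoff is the (1 - pos_tail) quantile of the
pooled null built from independent per-gene shuffles (pooling across
replicates).  The "no correlation" interval holds ``nocorr_mass_per_side``
probability mass on each side of the null median.  A pair is classified
as level-specific only when the other level is affirmatively inside the
no-correlation interval; correlations between the interval and the
positive cutoff are recorded as "intermediate" and the pair falls into
the residual class "other".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

CLASSES = ("shared", "sc_specific", "bulk_specific", "other")


@dataclass
class NullDistribution:
    """Pooled correlation values from repeated per-gene expression shuffles."""

    level: str
    values: np.ndarray
    n_reps: int
    seed: int


@dataclass
class LevelThresholds:
    pos_cutoff: float
    neg_cutoff: float
    nocorr_lo: float
    nocorr_hi: float
    tail_method: str  # "empirical" or "normal_fit"

    def __post_init__(self) -> None:
        if not (self.neg_cutoff < self.pos_cutoff
                and self.nocorr_lo < self.nocorr_hi):
            raise ValueError("threshold ordering violated")

    def check_stringent(self) -> None:
        """Strict ordering neg < lo < hi < pos; holds whenever the
        no-correlation interval does not span the whole null."""
        if not (self.neg_cutoff < self.nocorr_lo
                < self.nocorr_hi < self.pos_cutoff):
            raise ValueError("threshold ordering violated: need "
                             "neg < nocorr_lo < nocorr_hi < pos")


@dataclass
class ThresholdSet:
    by_level: dict[str, LevelThresholds]
    pos_tail: float
    nocorr_mass_per_side: float
    metadata: dict = field(default_factory=dict)


def build_null(m: ExpressionMatrix, n_reps: int = 1000, seed: int = 0) -> NullDistribution:
    """Null correlation distribution from independent per-gene shuffles.

    Each replicate permutes every gene's values independently across the
    samples and recomputes all-pairs Pearson r; values are pooled over
    replicates.  Deterministic given ``seed``.
    """
    X = m.values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(X.shape[0], k=1)
    sd = X.std(axis=1)
    ok = sd > 0
    chunks = []
    for _ in range(n_reps):
        P = rng.permuted(X, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(P)
        vals = R[iu]
        keep = ok[iu[0]] & ok[iu[1]]
        chunks.append(vals[keep].astype(np.float32))
    pooled = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.float32)
    return NullDistribution(level=m.level, values=pooled, n_reps=n_reps, seed=seed)


def _level_thresholds(null: NullDistribution, pos_tail: float,
                      nocorr_mass_per_side: float) -> LevelThresholds:
    v = null.values.astype(np.float64)
    if v.size == 0:
        raise ValueError("empty null distribution")
    if not 0 < pos_tail < 0.5:
        raise ValueError("pos_tail must lie in (0, 0.5)")
    if not 0 < nocorr_mass_per_side <= 0.5:
        raise ValueError("nocorr_mass_per_side must lie in (0, 0.5]")
    if v.size >= 1.0 / pos_tail:
        pos = float(np.quantile(v, 1.0 - pos_tail))
        neg = float(np.quantile(v, pos_tail))
        method = "empirical"
    else:
        warnings.warn(
            f"pooled null of size {v.size} is too small for an empirical "
            f"{pos_tail:g} tail quantile; extrapolating from a fitted normal",
            stacklevel=3)
        mu, sd = float(v.mean()), float(v.std())
        z = norm.ppf(1.0 - pos_tail)
        pos, neg = mu + z * sd, mu - z * sd
        method = "normal_fit"
    lo = float(np.quantile(v, 0.5 - nocorr_mass_per_side))
    hi = float(np.quantile(v, min(1.0, 0.5 + nocorr_mass_per_side)))
    if nocorr_mass_per_side == 0.5:
        # limiting case: the interval spans the whole null
        lo = min(lo, float(v.min()))
        hi = max(hi, float(v.max()))
    out = LevelThresholds(pos_cutoff=pos, neg_cutoff=neg,
                          nocorr_lo=lo, nocorr_hi=hi, tail_method=method)
    if nocorr_mass_per_side < 0.5:
        out.check_stringent()
    return out


def derive_thresholds(null_sc: NullDistribution, null_bulk: NullDistribution,
                      pos_tail: float = 1e-6,
                      nocorr_mass_per_side: float = 0.3) -> ThresholdSet:
    """Positive/negative/no-correlation cutoffs per level from pooled nulls."""
    by_level = {
        "single_cell": _level_thresholds(null_sc, pos_tail, nocorr_mass_per_side),
        "bulk": _level_thresholds(null_bulk, pos_tail, nocorr_mass_per_side),
    }
    meta = {
        "null_sizes": {"single_cell": int(null_sc.values.size),
                       "bulk": int(null_bulk.values.size)},
        "n_reps": {"single_cell": null_sc.n_reps, "bulk": null_bulk.n_reps},
        "seeds": {"single_cell": null_sc.seed, "bulk": null_bulk.seed},
        "nocorr_convention": "central interval holding nocorr_mass_per_side of "
                             "null probability on each side of the null median",
    }
    return ThresholdSet(by_level=by_level, pos_tail=pos_tail,
                        nocorr_mass_per_side=nocorr_mass_per_side, metadata=meta)


def _patterns(r: np.ndarray, th: LevelThresholds) -> np.ndarray:
    out = np.full(r.shape, "intermediate", dtype=object)
    out[r >= th.pos_cutoff] = "+"
    out[r <= th.neg_cutoff] = "-"
    out[(r >= th.nocorr_lo) & (r <= th.nocorr_hi)] = "0"
    return out


def classify_pairs(table: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Assign each pair a per-level pattern and a co-expression class.

    Patterns per level: "+" (>= positive cutoff), "-" (<= negative cutoff),
    "0" (inside the no-correlation interval), "intermediate" otherwise.
    Class: (+,+) -> shared; (+,0) -> sc_specific; (0,+) -> bulk_specific;
    anything else -> other.  Pairs with undefined correlation at either
    level are dropped (logged).
    """
    n_undef = int(table[["r_sc", "r_bulk"]].isna().any(axis=1).sum())
    if n_undef:
        logger.info("dropping %d pairs with undefined correlation", n_undef)
    tbl = table.dropna(subset=["r_sc", "r_bulk"]).copy()
    p_sc = _patterns(tbl["r_sc"].to_numpy(dtype=float), thresholds.by_level["single_cell"])
    p_bulk = _patterns(tbl["r_bulk"].to_numpy(dtype=float), thresholds.by_level["bulk"])
    cls = np.full(len(tbl), "other", dtype=object)
    cls[(p_sc == "+") & (p_bulk == "+")] = "shared"
    cls[(p_sc == "+") & (p_bulk == "0")] = "sc_specific"
    cls[(p_sc == "0") & (p_bulk == "+")] = "bulk_specific"
    tbl["pattern_sc"] = p_sc
    tbl["pattern_bulk"] = p_bulk
    tbl["class"] = cls
    return tbl.reset_index(drop=True)


def class_counts(class_table: pd.DataFrame) -> dict[str, int]:
    counts = class_table["class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CLASSES}
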