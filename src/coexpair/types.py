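"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LEVELS = ("single_cell", "bulk")

#: Allowed processing states, in the only order transitions may occur.
STATES = ("raw_rpkm", "log2", "centered", "quantile_normalized")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix tagged with its measurement level
    and processing state.

    ``values`` holds genes as rows and samples as columns.  ``level`` is
    ``"single_cell"`` or ``"bulk"``; ``state`` tracks how far along the
    normalization chain (raw RPKM -> log2 -> centered -> quantile
    normalized) the matrix is, and downstream operations refuse matrices
    in the wrong state.
    """

    values: pd.DataFrame
    level: str
    state: str = "raw_rpkm"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.state == "raw_rpkm":
            arr = self.values.to_numpy()
            if arr.size and np.nanmin(arr) < 0:
                raise ValueError("raw RPKM values must be non-negative")

    # -- conveniences -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require(self, *, level: str | None = None, state: str | None = None) -> None:
        """Raise if the matrix is not at the expected level/state."""
        if level is not None and self.level != level:
            raise ValueError(f"expected level {level!r}, got {self.level!r}")
        if state is not None and self.state != state:
            raise ValueError(f"expected state {state!r}, got {self.state!r}")

    def advance(self, values: pd.DataFrame, state: str) -> "ExpressionMatrix":
        """Return a copy with new values in the next processing state.

        State transitions must follow the order of :data:`STATES`.
        """
        if STATES.index(state) != STATES.index(self.state) + 1:
            raise ValueError(f"illegal state transition {self.state!r} -> {state!r}")
        return ExpressionMatrix(values=values, level=self.level, state=state)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])


@dataclass
class SurvivalCohort:
    """Clinical follow-up for one patient cohort.

    ``table`` has one row per patient with columns ``patient``, ``time``
    (days, strictly positive) and ``event`` (1 = death observed,
    0 = censored).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"patient", "time", "event"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        if self.table["patient"].duplicated().any():
            raise ValueError("duplicate patient identifiers")
        if (self.table["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")

    @property
    def patients(self) -> list[str]:
        return list(self.table["patient"])

    def subset(self, patients) -> "SurvivalCohort":
        keep = self.table[self.table["patient"].isin(set(patients))]
        return SurvivalCohort(keep.reset_index(drop=True))


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered gene pair."""
    if a == b:
        raise ValueError(f"self-pair ({a},{a}) is not a gene pair")
    return (a, b) if a < b else (b, a)
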