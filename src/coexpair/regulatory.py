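"""Co-regulation signatures: promoter accessibility, chromatin contacts and
chromosomal / topological-domain co-location of gene pairs.

Coordinate conventions: all internal intervals are 0-based half-open.  The
gene layout table on disk is 1-based inclusive (gene start/end) with a
1-based TSS, the common TSV convention; BED-like peak, domain and contact
files are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import density_mode
from .types import pair_key


@dataclass
class GenomeLayout:
    """Gene coordinates and topological-domain intervals.

    ``genes``: columns gene, chrom, strand (+/-), tss, start, end -- all
    1-based inclusive as read from the layout TSV.  ``tads``: columns
    chrom, start, end, tad_id with 0-based half-open intervals.
    """

    genes: pd.DataFrame
    tads: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "chrom", "strand", "tss", "start", "end"}
        if not need.issubset(self.genes.columns):
            raise ValueError(f"layout needs columns {sorted(need)}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")
        if not self.genes["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.genes = self.genes.set_index("gene", drop=False)
        # 0-based conversions
        self.genes["tss0"] = self.genes["tss"] - 1
        self.genes["start0"] = self.genes["start"] - 1
        self.genes["end0"] = self.genes["end"]  # half-open end

    def chrom(self, gene: str) -> str:
        return self.genes.at[gene, "chrom"]

    def promoter(self, gene: str, length: int = 1000) -> tuple[str, int, int]:
        """Strictly upstream, strand-aware promoter interval (0-based half-open).

        On '+': [tss0 - length, tss0); on '-': positions just downstream in
        genomic coordinates, (tss, tss + length] one-based, i.e.
        [tss0 + 1, tss0 + 1 + length) zero-based.
        """
        row = self.genes.loc[gene]
        if row["strand"] == "+":
            return row["chrom"], max(0, int(row["tss0"]) - length), int(row["tss0"])
        if row["strand"] == "-":
            return row["chrom"], int(row["tss0"]) + 1, int(row["tss0"]) + 1 + length
        raise ValueError(f"gene {gene} has unknown strand {row['strand']!r}")

    def gene_region(self, gene: str, flank: int = 5000) -> tuple[str, int, int]:
        row = self.genes.loc[gene]
        return row["chrom"], max(0, int(row["start0"]) - flank), int(row["end0"]) + flank

    def tad_of_tss(self, gene: str) -> str | None:
        """The domain whose half-open interval contains the gene's TSS."""
        row = self.genes.loc[gene]
        t = self.tads[(self.tads["chrom"] == row["chrom"]) &
                      (self.tads["start"] <= row["tss0"]) &
                      (row["tss0"] < self.tads["end"])]
        if t.empty:
            return None
        return str(t.iloc[0]["tad_id"])


def _overlap(a_lo: int, a_hi: int, b_lo, b_hi) -> np.ndarray:
    return (np.asarray(b_lo) < a_hi) & (a_lo < np.asarray(b_hi))


def promoter_dhs_signal(peaks: dict[str, pd.DataFrame], layout: GenomeLayout,
                        promoter_length: int = 1000, agg: str = "sum") -> pd.DataFrame:
    """Gene x cell-type matrix of promoter accessibility.

    ``peaks`` maps cell type -> BED-like frame (chrom, start, end, score;
    0-based half-open).  A gene's intensity in a cell type is the sum (or
    max, by ``agg``) of scores of peaks overlapping its promoter; genes
    without overlapping peaks get 0.
    """
    if agg not in ("sum", "max"):
        raise ValueError("agg must be 'sum' or 'max'")
    genes = list(layout.genes["gene"])
    proms = {g: layout.promoter(g, promoter_length) for g in genes}
    out = pd.DataFrame(0.0, index=genes, columns=sorted(peaks))
    for ct in sorted(peaks):
        bed = peaks[ct]
        by_chrom = {c: sub for c, sub in bed.groupby("chrom")}
        for g in genes:
            chrom, lo, hi = proms[g]
            sub = by_chrom.get(chrom)
            if sub is None:
                continue
            hit = sub[_overlap(lo, hi, sub["start"].to_numpy(), sub["end"].to_numpy())]
            if len(hit):
                score = hit["score"].sum() if agg == "sum" else hit["score"].max()
                out.at[g, ct] = float(score)
    return out


def dhs_correlation(pairs, dhs: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of the two genes' promoter-accessibility vectors per pair.

    Genes with all-zero (or constant) accessibility are undefined and get
    NaN.  Requires at least 3 cell types.
    """
    if dhs.shape[1] < 3:
        raise ValueError("need at least 3 cell types")
    X = dhs.to_numpy(dtype=float)
    idx = {g: i for i, g in enumerate(dhs.index)}
    sd = X.std(axis=1)
    rows = []
    for a, b in pairs:
        a, b = pair_key(a, b)
        ia, ib = idx.get(a), idx.get(b)
        if ia is None or ib is None or sd[ia] == 0 or sd[ib] == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(X[ia], X[ib])[0, 1])
        rows.append({"gene_a": a, "gene_b": b, "dhs_r": r})
    return pd.DataFrame(rows)


def dhs_class_modes(class_table: pd.DataFrame, dhs: pd.DataFrame,
                    classes=("shared", "sc_specific", "bulk_specific")) -> dict[str, float]:
    """Highest density peak of the DHS-correlation distribution per class."""
    modes = {}
    for cls in classes:
        sub = class_table[class_table["class"] == cls]
        if len(sub) == 0:
            modes[cls] = float("nan")
            continue
        rs = dhs_correlation(zip(sub["gene_a"], sub["gene_b"]), dhs)["dhs_r"].dropna()
        modes[cls] = density_mode(rs) if len(rs) >= 3 else float("nan")
    return modes


# ---------------------------------------------------------------------------
# Chromatin contacts
# ---------------------------------------------------------------------------

def contact_overlap(pairs, layout: GenomeLayout, contacts: pd.DataFrame,
                    flank: int = 5000) -> pd.DataFrame:
    """Whether each gene pair is linked by a chromatin contact.

    A pair has a contact iff some contact joins one gene's flanked region
    (gene body +/- ``flank``) to the other's, in either orientation.
    Contact coordinates are 0-based half-open.
    """
    c = contacts
    rows = []
    for a, b in pairs:
        a, b = pair_key(a, b)
        ra = layout.gene_region(a, flank)
        rb = layout.gene_region(b, flank)
        hit = False
        for r1, r2 in ((ra, rb), (rb, ra)):
            m = ((c["chrom1"] == r1[0]) & (c["chrom2"] == r2[0]) &
                 _overlap(r1[1], r1[2], c["start1"], c["end1"]) &
                 _overlap(r2[1], r2[2], c["start2"], c["end2"]))
            if bool(m.any()):
                hit = True
                break
        rows.append({"gene_a": a, "gene_b": b, "has_contact": hit})
    return pd.DataFrame(rows)


def same_chromosome_fraction(pairs, layout: GenomeLayout,
                             n_control: int = 1000, seed: int = 0
                             ) -> tuple[float, float]:
    """Fraction of pairs on one chromosome, plus a random-pair control fraction."""
    plist = [pair_key(a, b) for a, b in pairs]
    if not plist:
        raise ValueError("empty pair set")
    chrom = layout.genes["chrom"]
    frac = float(np.mean([chrom[a] == chrom[b] for a, b in plist]))
    rng = np.random.default_rng(seed)
    genes = np.asarray(layout.genes["gene"])
    i = rng.integers(0, genes.size, size=n_control)
    j = rng.integers(0, genes.size, size=n_control)
    ok = i != j
    ctrl = float(np.mean((chrom[genes[i[ok]]].to_numpy() ==
                          chrom[genes[j[ok]]].to_numpy())))
    return frac, ctrl


def same_tad_fraction(intra_chrom_pairs, layout: GenomeLayout) -> float:
    """Fraction of same-chromosome pairs whose TSSs fall in one domain.

    A TSS outside every domain never counts as same-domain.
    """
    plist = [pair_key(a, b) for a, b in intra_chrom_pairs]
    if not plist:
        raise ValueError("empty pair set")
    hits = 0
    for a, b in plist:
        if layout.chrom(a) != layout.chrom(b):
            raise ValueError(f"pair ({a},{b}) spans chromosomes; restrict to "
                             "same-chromosome pairs first")
        ta, tb = layout.tad_of_tss(a), layout.tad_of_tss(b)
        hits += int(ta is not None and ta == tb)
    return hits / len(plist)


def intra_inter_contact_enrichment(class_table: pd.DataFrame, layout: GenomeLayout,
                                   contacts: pd.DataFrame, flank: int = 5000,
                                   classes=("shared", "sc_specific", "bulk_specific")
                                   ) -> pd.DataFrame:
    """Contact fraction per class, stratified by same- vs different-chromosome."""
    rows = []
    chrom = layout.genes["chrom"]
    for cls in classes:
        sub = class_table[class_table["class"] == cls]
        if len(sub) == 0:
            for stratum in ("intra", "inter"):
                rows.append({"class": cls, "stratum": stratum,
                             "n_pairs": 0, "fraction": float("nan")})
            continue
        same = np.array([chrom[a] == chrom[b]
                         for a, b in zip(sub["gene_a"], sub["gene_b"])])
        for stratum, mask in (("intra", same), ("inter", ~same)):
            part = sub[mask]
            if len(part) == 0:
                rows.append({"class": cls, "stratum": stratum,
                             "n_pairs": 0, "fraction": float("nan")})
                continue
            ov = contact_overlap(zip(part["gene_a"], part["gene_b"]),
                                 layout, contacts, flank)
            rows.append({"class": cls, "stratum": stratum,
                         "n_pairs": int(len(part)),
                         "fraction": float(ov["has_contact"].mean())})
    return pd.DataFrame(rows)
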