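"""Plain-text readers and writers for every pipeline input and output.

Formats: expression TSV (genes as rows, first column = gene id, header =
sample ids) with a JSON sidecar recording level/state; edge-list,
catalog, annotation, layout, peak, domain, contact and clinical TSVs;
ground-truth and report JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .regulatory import GenomeLayout
from .synthetic import AnnotationBundle, GroundTruth
from .types import ExpressionMatrix, SurvivalCohort


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_expression(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    _sidecar(path).write_text(json.dumps({"level": m.level, "state": m.state}))


def read_expression(path, level: str | None = None,
                    state: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    level = level or meta.get("level")
    state = state or meta.get("state", "raw_rpkm")
    if level is None:
        raise ValueError("expression level not given and no sidecar found")
    return ExpressionMatrix(values, level=level, state=state)


def write_ppi(ppi: set, path) -> None:
    rows = sorted(tuple(sorted(e)) for e in ppi)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_ppi(path) -> set:
    df = pd.read_csv(path, sep="\t")
    return {frozenset((a, b)) for a, b in zip(df["gene_a"], df["gene_b"])}


def write_complexes(complexes: dict, path) -> None:
    rows = [{"complex_id": cid, "gene": g}
            for cid in sorted(complexes) for g in sorted(complexes[cid])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_complexes(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {cid: set(sub["gene"]) for cid, sub in df.groupby("complex_id")}


def write_terms(terms, dag_path, annotation_path) -> None:
    edges = sorted(terms.graph.edges)
    pd.DataFrame(edges, columns=["child", "parent"]).to_csv(dag_path, sep="\t", index=False)
    rows = [{"gene": g, "term": t}
            for g in sorted(terms.gene_terms) for t in sorted(terms.gene_terms[g])]
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)


def read_terms(dag_path, annotation_path):
    from .enrichment import TermAnnotation
    dag = pd.read_csv(dag_path, sep="\t")
    ann = pd.read_csv(annotation_path, sep="\t")
    gene_terms = {g: set(sub["term"]) for g, sub in ann.groupby("gene")}
    return TermAnnotation(list(zip(dag["child"], dag["parent"])), gene_terms)


def write_layout(layout: GenomeLayout, genes_path, tads_path) -> None:
    cols = ["gene", "chrom", "strand", "tss", "start", "end"]
    layout.genes[cols].to_csv(genes_path, sep="\t", index=False)
    layout.tads.to_csv(tads_path, sep="\t", index=False)


def read_layout(genes_path, tads_path) -> GenomeLayout:
    genes = pd.read_csv(genes_path, sep="\t")
    tads = pd.read_csv(tads_path, sep="\t")
    return GenomeLayout(genes=genes, tads=tads)


def write_dhs_peaks(peaks: dict, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ct in sorted(peaks):
        peaks[ct].to_csv(directory / f"{ct}.bed", sep="\t", index=False,
                         header=False)


def read_dhs_peaks(directory) -> dict:
    directory = Path(directory)
    out = {}
    for f in sorted(directory.glob("*.bed")):
        out[f.stem] = pd.read_csv(f, sep="\t", header=None,
                                  names=["chrom", "start", "end", "score"])
    return out


def write_contacts(contacts: pd.DataFrame, path) -> None:
    contacts.to_csv(path, sep="\t", index=False)


def read_contacts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clinical(cohort: SurvivalCohort, path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> SurvivalCohort:
    return SurvivalCohort(pd.read_csv(path, sep="\t"))


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "genes": truth.genes,
        "pair_labels": {f"{a}|{b}": c for (a, b), c in sorted(truth.pair_labels.items())},
        "independent_pairs": {f"{a}|{b}": c
                              for (a, b), c in sorted(truth.independent_pairs.items())},
        "prognostic_module": truth.prognostic_module,
        "patient_group": truth.patient_group,
        "validation_group": truth.validation_group,
        "cell_tumor": truth.cell_tumor,
        "complexes": {cid: {"genes": sorted(m), "class": c}
                      for cid, (m, c) in sorted(truth.complexes.items())},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_class_table(class_table: pd.DataFrame, path) -> None:
    class_table.to_csv(path, sep="\t", index=False)


def read_class_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_thresholds(thresholds, path) -> None:
    payload = {
        "pos_tail": thresholds.pos_tail,
        "nocorr_mass_per_side": thresholds.nocorr_mass_per_side,
        "levels": {lvl: vars(t) for lvl, t in thresholds.by_level.items()},
        "metadata": thresholds.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj, key=str) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
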