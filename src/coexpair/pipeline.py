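"""End-to-end orchestration: simulate -> preprocess -> correlate ->
classify -> enrich -> regulatory -> survival, with one root seed and a
single machine-readable report."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification, coexpression, enrichment, io, preprocess, regulatory, survival
from .synthetic import (AnnotationBundle, GroundTruth, SimulationConfig,
                        simulate_annotations, simulate_expression,
                        simulate_survival, simulate_validation)
from .types import ExpressionMatrix, pair_key

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "preprocess", "correlate", "classify",
              "enrich", "regulatory", "survival")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with seeded reproducibility."""

    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str | None = None
    seed: int = 0
    # thresholds / knobs
    pos_tail: float = 1e-6
    nocorr_mass_per_side: float = 0.3
    n_null_reps: int = 200
    top_k: int = 1000
    n_control_sets: int = 1000
    control_set_size: int = 1000
    alpha: float = 0.05
    max_combo: int = 3
    min_size: int = 3
    flank: int = 5000
    bin_width: float = 0.1
    min_mean_rpkm: float = 100.0
    max_zero_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{k: (tuple(tuple(x) for x in v)
                                      if k == "complexes" else v)
                                  for k, v in (raw.pop("simulate", {}) or {}).items()})
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulate=sim, **raw)


def _stage_seed(root: int, salt: int) -> int:
    return int(np.random.SeedSequence([root, salt]).generate_state(1)[0] % (2 ** 31))


def _recovery_metrics(class_table: pd.DataFrame, truth: GroundTruth) -> dict:
    """Planted-class recovery and cross-class mislabel rates."""
    label_to_class = {"shared": "shared", "sc_only": "sc_specific",
                      "bulk_only": "bulk_specific"}
    assigned = {pair_key(a, b): c for a, b, c in
                zip(class_table["gene_a"], class_table["gene_b"],
                    class_table["class"])}
    out: dict = {}
    cross = 0
    total = 0
    for label, expect in label_to_class.items():
        pairs = [p for p, l in truth.pair_labels.items() if l == label]
        if not pairs:
            out[f"recovery_{label}"] = float("nan")
            continue
        got = [assigned.get(p, "other") for p in pairs]
        out[f"recovery_{label}"] = float(np.mean([g == expect for g in got]))
        wrong = {"shared": {"sc_specific", "bulk_specific"},
                 "sc_only": {"shared", "bulk_specific"},
                 "bulk_only": {"shared", "sc_specific"}}[label]
        cross += sum(1 for g in got if g in wrong)
        total += len(got)
    out["cross_class_rate"] = cross / total if total else float("nan")
    out["n_planted_pairs"] = total
    return out


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and optionally write) a report."""
    stages = set(config.stages)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {
        **{k: v for k, v in dataclasses.asdict(config).items()
           if k not in ("simulate", "outdir")},
        "simulate": dataclasses.asdict(config.simulate)}}

    # ---- simulate ---------------------------------------------------------
    sim_cfg = replace(config.simulate, seed=config.seed)
    sc_raw, bulk_raw, truth = simulate_expression(sim_cfg)
    bundle = simulate_annotations(sim_cfg, truth)
    cohort = simulate_survival(sim_cfg, truth)
    val_expr, reference_id = simulate_validation(sim_cfg, truth)
    val_cohort = simulate_survival(sim_cfg, truth,
                                   group_map=truth.validation_group, seed_salt=5)
    if outdir and "simulate" in stages:
        io.write_expression(sc_raw, outdir / "expression_sc.tsv")
        io.write_expression(bulk_raw, outdir / "expression_bulk.tsv")
        io.write_expression(val_expr, outdir / "expression_validation.tsv")
        io.write_ppi(bundle.ppi, outdir / "ppi.tsv")
        io.write_complexes(bundle.complexes, outdir / "complexes.tsv")
        io.write_terms(bundle.terms, outdir / "term_dag.tsv",
                       outdir / "term_annotation.tsv")
        io.write_layout(bundle.layout, outdir / "layout.tsv", outdir / "tads.bed")
        io.write_dhs_peaks(bundle.dhs_peaks, outdir / "dhs_peaks")
        io.write_contacts(bundle.contacts, outdir / "contacts.tsv")
        io.write_clinical(cohort, outdir / "clinical.tsv")
        io.write_clinical(val_cohort, outdir / "clinical_validation.tsv")
        io.write_ground_truth(truth, outdir / "ground_truth.json")

    if "preprocess" not in stages:
        if outdir:
            io.write_report(report, outdir / "report.json")
        return report

    # ---- preprocess -------------------------------------------------------
    sc, bulk = preprocess.preprocess_pair(
        sc_raw, bulk_raw, min_mean=config.min_mean_rpkm,
        max_zero_fraction=config.max_zero_fraction)
    bulk_log2 = preprocess.log2_plus_one(
        preprocess.filter_bulk_genes(bulk_raw, config.min_mean_rpkm))
    report["preprocess"] = {"n_genes": sc.n_genes,
                            "n_cells": sc.n_samples, "n_bulk": bulk.n_samples}

    if "correlate" not in stages:
        if outdir:
            io.write_report(report, outdir / "report.json")
        return report

    # ---- correlate --------------------------------------------------------
    table = coexpression.correlation_table(sc, bulk)
    n_pairs = len(table)
    k = min(config.top_k, n_pairs)
    top_sc = coexpression.pair_set(coexpression.top_k_pairs(table, "single_cell", k))
    top_bulk = coexpression.pair_set(coexpression.top_k_pairs(table, "bulk", k))
    overlap = len(top_sc & top_bulk)
    report["coexpression"] = {
        "n_pairs": n_pairs, "top_k": k,
        "top_k_overlap": overlap,
        "top_k_overlap_pct": 100.0 * overlap / k,
        "split_half_overlap_sc": coexpression.split_half_overlap(
            sc, k, _stage_seed(config.seed, 11)),
        "split_half_overlap_bulk": coexpression.split_half_overlap(
            bulk, k, _stage_seed(config.seed, 12)),
    }

    if "classify" not in stages:
        if outdir:
            io.write_report(report, outdir / "report.json")
        return report

    # ---- classify ---------------------------------------------------------
    null_sc = classification.build_null(sc, n_reps=config.n_null_reps,
                                        seed=_stage_seed(config.seed, 21))
    null_bulk = classification.build_null(bulk, n_reps=config.n_null_reps,
                                          seed=_stage_seed(config.seed, 22))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        thresholds = classification.derive_thresholds(
            null_sc, null_bulk, pos_tail=config.pos_tail,
            nocorr_mass_per_side=config.nocorr_mass_per_side)
    class_table = classification.classify_pairs(table, thresholds)
    report["classification"] = {
        "counts": classification.class_counts(class_table),
        "thresholds": {lvl: dataclasses.asdict(t)
                       for lvl, t in thresholds.by_level.items()},
        "recovery": _recovery_metrics(class_table, truth),
    }
    if outdir:
        io.write_class_table(class_table, outdir / "class_table.tsv")
        io.write_thresholds(thresholds, outdir / "thresholds.json")

    by_class = {cls: class_table[class_table["class"] == cls]
                for cls in ("shared", "sc_specific", "bulk_specific")}

    # ---- enrich -----------------------------------------------------------
    if "enrich" in stages:
        universe = sc.genes
        enr: dict = {}
        for i, (cls, sub) in enumerate(by_class.items()):
            if len(sub) == 0:
                enr[cls] = None
                continue
            pairs = list(zip(sub["gene_a"], sub["gene_b"]))
            frac = enrichment.ppi_fraction(pairs, bundle.ppi)
            ctrl = enrichment.random_pair_control(
                universe, enrichment.ppi_indicator(bundle.ppi), frac,
                n_sets=config.n_control_sets, set_size=config.control_set_size,
                seed=_stage_seed(config.seed, 31 + i))
            go_frac, go_n, go_ctrl = enrichment.go_similarity_fraction(
                pairs, bundle.terms, universe=universe,
                n_sets=min(200, config.n_control_sets),
                set_size=config.control_set_size,
                seed=_stage_seed(config.seed, 41 + i))
            enr[cls] = {
                "n_pairs": len(pairs),
                "ppi_fraction": frac, "ppi_control_mean": ctrl.control_mean,
                "ppi_fold": ctrl.fold, "ppi_t_p": ctrl.t_p,
                "ppi_empirical_p": ctrl.empirical_p,
                "go_fraction": go_frac, "go_n_scored": go_n,
                "go_control_mean": go_ctrl.control_mean if go_ctrl else None,
                "go_fold": go_ctrl.fold if go_ctrl else None,
            }
        cmap = enrichment.complex_coexpression_map(class_table, bundle.complexes)
        report["enrichment"] = {
            "by_class": enr,
            "complex_map": cmap.to_dict(orient="records"),
        }
        if outdir:
            cmap.to_csv(outdir / "complex_map.tsv", sep="\t", index=False)

    # ---- regulatory -------------------------------------------------------
    if "regulatory" in stages:
        dhs = regulatory.promoter_dhs_signal(bundle.dhs_peaks, bundle.layout)
        modes = regulatory.dhs_class_modes(class_table, dhs)
        reg: dict = {"dhs_modes": modes}
        rng = np.random.default_rng(_stage_seed(config.seed, 51))
        genes_arr = np.asarray(sc.genes)
        rand_pairs = []
        while len(rand_pairs) < 300:
            a, b = rng.choice(genes_arr, size=2, replace=False)
            rand_pairs.append(pair_key(a, b))
        rand_r = regulatory.dhs_correlation(rand_pairs, dhs)["dhs_r"].dropna()
        from .stats import density_mode
        reg["dhs_mode_random"] = density_mode(rand_r) if len(rand_r) >= 3 else None
        chrom_info = {}
        for cls, sub in by_class.items():
            if len(sub) == 0:
                chrom_info[cls] = None
                continue
            pairs = list(zip(sub["gene_a"], sub["gene_b"]))
            frac, ctrl = regulatory.same_chromosome_fraction(
                pairs, bundle.layout, seed=_stage_seed(config.seed, 52))
            intra = [p for p in pairs
                     if bundle.layout.chrom(p[0]) == bundle.layout.chrom(p[1])]
            tad = regulatory.same_tad_fraction(intra, bundle.layout) if intra else None
            chrom_info[cls] = {"same_chromosome_fraction": frac,
                               "random_control": ctrl,
                               "n_intra": len(intra),
                               "same_tad_fraction": tad}
        reg["location"] = chrom_info
        reg["contacts"] = regulatory.intra_inter_contact_enrichment(
            class_table, bundle.layout, bundle.contacts,
            flank=config.flank).to_dict(orient="records")
        report["regulatory"] = reg

    # ---- survival ---------------------------------------------------------
    if "survival" in stages:
        subnets = []
        for cls in ("shared", "sc_specific", "bulk_specific"):
            g = survival.build_class_network(class_table, cls)
            subnets.extend(survival.detect_subnetworks(
                g, min_size=config.min_size, class_label=cls))
        screened = survival.screen_subnetworks(subnets, bulk, cohort,
                                               alpha=config.alpha)
        sig = survival.combine_and_search(screened, bulk, cohort,
                                          max_combo=config.max_combo)
        block: dict = {
            "n_subnetworks": len(subnets),
            "n_significant": int(screened["significant"].sum())
            if len(screened) else 0,
        }
        if sig is not None:
            val_p, _ = survival.validate_signature(
                sig, bulk_log2.values, val_expr.values, reference_id,
                cohort, val_cohort)
            sig.validation_p = val_p
            module = set(truth.prognostic_module)
            block["signature"] = {
                "subnetworks": list(sig.subnetwork_ids),
                "genes": sig.genes,
                "gene_classes": sig.gene_classes,
                "composition": sig.composition,
                "logrank_statistic": sig.statistic,
                "logrank_p": sig.p, "q": sig.q,
                "silhouette": sig.silhouette,
                "validation_logrank_p": val_p,
                "module_gene_recall": (len(module & set(sig.genes)) / len(module))
                if module else None,
            }
            if outdir:
                named = survival.label_groups_by_survival(sig.partition, cohort)
                km = survival.km_curve_table(cohort, named)
                km.to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
        else:
            block["signature"] = None
        report["survival"] = block

    if outdir:
        io.write_report(report, outdir / "report.json")
    return report
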