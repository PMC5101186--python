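"""Multi-method benchmark orchestration and the end-to-end synthetic pipeline.

``run_benchmark`` executes enrichment QC and specificity scoring for each
configured pulldown method and consolidates a comparison report ranked by
specificity ratio.  ``run_full_pipeline`` chains the synthetic generators
through every analysis stage (enrichment, specificity, SILAC differential
binding, genomic occupancy, genetic interaction) with planted-truth checks,
reproducing the whole benchmark from one seed.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential_binding as db
from . import enrichment_qc as eq
from . import genetic_interaction as gi
from . import occupancy as oc
from . import specificity as sp
from . import synthetic as syn
from ._errors import ChromabenchError, ConfigError
from .io_formats import (
    AnnotationCatalog,
    ProteinQuantTable,
    SampleDescriptor,
    read_annotation_catalog,
    read_quant_table,
)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from one master seed."""
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class MethodReport:
    name: str
    ok: bool
    error: str | None = None
    n_detected: int = 0
    n_enriched: int = 0
    bait_qc_passed: bool = False
    bait_qc_status: str = ""
    class_fractions: dict[str, float] = field(default_factory=dict)
    ptp_fraction: float | None = None
    pfp_fraction: float | None = None
    specificity_ratio: float | None = None
    contamination_intensity_fraction: float | None = None
    contamination_peptide_fraction: float | None = None
    n_reference_recovered: int | None = None
    precision_percent: float | None = None


@dataclass
class BenchmarkReport:
    methods: dict[str, MethodReport]
    ranking: list[str]  # method names by descending specificity ratio

    @property
    def ok(self) -> bool:
        return all(m.ok for m in self.methods.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.ranking:
            m = self.methods[name]
            row = asdict(m)
            fracs = row.pop("class_fractions")
            for cls, f in sorted(fracs.items()):
                row[f"fraction_{cls}"] = f
            rows.append(row)
        return pd.DataFrame(rows).set_index("name")


def _load_samples(spec: dict) -> list[SampleDescriptor]:
    return [
        SampleDescriptor(
            label=lab,
            channel=d.get("channel", "none"),
            replicate=int(d.get("replicate", 1)),
            condition=d.get("condition", ""),
            role=d.get("role", ""),
        )
        for lab, d in spec.items()
    ]


def _benchmark_one(
    name: str,
    table: ProteinQuantTable,
    catalog: AnnotationCatalog,
    bait_samples: list[str],
    control_samples: list[str],
    reference_ids: set[str],
    bait_id: str | None,
    min_fold: float,
    top_k: int,
) -> MethodReport:
    enr = eq.filter_enriched(table, bait_samples, control_samples, min_fold=min_fold)
    ranked = eq.rank_by_abundance(table, bait_samples)
    partition = sp.resolve_classes(catalog)
    if bait_id is None:
        bait_members = sorted(catalog.members("bait"))
        bait_id = bait_members[0] if bait_members else ""
    qc = eq.bait_qc(ranked, bait_id, catalog.members("histone"), top_k=top_k)
    # fractions over the whole pulldown sample: the normalizing denominator is
    # the total protein intensity, so contaminant classes count against it
    report = sp.class_intensity_fractions(table, partition, bait_samples)
    ratio = sp.specificity_ratio(report)
    contam = sp.contamination_report(table, partition, bait_samples)
    n_rec, prec = eq.precision_against_reference(
        enr.enriched_ids, reference_ids, len(enr.enriched_ids)
    ) if enr.enriched_ids else (0, None)
    return MethodReport(
        name=name,
        ok=True,
        n_detected=int(enr.detected.sum()),
        n_enriched=len(enr.enriched_ids),
        bait_qc_passed=qc.passed,
        bait_qc_status=qc.status,
        class_fractions={k: float(v) for k, v in report.class_fraction.items()},
        ptp_fraction=report.ptp_fraction,
        pfp_fraction=report.pfp_fraction,
        specificity_ratio=ratio,
        contamination_intensity_fraction=contam.intensity_fraction,
        contamination_peptide_fraction=contam.peptide_fraction,
        n_reference_recovered=n_rec,
        precision_percent=prec,
    )


def run_benchmark(config: dict, outdir: str | Path | None = None) -> BenchmarkReport:
    """Run enrichment QC + specificity scoring for every configured method.

    Each method entry names a quant table (path or in-memory ``table``),
    its pulldown/control sample labels, and shares the annotation catalog.
    A failing method is recorded in the report instead of aborting the run.
    """
    methods_cfg = config.get("methods") or []
    if not methods_cfg:
        raise ConfigError("benchmark config lists no methods")
    catalog = config.get("catalog")
    if isinstance(catalog, (str, Path)):
        catalog = read_annotation_catalog(catalog)
    if catalog is None:
        raise ConfigError("benchmark config needs an annotation catalog")
    reference_class = config.get("reference_class", "known_interactor")
    reference_ids = catalog.members(reference_class)
    min_fold = float(config.get("min_fold", 2.0))
    top_k = int(config.get("top_k", 10))
    bait_id = config.get("bait_id")

    methods: dict[str, MethodReport] = {}
    for m in methods_cfg:
        name = m["name"]
        try:
            table = m.get("table")
            if table is None:
                table = read_quant_table(m["quant_table"], _load_samples(m["samples"]))
            methods[name] = _benchmark_one(
                name, table, catalog, list(m["bait_samples"]), list(m["control_samples"]),
                reference_ids, bait_id, min_fold, top_k,
            )
        except (ChromabenchError, KeyError, OSError, ValueError) as exc:
            methods[name] = MethodReport(name=name, ok=False, error=f"{type(exc).__name__}: {exc}")
    ranking = sorted(
        methods,
        key=lambda n: (
            methods[n].specificity_ratio if methods[n].specificity_ratio is not None else -np.inf
        ),
        reverse=True,
    )
    report = BenchmarkReport(methods=methods, ranking=ranking)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(outdir / "benchmark_report.tsv", sep="\t")
        with open(outdir / "benchmark_report.json", "w") as fh:
            json.dump(
                {"ranking": report.ranking,
                 "methods": {k: asdict(v) for k, v in report.methods.items()}},
                fh, indent=2, default=str,
            )
    return report


def simulate_fixture_dir(
    config: dict | None = None,
    outdir: str | Path = "fixtures",
    seed: int | None = None,
) -> Path:
    """Write a complete synthetic fixture directory for every pipeline stage.

    Emits quant tables for a clean and a contaminated protocol, the shared
    annotation catalog, SILAC ratios, peak/enhancer/superenhancer BEDs, a
    two-enrichment concordance BED, region and knockdown count matrices with
    design sidecars, a gene annotation, and the planted truth as JSON.
    """
    import yaml

    from .io_formats import (
        write_annotation_catalog,
        write_bed,
        write_counts,
        write_gene_annotation,
        write_quant_table,
    )

    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seeds = _spawn_seeds(int(cfg["seed"]), 10)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dump: dict = {"seed": int(cfg["seed"])}

    table_clean, catalog, truth_clean = syn.simulate_quant_experiment(
        cfg["quant"]["n_proteins"], profile=syn.clean_profile(),
        n_replicates=cfg["quant"]["n_replicates"], seed=seeds[0],
    )
    table_dirty, _, _ = syn.simulate_quant_experiment(
        cfg["quant"]["n_proteins"], profile=syn.contaminated_profile(),
        n_replicates=cfg["quant"]["n_replicates"], seed=seeds[1],
    )
    write_quant_table(table_clean, out / "quant_clean.tsv")
    write_quant_table(table_dirty, out / "quant_contaminated.tsv")
    write_annotation_catalog(catalog, out / "catalog.gmt")
    samples_cfg = {
        s.label: {"channel": s.channel, "replicate": s.replicate,
                  "condition": s.condition, "role": s.role}
        for s in table_clean.samples
    }
    with open(out / "samples.yaml", "w") as fh:
        yaml.safe_dump({"samples": samples_cfg}, fh)
    truth_dump["protein_class"] = truth_clean.protein_class

    s_cfg = cfg["silac"]
    ratio_table, truth_silac = syn.simulate_silac_ratios(
        s_cfg["n_proteins"], s_cfg["n_differential"], tuple(s_cfg["effect_log2_range"]),
        s_cfg["sigma_rep"], s_cfg["n_replicates"], seed=seeds[2],
    )
    db.write_ratio_table(ratio_table, out / "silac_ratios.tsv")
    truth_dump["differential_effects"] = truth_silac.differential_effects

    p_cfg = cfg["peaks"]
    peaks_a, peaks_b, superenh, truth_peaks = syn.simulate_peaks(
        p_cfg["genome_spec"], p_cfg["n_peaks_a"], p_cfg["n_peaks_b"],
        p_cfg["colocalization_fraction"], p_cfg["n_superenhancers"], seed=seeds[3],
    )
    write_bed(peaks_a, out / "peaks_a.bed")
    write_bed(peaks_b, out / "peaks_b.bed")
    write_bed(superenh, out / "superenhancers.bed")
    c_cfg = cfg["concordance"]
    two, truth_conc = syn.plant_two_method_enrichments(
        syn.tiled_peaks(c_cfg["n_peaks"], seed=seeds[4]),
        c_cfg["n_top"], c_cfg["n_discordant"],
        fold_threshold=c_cfg["fold_threshold"], seed=seeds[4],
    )
    write_bed(two, out / "concordance_peaks.bed")
    truth_dump["peak_counts"] = {**truth_peaks.peak_counts, **truth_conc.peak_counts}

    r_cfg = cfg["regions"]
    region_counts, region_design, truth_regions = syn.simulate_region_counts(
        r_cfg["n_regions"], r_cfg["n_preferential"], r_cfg["fold"],
        r_cfg["dispersion"], r_cfg["n_replicates"], seed=seeds[5],
    )
    region_counts.reset_index().to_csv(out / "region_counts.tsv", sep="\t", index=False)
    with open(out / "region_design.yaml", "w") as fh:
        yaml.safe_dump(
            {"samples": {k: {"condition": c, "replicate": r}
                         for k, (c, r) in region_design.items()}}, fh,
        )
    truth_dump["region_effects"] = truth_regions.differential_effects

    k_cfg = cfg["knockdown"]
    counts, truth_gi = syn.simulate_knockdown_counts(
        k_cfg["n_genes"], n_targets=k_cfg["n_targets"], effect_log2=k_cfg["effect_log2"],
        dispersion=k_cfg["dispersion"], n_replicates=k_cfg["n_replicates"], seed=seeds[6],
    )
    write_counts(counts, out / "knockdown_counts.tsv")
    with open(out / "knockdown_design.yaml", "w") as fh:
        yaml.safe_dump(
            {"samples": {k: {"condition": c, "replicate": r}
                         for k, (c, r) in counts.design.items()}}, fh,
        )
    truth_dump["gi_labels"] = truth_gi.gi_labels
    truth_dump["gi_ratios"] = truth_gi.gi_ratios

    prox_cfg = cfg["proximity"]
    genes, truth_genes = syn.simulate_gene_annotation(
        peaks_a, prox_cfg["n_near"], prox_cfg["n_far"],
        max_distance=prox_cfg["max_distance"], seed=seeds[7],
    )
    write_gene_annotation(genes, out / "genes.tsv")
    truth_dump["n_genes_near"] = truth_genes.peak_counts["n_genes_near"]

    with open(out / "truth.json", "w") as fh:
        json.dump(truth_dump, fh, indent=2)
    return out


DEFAULT_PIPELINE_CONFIG: dict = {
    "seed": 20170915,
    "quant": {"n_proteins": 500, "n_replicates": 2},
    "silac": {
        "n_proteins": 500, "n_differential": 50, "effect_log2_range": [2.0, 4.0],
        "sigma_rep": 0.3, "n_replicates": 3,
    },
    "peaks": {
        "genome_spec": {f"chr{i}": 2_000_000 for i in range(1, 6)},
        "n_peaks_a": 500, "n_peaks_b": 500,
        "colocalization_fraction": 0.6, "n_superenhancers": 142,
    },
    "concordance": {"n_peaks": 2000, "n_top": 1000, "n_discordant": 33, "fold_threshold": 2.0},
    "regions": {"n_regions": 1000, "n_preferential": 50, "fold": 4.0,
                "dispersion": 0.05, "n_replicates": 3},
    "knockdown": {"n_genes": 2000, "n_targets": 200, "effect_log2": 3.0,
                  "dispersion": 0.05, "n_replicates": 3},
    "proximity": {"n_near": 60, "n_far": 140, "max_distance": 10000},
}


def _merged_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_full_pipeline(
    config: dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate every input and run every stage, returning a result bundle.

    The bundle carries per-stage summaries plus boolean planted-truth checks
    under ``checks``; ``ok`` is their conjunction.  With ``outdir`` set, each
    stage writes its tables and a consolidated ``pipeline_summary.json``.
    """
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seeds = _spawn_seeds(int(cfg["seed"]), 10)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": int(cfg["seed"]), "stages": {}, "checks": {}}
    checks = bundle["checks"]

    # --- stage 1: two synthetic pulldown protocols, benchmarked -------------
    qc_cfg = cfg["quant"]
    table_clean, catalog, truth_clean = syn.simulate_quant_experiment(
        qc_cfg["n_proteins"], profile=syn.clean_profile(),
        n_replicates=qc_cfg["n_replicates"], seed=seeds[0],
    )
    table_dirty, _, _ = syn.simulate_quant_experiment(
        qc_cfg["n_proteins"], profile=syn.contaminated_profile(),
        n_replicates=qc_cfg["n_replicates"], seed=seeds[1],
    )
    bait_samples = [s.label for s in table_clean.samples if s.role == "bait"]
    control_samples = [s.label for s in table_clean.samples if s.role == "control"]
    bench = run_benchmark(
        {
            "catalog": catalog,
            "methods": [
                {"name": "clean_capture", "table": table_clean,
                 "bait_samples": bait_samples, "control_samples": control_samples},
                {"name": "bead_digest", "table": table_dirty,
                 "bait_samples": bait_samples, "control_samples": control_samples},
            ],
        },
        outdir=out,
    )
    clean = bench.methods["clean_capture"]
    dirty = bench.methods["bead_digest"]
    planted_specific = {
        pid for pid, cls in truth_clean.protein_class.items() if cls in syn.SPECIFIC_CLASSES
    }
    enr = eq.filter_enriched(table_clean, bait_samples, control_samples)
    recovered = enr.enriched_ids & planted_specific
    recall = len(recovered) / len(planted_specific)
    precision = len(recovered) / len(enr.enriched_ids) if enr.enriched_ids else 0.0
    checks["benchmark_ran"] = bench.ok
    checks["specificity_orders_methods"] = (
        clean.specificity_ratio is not None
        and dirty.specificity_ratio is not None
        and clean.specificity_ratio > dirty.specificity_ratio
    )
    checks["bait_qc_clean_method"] = clean.bait_qc_passed
    checks["enrichment_recovers_planted"] = recall >= 0.95 and precision >= 0.95
    bundle["stages"]["benchmark"] = {
        "ranking": bench.ranking,
        "specificity_ratio_clean": clean.specificity_ratio,
        "specificity_ratio_contaminated": dirty.specificity_ratio,
        "enrichment_recall": recall,
        "enrichment_precision": precision,
        "n_enriched_clean": clean.n_enriched,
    }

    # --- stage 2: SILAC differential binding --------------------------------
    s_cfg = cfg["silac"]
    ratio_table, truth_silac = syn.simulate_silac_ratios(
        s_cfg["n_proteins"], s_cfg["n_differential"],
        tuple(s_cfg["effect_log2_range"]), s_cfg["sigma_rep"],
        s_cfg["n_replicates"], seed=seeds[2],
    )
    diff = db.test_differential(ratio_table, alpha=0.1, moderate_variance=True)
    planted_diff = {p for p, e in truth_silac.differential_effects.items() if e != 0.0}
    sens = len(diff.significant_ids & planted_diff) / len(planted_diff)
    null_ids = set(ratio_table.protein_ids) - planted_diff
    null_frac = len(diff.significant_ids & null_ids) / len(null_ids)
    checks["silac_sensitivity"] = sens >= 0.9
    bundle["stages"]["silac"] = {
        "n_significant": len(diff.significant_ids),
        "sensitivity": sens,
        "null_significant_fraction": null_frac,
    }
    if out is not None:
        db.write_ratio_table(ratio_table, out / "silac_ratios.tsv")
        diff.table.to_csv(out / "silac_differential.tsv", sep="\t")

    # --- stage 3: occupancy --------------------------------------------------
    p_cfg = cfg["peaks"]
    peaks_a, peaks_b, superenh, truth_peaks = syn.simulate_peaks(
        p_cfg["genome_spec"], p_cfg["n_peaks_a"], p_cfg["n_peaks_b"],
        p_cfg["colocalization_fraction"], p_cfg["n_superenhancers"], seed=seeds[3],
    )
    ovl = oc.overlap(peaks_a, peaks_b)
    coloc = oc.superenhancer_colocalization(peaks_a, peaks_b, superenh)
    checks["peak_overlap_planted"] = (
        ovl.n_a_overlapping_b == truth_peaks.peak_counts["n_a_overlapping_b"]
    )
    checks["superenhancer_planted"] = (
        coloc.n_se_cobound == truth_peaks.peak_counts["n_se_overlapping_a"]
    )
    c_cfg = cfg["concordance"]
    tiled = syn.tiled_peaks(c_cfg["n_peaks"], seed=seeds[4])
    two, truth_conc = syn.plant_two_method_enrichments(
        tiled, c_cfg["n_top"], c_cfg["n_discordant"],
        fold_threshold=c_cfg["fold_threshold"], seed=seeds[4],
    )
    conc = oc.top_n_concordance(
        two, n=c_cfg["n_top"], fold_threshold=c_cfg["fold_threshold"]
    )
    checks["concordance_planted"] = conc.n_discordant == truth_conc.peak_counts["n_discordant"]
    r_cfg = cfg["regions"]
    region_counts, region_design, truth_regions = syn.simulate_region_counts(
        r_cfg["n_regions"], r_cfg["n_preferential"], r_cfg["fold"],
        r_cfg["dispersion"], r_cfg["n_replicates"], seed=seeds[5],
    )
    docc = oc.differential_occupancy(
        region_counts, region_design, "2iL", "serum", moderate_variance=True
    )
    planted_pref = {r for r, e in truth_regions.differential_effects.items() if e != 0.0}
    pref = docc.preferential("2iL")
    n_recovered = len(pref & planted_pref)
    n_false = len((pref | docc.preferential("serum")) - planted_pref)
    checks["differential_occupancy_recovery"] = (
        n_recovered >= 0.9 * len(planted_pref) and n_false <= 2
    )
    bundle["stages"]["occupancy"] = {
        "overlap_fraction": ovl.fraction_a_overlapping,
        "n_a_overlapping_b": ovl.n_a_overlapping_b,
        "se_cobound": coloc.n_se_cobound,
        "se_fraction_percent": coloc.se_fraction_percent,
        "n_discordant_top_n": conc.n_discordant,
        "preferential_recovered": n_recovered,
        "preferential_false": n_false,
    }
    if out is not None:
        from .io_formats import write_bed

        write_bed(peaks_a, out / "peaks_a.bed")
        write_bed(peaks_b, out / "peaks_b.bed")
        write_bed(superenh, out / "superenhancers.bed")
        docc.table.to_csv(out / "differential_occupancy.tsv", sep="\t")

    # --- stage 4: knockdown genetic interaction ------------------------------
    k_cfg = cfg["knockdown"]
    counts, truth_gi = syn.simulate_knockdown_counts(
        k_cfg["n_genes"], n_targets=k_cfg["n_targets"], effect_log2=k_cfg["effect_log2"],
        dispersion=k_cfg["dispersion"], n_replicates=k_cfg["n_replicates"], seed=seeds[6],
    )
    de_single = gi.de_test(counts, "kd_T", moderate_variance=True)
    de_double = gi.de_test(counts, "kd_TP", moderate_variance=True)
    cls = gi.gi_classify(de_single, de_double)
    labelled = [g for g in cls.table.index if g in truth_gi.gi_labels]
    correct = sum(cls.table.loc[g, "gi_class"] == truth_gi.gi_labels[g] for g in labelled)
    accuracy = correct / len(labelled) if labelled else 0.0
    de_sens = len(de_single.de_ids & set(truth_gi.gi_labels)) / len(truth_gi.gi_labels)
    checks["gi_accuracy"] = accuracy >= 0.95
    checks["de_sensitivity"] = de_sens >= 0.9
    prox_cfg = cfg["proximity"]
    gene_ids = list(cls.table.index)
    n_need = prox_cfg["n_near"] + prox_cfg["n_far"]
    gene_ids += [f"GX{i:05d}" for i in range(max(0, n_need - len(gene_ids)))]
    genes, truth_genes = syn.simulate_gene_annotation(
        peaks_a, prox_cfg["n_near"], prox_cfg["n_far"],
        max_distance=prox_cfg["max_distance"],
        gene_ids=gene_ids[:n_need], seed=seeds[7],
    )
    prox = oc.assign_nearby_genes(peaks_a, genes, max_distance=prox_cfg["max_distance"])
    checks["proximity_planted"] = (
        len(prox.genes_near) == truth_genes.peak_counts["n_genes_near"]
    )
    annotated, contingency = gi.integrate_with_binding(cls, prox.gene_to_peaks)
    bundle["stages"]["genetic_interaction"] = {
        "n_targets_de": len(de_single.de_ids),
        "de_sensitivity": de_sens,
        "classification_accuracy": accuracy,
        "class_proportions": {k: float(v) for k, v in cls.class_proportions().items()},
        "n_genes_near_peaks": len(prox.genes_near),
        "binding_contingency": {
            str(k): {str(c): int(v) for c, v in row.items()}
            for k, row in contingency.iterrows()
        },
    }
    if out is not None:
        from .io_formats import write_counts, write_gene_annotation

        write_counts(counts, out / "knockdown_counts.tsv")
        de_single.table.to_csv(out / "de_single.tsv", sep="\t")
        de_double.table.to_csv(out / "de_double.tsv", sep="\t")
        annotated.to_csv(out / "gi_classification.tsv", sep="\t")
        write_gene_annotation(genes, out / "genes.tsv")

    bundle["ok"] = all(checks.values())
    if out is not None:
        with open(out / "pipeline_summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=str)
    return bundle
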