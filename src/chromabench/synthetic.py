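"""Synthetic data with planted ground truth for every pipeline input.

The generators emulate the structure of chromatin-proteomics benchmark data —
lognormal MS intensities with class-wise enrichment factors and a hard
detection limit, SILAC replicate log2 ratios, genomic peak sets with an exact
planted colocalization fraction, and gamma-Poisson knockdown count matrices
with planted genetic-interaction labels.  Everything is deterministic under a
fixed seed, and every generated entity is recorded in :class:`SyntheticTruth`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .differential_binding import RatioTable
from .io_formats import (
    AnnotationCatalog,
    CountMatrix,
    GeneAnnotation,
    PeakSet,
    ProteinQuantTable,
    SampleDescriptor,
)

#: classes whose enrichment is antibody-driven; reset to background in the
#: no-antibody control.
SPECIFIC_CLASSES = ("bait", "known_interactor", "chromatin_dna_binder", "histone")

#: default class mix of a detected chromatin pulldown proteome.
DEFAULT_CLASS_PROPORTIONS = {
    "histone": 0.05,
    "known_interactor": 0.15,
    "chromatin_dna_binder": 0.20,
    "ribosomal": 0.15,
    "ribonucleoprotein": 0.13,
    "cytoplasmic_other": 0.30,
    "affinity_reagent": 0.02,
}

GI_LABELS = ("independent", "antagonistic", "synergistic")

#: planted double/single knockdown effect-ratio ranges per label; chosen to
#: sit clearly outside the classifier's default independence band [0.5, 1.5].
GI_RATIO_RANGES = {"antagonistic": (0.0, 0.4), "synergistic": (1.6, 2.5)}

#: observed split of single-knockdown target genes across interaction modes
#: (73.4/18.1/8.4, renormalized so the rounded percentages sum to exactly 1).
DEFAULT_GI_PROPORTIONS = {
    "independent": 0.734 / 0.999,
    "antagonistic": 0.181 / 0.999,
    "synergistic": 0.084 / 0.999,
}


@dataclass
class MethodProfile:
    """Intensity model of one pulldown protocol.

    ``class_factors`` multiply the baseline intensity per annotation class;
    ``bait_boost`` does the same for the single bait protein; intensities below
    ``detection_limit`` are censored to 0; ``sigma_rep`` is the SD of the
    log10 multiplicative replicate noise.
    """

    class_factors: dict[str, float]
    bait_boost: float = 100.0
    detection_limit: float = 0.0
    sigma_rep: float = 0.15
    mu_base: float = 6.0  # log10 of the baseline (background) intensity
    background_factor: float = 1.0

    def __post_init__(self):
        if any(f <= 0 for f in self.class_factors.values()):
            raise ConfigError("class factors must be > 0")
        if self.bait_boost <= 0 or self.background_factor <= 0:
            raise ConfigError("bait boost and background factor must be > 0")
        if self.sigma_rep < 0:
            raise ConfigError("sigma_rep must be >= 0")


def clean_profile(**overrides) -> MethodProfile:
    """A stringently washed DNA-capture protocol: strong chromatin enrichment,
    negligible reagent carry-over."""
    params = dict(
        class_factors={
            "histone": 30.0,
            "known_interactor": 8.0,
            "chromatin_dna_binder": 8.0,
            "ribosomal": 1.0,
            "ribonucleoprotein": 1.0,
            "cytoplasmic_other": 1.0,
            "affinity_reagent": 0.5,
        },
        bait_boost=100.0,
        detection_limit=1e5,
        sigma_rep=0.15,
    )
    params.update(overrides)
    return MethodProfile(**params)


def contaminated_profile(**overrides) -> MethodProfile:
    """A bead-digest protocol: chromatin still enriched, but ribosomal/RNP
    hitchhikers and the affinity reagent dominate much more of the signal."""
    params = dict(
        class_factors={
            "histone": 10.0,
            "known_interactor": 3.0,
            "chromatin_dna_binder": 3.0,
            "ribosomal": 8.0,
            "ribonucleoprotein": 8.0,
            "cytoplasmic_other": 3.0,
            "affinity_reagent": 50.0,
        },
        bait_boost=20.0,
        detection_limit=1e5,
        sigma_rep=0.15,
    )
    params.update(overrides)
    return MethodProfile(**params)


@dataclass
class SyntheticTruth:
    """Planted ground truth; only the fields relevant to a generator are set."""

    protein_class: dict[str, str] = field(default_factory=dict)
    differential_effects: dict[str, float] = field(default_factory=dict)
    gi_labels: dict[str, str] = field(default_factory=dict)
    gi_ratios: dict[str, float] = field(default_factory=dict)
    target_effects: dict[str, float] = field(default_factory=dict)
    peak_counts: dict[str, int] = field(default_factory=dict)


def _allocate_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items over named proportions."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"proportions must sum to 1, got {total}")
    names = list(proportions)
    raw = np.array([proportions[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return dict(zip(names, counts))


def simulate_quant_experiment(
    n_proteins: int,
    class_proportions: dict[str, float] | None = None,
    profile: MethodProfile | None = None,
    n_replicates: int = 2,
    include_control: bool = True,
    seed: int = 0,
) -> tuple[ProteinQuantTable, AnnotationCatalog, SyntheticTruth]:
    """Simulate one pulldown experiment (plus optional no-antibody control).

    log10 intensity of protein p in replicate r ~ Normal(mu_base +
    log10(factor(class(p))), sigma_rep), censored at the detection limit.  One
    dedicated bait protein (id ``BAIT``) is appended with factor
    ``bait_boost``.  In control samples the antibody-driven classes
    (:data:`SPECIFIC_CLASSES`) fall back to the background factor.
    """
    if class_proportions is None:
        class_proportions = DEFAULT_CLASS_PROPORTIONS
    if profile is None:
        profile = clean_profile()
    if n_replicates < 2:
        raise ConfigError("n_replicates must be >= 2")
    counts = _allocate_counts(n_proteins, class_proportions)
    rng = np.random.default_rng(seed)

    ids, classes = ["BAIT"], ["bait"]
    for cls in counts:
        for _ in range(counts[cls]):
            ids.append(f"P{len(ids):05d}")
            classes.append(cls)
    n = len(ids)

    log_factor = np.empty(n)
    log_factor[0] = np.log10(profile.bait_boost)
    for i in range(1, n):
        log_factor[i] = np.log10(profile.class_factors.get(classes[i], 1.0))
    ctrl_factor = np.array(
        [
            np.log10(profile.background_factor)
            if classes[i] in SPECIFIC_CLASSES
            else log_factor[i]
            for i in range(n)
        ]
    )

    samples: list[SampleDescriptor] = []
    cols: dict[str, np.ndarray] = {}

    def draw(mu_log):
        noise = rng.normal(0.0, profile.sigma_rep, n) if profile.sigma_rep > 0 else 0.0
        inten = 10.0 ** (profile.mu_base + mu_log + noise)
        inten[inten < profile.detection_limit] = 0.0
        return inten

    for r in range(1, n_replicates + 1):
        lab = f"pulldown_r{r}"
        samples.append(SampleDescriptor(label=lab, replicate=r, role="bait"))
        cols[lab] = draw(log_factor)
    if include_control:
        for r in range(1, n_replicates + 1):
            lab = f"noAB_r{r}"
            samples.append(SampleDescriptor(label=lab, replicate=r, role="control"))
            cols[lab] = draw(ctrl_factor)

    index = pd.Index(ids, name="protein_id")
    intensity = pd.DataFrame(cols, index=index)
    # peptide count: deterministic monotone function of intensity, 0 iff censored
    pep = intensity.map(lambda v: 0 if v == 0 else max(1, int(np.log10(v))))
    catalog = AnnotationCatalog(
        classes={
            cls: {ids[i] for i in range(n) if classes[i] == cls}
            for cls in ["bait"] + list(counts)
        }
    )
    truth = SyntheticTruth(protein_class=dict(zip(ids, classes)))
    table = ProteinQuantTable(
        intensity=intensity,
        peptide_count=pep.astype(np.int64),
        samples=samples,
        gene_symbol=pd.Series(ids, index=index, name="gene_symbol"),
    )
    return table, catalog, truth


def simulate_silac_ratios(
    n_proteins: int,
    n_differential: int,
    effect_log2_range: tuple[float, float] = (2.0, 4.0),
    sigma_rep: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[RatioTable, SyntheticTruth]:
    """Replicate log2(heavy/light) ratios ~ Normal(planted effect or 0, sigma_rep).

    Heavy encodes the ground-state (2iL) condition, light the serum condition.
    """
    if n_differential > n_proteins:
        raise ConfigError("n_differential must be <= n_proteins")
    if sigma_rep < 0:
        raise ConfigError("sigma_rep must be >= 0")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    diff_idx = np.sort(rng.choice(n_proteins, size=n_differential, replace=False))
    effects = np.zeros(n_proteins)
    lo, hi = effect_log2_range
    mags = rng.uniform(lo, hi, n_differential)
    signs = rng.choice([-1.0, 1.0], n_differential)
    effects[diff_idx] = mags * signs
    noise = (
        rng.normal(0.0, sigma_rep, (n_proteins, n_replicates))
        if sigma_rep > 0
        else np.zeros((n_proteins, n_replicates))
    )
    ratios = pd.DataFrame(
        effects[:, None] + noise,
        index=pd.Index(ids, name="protein_id"),
        columns=[f"r{j + 1}" for j in range(n_replicates)],
    )
    truth = SyntheticTruth(differential_effects=dict(zip(ids, effects)))
    return RatioTable(ratios=ratios), truth


def _place_loci(genome_spec: dict[str, int], n_loci: int, window: int, rng) -> list[tuple[str, int]]:
    """Non-overlapping locus anchors: each locus owns `window` bases."""
    slots: list[tuple[str, int]] = []
    for chrom in genome_spec:
        length = genome_spec[chrom]
        for pos in range(0, length - window, window):
            slots.append((chrom, pos))
    if len(slots) < n_loci:
        raise ConfigError(
            f"genome too small: {len(slots)} loci of {window} bp available, {n_loci} needed"
        )
    chosen = rng.choice(len(slots), size=n_loci, replace=False)
    return [slots[i] for i in np.sort(chosen)]


def simulate_peaks(
    genome_spec: dict[str, int],
    n_peaks_a: int,
    n_peaks_b: int,
    colocalization_fraction: float,
    n_superenhancers: int = 0,
    seed: int = 0,
    peak_length: int = 500,
    se_length: int = 5000,
) -> tuple[PeakSet, PeakSet, PeakSet, SyntheticTruth]:
    """Two peak sets with an exact planted overlap, plus superenhancers.

    Exactly ``round(colocalization_fraction * n_peaks_a)`` A peaks are overlapped
    by a B peak, and ``round(colocalization_fraction * n_superenhancers)``
    superenhancers are overlapped by an A peak; all remaining intervals are
    pairwise disjoint.  Enrichment values are attached to every interval.
    """
    if not 0.0 <= colocalization_fraction <= 1.0:
        raise ConfigError("colocalization_fraction must be in [0, 1]")
    k_b = int(round(colocalization_fraction * n_peaks_a))
    k_se = int(round(colocalization_fraction * n_superenhancers))
    if k_b > n_peaks_b:
        raise ConfigError("n_peaks_b too small for the requested colocalization fraction")
    if k_se > n_peaks_a:
        raise ConfigError("n_peaks_a too small to anchor the superenhancer overlap")
    rng = np.random.default_rng(seed)
    window = se_length + 4 * peak_length
    margin = se_length + peak_length  # anchor offset inside the window
    loci = _place_loci(genome_spec, n_peaks_a + (n_peaks_b - k_b) + n_superenhancers, window, rng)

    def enr(size):
        return np.round(rng.gamma(4.0, 2.0, size), 4)

    a_loci = loci[:n_peaks_a]
    rows_a = [
        {"chrom": c, "start": p + margin, "end": p + margin + peak_length, "name": f"A_{i}"}
        for i, (c, p) in enumerate(a_loci)
    ]
    # B peaks overlapping A: shifted by half a peak length onto k_b chosen A peaks
    b_anchor = rng.choice(n_peaks_a, size=k_b, replace=False)
    rows_b = [
        {
            "chrom": rows_a[i]["chrom"],
            "start": rows_a[i]["start"] + peak_length // 2,
            "end": rows_a[i]["start"] + peak_length // 2 + peak_length,
            "name": f"B_ov_{j}",
        }
        for j, i in enumerate(np.sort(b_anchor))
    ]
    free = loci[n_peaks_a : n_peaks_a + (n_peaks_b - k_b)]
    rows_b += [
        {"chrom": c, "start": p + margin, "end": p + margin + peak_length, "name": f"B_{j}"}
        for j, (c, p) in enumerate(free)
    ]
    # superenhancers: k_se anchored around A peaks (preferring A peaks without
    # a planted B partner so B and SE sets stay disjoint), rest on free loci
    not_b = np.setdiff1d(np.arange(n_peaks_a), b_anchor)
    pool = np.concatenate([not_b, np.sort(b_anchor)])
    se_anchor = pool[:k_se]
    rows_se = []
    for j, i in enumerate(np.sort(se_anchor)):
        start = max(0, rows_a[i]["start"] - (se_length - peak_length) // 2)
        rows_se.append(
            {"chrom": rows_a[i]["chrom"], "start": start, "end": start + se_length,
             "name": f"SE_ov_{j}"}
        )
    free_se = loci[n_peaks_a + (n_peaks_b - k_b) :]
    rows_se += [
        {"chrom": c, "start": p, "end": p + se_length, "name": f"SE_{j}"}
        for j, (c, p) in enumerate(free_se[: n_superenhancers - k_se])
    ]

    def build(rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        if len(df):
            df["enrichment"] = enr(len(df))
        else:
            df["enrichment"] = pd.Series(dtype=float)
        return PeakSet(df=df)

    truth = SyntheticTruth(
        peak_counts={
            "n_a_overlapping_b": k_b,
            "n_b_overlapping_a": k_b,
            "n_se_overlapping_a": k_se,
        }
    )
    return build(rows_a), build(rows_b), build(rows_se), truth


def tiled_peaks(
    n_peaks: int,
    chrom: str = "chr1",
    peak_length: int = 500,
    gap: int = 500,
    seed: int = 0,
) -> PeakSet:
    """Simple non-overlapping peak tiling along one chromosome (enrichment-free)."""
    step = peak_length + gap
    starts = np.arange(n_peaks, dtype=np.int64) * step
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + peak_length,
            "name": [f"T_{i}" for i in range(n_peaks)],
        }
    )
    return PeakSet(df=df)


def plant_two_method_enrichments(
    peaks: PeakSet,
    n_top: int,
    n_discordant: int,
    fold_threshold: float = 2.0,
    seed: int = 0,
) -> tuple[PeakSet, SyntheticTruth]:
    """Attach paired enrichment columns with an exact planted discordance.

    ``enrichment_A`` strictly decreases with a random peak order; among the
    top ``n_top`` peaks by A, exactly ``n_discordant`` receive a B enrichment
    strictly below ``fold_threshold`` and the rest strictly above it.
    """
    n = len(peaks)
    if n_top > n or n_discordant > n_top:
        raise ConfigError("n_discordant <= n_top <= number of peaks required")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)  # order[j] = peak holding rank j+1 by A
    enr_a = np.empty(n)
    enr_a[order] = np.linspace(100.0, 1.0, n)
    enr_b = np.empty(n)
    top = order[:n_top]
    disc = rng.choice(n_top, size=n_discordant, replace=False)
    is_disc = np.zeros(n_top, dtype=bool)
    is_disc[disc] = True
    enr_b[top[is_disc]] = rng.uniform(0.1, 0.9 * fold_threshold, n_discordant)
    enr_b[top[~is_disc]] = rng.uniform(1.1 * fold_threshold, 10 * fold_threshold, n_top - n_discordant)
    enr_b[order[n_top:]] = rng.uniform(0.1, 10 * fold_threshold, n - n_top)
    df = peaks.df.copy()
    df["enrichment_A"] = enr_a
    df["enrichment_B"] = enr_b
    truth = SyntheticTruth(peak_counts={"n_discordant": n_discordant})
    return PeakSet(df=df), truth


def _nb_counts(mean: np.ndarray, dispersion: float, rng) -> np.ndarray:
    """Negative-binomial-like counts via a gamma-Poisson mixture."""
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    else:
        lam = mean
    return rng.poisson(lam)


def simulate_knockdown_counts(
    n_genes: int,
    baseline_log2_expr_range: tuple[float, float] = (5.0, 12.0),
    n_targets: int = 200,
    gi_label_proportions: dict[str, float] | None = None,
    effect_log2: float = 3.0,
    dispersion: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Count matrix for control / single-KD / double-KD conditions.

    Each target gene responds to the single knockdown with log2 change
    +-effect_log2; its double-knockdown response is r times that, with r = 1
    (independent), r ~ U[0, 0.4] (antagonistic) or r ~ U[1.6, 2.5]
    (synergistic) per the planted label.
    """
    if gi_label_proportions is None:
        gi_label_proportions = DEFAULT_GI_PROPORTIONS
    if n_targets > n_genes:
        raise ConfigError("n_targets must be <= n_genes")
    if effect_log2 < np.log2(1.5):
        warnings.warn(
            "effect_log2 below log2(1.5): planted targets would fail the DE fold filter",
            stacklevel=2,
        )
    label_counts = _allocate_counts(n_targets, gi_label_proportions)
    rng = np.random.default_rng(seed)
    ids = [f"G{i:05d}" for i in range(n_genes)]
    base = 2.0 ** rng.uniform(*baseline_log2_expr_range, n_genes)

    target_idx = np.sort(rng.choice(n_genes, size=n_targets, replace=False))
    labels = np.concatenate(
        [np.repeat(lab, label_counts[lab]) for lab in GI_LABELS if label_counts.get(lab)]
    )
    rng.shuffle(labels)
    delta = np.zeros(n_genes)
    delta[target_idx] = effect_log2 * rng.choice([-1.0, 1.0], n_targets)
    ratio = np.ones(n_genes)
    for j, gi in enumerate(target_idx):
        lab = labels[j]
        if lab in GI_RATIO_RANGES:
            ratio[gi] = rng.uniform(*GI_RATIO_RANGES[lab])

    cond_means = {
        "control": base,
        "kd_T": base * 2.0 ** delta,
        "kd_P": base,
        "kd_TP": base * 2.0 ** (ratio * delta),
    }
    design: dict[str, tuple[str, int]] = {}
    cols = {}
    for cond in ("control", "kd_T", "kd_P", "kd_TP"):
        for r in range(1, n_replicates + 1):
            lab = f"{cond}_r{r}"
            design[lab] = (cond, r)
            cols[lab] = _nb_counts(cond_means[cond], dispersion, rng)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    truth = SyntheticTruth(
        gi_labels={ids[g]: labels[j] for j, g in enumerate(target_idx)},
        gi_ratios={ids[g]: float(ratio[g]) for g in target_idx},
        target_effects={ids[g]: float(delta[g]) for g in target_idx},
    )
    return CountMatrix(counts=counts, design=design), truth


def simulate_region_counts(
    n_regions: int,
    n_preferential: int,
    fold: float = 4.0,
    dispersion: float = 0.05,
    n_replicates: int = 3,
    baseline_log2_range: tuple[float, float] = (5.0, 10.0),
    condition_a: str = "2iL",
    condition_b: str = "serum",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, tuple[str, int]], SyntheticTruth]:
    """Per-region read counts for two conditions with planted preferential regions.

    The first ``n_preferential`` regions (after a seeded shuffle) have
    ``fold``-times higher mean coverage in condition A.
    """
    if n_preferential > n_regions:
        raise ConfigError("n_preferential must be <= n_regions")
    rng = np.random.default_rng(seed)
    ids = [f"R{i:05d}" for i in range(n_regions)]
    base = 2.0 ** rng.uniform(*baseline_log2_range, n_regions)
    pref = np.zeros(n_regions, dtype=bool)
    pref[rng.choice(n_regions, size=n_preferential, replace=False)] = True
    mean_a = np.where(pref, base * fold, base)
    design: dict[str, tuple[str, int]] = {}
    cols = {}
    for cond, mean in ((condition_a, mean_a), (condition_b, base)):
        for r in range(1, n_replicates + 1):
            lab = f"{cond}_r{r}"
            design[lab] = (cond, r)
            cols[lab] = _nb_counts(mean, dispersion, rng)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="region_id"))
    truth = SyntheticTruth(
        differential_effects={ids[i]: (np.log2(fold) if pref[i] else 0.0) for i in range(n_regions)}
    )
    return counts, design, truth


def simulate_gene_annotation(
    peaks: PeakSet,
    n_near: int,
    n_far: int,
    max_distance: int = 10000,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[GeneAnnotation, SyntheticTruth]:
    """Gene TSS table with exactly ``n_near`` genes planted < max_distance from a peak.

    ``gene_ids`` optionally names the genes (near genes first); default ids
    are ``GN*`` (near) and ``GF*`` (far).
    """
    if n_near > len(peaks):
        raise ConfigError("n_near must be <= number of peaks")
    if gene_ids is not None and len(gene_ids) < n_near + n_far:
        raise ConfigError("gene_ids shorter than n_near + n_far")
    rng = np.random.default_rng(seed)

    def gid(j: int, near: bool) -> str:
        if gene_ids is not None:
            return gene_ids[j if near else n_near + j]
        return f"GN{j:05d}" if near else f"GF{j:05d}"

    rows = []
    near_peaks = rng.choice(len(peaks), size=n_near, replace=False)
    for j, i in enumerate(np.sort(near_peaks)):
        rec = peaks.df.iloc[i]
        offset = int(rng.integers(0, max_distance - 1))
        rows.append(
            {"gene_id": gid(j, True), "chrom": rec["chrom"],
             "tss": int(rec["end"]) - 1 + offset, "strand": "+" if j % 2 else "-"}
        )
    chroms = sorted(set(peaks.df["chrom"])) or ["chr1"]
    far_base = int(peaks.df["end"].max()) + 10 * max_distance if len(peaks) else 0
    for j in range(n_far):
        rows.append(
            {"gene_id": gid(j, False), "chrom": chroms[j % len(chroms)],
             "tss": far_base + j * max_distance, "strand": "+"}
        )
    truth = SyntheticTruth(peak_counts={"n_genes_near": n_near})
    return GeneAnnotation(df=pd.DataFrame(rows)), truth
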