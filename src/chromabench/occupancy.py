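"""Genomic-occupancy integration: interval overlap, colocalization, top-N
cross-method concordance, differential occupancy and gene-proximity assignment.

All coordinates are 0-based half-open.  Overlap uses a per-chromosome sorted
sweep; touching intervals ([0,10) vs [10,20)) do not overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import AnalysisError, DesignError
from ._stats import bh_adjust, log2_normalized, welch_t
from .io_formats import GeneAnnotation, PeakSet


def _by_chrom(peaks: PeakSet) -> dict[str, np.ndarray]:
    """chrom -> intervals sorted by start, as an (n, 2) array."""
    out = {}
    for chrom, sub in peaks.df.groupby("chrom", sort=True):
        arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
        out[str(chrom)] = arr[np.argsort(arr[:, 0], kind="stable")]
    return out


def _overlap_flags(a: PeakSet, b: PeakSet, min_bp: int) -> np.ndarray:
    """For each interval of `a` (original order): does it share >= min_bp bases
    with any single interval of `b`?  Sorted sweep per chromosome."""
    b_chrom = _by_chrom(b)
    flags = np.zeros(len(a), dtype=bool)
    starts = a.df["start"].to_numpy()
    ends = a.df["end"].to_numpy()
    chroms = a.df["chrom"].to_numpy()
    cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in b_chrom:
        arr = b_chrom[chrom]
        cache[chrom] = (arr[:, 0], arr[:, 1], np.maximum.accumulate(arr[:, 1]))
    for i in range(len(a)):
        c = chroms[i]
        if c not in cache:
            continue
        bs, be, be_max = cache[c]
        s, e = starts[i], ends[i]
        hi = int(np.searchsorted(bs, e - min_bp, side="right"))  # need bs <= e - min_bp
        if hi == 0:
            continue
        if min_bp == 1:
            flags[i] = be_max[hi - 1] > s
        else:
            ov = np.minimum(e, be[:hi]) - np.maximum(s, bs[:hi])
            flags[i] = bool((ov >= min_bp).any())
    return flags


def _merge(arr: np.ndarray) -> np.ndarray:
    """Merge sorted-by-start intervals into disjoint covered runs."""
    merged = []
    for s, e in arr:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def _covered_bases(by_chrom: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {c: _merge(arr) for c, arr in by_chrom.items()}


def _jaccard(a: PeakSet, b: PeakSet) -> float:
    """Base-pair Jaccard index over the merged footprints of the two sets."""
    ca = _covered_bases(_by_chrom(a))
    cb = _covered_bases(_by_chrom(b))
    inter = 0
    union = 0
    for chrom in set(ca) | set(cb):
        ma = ca.get(chrom, np.empty((0, 2), dtype=np.int64))
        mb = cb.get(chrom, np.empty((0, 2), dtype=np.int64))
        union += int((ma[:, 1] - ma[:, 0]).sum() + (mb[:, 1] - mb[:, 0]).sum())
        i = j = 0
        while i < len(ma) and j < len(mb):
            s = max(ma[i, 0], mb[j, 0])
            e = min(ma[i, 1], mb[j, 1])
            if e > s:
                inter += int(e - s)
            if ma[i, 1] < mb[j, 1]:
                i += 1
            else:
                j += 1
    union -= inter
    return inter / union if union > 0 else 0.0


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_a_overlapping_b: int
    n_b_overlapping_a: int
    fraction_a_overlapping: float
    jaccard: float
    min_bp: int


def overlap(peaks_a: PeakSet, peaks_b: PeakSet, min_bp: int = 1) -> OverlapSummary:
    """Count intervals of A sharing >= min_bp bases with any B interval (and
    vice versa), plus the base-pair Jaccard of the merged footprints.

    Chromosomes present in only one set are warned about and treated as
    non-overlapping.
    """
    if min_bp < 1:
        raise DesignError("min_bp must be >= 1")
    chroms_a = set(peaks_a.df["chrom"])
    chroms_b = set(peaks_b.df["chrom"])
    only = chroms_a ^ chroms_b
    if only and chroms_a and chroms_b:
        warnings.warn(
            f"chromosomes present in only one set treated as non-overlapping: {sorted(only)}",
            stacklevel=2,
        )
    fa = _overlap_flags(peaks_a, peaks_b, min_bp)
    fb = _overlap_flags(peaks_b, peaks_a, min_bp)
    n_a = len(peaks_a)
    return OverlapSummary(
        n_a=n_a,
        n_b=len(peaks_b),
        n_a_overlapping_b=int(fa.sum()),
        n_b_overlapping_a=int(fb.sum()),
        fraction_a_overlapping=float(fa.sum()) / n_a if n_a else 0.0,
        jaccard=_jaccard(peaks_a, peaks_b),
        min_bp=min_bp,
    )


@dataclass
class ColocalizationSummary:
    n_enhancers: int
    n_enhancers_cobound: int
    n_superenhancers: int
    n_se_cobound: int
    se_fraction_percent: int | None  # None when no superenhancers supplied


def superenhancer_colocalization(
    peaks: PeakSet,
    enhancers: PeakSet,
    superenhancers: PeakSet,
    min_bp: int = 1,
) -> ColocalizationSummary:
    """Enhancers and superenhancers overlapped by >= 1 peak; the superenhancer
    share is reported as a whole-number percentage (not applicable when the
    superenhancer set is empty)."""
    enh = _overlap_flags(enhancers, peaks, min_bp)
    se = _overlap_flags(superenhancers, peaks, min_bp)
    n_se = len(superenhancers)
    return ColocalizationSummary(
        n_enhancers=len(enhancers),
        n_enhancers_cobound=int(enh.sum()),
        n_superenhancers=n_se,
        n_se_cobound=int(se.sum()),
        se_fraction_percent=int(round(100.0 * se.sum() / n_se)) if n_se else None,
    )


@dataclass
class ConcordanceSummary:
    n: int
    fold_threshold: float
    n_discordant: int
    discordant_names: list[str]


def top_n_concordance(
    peaks: PeakSet,
    rank_by: str = "enrichment_A",
    other: str = "enrichment_B",
    n: int = 10000,
    fold_threshold: float = 2.0,
) -> ConcordanceSummary:
    """Among the top-``n`` peaks by one method's enrichment, count those the
    other method enriched strictly below ``fold_threshold``.

    Ranking ties are broken by (chrom, start) for determinism; ``n`` larger
    than the peak set is truncated with a warning.
    """
    df = peaks.df
    for col in (rank_by, other):
        if col not in df.columns:
            raise AnalysisError(f"missing enrichment column {col!r}")
    if n > len(df):
        warnings.warn(f"n={n} exceeds {len(df)} peaks; truncating", stacklevel=2)
        n = len(df)
    ordered = df.sort_values(
        [rank_by, "chrom", "start"], ascending=[False, True, True], kind="stable"
    ).head(n)
    disc = ordered[pd.to_numeric(ordered[other]) < fold_threshold]
    return ConcordanceSummary(
        n=n,
        fold_threshold=fold_threshold,
        n_discordant=int(len(disc)),
        discordant_names=list(disc["name"]),
    )


@dataclass
class DifferentialOccupancy:
    """Per-region condition comparison with mutually exclusive preference flags."""

    table: pd.DataFrame  # lfc, t, p, p_adj, preferential_a, preferential_b, tested
    condition_a: str
    condition_b: str
    fdr: float
    min_fold: float

    def preferential(self, condition: str) -> set[str]:
        col = {self.condition_a: "preferential_a", self.condition_b: "preferential_b"}[condition]
        return set(self.table.index[self.table[col]])


def differential_occupancy(
    region_counts: pd.DataFrame,
    design: dict[str, tuple[str, int]],
    condition_a: str,
    condition_b: str,
    fdr: float = 0.05,
    min_fold: float = 1.5,
    moderate_variance: bool = False,
) -> DifferentialOccupancy:
    """Welch t on log2 CPM per region, BH across regions; a region is
    preferential for a condition when adjusted p < fdr (strict) and linear
    fold > min_fold (strict) in that direction.  Counts are normalized with
    median-of-ratios size factors, which are robust to a subset of regions
    shifting strongly in one condition.  Regions with zero counts everywhere
    are left untested."""
    labels_a = [lab for lab, (c, _r) in design.items() if c == condition_a]
    labels_b = [lab for lab, (c, _r) in design.items() if c == condition_b]
    if len(labels_a) < 2 or len(labels_b) < 2:
        raise DesignError("need >= 2 replicates per condition")
    counts = region_counts[labels_a + labels_b]
    log_cpm = log2_normalized(counts)
    tested = counts.sum(axis=1) > 0
    res = welch_t(
        log_cpm[labels_a].to_numpy(), log_cpm[labels_b].to_numpy(),
        moderate_variance=moderate_variance,
        trend_covariate=log_cpm.mean(axis=1).to_numpy(),
    )
    res.index = region_counts.index
    p = res["p"].to_numpy(copy=True)
    p[~tested.to_numpy()] = np.nan
    res["p"] = p
    res["p_adj"] = bh_adjust(p)
    fold = 2.0 ** res["lfc"]
    sig = tested & (res["p_adj"] < fdr)
    res["preferential_a"] = sig & (fold > min_fold)
    res["preferential_b"] = sig & (1.0 / fold > min_fold)
    res["tested"] = tested
    return DifferentialOccupancy(
        table=res,
        condition_a=condition_a,
        condition_b=condition_b,
        fdr=fdr,
        min_fold=min_fold,
    )


def tss_peak_distance(tss: int, start: int, end: int) -> int:
    """Distance between a TSS and the nearest covered base of a half-open
    interval; 0 when the TSS lies inside the peak."""
    return max(0, start - tss, tss - (end - 1))


@dataclass
class GeneProximity:
    pairs: pd.DataFrame  # peak_name, gene_id, distance
    max_distance: int

    @property
    def peak_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for row in self.pairs.itertuples(index=False):
            out.setdefault(row.peak_name, set()).add(row.gene_id)
        return out

    @property
    def gene_to_peaks(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for row in self.pairs.itertuples(index=False):
            out.setdefault(row.gene_id, set()).add(row.peak_name)
        return out

    @property
    def genes_near(self) -> set[str]:
        return set(self.pairs["gene_id"])


def assign_nearby_genes(
    peaks: PeakSet,
    genes: GeneAnnotation,
    max_distance: int = 10000,
) -> GeneProximity:
    """All (peak, gene) pairs with TSS-to-peak distance strictly below
    ``max_distance``; strand only determines where the TSS is, not the match."""
    rows = []
    peak_by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("start", kind="stable")
        for c, sub in peaks.df.groupby("chrom", sort=True)
    }
    for g in genes.df.itertuples(index=False):
        sub = peak_by_chrom.get(str(g.chrom))
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # distance < D  <=>  start < tss + D  and  end - 1 > tss - D
        cand = np.flatnonzero((starts < g.tss + max_distance) & (ends - 1 > g.tss - max_distance))
        for i in cand:
            d = tss_peak_distance(int(g.tss), int(starts[i]), int(ends[i]))
            if d < max_distance:
                rows.append({"peak_name": sub["name"].iloc[i], "gene_id": g.gene_id, "distance": d})
    pairs = pd.DataFrame(rows, columns=["peak_name", "gene_id", "distance"])
    return GeneProximity(pairs=pairs, max_distance=max_distance)
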