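"""Enrichment against the no-antibody control, abundance ranking and bait QC.

A protein counts as enriched when its pulldown/control intensity ratio
exceeds the fold threshold (strictly) in every replicate pair; absence from
the control with signal present is treated as infinitely enriched.  Abundance
is the summed MS intensity across the pulldown replicates and drives the
rank-abundance QC: in a clean chromatin pulldown the bait itself and the
histones should sit at the top of the ranking.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import AnalysisError, DesignError
from .io_formats import ProteinQuantTable


@dataclass
class EnrichmentResult:
    """Per-protein fold changes vs control, enrichment calls, abundance ranking."""

    fold_changes: pd.DataFrame  # protein x replicate pair, +inf where control = 0
    enriched: pd.Series  # bool
    abundance: pd.Series  # summed intensity over pulldown samples
    detected: pd.Series  # bool: intensity > 0 in >= 1 pulldown sample
    rank: pd.Series  # 1-based dense rank over detected proteins, NaN otherwise
    min_fold: float

    @property
    def enriched_ids(self) -> set[str]:
        return set(self.enriched.index[self.enriched])

    def to_frame(self) -> pd.DataFrame:
        out = self.fold_changes.copy()
        out.columns = [f"fold_{c}" for c in out.columns]
        out["abundance"] = self.abundance
        out["detected"] = self.detected
        out["enriched"] = self.enriched
        out["rank"] = self.rank
        return out


def _default_pairing(table: ProteinQuantTable, bait_samples, control_samples):
    """Pair pulldown and control samples by replicate index."""
    by_rep = {table.sample(lab).replicate: lab for lab in control_samples}
    pairs = []
    for lab in bait_samples:
        rep = table.sample(lab).replicate
        if rep not in by_rep:
            raise DesignError(f"no control sample for replicate {rep} (pulldown {lab!r})")
        pairs.append((lab, by_rep[rep]))
    return pairs


def rank_by_abundance(table: ProteinQuantTable, samples: list[str]) -> pd.Series:
    """Detected proteins ordered by descending summed intensity.

    Ties are broken by lexicographic protein id, making the order
    deterministic.  Returns the ordered abundance series (index = protein_id).
    """
    if not samples:
        raise DesignError("samples must be non-empty")
    ab = table.intensity[samples].sum(axis=1)
    ab = ab[ab > 0]
    order = sorted(ab.index, key=lambda pid: (-ab[pid], pid))
    return ab.loc[order]


def filter_enriched(
    table: ProteinQuantTable,
    bait_samples: list[str],
    control_samples: list[str],
    min_fold: float = 2.0,
    require_all_replicates: bool = True,
    pairing: list[tuple[str, str]] | None = None,
) -> EnrichmentResult:
    """Call proteins enriched over the no-antibody control.

    Enriched iff the pulldown/control fold change is strictly > ``min_fold``
    in every replicate pair (or in >= 1 pair when ``require_all_replicates``
    is off) and the protein is detected in every pulldown replicate.  A pair
    with control intensity 0 and positive signal passes (fold +inf).
    """
    if not bait_samples or not control_samples:
        raise DesignError("bait and control sample sets must be non-empty")
    if set(bait_samples) & set(control_samples):
        raise DesignError("bait and control samples must be disjoint")
    if pairing is None:
        pairing = _default_pairing(table, bait_samples, control_samples)

    folds = {}
    for bait_lab, ctrl_lab in pairing:
        sig = table.intensity[bait_lab].to_numpy(dtype=float)
        ctl = table.intensity[ctrl_lab].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ctl > 0, sig / ctl, np.where(sig > 0, np.inf, 0.0))
        folds[bait_lab] = f
    fold_changes = pd.DataFrame(folds, index=table.protein_ids)

    detected_all = (table.intensity[bait_samples] > 0).all(axis=1)
    passes = fold_changes > min_fold
    enriched = (passes.all(axis=1) if require_all_replicates else passes.any(axis=1)) & detected_all

    abundance = table.intensity[bait_samples].sum(axis=1)
    detected = abundance > 0
    ranked = rank_by_abundance(table, bait_samples)
    rank = pd.Series(np.nan, index=table.protein_ids)
    rank.loc[ranked.index] = np.arange(1, len(ranked) + 1, dtype=float)
    return EnrichmentResult(
        fold_changes=fold_changes,
        enriched=enriched,
        abundance=abundance,
        detected=detected,
        rank=rank,
        min_fold=min_fold,
    )


@dataclass
class BaitQCReport:
    """Advisory abundance-rank check: bait and histones should top the ranking."""

    bait_id: str
    bait_detected: bool
    bait_rank: int | None
    histone_ranks: dict[str, int]
    top_k: int
    passed: bool
    status: str


def bait_qc(
    ranked: pd.Series,
    bait_id: str,
    histone_ids: set[str],
    top_k: int = 10,
) -> BaitQCReport:
    """QC the abundance ranking: pass iff the bait ranks within ``top_k`` and
    at least one histone does too.  An undetected bait yields a failed report
    with status "bait not detected", never an exception."""
    if ranked.empty:
        raise AnalysisError("ranking is empty")
    positions = {pid: i + 1 for i, pid in enumerate(ranked.index)}
    histone_ranks = {h: positions[h] for h in sorted(histone_ids) if h in positions}
    if bait_id not in positions:
        return BaitQCReport(
            bait_id=bait_id,
            bait_detected=False,
            bait_rank=None,
            histone_ranks=histone_ranks,
            top_k=top_k,
            passed=False,
            status="bait not detected",
        )
    bait_rank = positions[bait_id]
    histone_top = any(r <= top_k for r in histone_ranks.values())
    passed = bait_rank <= top_k and histone_top
    status = "pass" if passed else f"fail: bait rank {bait_rank}, histone in top {top_k}: {histone_top}"
    return BaitQCReport(
        bait_id=bait_id,
        bait_detected=True,
        bait_rank=bait_rank,
        histone_ranks=histone_ranks,
        top_k=top_k,
        passed=passed,
        status=status,
    )


def precision_against_reference(
    enriched_ids: set[str],
    reference_ids: set[str],
    detected_count: int,
) -> tuple[int, float]:
    """Recovered reference proteins and their share of the detected proteins.

    Returns ``(n_recovered, precision_percent)`` with the percentage reported
    to one decimal, mirroring a "recovered X of N detected (Y%)" statement.
    """
    n_recovered = len(set(enriched_ids) & set(reference_ids))
    if detected_count == 0:
        raise AnalysisError("precision undefined: zero detected proteins")
    if detected_count < n_recovered:
        raise AnalysisError("detected_count smaller than the recovered overlap")
    return n_recovered, round(100.0 * n_recovered / detected_count, 1)


def fold_change(after: float, before: float) -> float:
    """Plain ratio after/before (e.g. colony counts before/after an intervention)."""
    if before <= 0:
        raise AnalysisError("fold change undefined for non-positive baseline")
    return after / before
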