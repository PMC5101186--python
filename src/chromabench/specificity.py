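"""Intensity-fraction specificity scoring of chromatin pulldowns.

Detected proteins are partitioned into effective annotation classes; the
share of total MS intensity held by potential true positives (known
interactors, histones, other chromatin/DNA binders) over that held by
potential false positives (ribosomal proteins, ribonucleoproteins, other
cytoplasmic proteins) is the specificity ratio used to compare protocols.
Cumulative rank-class curves and affinity-reagent (IgG / protein A)
contamination accounting complete the benchmark readout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import AnalysisError, DesignError
from .io_formats import AnnotationCatalog, ProteinQuantTable

#: multi-annotated proteins resolve to the first matching class
CLASS_PRECEDENCE = (
    "bait",
    "known_interactor",
    "histone",
    "chromatin_dna_binder",
    "ribosomal",
    "ribonucleoprotein",
    "affinity_reagent",
    "cytoplasmic_other",
)

UNCLASSIFIED = "unclassified"

PTP_CLASSES = frozenset({"known_interactor", "histone", "chromatin_dna_binder"})
PFP_CLASSES = frozenset({"ribosomal", "ribonucleoprotein", "cytoplasmic_other"})


def resolve_classes(catalog: AnnotationCatalog) -> dict[str, str]:
    """Assign every annotated protein exactly one effective class.

    Precedence follows :data:`CLASS_PRECEDENCE`; catalog classes outside the
    reserved set rank after it in sorted order.  Unannotated proteins are not
    in the returned mapping (they fall into ``unclassified`` downstream).
    """
    order = list(CLASS_PRECEDENCE) + sorted(set(catalog.classes) - set(CLASS_PRECEDENCE))
    assignment: dict[str, str] = {}
    for cls in order:
        for pid in catalog.members(cls):
            assignment.setdefault(pid, cls)
    return assignment


@dataclass
class SpecificityReport:
    """Per-class intensity sums/fractions plus the PTP/PFP specificity ratio."""

    class_intensity: pd.Series
    class_fraction: pd.Series  # sums to 1 over effective classes incl. unclassified
    total_intensity: float
    ptp_fraction: float | None = None
    pfp_fraction: float | None = None
    specificity_ratio: float | None = None


def class_intensity_fractions(
    table: ProteinQuantTable,
    partition: dict[str, str],
    samples: list[str],
    protein_ids: set[str] | None = None,
) -> SpecificityReport:
    """Summed intensity per effective class, normalized by the total intensity.

    ``protein_ids`` optionally restricts the accounting to a protein subset
    (e.g. the enriched set of one method); the normalizing total is the total
    over the same subset.
    """
    if not samples:
        raise DesignError("samples must be non-empty")
    ab = table.intensity[samples].sum(axis=1)
    if protein_ids is not None:
        ab = ab[ab.index.isin(protein_ids)]
    total = float(ab.sum())
    if total <= 0:
        raise AnalysisError("total intensity is zero; fractions undefined")
    classes = pd.Series([partition.get(pid, UNCLASSIFIED) for pid in ab.index], index=ab.index)
    sums = ab.groupby(classes).sum().sort_index()
    return SpecificityReport(
        class_intensity=sums,
        class_fraction=sums / total,
        total_intensity=total,
    )


def specificity_ratio(
    report: SpecificityReport,
    ptp_classes: frozenset[str] = PTP_CLASSES,
    pfp_classes: frozenset[str] = PFP_CLASSES,
) -> float:
    """PTP over PFP intensity fraction; +inf when no PFP signal exists.

    Fills ``ptp_fraction``, ``pfp_fraction`` and ``specificity_ratio`` on the
    report and returns the ratio.  Invariant under uniform intensity rescaling.
    """
    frac = report.class_fraction
    ptp = float(frac[frac.index.isin(ptp_classes)].sum())
    pfp = float(frac[frac.index.isin(pfp_classes)].sum())
    if ptp == 0 and pfp == 0:
        raise AnalysisError("both PTP and PFP intensity sums are zero; ratio undefined")
    ratio = np.inf if pfp == 0 else ptp / pfp
    report.ptp_fraction = ptp
    report.pfp_fraction = pfp
    report.specificity_ratio = float(ratio)
    return float(ratio)


@dataclass
class CumulativeClassCurve:
    """Cumulative class membership along the abundance ranking."""

    class_name: str
    rank: np.ndarray  # 1..n
    y_count: np.ndarray  # cumulative members among the top-x
    class_size: int  # members among the ranked (detected) proteins
    y_fraction: np.ndarray = field(init=False)  # NaN when the class is empty

    def __post_init__(self):
        if self.class_size > 0:
            self.y_fraction = self.y_count / float(self.class_size)
        else:
            self.y_fraction = np.full(len(self.rank), np.nan)


def cumulative_class_curve(
    ranked: pd.Series,
    partition: dict[str, str],
    class_name: str,
    known_classes: set[str] | None = None,
) -> CumulativeClassCurve:
    """Prefix counts of one class along a descending abundance ranking.

    ``known_classes`` is the class universe (defaults to the classes present
    in the partition plus ``unclassified``); asking for a class outside it is
    a KeyError, while a declared class with no detected member yields a flat
    zero curve of size 0.
    """
    if known_classes is None:
        known_classes = set(partition.values()) | {UNCLASSIFIED}
    if class_name not in known_classes:
        raise KeyError(f"unknown class {class_name!r}")
    member = np.array(
        [partition.get(pid, UNCLASSIFIED) == class_name for pid in ranked.index], dtype=int
    )
    y_count = np.cumsum(member)
    return CumulativeClassCurve(
        class_name=class_name,
        rank=np.arange(1, len(ranked) + 1),
        y_count=y_count,
        class_size=int(member.sum()),
    )


@dataclass
class ContaminationReport:
    """Signal attributable to the affinity reagents (IgG chains, protein A)."""

    intensity: float
    peptides: int
    intensity_fraction: float
    peptide_fraction: float


def contamination_report(
    table: ProteinQuantTable,
    partition: dict[str, str],
    samples: list[str],
) -> ContaminationReport:
    """Summed intensity and peptide count of affinity_reagent proteins, and
    their share of the sample totals (0 when nothing is detected)."""
    if not samples:
        raise DesignError("samples must be non-empty")
    reagent = [pid for pid, cls in partition.items() if cls == "affinity_reagent"]
    inten = table.intensity[samples]
    pep = table.peptide_count[samples]
    total_i = float(inten.to_numpy().sum())
    total_p = int(pep.to_numpy().sum())
    mask = inten.index.isin(reagent)
    sum_i = float(inten.loc[mask].to_numpy().sum())
    sum_p = int(pep.loc[mask].to_numpy().sum())
    return ContaminationReport(
        intensity=sum_i,
        peptides=sum_p,
        intensity_fraction=sum_i / total_i if total_i > 0 else 0.0,
        peptide_fraction=sum_p / total_p if total_p > 0 else 0.0,
    )
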