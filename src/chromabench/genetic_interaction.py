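"""Knockdown differential expression and genetic-interaction classification.

Genes responding to the single knockdown (adjusted p < 0.01 and fold > 1.5)
are the targets; the ratio of their double-knockdown to single-knockdown log2
expression change classifies each as independent of the second factor
(ratio within the independence band), antagonistic (effect attenuated or
sign-flipped) or synergistic (effect amplified).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DesignError
from ._stats import bh_adjust, log2_cpm, welch_t
from .io_formats import CountMatrix


@dataclass
class DEResult:
    """Per-gene knockdown-vs-control test at (FDR, fold) thresholds."""

    table: pd.DataFrame  # lfc, t, p, p_adj, de, tested
    condition: str
    reference: str
    fdr: float
    min_fold: float

    @property
    def de_ids(self) -> set[str]:
        return set(self.table.index[self.table["de"]])


def de_test(
    counts: CountMatrix,
    condition: str,
    reference: str = "control",
    fdr: float = 0.01,
    min_fold: float = 1.5,
    moderate_variance: bool = False,
    prior_df: float = 4.0,
) -> DEResult:
    """Library-size-normalized (log2 CPM + 1) Welch t per gene with BH across
    genes; the DE flag requires adjusted p < fdr and |linear fold| > min_fold
    (both strict).  Genes with zero counts in both groups are left untested."""
    groups = counts.conditions
    for grp in (condition, reference):
        if grp not in groups:
            raise DesignError(f"condition {grp!r} absent from design")
        if len(groups[grp]) < 2:
            raise DesignError(f"condition {grp!r} needs >= 2 replicates")
    labels_c = groups[condition]
    labels_r = groups[reference]
    sub = counts.counts[labels_c + labels_r]
    log_cpm = log2_cpm(sub)
    tested = sub.sum(axis=1) > 0
    res = welch_t(
        log_cpm[labels_c].to_numpy(),
        log_cpm[labels_r].to_numpy(),
        moderate_variance=moderate_variance,
        prior_df=prior_df,
        trend_covariate=log_cpm.mean(axis=1).to_numpy(),
    )
    res.index = counts.counts.index
    p = res["p"].to_numpy(copy=True)
    p[~tested.to_numpy()] = np.nan
    res["p"] = p
    res["p_adj"] = bh_adjust(p)
    res["tested"] = tested
    res["de"] = tested & (res["p_adj"] < fdr) & (2.0 ** res["lfc"].abs() > min_fold)
    return DEResult(table=res, condition=condition, reference=reference, fdr=fdr, min_fold=min_fold)


GI_CLASSES = ("independent", "antagonistic", "synergistic")


@dataclass
class GIClassification:
    """Per-target effect ratio r = delta_double / delta_single and its class."""

    table: pd.DataFrame  # delta_single, delta_double, ratio, gi_class
    independence_band: tuple[float, float]

    def class_counts(self) -> pd.Series:
        return self.table["gi_class"].value_counts().reindex(GI_CLASSES, fill_value=0)

    def class_proportions(self) -> pd.Series:
        counts = self.class_counts()
        return counts / counts.sum()


def gi_classify(
    de_single: DEResult,
    de_double: DEResult,
    independence_band: tuple[float, float] = (0.5, 1.5),
) -> GIClassification:
    """Classify the single-knockdown target genes by their double/single
    log2-change ratio.

    Within the band (inclusive) the second factor is irrelevant
    (independent); below it the double knockdown attenuates or flips the
    effect (antagonistic, the rescue pattern); above it the effect is
    amplified (synergistic).  Targets missing from the double-knockdown
    result are skipped with a warning.
    """
    lo, hi = independence_band
    if not lo < hi:
        raise DesignError("independence band must satisfy lo < hi")
    rows = []
    for gene in sorted(de_single.de_ids):
        if gene not in de_double.table.index or not de_double.table.loc[gene, "tested"]:
            warnings.warn(f"gene {gene!r} missing from double-knockdown result; skipped",
                          stacklevel=2)
            continue
        d_single = float(de_single.table.loc[gene, "lfc"])
        d_double = float(de_double.table.loc[gene, "lfc"])
        r = d_double / d_single
        cls = "independent" if lo <= r <= hi else ("antagonistic" if r < lo else "synergistic")
        rows.append(
            {"gene_id": gene, "delta_single": d_single, "delta_double": d_double,
             "ratio": r, "gi_class": cls}
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "delta_single", "delta_double", "ratio", "gi_class"]
    ).set_index("gene_id")
    return GIClassification(table=table, independence_band=(lo, hi))


def integrate_with_binding(
    gi: GIClassification,
    gene_to_peaks: dict[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate classified genes with a has_binding_site flag (a peak within
    the proximity threshold) and tally the class x flag contingency table."""
    annotated = gi.table.copy()
    annotated["has_binding_site"] = [
        bool(gene_to_peaks.get(g)) for g in annotated.index
    ]
    counts = (
        annotated.groupby(["gi_class", "has_binding_site"])
        .size()
        .unstack(fill_value=0)
        .reindex(list(GI_CLASSES), fill_value=0)
    )
    counts = counts.reindex(columns=[False, True], fill_value=0)
    return annotated, counts
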