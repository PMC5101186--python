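"""SILAC two-condition differential chromatin-binding analysis.

Replicate log2(heavy/light) ratios (heavy = ground-state 2iL medium, light =
serum) are tested protein-wise against 0 with a one-sample t-test and BH
adjustment; helper operations cover no-antibody-control subtraction with
cross-bait intersection, hierarchical clustering of the protein x bait ratio
matrix, and PTM-vs-parent-protein ratio shifts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from ._errors import AnalysisError, DesignError
from ._stats import bh_adjust, one_sample_t
from .io_formats import ProteinQuantTable


@dataclass
class RatioTable:
    """Per-protein per-replicate log2(heavy/light) ratios; NaN = not quantified."""

    ratios: pd.DataFrame  # protein x replicate

    @property
    def protein_ids(self) -> pd.Index:
        return self.ratios.index

    def equals(self, other: "RatioTable") -> bool:
        return self.ratios.equals(other.ratios)


def write_ratio_table(table: RatioTable, path) -> None:
    table.ratios.reset_index().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ratio_table(path) -> RatioTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df = df.set_index(df.columns[0])
    df.index.name = "protein_id"
    return RatioTable(ratios=df.astype(float))


def compute_ratios(
    table: ProteinQuantTable,
    pairing: list[tuple[str, str]],
    median_center: bool = True,
) -> RatioTable:
    """log2(heavy/light) per replicate pair; a pair with either channel
    undetected yields no ratio.  Per-replicate median centering (default on)
    removes mixing-ratio offsets, standard SILAC practice."""
    cols = {}
    for i, (heavy, light) in enumerate(pairing, start=1):
        h = table.intensity[heavy].to_numpy(dtype=float)
        l = table.intensity[light].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((h > 0) & (l > 0), np.log2(h / l), np.nan)
        cols[f"r{i}"] = r
    ratios = pd.DataFrame(cols, index=table.protein_ids)
    if ratios.notna().sum().sum() == 0:
        raise AnalysisError("no valid heavy/light pairs; ratio table is empty")
    if median_center:
        ratios = ratios - ratios.median(axis=0, skipna=True)
    return RatioTable(ratios=ratios)


@dataclass
class DifferentialResult:
    """Per-protein test of the mean log2 ratio against 0 with BH adjustment."""

    table: pd.DataFrame  # columns: n, mean, t, p, p_adj, significant, tested, zero_variance
    alpha: float

    @property
    def significant_ids(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def test_differential(
    ratios: RatioTable,
    alpha: float = 0.1,
    min_replicates: int = 2,
    moderate_variance: bool = False,
    prior_df: float = 4.0,
) -> DifferentialResult:
    """Two-sided one-sample t-test of replicate log2 ratios against 0.

    Proteins with fewer than ``min_replicates`` quantified ratios are left
    untested.  BH adjustment runs across all tested proteins; significance is
    adjusted p <= alpha (non-strict).  ``moderate_variance`` shrinks
    per-protein variances toward the across-protein median (prior weight
    ``prior_df``), the recommended setting for 2-3 replicate designs.
    """
    values = ratios.ratios.to_numpy(dtype=float)
    res = one_sample_t(values, moderate_variance=moderate_variance, prior_df=prior_df)
    res.index = ratios.protein_ids
    res.loc[res["n"] < min_replicates, "tested"] = False
    p = res["p"].to_numpy(copy=True)
    p[~res["tested"].to_numpy()] = np.nan
    res["p"] = p
    res["p_adj"] = bh_adjust(p)
    res["significant"] = res["tested"] & (res["p_adj"] <= alpha)
    return DifferentialResult(table=res, alpha=alpha)


def subtract_control_and_intersect(
    enriched_sets: list[set[str]],
    control_set: set[str] = frozenset(),
) -> set[str]:
    """Proteins common to every experiment, minus the no-antibody control."""
    if len(enriched_sets) < 2:
        raise DesignError("need >= 2 enriched sets to intersect")
    out = set(enriched_sets[0])
    for s in enriched_sets[1:]:
        out &= set(s)
    return out - set(control_set)


@dataclass
class ClusterResult:
    """Two-way agglomerative clustering of a protein x bait ratio matrix."""

    matrix: pd.DataFrame  # NaN-imputed input
    imputed_mask: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_distance_used: str
    col_distance_used: str

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _axis_linkage(x: np.ndarray, distance: str, method: str) -> tuple[np.ndarray, str]:
    """Linkage with correlation->euclidean fallback for constant observations."""
    used = distance
    if distance == "correlation" and (x.std(axis=1) == 0).any():
        used = "euclidean"
    d = pdist(x, metric=used)
    return linkage(d, method=method), used


def cluster_ratio_matrix(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    method: str = "average",
) -> ClusterResult:
    """Cluster proteins (rows) and baits (columns) of a mean-log2-ratio matrix.

    Missing cells are imputed by 0 (no change) for the distance computation
    only, with the mask recorded.  A constant row/column under correlation
    distance triggers a euclidean fallback for that axis, recorded in
    ``*_distance_used``.  Deterministic for a fixed input order.
    """
    if matrix.shape[1] < 2:
        raise DesignError("need >= 2 bait columns to cluster")
    if matrix.shape[0] < 2:
        raise DesignError("need >= 2 proteins to cluster")
    mask = matrix.isna()
    filled = matrix.fillna(0.0)
    x = filled.to_numpy(dtype=float)
    row_link, row_used = _axis_linkage(x, distance, method)
    col_link, col_used = _axis_linkage(x.T, distance, method)
    return ClusterResult(
        matrix=filled,
        imputed_mask=mask,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[filled.index[i] for i in leaves_list(row_link)],
        col_order=[filled.columns[i] for i in leaves_list(col_link)],
        row_distance_used=row_used,
        col_distance_used=col_used,
    )


@dataclass
class PtmShift:
    """Difference between a PTM-site ratio and its parent-protein ratio."""

    site_id: str
    protein_id: str
    ptm_ratio: float
    protein_ratio: float
    delta: float
    flagged: bool


def ptm_shift(
    ptm_ratios: pd.DataFrame,
    protein_ratios: pd.Series,
    flag_threshold: float = 1.0,
) -> list[PtmShift]:
    """Delta = mean log2 ratio(PTM peptide) - mean log2 ratio(parent protein).

    ``ptm_ratios`` needs columns site_id, protein_id, log2_ratio.  Sites whose
    parent protein has no ratio are skipped with a warning; |delta| above the
    threshold flags a candidate stoichiometry shift.
    """
    out: list[PtmShift] = []
    for row in ptm_ratios.itertuples(index=False):
        if row.protein_id not in protein_ratios.index or pd.isna(protein_ratios[row.protein_id]):
            warnings.warn(f"orphan PTM site {row.site_id!r}: no parent protein ratio", stacklevel=2)
            continue
        prot = float(protein_ratios[row.protein_id])
        delta = float(row.log2_ratio) - prot
        out.append(
            PtmShift(
                site_id=row.site_id,
                protein_id=row.protein_id,
                ptm_ratio=float(row.log2_ratio),
                protein_ratio=prot,
                delta=delta,
                flagged=abs(delta) > flag_threshold,
            )
        )
    return out
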