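"""Shared statistical primitives: BH adjustment, (moderated) t-tests, CPM transform.

The moderated variants shrink per-feature variances toward the across-feature
median with a fixed prior weight, which stabilises t statistics in
few-replicate designs; the plain variants are ordinary one-sample / Welch
t-tests.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: p-value reported for a zero-variance, nonzero-mean contrast
P_FLOOR = float(np.nextafter(0, 1))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries are passed through untested."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _trend_prior(s2: np.ndarray, ok: np.ndarray, covariate: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Per-feature prior variance: median s2 within quantile bins of the covariate.

    Removes the mean-variance trend of count data before shrinkage, so
    low-abundance features are not shrunk toward a too-small global prior.
    """
    prior = np.full(len(s2), np.nan)
    idx = np.flatnonzero(ok)
    if len(idx) < 2 * n_bins:
        prior[:] = float(np.median(s2[idx])) if len(idx) else 0.0
        return prior
    order = idx[np.argsort(covariate[idx], kind="stable")]
    bins = np.array_split(order, n_bins)
    for b in bins:
        prior[b] = float(np.median(s2[b]))
    # features never tested inherit the global median
    prior[np.isnan(prior)] = float(np.median(s2[idx]))
    return prior


def _moderate(
    s2: np.ndarray,
    df: np.ndarray,
    prior_df: float,
    covariate: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrink sample variances toward a prior; returns (s2_tilde, total df).

    The prior is the across-feature median, or a covariate-trended median
    when a covariate (e.g. mean log abundance) is supplied.
    """
    ok = (df > 0) & np.isfinite(s2)
    if covariate is not None:
        s2_0 = _trend_prior(s2, ok, np.asarray(covariate, dtype=float))
    else:
        s2_0 = np.full(len(s2), float(np.median(s2[ok])) if ok.any() else 0.0)
    s2_t = np.where(ok, (prior_df * s2_0 + df * s2) / (prior_df + df), s2_0)
    return s2_t, df + prior_df


def one_sample_t(
    values: np.ndarray,
    moderate_variance: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Row-wise two-sided one-sample t-test against 0 with NaN-aware replicates.

    `values` is features x replicates; NaN marks a missing replicate.  Rows
    with < 2 observations get NaN statistics.  Zero variance with nonzero mean
    yields the smallest representable p and a ``zero_variance`` flag.
    """
    values = np.asarray(values, dtype=float)
    n = np.sum(~np.isnan(values), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(values, axis=1) / n
        resid = values - mean[:, None]
        s2 = np.nansum(resid * resid, axis=1) / np.where(n > 1, n - 1, np.nan)
    df = np.maximum(n - 1, 0).astype(float)
    if moderate_variance:
        s2_use, df_use = _moderate(s2, df, prior_df)
    else:
        s2_use, df_use = s2, df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_use / n)
    p = np.full(len(values), np.nan)
    tested = n >= 2
    zero_var = tested & (s2 == 0)
    calc = tested & ~zero_var & (df_use > 0)
    p[calc] = 2.0 * stats.t.sf(np.abs(t[calc]), df_use[calc])
    # zero variance: exact replicate agreement
    p[zero_var & (mean == 0)] = 1.0
    t[zero_var & (mean == 0)] = 0.0
    nz = zero_var & (mean != 0)
    p[nz] = P_FLOOR
    t[nz] = np.sign(mean[nz]) * np.inf
    return pd.DataFrame(
        {"n": n, "mean": mean, "t": t, "p": p, "tested": tested, "zero_variance": zero_var}
    )


def welch_t(
    x_a: np.ndarray,
    x_b: np.ndarray,
    moderate_variance: bool = False,
    prior_df: float = 4.0,
    trend_covariate: np.ndarray | None = None,
) -> pd.DataFrame:
    """Row-wise two-sided Welch t-test (group A minus group B).

    With ``moderate_variance`` the per-group variances are shrunk toward a
    prior (optionally trended along ``trend_covariate``, typically the mean
    log abundance) and the degrees of freedom credited accordingly.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    m_a, m_b = x_a.mean(axis=1), x_b.mean(axis=1)
    v_a = x_a.var(axis=1, ddof=1)
    v_b = x_b.var(axis=1, ddof=1)
    df_a = np.full(len(x_a), float(n_a - 1))
    df_b = np.full(len(x_b), float(n_b - 1))
    if moderate_variance:
        v_a, df_a = _moderate(v_a, df_a, prior_df, covariate=trend_covariate)
        v_b, df_b = _moderate(v_b, df_b, prior_df, covariate=trend_covariate)
    se2 = v_a / n_a + v_b / n_b
    diff = m_a - m_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v_a / n_a) ** 2 / df_a + (v_b / n_b) ** 2 / df_b)
    if moderate_variance:
        # the prior is shared information, not fresh observations per group:
        # cap total df at prior + pooled residual df to stay calibrated
        df = np.minimum(df, prior_df + (n_a - 1) + (n_b - 1))
    p = np.full(len(x_a), np.nan)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    zero = ~ok
    p[zero & (diff == 0)] = 1.0
    t[zero & (diff == 0)] = 0.0
    nz = zero & (diff != 0)
    p[nz] = P_FLOOR
    t[nz] = np.sign(diff[nz]) * np.inf
    return pd.DataFrame({"lfc": diff, "t": t, "p": p, "zero_variance": zero})


def log2_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudocount); all-zero libraries raise."""
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        bad = libsize.index[libsize == 0][0]
        raise ValueError(f"library {bad!r} has zero total counts")
    return np.log2(counts.astype(float) / libsize * 1e6 + pseudocount)


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Robust to composition bias: a handful of strongly shifted features does
    not drag the normalization of everything else, unlike total-count
    scaling.  Features with a zero anywhere are excluded from the reference.
    """
    arr = counts.to_numpy(dtype=float)
    pos = (arr > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no feature observed in every sample; size factors undefined")
    log_ref = np.log(arr[pos]).mean(axis=1)
    sf = np.exp(np.median(np.log(arr[pos]) - log_ref[:, None], axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return pd.Series(sf, index=counts.columns)


def log2_normalized(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 of median-of-ratios-normalized counts per million (+ pseudocount)."""
    sf = median_ratio_size_factors(counts)
    eff_lib = sf * counts.sum(axis=0).astype(float).mean()
    return np.log2(counts.astype(float) / eff_lib * 1e6 + pseudocount)
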