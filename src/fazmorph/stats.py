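"""Cohort-level statistical battery.

Non-parametric group comparison (Mann–Whitney U), rank correlation
(Spearman's rho), grader agreement (ICC(2,1) and Cohen's kappa), the
Shapiro–Wilk normality gate that motivates the non-parametric choices, and
the Snellen → ETDRS acuity conversion.  Every routine returns a
:class:`~fazmorph.types.StatResult` so results serialise uniformly.

Eyes are treated as independent observations throughout, mirroring the
clinical analyses this package models (no within-patient clustering
adjustment); this is a documented limitation, not an oversight.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .types import RatingsMatrix, StatResult

#: Largest per-group size at which the exact Mann–Whitney null is enumerated.
EXACT_MW_MAX_N = 8


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann–Whitney U test with midrank tie handling.

    The exact null distribution is enumerated when both groups have at most
    ``EXACT_MW_MAX_N`` observations and the pooled data are tie-free;
    otherwise the tie-corrected normal approximation is used (no continuity
    correction, matching common clinical-statistics software).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    notes = (
        "exact enumeration"
        if exact
        else "normal approximation with tie correction, no continuity correction"
    )
    return StatResult(
        name="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size + y.size),
        method_notes=notes,
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with midranks; two-sided p via the t
    approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho is undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    return StatResult(
        name="spearman_rho",
        statistic=float(rho),
        p_value=float(p),
        n=int(x.size),
        method_notes="midranks; two-sided p via t approximation",
    )


def icc_2_1(ratings: RatingsMatrix | np.ndarray) -> StatResult:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    Shrout–Fleiss convention:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)`` with MSR/MSC/MSE
    the row (subject), column (rater) and residual mean squares of the
    two-way ANOVA without replication.  The p-value is that of the
    F = MSR/MSE test against ICC = 0.
    """
    if not isinstance(ratings, RatingsMatrix):
        ratings = RatingsMatrix(values=np.asarray(ratings))
    y = ratings.values.astype(float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sse = float(((y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum())
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0):
        raise ValueError("ICC undefined: no variance in the ratings")
    icc = (msr - mse) / denom
    if mse > 0:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    else:
        f, p = math.inf, 0.0
    return StatResult(
        name="icc_2_1",
        statistic=float(icc),
        p_value=p,
        n=n,
        method_notes=f"two-way random, single measure, absolute agreement; F={f:.4g}",
    )


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> StatResult:
    """Cohen's kappa for two raters' categorical labels.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with chance agreement from the
    marginal products; the two-sided p tests kappa = 0 via the large-sample
    normal approximation.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label lists must have equal length")
    if len(a) == 0:
        raise ValueError("empty input")
    cats = sorted(set(a) | set(b))
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).to_numpy()
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        raise ValueError("kappa undefined: both raters constant")
    if p_o == 1.0:
        return StatResult(
            name="cohen_kappa", statistic=1.0, p_value=0.0, n=int(n),
            method_notes="perfect agreement",
        )
    res = _sm_kappa(table, return_results=True)
    return StatResult(
        name="cohen_kappa",
        statistic=float(res.kappa),
        p_value=float(res.pvalue_two_sided),
        n=int(n),
        method_notes="normal-approximation p for kappa = 0",
    )


def shapiro_wilk_gate(x: Sequence[float], alpha: float = 0.05) -> StatResult:
    """Shapiro–Wilk normality test used as the parametric/non-parametric gate.

    When p < ``alpha`` in any analysed group the pipeline falls back to
    non-parametric tests; the decision is recorded in ``method_notes``.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.unique(x).size == 1:
        raise ValueError("normality test undefined for zero-variance sample")
    w, p = sps.shapiro(x)
    decision = "non-parametric" if p < alpha else "parametric"
    return StatResult(
        name="shapiro_wilk",
        statistic=float(w),
        p_value=float(p),
        n=int(x.size),
        method_notes=f"gate at alpha={alpha}: use {decision} tests",
    )


def snellen_to_etdrs(snellen_fraction: float | str) -> int:
    """Convert a Snellen acuity fraction to an ETDRS letter score.

    ``letters = 85 + 50 * log10(fraction)``, rounded to the nearest integer
    and clipped to [0, 100].  Accepts a float (e.g. ``0.5``) or a fraction
    string (``"20/40"``).
    """
    if isinstance(snellen_fraction, str):
        num, _, den = snellen_fraction.partition("/")
        if not den:
            raise ValueError("fraction string must look like '20/40'")
        snellen_fraction = float(num) / float(den)
    if snellen_fraction <= 0:
        raise ValueError("Snellen fraction must be positive")
    letters = 85.0 + 50.0 * math.log10(snellen_fraction)
    return int(np.clip(round(letters), 0, 100))
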