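"""The angle-typicality rule evaluated as a diagnostic test for DR.

An atypical maximum-diameter angle (further than 15° from both the
horizontal and the vertical axis) is the positive test; diabetic
retinopathy is the condition.  Sensitivity and specificity carry exact
Clopper–Pearson binomial confidence intervals, and association is tested
with Pearson's chi-square.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

from .types import DiagnosticResult


def build_contingency(
    classes: Sequence[str], labels: Sequence[str]
) -> np.ndarray:
    """Cross-tabulate angle classes against group labels.

    Rows are (dr, control), columns (atypical, typical); entry [0, 0] is
    the number of DR eyes testing positive (atypical angle).
    """
    if len(classes) != len(labels):
        raise ValueError("classes and labels must have equal length")
    if len(classes) == 0:
        raise ValueError("empty input")
    bad = set(classes) - {"typical", "atypical"}
    if bad:
        raise ValueError(f"unknown angle classes: {bad}")
    bad = set(labels) - {"control", "dr"}
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    table = np.zeros((2, 2), dtype=int)
    for cls, lab in zip(classes, labels):
        r = 0 if lab == "dr" else 1
        c = 0 if cls == "atypical" else 1
        table[r, c] += 1
    return table


def pearson_chi2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2×2 table.

    No continuity correction by default (plain Pearson statistic); set
    ``yates=True`` for the Yates-corrected variant.  Requires all row and
    column marginals to be positive.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all marginals must be positive")
    stat, p, _, _ = chi2_contingency(t, correction=yates)
    return float(stat), float(p)


def sens_spec_ci(
    table: np.ndarray, confidence: float = 0.95
) -> DiagnosticResult:
    """Sensitivity/specificity of the atypical-angle test with exact CIs.

    ``table`` rows are (dr, control), columns (atypical, typical).
    Sensitivity = atypical DR eyes / all DR eyes; specificity = typical
    control eyes / all control eyes.  Intervals are exact Clopper–Pearson
    binomial intervals at the requested confidence.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    n_dr, n_ctrl = int(t[0].sum()), int(t[1].sum())
    if n_dr == 0 or n_ctrl == 0:
        raise ValueError("both groups must be present to estimate sens/spec")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    alpha = 1.0 - confidence
    sens = t[0, 0] / n_dr
    spec = t[1, 1] / n_ctrl
    sens_ci = proportion_confint(t[0, 0], n_dr, alpha=alpha, method="beta")
    spec_ci = proportion_confint(t[1, 1], n_ctrl, alpha=alpha, method="beta")
    try:
        chi2_stat, chi2_p = pearson_chi2(t)
    except ValueError:
        chi2_stat, chi2_p = float("nan"), float("nan")
    return DiagnosticResult(
        table=t,
        sensitivity=float(sens),
        specificity=float(spec),
        sens_ci95=(float(sens_ci[0]), float(sens_ci[1])),
        spec_ci95=(float(spec_ci[0]), float(spec_ci[1])),
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
    )


def counts_from_fractions(n_dr: int, n_control: int,
                          typical_frac_dr: float,
                          typical_frac_control: float) -> np.ndarray:
    """Reconstruct the 2×2 table from group sizes and typical proportions.

    Counts are the rounded products; useful for rebuilding a published
    table from printed percentages.
    """
    typ_dr = int(round(typical_frac_dr * n_dr))
    typ_ctrl = int(round(typical_frac_control * n_control))
    return np.array([[n_dr - typ_dr, typ_dr], [n_control - typ_ctrl, typ_ctrl]])
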