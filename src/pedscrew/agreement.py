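"""Agreement and diagnostic statistics for validating dpw-based grading.

The dpw-based grades (rows) are cross-tabulated against a reference
image-based assessment (columns).  The table may contain the reserved
category ``"/"`` for directional breaches with no grade in the clinical
classification.  Provided statistics:

* Cohen's kappa with large-sample SE and Wald 95% CI (via statsmodels);
* Gwet's AC1, a chance-corrected agreement coefficient robust to extreme
  category prevalence, with its linearised variance estimator;
* Landis-Koch qualitative labels for agreement coefficients;
* binary reduction of the table to breach / no-breach with sensitivity,
  specificity, PPV and NPV (Wilson score CIs);
* Mann-Whitney U (exact enumeration for small samples, tie-corrected normal
  approximation otherwise) and Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedStatisticError

__all__ = [
    "CrossTab",
    "BinaryDiagnostic",
    "AgreementResult",
    "binarize_crosstab",
    "cohen_kappa",
    "gwet_ac1",
    "diagnostic_metrics",
    "mann_whitney_u",
    "spearman_rho",
    "landis_koch_label",
    "discordant_count",
    "marginal_breach_counts",
]

NO_GRADE = "/"


@dataclass(frozen=True)
class CrossTab:
    """Square contingency table of grades: rows = dpw-based, cols = reference.

    ``printed_row_totals`` / ``printed_col_totals`` / ``printed_grand_total``
    optionally carry margins as printed in a source document; when present
    they are checked against the cell sums and ``margins_consistent``
    reports the outcome (tables transcribed from print occasionally disagree
    with their own margins).
    """

    categories: tuple
    counts: np.ndarray
    printed_row_totals: tuple | None = None
    printed_col_totals: tuple | None = None
    printed_grand_total: int | None = None

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        k = len(self.categories)
        if c.shape != (k, k):
            raise ValueError("counts must be square and match the category list")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if c.sum() <= 0:
            raise ValueError("table must contain at least one observation")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "categories", tuple(str(x) for x in self.categories))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def margins_consistent(self) -> bool:
        ok = True
        if self.printed_row_totals is not None:
            ok &= tuple(self.counts.sum(axis=1)) == tuple(self.printed_row_totals)
        if self.printed_col_totals is not None:
            ok &= tuple(self.counts.sum(axis=0)) == tuple(self.printed_col_totals)
        if self.printed_grand_total is not None:
            ok &= self.total == self.printed_grand_total
        return bool(ok)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories), columns=list(self.categories))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "CrossTab":
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(), **kw)

    def index_of(self, category: str) -> int:
        return self.categories.index(str(category))


@dataclass(frozen=True)
class BinaryDiagnostic:
    """2x2 reduction: test = dpw-based breach flag, reference = image-based."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")
        if self.total <= 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementResult:
    estimate: float
    se: float
    ci95_low: float
    ci95_high: float
    label: str | None = None

    def __post_init__(self):
        if np.isfinite(self.estimate) and not (
            self.ci95_low - 1e-9 <= self.estimate <= self.ci95_high + 1e-9
        ):
            raise ValueError("estimate must lie within its confidence interval")


def binarize_crosstab(
    tab: CrossTab,
    positive_grades,
    exclude_categories=frozenset({NO_GRADE}),
) -> BinaryDiagnostic:
    """Reduce a grade table to breach / no-breach counts.

    Screws falling in an excluded category (default ``{"/"}``) for either
    rater are dropped; remaining grades are mapped to positive (breach) if
    in ``positive_grades``, else negative.  Counts are conserved:
    TP+FP+FN+TN = total - excluded.
    """
    pos = {str(g) for g in positive_grades}
    exc = {str(g) for g in exclude_categories}
    unknown = pos - set(tab.categories)
    if unknown:
        raise ValueError(f"positive grades not in table: {sorted(unknown)}")
    tp = fp = fn = tn = 0
    for i, gi in enumerate(tab.categories):
        for j, gj in enumerate(tab.categories):
            if gi in exc or gj in exc:
                continue
            c = int(tab.counts[i, j])
            test_pos, ref_pos = gi in pos, gj in pos
            if test_pos and ref_pos:
                tp += c
            elif test_pos:
                fp += c
            elif ref_pos:
                fn += c
            else:
                tn += c
    if tp + fp + fn + tn == 0:
        raise UndefinedStatisticError("table is empty after exclusions")
    return BinaryDiagnostic(tp=tp, fp=fp, fn=fn, tn=tn)


def cohen_kappa(tab: CrossTab) -> AgreementResult:
    """Cohen's kappa with large-sample SE and Wald 95% CI.

    kappa = (po - pe) / (1 - pe), with chance agreement pe from the product
    of the two raters' marginal proportions.
    """
    c = tab.counts.astype(float)
    n = c.sum()
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if abs(1.0 - pe) < 1e-12:
        raise UndefinedStatisticError("kappa undefined: chance agreement equals 1")
    res = _sm_kappa(c, return_results=True)
    k = float(res.kappa)
    se = float(res.var_kappa**0.5)
    lo, hi = float(res.kappa_low), float(res.kappa_upp)
    return AgreementResult(k, se, min(lo, k), max(hi, k), label=landis_koch_label(k))


def gwet_ac1(tab: CrossTab) -> AgreementResult:
    """Gwet's AC1 with its linearised variance estimator.

    Chance agreement pe = sum_k pi_k (1 - pi_k) / (K - 1), where pi_k is the
    mean of the two raters' marginal proportions for category k.
    """
    c = tab.counts.astype(float)
    n = c.sum()
    k = c.shape[0]
    if k < 2:
        raise UndefinedStatisticError("AC1 needs at least two categories")
    pa = np.trace(c) / n
    pi = (c.sum(axis=1) + c.sum(axis=0)) / (2.0 * n)
    pe = float(np.sum(pi * (1.0 - pi)) / (k - 1))
    if abs(1.0 - pe) < 1e-12:
        raise UndefinedStatisticError("AC1 undefined: chance agreement equals 1")
    ac1 = (pa - pe) / (1.0 - pe)

    # linearised per-item variance (single table, no finite-population factor)
    var_sum = 0.0
    for i in range(k):
        for j in range(k):
            cnt = c[i, j]
            if cnt == 0:
                continue
            a_ij = 1.0 if i == j else 0.0
            pe_ij = ((1.0 - pi[i]) + (1.0 - pi[j])) / (2.0 * (k - 1))
            gamma = (a_ij - pe) / (1.0 - pe)
            gamma_star = gamma - 2.0 * (1.0 - ac1) * (pe_ij - pe) / (1.0 - pe)
            var_sum += cnt * (gamma_star - ac1) ** 2
    var = var_sum / (n * (n - 1.0))
    se = float(np.sqrt(max(var, 0.0)))
    z = 1.959963984540054
    return AgreementResult(
        float(ac1), se, float(ac1 - z * se), float(ac1 + z * se), label=landis_koch_label(ac1)
    )


def _wilson(successes: int, n: int) -> AgreementResult:
    p = successes / n
    se = float(np.sqrt(p * (1 - p) / n))
    lo, hi = proportion_confint(successes, n, alpha=0.05, method="wilson")
    return AgreementResult(float(p), se, float(lo), float(hi))


def diagnostic_metrics(d: BinaryDiagnostic) -> dict:
    """Sensitivity, specificity, PPV, NPV with Wilson score 95% CIs.

    A metric with a zero denominator is returned with estimate NaN and the
    label ``"undefined"``.
    """
    defs = {
        "sensitivity": (d.tp, d.tp + d.fn),
        "specificity": (d.tn, d.tn + d.fp),
        "ppv": (d.tp, d.tp + d.fp),
        "npv": (d.tn, d.tn + d.fn),
    }
    out = {}
    for name, (num, den) in defs.items():
        if den == 0:
            out[name] = AgreementResult(float("nan"), float("nan"), float("nan"), float("nan"),
                                        label="undefined")
        else:
            out[name] = _wilson(num, den)
    return out


def mann_whitney_u(x, y) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples have at most 8 observations and no
    ties; tie-corrected normal approximation otherwise.  Returns
    ``{"U": ..., "p_two_sided": ...}`` with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UndefinedStatisticError("samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_two_sided": float(min(res.pvalue, 1.0))}


def spearman_rho(x, y) -> dict:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedStatisticError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p)}


_LANDIS_KOCH = (
    (0.0, "poor"),
    (0.205, "slight"),
    (0.405, "fair"),
    (0.605, "moderate"),
    (0.81, "substantial"),
)


def landis_koch_label(estimate: float) -> str:
    """Landis-Koch qualitative label for an agreement coefficient.

    Bins follow the conventional cut points at 0.20/0.40/0.60/0.80 applied
    to values rounded to two decimals (so 0.205 falls in "fair"); values of
    at least 0.81 are "almost perfect".
    """
    if not -1.0 - 1e-9 <= estimate <= 1.0 + 1e-9:
        raise ValueError("agreement estimates lie in [-1, 1]")
    label = "almost perfect"
    for bound, name in reversed(_LANDIS_KOCH):
        if estimate < bound:
            label = name
    return label


def discordant_count(tab: CrossTab, ungraded: str = NO_GRADE) -> int:
    """Number of screws graded differently by the two assessments.

    Screws in the reserved ``ungraded`` category count as discordant even
    when both raters assign it: it marks a breach direction outside the
    classification, i.e. a finding the reference scheme cannot express.
    """
    diag = sum(
        int(tab.counts[i, i]) for i, g in enumerate(tab.categories) if g != ungraded
    )
    return tab.total - diag


def marginal_breach_counts(
    tab: CrossTab, negative_grade: str, ungraded: str = NO_GRADE
) -> dict:
    """Per-rater breach counts from the table margins.

    For the dpw rater (rows) the reserved category marks a detected breach
    with no corresponding grade, so it counts as a breach; for the reference
    rater (columns) those same screws carry no breach record, so the
    reserved column is excluded.  Returns ``{"dpw": ..., "reference": ...}``.
    """
    i_neg = tab.index_of(negative_grade)
    row_breach = tab.total - int(tab.counts[i_neg, :].sum())
    col_breach = tab.total - int(tab.counts[:, i_neg].sum())
    if ungraded in tab.categories:
        col_breach -= int(tab.counts[:, tab.index_of(ungraded)].sum())
    return {"dpw": row_breach, "reference": col_breach}
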