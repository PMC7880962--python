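"""Per-feature reproducibility between acquisition protocols.

Robustness screening follows the standard phantom-study recipe: for every
feature, the intraclass correlation coefficient between two protocols is
computed across the phantom materials (two-way random-effects model,
absolute agreement, single measurement — ICC(2,1)); a feature is *robust*
for a protocol pair when ICC > 0.8, and an acquisition variable is declared
a *batch* (a relevant source of variability) when any of its protocol pairs
leaves fewer than 80% of the features robust.

The absolute-agreement form is deliberate: a protocol that shifts every
measurement by a constant is *not* reproducible for harmonization purposes,
and consistency-type ICCs would hide exactly that shift.

Robust-feature proportions before/after a correction are compared with a
two-proportion test (chi-square with Yates continuity correction, the
algebraic equivalent of the continuity-corrected two-proportion z test),
with Benjamini-Hochberg control of the false discovery rate within each
variability factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PairingError

__all__ = [
    "ICCReport",
    "icc_agreement",
    "icc_pairwise",
    "identify_batches",
    "compare_proportions",
    "bh_adjust",
    "robustness_summary",
]

ICC_THRESHOLD = 0.8
RULE_THRESHOLD = 80.0  # % robust features below which a variable is a batch


@dataclass
class ICCReport:
    """Per-feature ICC between one pair of protocols."""

    protocol_pair: tuple[str, str]
    per_feature_icc: pd.Series  # indexed by feature name
    icc_threshold: float = ICC_THRESHOLD

    @property
    def robust_flags(self) -> pd.Series:
        return self.per_feature_icc > self.icc_threshold

    @property
    def robust_count(self) -> int:
        return int(self.robust_flags.sum())

    @property
    def n_features(self) -> int:
        return int(self.per_feature_icc.size)

    @property
    def robust_fraction(self) -> float:
        """Percentage of robust features (0-100)."""
        return 100.0 * self.robust_count / self.n_features


def icc_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``x`` and ``y`` are the paired measurements of the same n subjects under
    the two protocols.  Computed from the two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with k = 2 raters.  Degenerate case: if the total variance is zero
    (identical constant measurements) the ICC is defined as 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / 1  # k - 1
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0 if ss_total == 0 else 0.0
    return float((msr - mse) / denom)


def icc_pairwise(
    table: pd.DataFrame,
    protocol_a: str,
    protocol_b: str,
    feature_cols: list[str],
    protocol_col: str = "protocol",
    subject_col: str = "material",
) -> ICCReport:
    """Per-feature ICC(2,1) between two protocols, subjects matched by id.

    ``table`` holds one row per (subject, protocol).  Raises
    :class:`PairingError` when the two protocols do not cover the same
    subject set exactly once each.
    """
    a = table[table[protocol_col] == protocol_a].set_index(subject_col)
    b = table[table[protocol_col] == protocol_b].set_index(subject_col)
    if a.index.has_duplicates or b.index.has_duplicates:
        raise PairingError("duplicate subject measurements within a protocol")
    if set(a.index) != set(b.index) or len(a) == 0:
        raise PairingError(
            f"protocols {protocol_a!r} and {protocol_b!r} measure different subjects"
        )
    if len(a) < 3:
        raise ValueError("ICC needs at least 3 matched subjects")
    b = b.loc[a.index]
    iccs = {
        f: icc_agreement(a[f].to_numpy(), b[f].to_numpy()) for f in feature_cols
    }
    return ICCReport((protocol_a, protocol_b), pd.Series(iccs))


def identify_batches(
    reports_by_variable: dict[str, list[ICCReport]],
    rule_threshold: float = RULE_THRESHOLD,
) -> list[str]:
    """Acquisition variables that are relevant sources of variability.

    A variable is flagged as a batch when *any* of its pairwise protocol
    comparisons has a robust-feature percentage strictly below
    ``rule_threshold`` (default 80%).
    """
    flagged = []
    for variable, reports in reports_by_variable.items():
        if any(r.robust_fraction < rule_threshold for r in reports):
            flagged.append(variable)
    return flagged


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> float:
    """Two-sided two-proportion test p-value.

    Default: chi-square test on the 2x2 table with Yates continuity
    correction (algebraically equivalent to the continuity-corrected
    two-proportion z test).  ``continuity=False`` gives the plain z test.
    Equal observed proportions return p = 1.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    if k1 * n2 == k2 * n1:  # identical proportions
        return 1.0
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        return 1.0
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def robustness_summary(reports_by_variable: dict[str, list[ICCReport]]) -> pd.Series:
    """Mean robust-feature percentage per variability factor, to 2 decimals."""
    return pd.Series(
        {
            var: round(float(np.mean([r.robust_fraction for r in reports])), 2)
            for var, reports in reports_by_variable.items()
        }
    )
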