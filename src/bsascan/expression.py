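"""Comparative-Ct relative expression (2^-ddCt) and Student's t-test.

Each biological replicate contributes a target-gene Ct and a
reference-gene Ct (technical triplicates are averaged upstream).  The
fold change of a replicate is 2 to the minus ddCt, where
dCt = Ct_target - Ct_reference and ddCt subtracts the mean dCt of the
calibrator group; by construction the calibrator group's fold changes
have geometric mean 1, and folds are invariant to adding a constant to
every Ct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ExpressionAssay:
    """Ct values for a sample group and a calibrator group."""

    sample_ct_target: tuple
    sample_ct_reference: tuple
    calibrator_ct_target: tuple
    calibrator_ct_reference: tuple

    def __post_init__(self) -> None:
        for name in ("sample_ct_target", "sample_ct_reference",
                     "calibrator_ct_target", "calibrator_ct_reference"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size == 0 and name.startswith("calibrator"):
                raise ValueError("calibrator group must be non-empty")
            if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
                raise ValueError(f"{name}: Ct values must be finite and > 0")
        if len(self.sample_ct_target) != len(self.sample_ct_reference) or \
                len(self.calibrator_ct_target) != len(self.calibrator_ct_reference):
            raise ValueError("target/reference Ct lengths must match per group")


@dataclass(frozen=True)
class FoldChanges:
    """2^-ddCt fold change per replicate, for both groups."""

    sample: np.ndarray
    calibrator: np.ndarray


def relative_expression(assay: ExpressionAssay) -> FoldChanges:
    """Comparative-Ct fold changes normalized to the calibrator group."""
    dct_sample = (np.asarray(assay.sample_ct_target, dtype=float)
                  - np.asarray(assay.sample_ct_reference, dtype=float))
    dct_cal = (np.asarray(assay.calibrator_ct_target, dtype=float)
               - np.asarray(assay.calibrator_ct_reference, dtype=float))
    baseline = dct_cal.mean()
    return FoldChanges(sample=2.0 ** -(dct_sample - baseline),
                       calibrator=2.0 ** -(dct_cal - baseline))


def relative_expression_table(df: pd.DataFrame,
                              calibrator_group: str) -> pd.DataFrame:
    """Tabular wrapper: TSV columns group, replicate, ct_target, ct_reference.

    Returns the input with ``delta_ct``, ``ddct`` and ``fold`` columns.
    """
    required = {"group", "ct_target", "ct_reference"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    cal = df[df["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    out = df.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    baseline = float(
        (cal["ct_target"] - cal["ct_reference"]).mean())
    out["ddct"] = out["delta_ct"] - baseline
    out["fold"] = 2.0 ** -out["ddct"]
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant: bool


def two_sample_t(group_a, group_b, alpha: float = 0.05,
                 welch: bool = False) -> TTestResult:
    """Two-sided two-sample t-test (pooled-variance Student's by default).

    Raises on groups smaller than 2 or on zero pooled variance (the test
    statistic is undefined for degenerate data).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0.0:
        raise ValueError("degenerate (zero) pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue),
                       significant=bool(res.pvalue < alpha))
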