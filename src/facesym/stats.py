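"""Two-sample comparison of asymmetry measures between cohorts.

A cohort table holds one row per subject with the 29 per-pair LSADs plus
their sum (30 measures) and a group label.  Each measure is screened with
an independent two-sample t-test; the report mirrors the conventional
group-comparison table layout: region, pair label, group mean ± SD,
p-value and a significance flag.  Pooled-variance (Student) is the default
variant, Welch is available; reported p-values are two-sided and no
multiple-testing correction is applied unless the optional FDR flag is on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pairs import PairTable, default_pair_table

__all__ = [
    "ComparisonRow",
    "independent_t_test",
    "compare_groups",
    "measure_columns",
    "cohort_from_frame",
]

MEASURE_SUM = "lsad_sum"


def measure_columns(pairs: PairTable | None = None) -> list[str]:
    """The 30 measure column names: pair_1..pair_n plus the sum."""
    if pairs is None:
        pairs = default_pair_table()
    return [f"pair_{i}" for i in pairs.pair_labels] + [MEASURE_SUM]


@dataclass(frozen=True)
class ComparisonRow:
    """One measure's group comparison."""

    measure: str
    region: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    t_statistic: float
    p_value: float
    significant: bool


def independent_t_test(
    a,
    b,
    tails: str = "two",
    variant: str = "pooled",
) -> tuple[float, float]:
    """Independent two-sample t-test.

    ``variant`` selects pooled-variance (Student) or unequal-variance
    (Welch).  ``tails='one'`` tests the directional hypothesis mean(a) >
    mean(b); ``'two'`` is the symmetric alternative.  Degenerate inputs
    with zero variance in both samples return (0, 1) for equal means and
    (±inf, 0) for different means — the limit of the statistic as the
    pooled variance vanishes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")

    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, 1.0
        t = np.inf if diff > 0 else -np.inf
        if tails == "two":
            return t, 0.0
        return t, 0.0 if diff > 0 else 1.0

    alternative = "greater" if tails == "one" else "two-sided"
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def cohort_from_frame(df: pd.DataFrame, pairs: PairTable | None = None) -> pd.DataFrame:
    """Validate a cohort table: group labels plus the 30 measure columns."""
    cols = measure_columns(pairs)
    missing = [c for c in ("subject_id", "group", *cols) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df[cols].isna().any().any():
        raise ValueError("cohort table contains missing measure values")
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"cohort table must contain exactly 2 groups, got {list(groups)}")
    return df


def compare_groups(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    *,
    variant: str = "pooled",
    case_label: str = "case",
    control_label: str = "control",
    pairs: PairTable | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Group-comparison table for the 30 asymmetry measures.

    Returns one row per measure (29 pairs in region order, then the sum)
    with group means ± SD (sample SD, ddof=1), pooled or Welch t, two-sided
    p and a significance flag at ``alpha``.  ``fdr=True`` additionally
    applies Benjamini–Hochberg and flags on the adjusted values (an
    extension; the default reproduces the uncorrected screen).
    """
    if pairs is None:
        pairs = default_pair_table()
    cohort = cohort_from_frame(cohort, pairs)
    for label in (case_label, control_label):
        if label not in set(cohort["group"]):
            raise ValueError(f"group label '{label}' not present in cohort")
    case = cohort[cohort["group"] == case_label]
    control = cohort[cohort["group"] == control_label]

    rows = []
    regions = list(pairs.regions) + ["all"]
    for measure, region in zip(measure_columns(pairs), regions):
        a = case[measure].to_numpy(float)
        b = control[measure].to_numpy(float)
        t, p = independent_t_test(a, b, tails="two", variant=variant)
        rows.append(
            ComparisonRow(
                measure=measure,
                region=region,
                case_mean=float(a.mean()),
                case_sd=float(a.std(ddof=1)),
                control_mean=float(b.mean()),
                control_sd=float(b.std(ddof=1)),
                t_statistic=t,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows])
    if fdr:
        out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] < alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
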