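"""Between-arm statistical comparison with explicit test routing.

Routing rules, applied per variable:

* categorical (incl. binary): Pearson chi-square on the contingency table,
  replaced by Fisher's exact test whenever any expected cell count is below 5
  (Fisher is applied to 2x2 tables; a wider sparse table keeps chi-square and
  the routing trace carries a warning).
* ordinal / metric: each group is first screened for normality with the
  Kolmogorov-Smirnov test using Lilliefors-corrected critical values (the
  plain KS test with estimated mean/sd is anti-conservative). If either group
  looks non-normal at alpha = 0.05 the comparison is the Mann-Whitney U test;
  if both look normal, Levene's test (mean-centred) decides between the
  pooled-variance t-test (Levene p >= 0.05) and Welch's t-test.

All p-values are two-sided. Degenerate data (a variable constant in both
arms) is reported as skipped with an em-dash, mirroring how baseline tables
print such rows.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .errors import AneumatchError
from .schema import ARM_AOI, ARM_REFERENCE, BINARY_COVARIATES, BINARY_OUTCOMES

__all__ = [
    "VariableDef",
    "ComparisonRow",
    "choose_test",
    "fisher_exact_2x2",
    "chi_square_2xC",
    "mann_whitney_u",
    "t_test",
    "baseline_table",
    "outcome_analysis",
    "format_count_percent",
    "parse_count_percent",
    "BASELINE_VARIABLES",
    "PRIMARY_OUTCOMES",
    "SECONDARY_OUTCOMES",
]

ALPHA_NORMALITY = 0.05
SKIPPED = "—"


@dataclass(frozen=True)
class VariableDef:
    name: str
    kind: str  # binary | categorical | ordinal | metric
    role: str = "descriptor"  # matching covariate | primary outcome | secondary outcome | descriptor
    ruptured_only: bool = False


#: baseline-balance table: epidemiology, history, rupture status, morphology
BASELINE_VARIABLES: tuple[VariableDef, ...] = (
    VariableDef("gender", "binary", "matching covariate"),
    VariableDef("age", "metric", "matching covariate"),
    *(VariableDef(n, "binary") for n in BINARY_COVARIATES if n != "multiple_aneurysms"),
    VariableDef("ruptured", "binary"),
    VariableDef("multiple_aneurysms", "binary"),
    VariableDef("size_mm", "metric", "matching covariate"),
    VariableDef("shape", "binary", "matching covariate"),
    VariableDef("hunt_hess", "ordinal", "matching covariate", ruptured_only=True),
    VariableDef("fisher_grade", "ordinal", "matching covariate", ruptured_only=True),
)

PRIMARY_OUTCOMES: tuple[VariableDef, ...] = (
    VariableDef("complete_occlusion", "binary", "primary outcome"),
    VariableDef("mrs_discharge", "ordinal", "primary outcome"),
)

SECONDARY_OUTCOMES: tuple[VariableDef, ...] = tuple(
    VariableDef(n, "binary", "secondary outcome")
    for n in BINARY_OUTCOMES
    if n != "complete_occlusion"
)


@dataclass
class ComparisonRow:
    variable: str
    summary_a: str
    summary_b: str
    test: str  # chi-square | fisher-exact | t-test | mann-whitney | skipped
    statistic: float | None
    p_value: float | None
    trace: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "arm_aoi": self.summary_a,
            "arm_reference": self.summary_b,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            **{f"trace_{k}": v for k, v in self.trace.items()},
        }


# ---------------------------------------------------------------------------
# elementary tests


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability method).

    A zero margin makes the table degenerate; p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise AneumatchError("fisher_exact_2x2 needs a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def chi_square_2xC(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for an r x c table."""
    t = np.asarray(table, dtype=float)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        warnings.warn("degenerate contingency table (zero margin); p = 1", stacklevel=2)
        return 0.0, 1.0
    res = stats.chi2_contingency(t, correction=False)
    return float(res[0]), float(res[1])


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for the first group) with the exact p-value when the
    combined sample has at most 20 observations and no cross-group ties,
    otherwise the normal approximation with tie and continuity corrections."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise AneumatchError("mann_whitney_u needs at least one observation per group")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def t_test(group_a, group_b, pooled: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test, pooled-variance or Welch."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AneumatchError("t_test needs at least two observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; p = 1", stacklevel=2)
            return 0.0, 1.0
        warnings.warn("zero variance in both groups with different means; p -> 0", stacklevel=2)
        return float(np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# routing


def _normality_p(x: np.ndarray) -> float:
    """Lilliefors-corrected KS normality p; degenerate samples count as
    non-normal (p = 0) so they route to the rank test."""
    if len(x) < 4 or np.std(x) == 0:
        return 0.0
    return float(lilliefors(x, dist="norm")[1])


def choose_test(variable: VariableDef, group_a, group_b) -> tuple[str, dict]:
    """Select the test for one variable; returns (test id, routing trace)."""
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if len(a) == 0 or len(b) == 0:
        raise AneumatchError(f"{variable.name}: both groups must be nonempty")
    trace: dict = {"kind": variable.kind}

    if variable.kind in ("binary", "categorical"):
        levels = sorted(set(a.tolist()) | set(b.tolist()))
        table = np.array(
            [[int(np.sum(a == lv)) for lv in levels], [int(np.sum(b == lv)) for lv in levels]]
        )
        if len(levels) < 2:
            trace["note"] = "constant in both arms"
            return "skipped", trace
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        trace["min_expected"] = float(expected.min())
        if expected.min() < 5:
            if table.shape == (2, 2):
                return "fisher-exact", trace
            trace["note"] = "sparse non-2x2 table; chi-square retained"
        return "chi-square", trace

    a = a.astype(float)
    b = b.astype(float)
    if np.std(np.concatenate([a, b])) == 0:
        trace["note"] = "constant in both arms"
        return "skipped", trace
    p_a, p_b = _normality_p(a), _normality_p(b)
    trace["normality_p_a"] = p_a
    trace["normality_p_b"] = p_b
    if p_a < ALPHA_NORMALITY or p_b < ALPHA_NORMALITY:
        return "mann-whitney", trace
    p_lev = float(stats.levene(a, b, center="mean")[1])
    trace["levene_p"] = p_lev
    trace["pooled"] = p_lev >= 0.05
    return "t-test", trace


def run_comparison(variable: VariableDef, group_a, group_b) -> ComparisonRow:
    """Route and execute the test for one variable, with group summaries."""
    test, trace = choose_test(variable, group_a, group_b)
    a = np.asarray(group_a)
    b = np.asarray(group_b)

    if variable.kind in ("binary", "categorical"):
        if variable.kind == "binary":
            pos = _positive_level(a, b)
            summary_a = format_count_percent(int(np.sum(a == pos)), len(a))
            summary_b = format_count_percent(int(np.sum(b == pos)), len(b))
        else:
            summary_a, summary_b = f"n={len(a)}", f"n={len(b)}"
        if test == "skipped":
            return ComparisonRow(variable.name, summary_a, summary_b, "skipped", None, None, trace)
        levels = sorted(set(a.tolist()) | set(b.tolist()))
        table = np.array(
            [[int(np.sum(a == lv)) for lv in levels], [int(np.sum(b == lv)) for lv in levels]]
        )
        if test == "fisher-exact":
            p = fisher_exact_2x2(table)
            return ComparisonRow(variable.name, summary_a, summary_b, test, None, p, trace)
        statistic, p = chi_square_2xC(table)
        return ComparisonRow(variable.name, summary_a, summary_b, test, statistic, p, trace)

    af = a.astype(float)
    bf = b.astype(float)
    if variable.kind == "ordinal":
        summary_a = f"median {np.median(af):g}"
        summary_b = f"median {np.median(bf):g}"
    else:
        summary_a = f"mean {np.mean(af):.1f}"
        summary_b = f"mean {np.mean(bf):.1f}"
    if test == "skipped":
        return ComparisonRow(variable.name, summary_a, summary_b, "skipped", None, None, trace)
    if test == "mann-whitney":
        statistic, p = mann_whitney_u(af, bf)
    else:
        statistic, p = t_test(af, bf, pooled=trace.get("pooled", True))
    return ComparisonRow(variable.name, summary_a, summary_b, test, statistic, p, trace)


def _positive_level(a: np.ndarray, b: np.ndarray):
    """The level counted as 'positive' in a binary summary."""
    levels = set(a.tolist()) | set(b.tolist())
    if levels <= {0, 1}:  # 0/1-coded: level 1 is positive even when absent
        return 1
    for candidate in ("female", "irregular", "yes"):
        if candidate in levels:
            return candidate
    return sorted(levels)[-1]


# ---------------------------------------------------------------------------
# formatting


def format_count_percent(count: int, n: int) -> str:
    """``5 of 14 -> '5 (35.7%)'``; integral percentages print without decimals."""
    if n <= 0:
        raise AneumatchError("arm size must be positive")
    pct = round(100.0 * count / n, 1)
    if pct == int(pct):
        return f"{count} ({int(pct)}%)"
    return f"{count} ({pct}%)"


_PCT_RE = re.compile(r"^\s*(\d+)\s*\(\s*([0-9.]+)\s*%\s*\)\s*$")


def parse_count_percent(text: str) -> tuple[int, float]:
    m = _PCT_RE.match(text)
    if not m:
        raise AneumatchError(f"cannot parse count-percent summary {text!r}")
    return int(m.group(1)), float(m.group(2))


# ---------------------------------------------------------------------------
# tables


def _arm_frames(cases: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    arm_a = cases[cases["arm"] == ARM_AOI]
    arm_b = cases[cases["arm"] == ARM_REFERENCE]
    if arm_a.empty or arm_b.empty:
        raise AneumatchError("both arms must be populated")
    return arm_a, arm_b


def _values(frame: pd.DataFrame, var: VariableDef) -> np.ndarray:
    if var.name not in frame.columns:
        raise AneumatchError(f"variable {var.name!r} absent from case table")
    sub = frame[frame["ruptured"] == 1] if var.ruptured_only else frame
    col = sub[var.name].dropna()
    if var.name == "shape":
        return (col == "irregular").astype(int).to_numpy()
    if var.name == "gender":
        return (col == "male").astype(int).to_numpy()  # male counts reported, as in 2 male/12 female
    return col.to_numpy()


def baseline_table(cases: pd.DataFrame, variables=BASELINE_VARIABLES) -> pd.DataFrame:
    """Baseline-balance table for a matched two-arm case table.

    One row per variable: per-arm summaries (count (percent) for binaries,
    mean/median for metric/ordinal), the routed test and its p-value. A
    variable constant in both arms is reported with an em-dash.
    """
    arm_a, arm_b = _arm_frames(cases)
    rows = []
    for var in variables:
        va, vb = _values(arm_a, var), _values(arm_b, var)
        if len(va) == 0 or len(vb) == 0:
            rows.append(ComparisonRow(var.name, "n=0", "n=0", "skipped", None, None, {"note": "no data"}))
            continue
        rows.append(run_comparison(var, va, vb))
    out = pd.DataFrame([r.as_dict() for r in rows])
    out["p_value"] = out["p_value"].astype(object).where(out["p_value"].notna(), SKIPPED)
    return out


def outcome_analysis(cases: pd.DataFrame) -> pd.DataFrame:
    """Primary and secondary outcome comparison for a matched cohort.

    Primary: completeness of aneurysm occlusion (binary) and the modified
    Rankin Scale at discharge (ordinal). Secondary: temporary clipping,
    intraoperative rupture, postoperative stroke/hemorrhage, hydrocephalus,
    ventriculoperitoneal shunt and vasospasm, each binary. The report adds
    the direction of effect (which arm has the higher rate / location).
    """
    arm_a, arm_b = _arm_frames(cases)
    rows = []
    for var in PRIMARY_OUTCOMES + SECONDARY_OUTCOMES:
        va, vb = _values(arm_a, var), _values(arm_b, var)
        if len(va) == 0 or len(vb) == 0:
            raise AneumatchError(f"outcome column {var.name!r} has no data")
        row = run_comparison(var, va, vb)
        d = float(np.mean(va.astype(float)) - np.mean(vb.astype(float)))
        row.trace["direction"] = (
            "higher in AIA arm" if d > 0 else "higher in PA arm" if d < 0 else "no difference"
        )
        row.trace["role"] = var.role
        rows.append(row)
    out = pd.DataFrame([r.as_dict() for r in rows])
    out["p_value"] = out["p_value"].astype(object).where(out["p_value"].notna(), SKIPPED)
    return out
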