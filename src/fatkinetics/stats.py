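"""Statistical procedures for the fat-kinetics analysis.

Covers test-retest reproducibility (one-way random-effects ICC of the
triplicate presurgical measurements), the exact paired Wilcoxon signed-rank
test used to compare per-subject decay constants, Bonferroni-corrected
paired comparisons of blood parameters against baseline, simple linear
association models (absolute values and differences from the preoperative
value), the HOMA-IR insulin-resistance index, and percent decline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import COMPARTMENTS

__all__ = [
    "ICCResult",
    "WilcoxonResult",
    "RegressionResult",
    "icc_oneway",
    "wilcoxon_signed_rank",
    "compare_decay_constants",
    "comparisons_vs_baseline",
    "ols_simple",
    "delta_from_baseline",
    "homa_ir",
    "percent_decline",
]

logger = logging.getLogger(__name__)

#: Smallest subnormal double; reported instead of an exact zero p-value.
P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects intraclass correlation (single measurement)."""

    msb: float  # between-subject mean square
    msw: float  # within-subject mean square
    n_subjects: int
    k: int  # replicates per subject
    icc: float


@dataclass(frozen=True)
class WilcoxonResult:
    n_nonzero: int
    w: float  # sum of positive ranks
    p: float  # two-sided
    method: str  # "exact" | "approximate" | "degenerate"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    se: float
    intercept: float
    p: float
    n: int


def icc_oneway(table) -> ICCResult:
    """ICC(1,1) from an n-subject x k-replicate table.

    ICC = (MSB - MSW) / (MSB + (k-1) MSW) with the one-way ANOVA mean
    squares; ranges from -1/(k-1) (no between-subject variance) to 1
    (perfect replicate agreement).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D (subjects x replicates)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 replicates")
    if np.any(~np.isfinite(x)):
        raise ValueError("table must be complete (no missing cells)")
    subj_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    if msw == 0 and msb == 0:
        raise ValueError("all values identical; ICC undefined")
    icc = (msb - msw) / (msb + (k - 1) * msw)
    return ICCResult(msb=float(msb), msw=float(msw), n_subjects=n, k=k, icc=float(icc))


def _exact_signed_rank_cdf(n: int) -> np.ndarray:
    """Counts of sign patterns per rank-sum value W = 0 .. n(n+1)/2.

    Dynamic program equivalent to enumerating all 2^n sign assignments of
    the untied ranks 1..n.
    """
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: m + 1 - r].copy()
    return counts


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's rule); |differences| are
    midranked.  The p-value is exact (full sign-assignment distribution)
    when there are at most 20 nonzero untied differences, otherwise a
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.ndim != 1 or d.size < 1:
        raise ValueError("need paired 1-D samples of length >= 1")
    if np.any(~np.isfinite(d)):
        raise ValueError("differences must be finite")

    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(n_nonzero=0, w=0.0, p=1.0, method="degenerate")

    ranks = sps.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    total = n * (n + 1) / 2
    has_ties = np.unique(np.abs(d)).size < n

    if n <= 20 and not has_ties:
        counts = _exact_signed_rank_cdf(n)
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / 2.0**n
        p_ge = counts[wi:].sum() / 2.0**n
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(n_nonzero=n, w=w, p=float(p), method="exact")

    mean = total / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var == 0:
        return WilcoxonResult(n_nonzero=n, w=w, p=1.0, method="degenerate")
    # continuity correction toward the mean
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(n_nonzero=n, w=w, p=float(max(p, P_FLOOR)), method="approximate")


def compare_decay_constants(table: pd.DataFrame) -> pd.DataFrame:
    """All pairwise paired Wilcoxon tests between compartment decay constants.

    ``table`` is subjects x compartments (as from kinetics.decay_constants).
    P-values are reported unadjusted.  Pairs with fewer than 6 complete
    subjects are flagged as low-power.
    """
    rows = []
    for a, b in itertools.combinations(table.columns, 2):
        pair = table[[a, b]].dropna()
        res = wilcoxon_signed_rank(pair[a].to_numpy(), pair[b].to_numpy())
        low_power = len(pair) < 6
        if low_power:
            logger.warning("pair %s vs %s has only %d complete pairs", a, b, len(pair))
        rows.append(
            {
                "compartment_1": a,
                "compartment_2": b,
                "n_pairs": len(pair),
                "n_nonzero": res.n_nonzero,
                "w": res.w,
                "p": res.p,
                "method": res.method,
                "low_power": low_power,
            }
        )
    return pd.DataFrame(rows)


def comparisons_vs_baseline(
    cohort: pd.DataFrame, parameter: str, family: int | None = None
) -> pd.DataFrame:
    """Bonferroni-corrected paired t-tests of each follow-up vs baseline.

    Baseline per subject is its (first available) t = 0 value; each
    follow-up month is compared on complete pairs.  Raw p-values are
    multiplied by the family size (defaulting to the number of comparisons
    actually performed for this parameter) and capped at 1.
    """
    base = baseline_values(cohort, parameter)
    months = sorted(m for m in cohort["time"].unique() if m > 0)
    rows = []
    for m in months:
        follow = (
            cohort.loc[cohort["time"] == m, ["subject_id", parameter]]
            .dropna()
            .groupby("subject_id")[parameter]
            .mean()
        )
        paired = pd.concat([base, follow], axis=1, keys=["base", "follow"]).dropna()
        if len(paired) < 2:
            logger.warning("%s at %g months: <2 complete pairs; skipped", parameter, m)
            continue
        if np.allclose(paired["base"], paired["follow"]):
            p_raw = 1.0
        else:
            p_raw = float(sps.ttest_rel(paired["follow"], paired["base"]).pvalue)
        rows.append({"time": m, "n_pairs": len(paired), "p_raw": p_raw})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    fam = family if family is not None else len(out)
    out["family"] = fam
    out["p_adjusted"] = np.minimum(out["p_raw"] * fam, 1.0)
    return out


def ols_simple(x, y) -> RegressionResult:
    """Simple linear regression of y on x with slope SE and two-sided p.

    A perfect fit (zero residual variance) reports SE 0 and the smallest
    positive double as the p-value sentinel.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    p = float(res.pvalue)
    se = float(res.stderr)
    if se == 0 or not np.isfinite(p) or p == 0:
        p = P_FLOOR
    return RegressionResult(
        slope=float(res.slope),
        se=se,
        intercept=float(res.intercept),
        p=p,
        n=int(x.size),
    )


def baseline_values(cohort: pd.DataFrame, field: str) -> pd.Series:
    """Per-subject preoperative value of ``field``.

    MRI compartments average their three t = 0 replicate measurements;
    blood analytes and BMI use the single recorded preoperative value.
    """
    base = cohort[cohort["time"] == 0].dropna(subset=[field])
    if field in COMPARTMENTS:
        return base.groupby("subject_id")[field].mean()
    return base.sort_values("visit_index").groupby("subject_id")[field].first()


def delta_from_baseline(cohort: pd.DataFrame, field: str) -> pd.DataFrame:
    """Per-subject differences from the preoperative value at each follow-up.

    Subjects without a usable baseline are excluded (logged).
    """
    base = baseline_values(cohort, field)
    missing = set(cohort["subject_id"].unique()) - set(base.index)
    for sid in sorted(missing):
        logger.warning("subject %s lacks a baseline for %s; excluded", sid, field)
    follow = cohort[(cohort["time"] > 0)].dropna(subset=[field])
    follow = follow[follow["subject_id"].isin(base.index)]
    out = follow[["subject_id", "time", field]].copy()
    out["baseline"] = out["subject_id"].map(base)
    out["delta"] = out[field] - out["baseline"]
    return out[["subject_id", "time", "baseline", field, "delta"]].reset_index(drop=True)


def homa_ir(glucose, insulin):
    """HOMA-IR = (fasting glucose [mmol/L] x fasting insulin [uU/mL]) / 22.5."""
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g < 0) or np.any(i < 0):
        raise ValueError("glucose and insulin must be non-negative")
    out = g * i / 22.5
    return float(out) if out.ndim == 0 else out


def percent_decline(baseline, value):
    """Percent decline from baseline: 100 * (1 - value/baseline).

    Cohort summaries should average per-subject declines (mean of ratios),
    not take the decline of the means.
    """
    b = np.asarray(baseline, dtype=float)
    v = np.asarray(value, dtype=float)
    if np.any(b <= 0):
        raise ValueError("baseline must be positive")
    out = 100.0 * (1.0 - v / b)
    return float(out) if out.ndim == 0 else out
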