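"""Exponential-decay-with-rebound kinetics of fat compartments.

The working model for every compartment trajectory is

    Y(t) = exp(A + B*t) + A1*t

with A the log of the initial value, B < 0 the decay rate (per month) and
A1 >= 0 the slope of the late ascending process.  The decay constant
reported for a compartment is -B, so larger means faster fat loss.  With
A1 > 0 and B < 0 the curve has a unique interior minimum at

    t* = ln(-A1 / (B * exp(A))) / B

which captures the observed nadir followed by a slow rebound.

Per-subject fits are damped Gauss-Newton least squares; the population
summary is a two-stage approximation of a nonlinear mixed-effects model:
fixed effects are the mean of converged subject estimates, their standard
errors the between-subject SD over sqrt(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecayParams",
    "FitResult",
    "PopulationFit",
    "model_predict",
    "initial_guess",
    "fit_subject",
    "fit_population",
    "decay_constants",
]

logger = logging.getLogger(__name__)

_MAX_EXPONENT = 700.0  # beyond this exp() overflows a double


@dataclass(frozen=True)
class DecayParams:
    """(A, B, A1) of Y(t) = exp(A + B t) + A1 t."""

    a: float
    b: float
    a1: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.a1], dtype=float)

    @property
    def decay_constant(self) -> float:
        """-B; positive for a decaying compartment."""
        return -self.b

    def nadir_time(self) -> float:
        """Interior minimum t* = ln(-A1/(B e^A))/B, or nan if undefined."""
        if self.b >= 0 or self.a1 <= 0:
            return float("nan")
        arg = -self.a1 / (self.b * np.exp(self.a))
        if arg <= 0:
            return float("nan")
        return float(np.log(arg) / self.b)


@dataclass
class FitResult:
    params: DecayParams
    se: np.ndarray  # SEs of (A, B, A1)
    rss: float
    converged: bool
    n_obs: int
    n_iter: int = 0
    flags: list = field(default_factory=list)


@dataclass
class PopulationFit:
    """Two-stage population summary for one compartment."""

    compartment: str
    subject_fits: Mapping[str, FitResult]
    fixed_effects: DecayParams
    between_sd: np.ndarray  # SD of (A, B, A1) across subjects
    se: np.ndarray  # SE of the fixed effects = between_sd / sqrt(n)
    n_subjects: int

    @property
    def decay_constant(self) -> float:
        return -self.fixed_effects.b


def model_predict(params: DecayParams | Sequence[float], t) -> np.ndarray | float:
    """Evaluate Y(t) = exp(A + B t) + A1 t at non-negative times."""
    a, b, a1 = (
        (params.a, params.b, params.a1)
        if isinstance(params, DecayParams)
        else tuple(float(x) for x in params)
    )
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    expo = a + b * t_arr
    if np.any(expo > _MAX_EXPONENT):
        raise OverflowError("exp(A + B t) overflows for these parameters")
    out = np.exp(expo) + a1 * t_arr
    return float(out) if np.isscalar(t) else out


def _residuals_jacobian(theta: np.ndarray, t: np.ndarray, y: np.ndarray):
    a, b, a1 = theta
    with np.errstate(over="ignore"):
        e = np.exp(np.minimum(a + b * t, _MAX_EXPONENT))
    f = e + a1 * t
    r = y - f
    jac = np.column_stack([e, t * e, t])  # d f / d theta
    return r, jac


def initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Documented initializer: A from the t=0 (earliest-time) mean, B from a
    log-linear slope over the first three distinct times, A1 from the last
    inter-visit slope floored at zero."""
    order = np.argsort(t)
    t, y = t[order], y[order]
    t0 = t.min()
    a0 = float(np.log(np.mean(y[t == t0])))

    distinct = np.unique(t)[:3]
    means = np.array([np.mean(y[t == ti]) for ti in distinct])
    if distinct.size >= 2 and np.all(means > 0):
        b0 = float(np.polyfit(distinct, np.log(means), 1)[0])
        if b0 >= 0:
            b0 = -0.05
    else:  # pragma: no cover - guarded by fit_subject preconditions
        b0 = -0.05

    last, prev = np.unique(t)[-1], np.unique(t)[-2]
    a1_0 = max(
        0.0,
        float((np.mean(y[t == last]) - np.mean(y[t == prev])) / (last - prev)),
    )
    return np.array([a0, b0, a1_0])


def fit_subject(
    times: Sequence[float],
    values: Sequence[float],
    *,
    max_iter: int = 500,
    rtol: float = 1e-10,
    x0: Sequence[float] | None = None,
) -> FitResult:
    """Least-squares fit of (A, B, A1) to one subject's trajectory.

    Damped Gauss-Newton: the full step is halved until the residual sum of
    squares does not increase; convergence is declared when the relative RSS
    change falls below ``rtol`` (or at ``max_iter``, flagged unconverged).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-D")
    if t.size < 4:
        raise ValueError("at least 4 observations are required")
    if np.unique(t).size < 2:
        raise ValueError("times are all identical; the model is unidentifiable")
    if np.any(y <= 0):
        raise ValueError("values must be positive")

    theta = np.asarray(x0, dtype=float) if x0 is not None else initial_guess(t, y)
    r, jac = _residuals_jacobian(theta, t, y)
    rss = float(r @ r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step, *_ = np.linalg.lstsq(jac, r, rcond=None)
        scale = 1.0
        new_theta, new_rss = theta, rss
        for _ in range(40):
            cand = theta + scale * step
            rc, _ = _residuals_jacobian(cand, t, y)
            with np.errstate(over="ignore"):
                rss_c = float(rc @ rc)
            if np.isfinite(rss_c) and rss_c <= rss:
                new_theta, new_rss = cand, rss_c
                break
            scale *= 0.5
        if new_rss >= rss:
            # no descent within line-search resolution: stationary point
            converged = True
            break
        rel_change = abs(rss - new_rss) / max(rss, np.finfo(float).tiny)
        theta, rss = new_theta, new_rss
        r, jac = _residuals_jacobian(theta, t, y)
        if rel_change < rtol:
            converged = True
            break

    dof = t.size - 3
    sigma2 = rss / dof if dof > 0 else np.nan
    try:
        cov = sigma2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(3, np.nan)

    flags: list[str] = []
    if not converged:
        flags.append("not_converged")
    if theta[1] > 0:
        flags.append("positive_decay_rate")
    return FitResult(
        params=DecayParams(*theta),
        se=se,
        rss=rss,
        converged=converged,
        n_obs=int(t.size),
        n_iter=it,
        flags=flags,
    )


def fit_population(cohort: pd.DataFrame, compartment: str) -> PopulationFit:
    """Two-stage population fit of one compartment over a tidy cohort table.

    Requires columns ``subject_id``, ``time`` and the compartment.  Fixed
    effects are the mean of converged per-subject estimates; the SE of each
    fixed effect is the between-subject SD over sqrt(n).
    """
    if compartment not in cohort.columns:
        raise KeyError(f"compartment {compartment!r} not in cohort table")
    fits: dict[str, FitResult] = {}
    for sid, grp in cohort.groupby("subject_id", sort=True):
        sub = grp.dropna(subset=[compartment])
        if len(sub) < 4:
            logger.warning("subject %s: <4 usable points for %s; skipped", sid, compartment)
            continue
        try:
            fit = fit_subject(sub["time"].to_numpy(), sub[compartment].to_numpy())
        except (ValueError, OverflowError) as exc:
            logger.warning("subject %s: fit failed for %s (%s)", sid, compartment, exc)
            continue
        fits[sid] = fit

    usable = {s: f for s, f in fits.items() if f.converged}
    if len(usable) < 2:
        raise RuntimeError(
            f"fewer than 2 convergent subject fits for {compartment!r}"
        )
    mat = np.vstack([f.params.as_array() for f in usable.values()])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    return PopulationFit(
        compartment=compartment,
        subject_fits=fits,
        fixed_effects=DecayParams(*mean),
        between_sd=sd,
        se=sd / np.sqrt(len(usable)),
        n_subjects=len(usable),
    )


def decay_constants(popfits: Mapping[str, PopulationFit]) -> pd.DataFrame:
    """Per-subject decay constants (-B) aligned by subject across compartments.

    Subjects missing a convergent fit in a compartment get NaN there and are
    logged; pairwise tests downstream drop incomplete pairs.
    """
    cols = {}
    for comp, pf in popfits.items():
        cols[comp] = {
            sid: -f.params.b for sid, f in pf.subject_fits.items() if f.converged
        }
    table = pd.DataFrame(cols).sort_index()
    for comp in table.columns:
        missing = table.index[table[comp].isna()]
        for sid in missing:
            logger.warning("subject %s has no convergent %s fit", sid, comp)
    table.index.name = "subject_id"
    return table
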