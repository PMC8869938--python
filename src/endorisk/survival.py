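"""Survival endpoints and evaluation statistics.

Kaplan–Meier product-limit curves with Greenwood variance and log–log
confidence bands, Cox proportional-hazards fits (binary, continuous, and
ordinal risk-group coding), the k-group log-rank test, and a
censoring-aware concordance index with exposed pair counts.

The concordance index follows the Harrell permissible-pair rules: a pair
is usable iff the patient with the smaller observed time had an event
(for tied times, iff exactly one of the two is an event, in which case
the event patient is the shorter-lived one); it is concordant iff the
shorter-lived patient carries the higher risk score, and score ties
count one half.  The raw concordant/discordant/tied counts are exposed
so the Goodman–Kruskal gamma variant (C−D)/(C+D) can be derived from the
same enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .cohort import NE, Cohort

__all__ = [
    "KMCurve",
    "CoxFit",
    "ConcordanceResult",
    "endpoint_arrays",
    "km_estimate",
    "survival_at",
    "cox_fit",
    "cox_ordinal_by_group",
    "concordance",
    "goodman_kruskal_gamma",
    "logrank_test",
    "univariate_screen",
    "UNIVARIATE_CODINGS",
]

ALPHA = 0.05


def endpoint_arrays(cohort: Cohort, endpoint: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, event) arrays for endpoint ``"rfs"`` or ``"os"``."""
    if endpoint not in ("rfs", "os"):
        raise ValueError(f"endpoint must be 'rfs' or 'os', got {endpoint!r}")
    t = cohort.df[f"{endpoint}_time_months"].to_numpy(dtype=float)
    e = cohort.df[f"{endpoint}_event"].to_numpy(dtype=int).astype(bool)
    return t, e


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray  # strictly increasing, events only
    survival: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # events at each event time
    greenwood_var: np.ndarray  # Greenwood variance of S(t)
    ci_low: np.ndarray
    ci_high: np.ndarray
    max_time: float  # largest observed time (events or censorings)
    n: int

    def __post_init__(self):
        if len(self.survival) and (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival must be non-increasing")


def km_estimate(time, event, alpha: float = ALPHA) -> KMCurve:
    """Kaplan–Meier estimate with Greenwood variance and log–log CIs.

    Censorings tied with an event time leave the risk set after the events
    at that time (the standard convention).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("no survival data")
    if (time < 0).any():
        raise ValueError("negative survival times")
    if np.all(time == 0):
        raise ValueError("all survival times are zero")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event_observed=event)
    table = kmf.event_table  # indexed by distinct observed times
    observed = table["observed"].to_numpy()
    mask = observed > 0
    times = table.index.to_numpy(dtype=float)[mask]
    d = observed[mask].astype(int)
    n_risk = table["at_risk"].to_numpy()[mask].astype(int)

    surv_all = kmf.survival_function_["KM_estimate"]
    surv = surv_all.loc[times].to_numpy(dtype=float)
    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_j <= t} d_j / (n_j (n_j - d_j))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = d / (n_risk * (n_risk - d).astype(float))
    incr[~np.isfinite(incr)] = np.nan  # S hits 0: variance undefined beyond
    gw = surv**2 * np.nancumsum(incr)

    ci = kmf.confidence_interval_  # log–log ("exponential Greenwood") bounds
    lo = ci.iloc[:, 0].loc[times].to_numpy(dtype=float)
    hi = ci.iloc[:, 1].loc[times].to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=n_risk,
        n_events=d,
        greenwood_var=gw,
        ci_low=lo,
        ci_high=hi,
        max_time=float(time.max()),
        n=int(time.size),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Step-function value S(t); t past the last observed time warns."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t > curve.max_time:
        warnings.warn(
            f"t={t} exceeds the largest observed time {curve.max_time}; "
            "returning the last step (extrapolation)",
            stacklevel=2,
        )
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxFit:
    """A one-covariate Cox partial-likelihood fit (Wald inference)."""

    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    n_events: int
    covariate_coding: str
    ties: str
    converged: bool

    def __str__(self) -> str:  # pragma: no cover - display helper
        lo, hi = self.ci95
        return (
            f"HR {self.hr:.2f} (95% CI {lo:.2f}-{hi:.2f}), p={self.p_value:.3g}, "
            f"n={self.n}, events={self.n_events} [{self.covariate_coding}]"
        )


class CoxNoFitError(ValueError):
    """Raised when a Cox model cannot be fitted (degenerate covariate, no events)."""


def cox_fit(
    time,
    event,
    covariate,
    ties: str = "efron",
    coding: str = "numeric covariate",
) -> CoxFit:
    """Univariate Cox PH fit with Efron (default) or Breslow tie handling.

    Raises :class:`CoxNoFitError` for a constant covariate or zero events;
    a monotone-likelihood fit (perfect separation) is returned flagged
    ``converged=False`` rather than silently.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if time.shape != event.shape or time.shape != x.shape:
        raise ValueError("time, event and covariate must be aligned")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if event.sum() == 0:
        raise CoxNoFitError("no events")
    if np.ptp(x) == 0:
        raise CoxNoFitError("constant covariate")

    model = PHReg(time, x[:, None], status=event.astype(int), ties=ties)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
        beta = float(res.params[0])
        se = float(res.bse[0])
    except np.linalg.LinAlgError:
        # monotone likelihood (separation): Hessian singular at divergence
        beta, se = np.nan, np.nan
    converged = bool(np.isfinite(beta) and np.isfinite(se) and abs(beta) < 20)
    z = stats.norm.ppf(1 - ALPHA / 2)
    if converged:
        ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
        p = float(2 * stats.norm.sf(abs(beta) / se))
    else:
        ci = (np.nan, np.nan)
        p = np.nan
    return CoxFit(
        beta=beta,
        se=se,
        hr=float(np.exp(beta)),
        ci95=ci,
        p_value=p,
        n=int(time.size),
        n_events=int(event.sum()),
        covariate_coding=coding,
        ties=ties,
        converged=converged,
    )


def cox_ordinal_by_group(
    labels, time, event, order: list[str], ties: str = "efron"
) -> CoxFit:
    """Cox fit with the risk group as a single ordinal covariate.

    Groups are scored 1, 2, … by their position in ``order`` (severity
    rank); an empty rank is skipped so the score stays contiguous, and the
    realised integer map is recorded in ``covariate_coding``.  The returned
    hazard ratio is per one-step increment in severity.
    """
    labels = pd.Series(list(labels))
    present = [g for g in order if (labels == g).any()]
    if len(present) < 2:
        raise CoxNoFitError("fewer than 2 distinct groups present")
    score_map = {g: i + 1 for i, g in enumerate(present)}
    unknown = set(labels.unique()) - set(score_map)
    if unknown:
        raise ValueError(f"labels outside the stated order: {sorted(unknown)}")
    x = labels.map(score_map).to_numpy(dtype=float)
    coding = "ordinal " + ", ".join(f"{g}={s}" for g, s in score_map.items())
    return cox_fit(time, event, x, ties=ties, coding=coding)


# ---------------------------------------------------------------------------
# Concordance


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    concordant: int
    discordant: int
    tied: int
    permissible: int

    def __post_init__(self):
        assert self.concordant + self.discordant + self.tied == self.permissible


def concordance(scores, time, event, chunk: int = 512) -> ConcordanceResult:
    """Censoring-aware concordance between risk scores and survival.

    Higher score must predict shorter survival for a concordant pair.
    Pair rules are described in the module docstring; evaluation is an
    exact pairwise enumeration, vectorised in chunks.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if not (s.shape == t.shape == e.shape):
        raise ValueError("scores, time and event must be aligned")
    n = t.size
    conc = disc = tied = 0
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti, si, ei = t[sl, None], s[sl, None], e[sl, None]
        # ordered pair (i, j): i is the determining (shorter-lived) patient
        usable = (ei & (ti < t[None, :])) | (
            ei & ~e[None, :] & (ti == t[None, :])
        )
        conc += int((usable & (si > s[None, :])).sum())
        disc += int((usable & (si < s[None, :])).sum())
        tied += int((usable & (si == s[None, :])).sum())
    permissible = conc + disc + tied
    if permissible == 0:
        raise ValueError("no permissible pairs; concordance undefined")
    return ConcordanceResult(
        c_index=(conc + 0.5 * tied) / permissible,
        concordant=conc,
        discordant=disc,
        tied=tied,
        permissible=permissible,
    )


def goodman_kruskal_gamma(result: ConcordanceResult) -> float:
    """Strict gamma variant (C−D)/(C+D) from the same pair counts."""
    cd = result.concordant + result.discordant
    if cd == 0:
        raise ValueError("gamma undefined: no untied permissible pairs")
    return (result.concordant - result.discordant) / cd


# ---------------------------------------------------------------------------
# Log-rank


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank_test(labels, time, event) -> LogrankResult:
    """k-group log-rank test (chi-square with k−1 degrees of freedom)."""
    labels = np.asarray(list(labels))
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if not np.asarray(event, dtype=bool).any():
        raise ValueError("log-rank test needs at least 1 event")
    res = multivariate_logrank_test(
        np.asarray(time, dtype=float), labels, np.asarray(event, dtype=int)
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        df=int(groups.size - 1),
    )


# ---------------------------------------------------------------------------
# Univariate Cox screen

# covariate -> (coding function df -> float series with NaN for NE, coding label)
UNIVARIATE_CODINGS: dict = {
    "age": (
        lambda df: (df["age_years"] > 60).astype(float),
        ">60 vs <=60 years",
    ),
    "histology": (
        lambda df: (df["histology"] == "EEC").astype(float),
        "EEC vs NEEC",
    ),
    "grade": (
        lambda df: (df["grade"] == "G3").astype(float),
        "high (G3) vs low (G1+G2)",
    ),
    "myometrial_invasion": (
        lambda df: df["myometrial_invasion"].map(
            {"none": 0.0, "lt50": 1.0, "ge50": 1.0}
        ),
        "invasion yes vs no",
    ),
    "figo_stage": (
        lambda df: df["figo_stage"].map({"IA": 1.0, "IB": 2.0, "II": 3.0}),
        "ordinal IA=1, IB=2, II=3",
    ),
    "lvsi": (
        lambda df: df["lvsi"].map({"negative": 0.0, "positive": 1.0}),
        "positive vs negative",
    ),
    "ctnnb1_exon3": (
        lambda df: df["ctnnb1_exon3"].map({"wildtype": 0.0, "mutated": 1.0}),
        "mutated vs non-mutated",
    ),
}
for _marker in ("er", "pr", "ecad", "her2", "arid1a", "pten", "l1cam"):
    UNIVARIATE_CODINGS[_marker] = (
        lambda df, _m=_marker: df[_m].map({"negative": 0.0, "positive": 1.0}),
        "positive vs negative",
    )


def univariate_screen(
    cohort: Cohort,
    covariates: list[str],
    endpoint: str = "rfs",
    subgroup_mask=None,
) -> pd.DataFrame:
    """Per-covariate univariate Cox fits, complete-case per covariate.

    NE records are excluded covariate by covariate.  ``subgroup_mask``
    (boolean, aligned with the cohort) restricts the analysis, e.g. to a
    histology or merged risk-group subset.  A covariate with fewer than two
    levels after exclusion yields a no-fit row rather than an error.
    """
    time, event = endpoint_arrays(cohort, endpoint)
    df = cohort.df
    if subgroup_mask is not None:
        subgroup_mask = np.asarray(subgroup_mask, dtype=bool)
    rows = []
    for cov in covariates:
        if cov not in UNIVARIATE_CODINGS:
            raise KeyError(f"no coding registered for covariate {cov!r}")
        fn, coding = UNIVARIATE_CODINGS[cov]
        x = fn(df).to_numpy(dtype=float)
        keep = np.isfinite(x)
        if subgroup_mask is not None:
            keep &= subgroup_mask
        row = {"covariate": cov, "endpoint": endpoint, "n": int(keep.sum())}
        try:
            fit = cox_fit(time[keep], event[keep], x[keep], coding=f"{cov}: {coding}")
            row.update(
                hr=fit.hr,
                ci_low=fit.ci95[0],
                ci_high=fit.ci95[1],
                p_value=fit.p_value,
                n_events=fit.n_events,
                note="" if fit.converged else "not converged",
            )
        except (CoxNoFitError, ValueError) as exc:
            row.update(
                hr=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                p_value=np.nan,
                n_events=int(event[keep].sum()) if keep.any() else 0,
                note=f"no fit: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows)
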