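"""Prognostic evaluation: Cox models, Kaplan-Meier strata, concordance,
time-dependent ROC, proportional-hazards diagnostics and a cohort simulator.

Cox fitting (Efron ties), Kaplan-Meier estimation and the log-rank test
are delegated to lifelines; the time-dependent cumulative/dynamic AUC with
inverse-probability-of-censoring weights comes from scikit-survival.  The
test suite cross-checks each of these against independent brute-force
oracles.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index

from .errors import DegenerateDataError


@dataclasses.dataclass
class Cohort:
    """Survival records: columns ``id``, ``time`` (years), ``event`` (0/1)
    plus arbitrary numeric covariates."""

    frame: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self):
        for col in ("id", "time", "event"):
            if col not in self.frame.columns:
                raise ValueError(f"cohort frame lacks required column '{col}'")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("id", "time", "event")]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclasses.dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs, plus fit diagnostics."""

    covariates: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    hazard_ratio: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_value: dict[str, float]
    log_likelihood: float
    n: int
    n_events: int
    _fitter: CoxPHFitter = dataclasses.field(repr=False, default=None)
    _frame: pd.DataFrame = dataclasses.field(repr=False, default=None)

    def linear_predictor(self, frame: pd.DataFrame | None = None) -> np.ndarray:
        df = self._frame if frame is None else frame
        x = df[self.covariates].to_numpy(dtype=float)
        beta = np.array([self.coef[c] for c in self.covariates])
        return x @ beta

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_value,
            }
        )


def fit_cox(cohort: Cohort, covariates: list[str], alpha: float = 0.05) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie handling.

    Raises :class:`DegenerateDataError` for < 2 events or a constant
    covariate; lifelines convergence errors propagate with context.
    """
    df = cohort.frame
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise KeyError(f"covariates not in cohort: {missing}")
    if cohort.n_events < 2:
        raise DegenerateDataError("need at least 2 events to fit a Cox model")
    for c in covariates:
        if df[c].nunique() < 2:
            raise DegenerateDataError(f"covariate '{c}' is constant")
    data = df[["time", "event"] + list(covariates)].astype(float)
    cph = CoxPHFitter(alpha=alpha)
    cph.fit(data, duration_col="time", event_col="event")
    s = cph.summary
    ci_cols = [c for c in s.columns if c.startswith("exp(coef) lower")]
    ci_lo_col = ci_cols[0]
    ci_hi_col = [c for c in s.columns if c.startswith("exp(coef) upper")][0]
    return CoxFit(
        covariates=list(covariates),
        coef=s["coef"].to_dict(),
        se=s["se(coef)"].to_dict(),
        hazard_ratio=s["exp(coef)"].to_dict(),
        ci_lower=s[ci_lo_col].to_dict(),
        ci_upper=s[ci_hi_col].to_dict(),
        p_value=s["p"].to_dict(),
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=cohort.n_events,
        _fitter=cph,
        _frame=data,
    )


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood variance."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(cohort: Cohort, groups=None) -> dict[str, KMCurve]:
    """Kaplan-Meier curve per group (single group "all" if none given)."""
    df = cohort.frame
    if groups is None:
        groups = pd.Series(["all"] * len(df), index=df.index)
    else:
        groups = pd.Series(np.asarray(groups), index=df.index)
    out = {}
    for name, idx in groups.groupby(groups).groups.items():
        sub = df.loc[idx]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        # Greenwood variance: S(t)^2 * cumsum d / (n (n - d))
        et = kmf.event_table.reindex(kmf.survival_function_.index).fillna(0.0)
        d = et["observed"].to_numpy(dtype=float)
        n_risk = et["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(
                (n_risk > 0) & (n_risk > d), d / (n_risk * (n_risk - d)), 0.0
            )
        var = surv**2 * np.cumsum(term)
        at_risk = n_risk
        out[str(name)] = KMCurve(
            times=times,
            survival=surv,
            variance=var,
            at_risk=at_risk,
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return out


def logrank_test(cohort: Cohort, groups) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p-value)."""
    df = cohort.frame
    res = multivariate_logrank_test(df["time"], np.asarray(groups), df["event"])
    return float(res.test_statistic), float(res.p_value)


def harrell_c(cohort: Cohort, risk_scores) -> float:
    """Harrell's concordance: higher risk should mean shorter survival.

    Usable pairs are those where the shorter observed time ends in an
    event; tied risk scores count one half.
    """
    risk = np.asarray(risk_scores, dtype=float)
    # lifelines' convention scores *survival-time* predictions, so negate
    return float(
        concordance_index(cohort.frame["time"], -risk, cohort.frame["event"])
    )


def time_dependent_auc(cohort: Cohort, marker, horizons) -> dict[float, float]:
    """Cumulative/dynamic AUC(t) with IPCW from the censoring Kaplan-Meier.

    Cases at horizon t are subjects with an event by t; controls are those
    still under observation beyond t.  Raises
    :class:`DegenerateDataError` naming the missing side.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    df = cohort.frame
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    for t in horizons:
        n_cases = int(((df["time"] <= t) & (df["event"] == 1)).sum())
        n_controls = int((df["time"] > t).sum())
        if n_cases == 0:
            raise DegenerateDataError(f"no cases (events by t={t})")
        if n_controls == 0:
            raise DegenerateDataError(f"no controls (subjects beyond t={t})")
    y = Surv.from_arrays(
        event=df["event"].to_numpy(dtype=bool), time=df["time"].to_numpy(dtype=float)
    )
    auc, _ = cumulative_dynamic_auc(y, y, np.asarray(marker, dtype=float), horizons)
    return {float(t): float(a) for t, a in zip(horizons, np.atleast_1d(auc))}


def schoenfeld_ph_check(fit: CoxFit) -> dict[str, float]:
    """Proportional-hazards check: scaled Schoenfeld residuals vs time.

    Returns a p-value per covariate; small p indicates a non-zero slope,
    i.e. a time-varying effect violating proportional hazards.
    """
    res = proportional_hazard_test(fit._fitter, fit._frame, time_transform="identity")
    summary = res.summary
    return {str(ix[0] if isinstance(ix, tuple) else ix): float(row["p"])
            for ix, row in summary.iterrows()}


def schoenfeld_residuals(fit: CoxFit) -> pd.DataFrame:
    """Unscaled Schoenfeld residuals (rows = events, columns = covariates)."""
    return fit._fitter.compute_residuals(fit._frame, kind="schoenfeld")


def progression_label(
    fvc0, fvc12, dlco0=None, dlco12=None, mode: str = "relative"
) -> bool:
    """12-month progression: FVC decline >= 10% or DLCO decline >= 15%.

    ``relative`` mode interprets the thresholds as a fraction of the
    baseline value; ``absolute`` as percentage-point drops.  Missing DLCO
    falls back to the FVC criterion alone (with a warning).
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown progression mode {mode!r}")

    def decline(v0, v1):
        if mode == "relative":
            return (v0 - v1) / v0
        return v0 - v1

    fvc_cut = 0.10 if mode == "relative" else 10.0
    dlco_cut = 0.15 if mode == "relative" else 15.0
    progressed = decline(float(fvc0), float(fvc12)) >= fvc_cut
    have_dlco = (
        dlco0 is not None and dlco12 is not None
        and np.isfinite(dlco0) and np.isfinite(dlco12)
    )
    if not have_dlco:
        warnings.warn("DLCO missing; progression from FVC criterion alone",
                      stacklevel=2)
        return bool(progressed)
    return bool(progressed or decline(float(dlco0), float(dlco12)) >= dlco_cut)


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Proportional-hazards cohort simulator parameters.

    Covariate distributions: ``("normal", mu, sd)`` or ``("bernoulli", p)``.
    Event times are exponential with rate ``baseline_rate * exp(beta @ x)``;
    censoring is uniform on ``(0, censor_window]`` (None = no censoring).
    """

    n: int
    betas: dict = dataclasses.field(default_factory=dict)
    covariates: dict = dataclasses.field(default_factory=dict)
    baseline_rate: float = 0.2
    censor_window: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.baseline_rate <= 0:
            raise ValueError("baseline hazard rate must be > 0")
        unknown = set(self.betas) - set(self.covariates)
        if unknown:
            raise ValueError(f"betas for undeclared covariates: {sorted(unknown)}")


def _draw_covariate(rng, dist, n):
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=n)
    if kind == "bernoulli":
        return rng.binomial(1, dist[1], size=n).astype(float)
    raise ValueError(f"unknown covariate distribution {kind!r}")


def simulate_cohort(spec: SimSpec) -> Cohort:
    """Draw a cohort under the proportional-hazards model of ``spec``."""
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name, dist in spec.covariates.items():
        cols[name] = _draw_covariate(rng, dist, spec.n)
    eta = np.zeros(spec.n)
    for name, beta in spec.betas.items():
        eta += beta * cols[name]
    rate = spec.baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if spec.censor_window is not None:
        c = rng.uniform(0.0, spec.censor_window, size=spec.n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(spec.n, dtype=int)
    time = np.maximum(time, 1e-9)
    frame = pd.DataFrame(
        {"id": [f"sim{i:05d}" for i in range(spec.n)], "time": time, "event": event,
         **cols}
    )
    return Cohort(frame=frame)


def calibrate_censor_window(spec: SimSpec, target_fraction: float,
                            tol: float = 0.01, n_probe: int = 20000) -> float:
    """Censoring window giving roughly the target censored fraction."""
    if not (0 < target_fraction < 1):
        raise ValueError("target censored fraction must lie in (0, 1)")
    lo, hi = 1e-3, 1e6

    def frac(w):
        probe = dataclasses.replace(spec, n=n_probe, censor_window=w, seed=spec.seed)
        c = simulate_cohort(probe)
        return 1.0 - c.frame["event"].mean()

    for _ in range(60):
        mid = np.sqrt(lo * hi)
        f = frac(mid)
        if abs(f - target_fraction) < tol:
            return float(mid)
        if f > target_fraction:  # shorter window censors more
            lo = mid
        else:
            hi = mid
    return float(mid)


@dataclasses.dataclass
class CIndexIncrement:
    c_base: float
    c_with: float
    delta: float


def cindex_increment(
    cohort: Cohort, base_covariates: list[str], added_covariate: str
) -> CIndexIncrement:
    """Harrell's C before and after adding one covariate to a Cox model."""
    fit_base = fit_cox(cohort, list(base_covariates))
    if added_covariate in base_covariates:
        c = harrell_c(cohort, fit_base.linear_predictor())
        return CIndexIncrement(c_base=c, c_with=c, delta=0.0)
    fit_full = fit_cox(cohort, list(base_covariates) + [added_covariate])
    c_base = harrell_c(cohort, fit_base.linear_predictor())
    c_with = harrell_c(cohort, fit_full.linear_predictor())
    return CIndexIncrement(c_base=c_base, c_with=c_with, delta=c_with - c_base)
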