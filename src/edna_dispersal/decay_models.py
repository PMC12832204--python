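"""Environmental-DNA decay kinetics.

Functional forms for the concentration of eDNA after shedding, the
temperature dependence of the first-order decay rate, half-life
computation, nonlinear model fitting with per-tank offsets, and
rule-based classification of decay patterns (exponential, biphasic,
delayed).

The two concentration models are

    first order:   C(t) = C00 * exp(-k  * t)
    second order:  C(t) = C01 * exp(-k1 * t) + C02 * exp(-k2 * t)

with t in hours and concentrations in copies per microlitre.  The
second-order (two-exponential mixture) form covers both biphasic decay
(both amplitudes positive, well-separated rates) and delayed decay (one
negative amplitude, producing an initial rise before the decline).

The temperature law k(T) = a * exp(b * T) maps water temperature in
degrees Celsius to a first-order rate in 1/h; the default coefficients
(a = 0.0419 /h at 0 degC, b = 0.0776 /degC) are the median
decay-temperature relationship for teleost fish eDNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FirstOrderParams",
    "SecondOrderParams",
    "TemperatureDecayLaw",
    "FitResult",
    "ConvergenceError",
    "eval_first_order",
    "eval_second_order",
    "temperature_decay_rate",
    "half_life",
    "fit_decay_models",
    "classify_decay_pattern",
    "decay_pattern_percentages",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FirstOrderParams:
    """Single-phase exponential decay: C(t) = C00 * exp(-k t)."""

    C00: float  # initial concentration, copies/uL
    k: float    # decay rate, 1/h

    def __post_init__(self) -> None:
        if self.C00 < 0:
            raise ValueError(f"C00 must be >= 0, got {self.C00}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class SecondOrderParams:
    """Two-exponential mixture: C(t) = C01 exp(-k1 t) + C02 exp(-k2 t).

    One amplitude may be negative (delayed decay: the concentration rises
    before it falls), but the initial concentration C01 + C02 must be
    non-negative.
    """

    C01: float
    C02: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rates k1, k2 must be >= 0")
        if self.C01 + self.C02 < 0:
            raise ValueError("initial concentration C01 + C02 must be >= 0")


@dataclass(frozen=True)
class TemperatureDecayLaw:
    """Exponential temperature dependence of the decay rate: k(T) = a e^(bT)."""

    a: float = 0.0419  # rate at 0 degC, 1/h
    b: float = 0.0776  # temperature coefficient, 1/degC

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")

    def __call__(self, temperature_C: float) -> float:
        return temperature_decay_rate(self, temperature_C)


@dataclass
class FitResult:
    """Outcome of a decay-model fit.

    ``params`` maps each temperature level to its fixed-effect parameter
    estimates; ``tank_offsets`` maps (temperature, tank) to the fitted
    log-amplitude offset (sum-to-zero within temperature).
    """

    model_form: str                                   # "first" | "second"
    params: dict[float, FirstOrderParams | SecondOrderParams]
    tank_offsets: dict[tuple[float, str], float]
    aic: float
    r2: float
    n_obs: int
    excluded_times: list[float] = field(default_factory=list)
    sigma: float = float("nan")

    def predict(self, temperature: float, t, tank: str | None = None):
        """Fitted concentration at time t for one temperature level."""
        p = self.params[temperature]
        if isinstance(p, FirstOrderParams):
            c = eval_first_order(p, t)
        else:
            c = eval_second_order(p, t)
        if tank is not None:
            c = c * math.exp(self.tank_offsets.get((temperature, tank), 0.0))
        return c

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-temperature parameter table."""
        rows = []
        for T, p in self.params.items():
            d = {"temperature_C": T, "model_form": self.model_form}
            d.update(vars(p))
            rows.append(d)
        return pd.DataFrame(rows)


class ConvergenceError(RuntimeError):
    """Raised when no multi-start fit converges; carries best-so-far info."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# --------------------------------------------------------------------------
# model evaluation
# --------------------------------------------------------------------------

def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since shedding must be >= 0")
    return t


def eval_first_order(p: FirstOrderParams, t):
    """Concentration under single-phase exponential decay."""
    t = _check_time(t)
    out = p.C00 * np.exp(-p.k * t)
    return out if out.ndim else float(out)


def eval_second_order(p: SecondOrderParams, t):
    """Concentration under the two-exponential mixture."""
    t = _check_time(t)
    out = p.C01 * np.exp(-p.k1 * t) + p.C02 * np.exp(-p.k2 * t)
    return out if out.ndim else float(out)


def temperature_decay_rate(law: TemperatureDecayLaw, temperature_C: float) -> float:
    """First-order decay rate (1/h) at the given water temperature.

    Valid over roughly -2..35 degC; outside that range the empirical law
    has no support and a ValueError is raised.
    """
    if not -2.0 <= temperature_C <= 35.0:
        raise ValueError(
            f"temperature {temperature_C} degC outside supported range [-2, 35]"
        )
    return law.a * math.exp(law.b * temperature_C)


def _expected_curve(model, temperature: float | None, law_temperature: float):
    """Expected concentration/abundance curve C(t)/C(0) for half_life."""
    # DecayScenarioSpec is duck-typed via its `kind` attribute to avoid a
    # circular import with the particle-tracking module.
    kind = getattr(model, "kind", None)
    if kind is None:
        if isinstance(model, FirstOrderParams):
            return lambda t: eval_first_order(model, t)
        if isinstance(model, SecondOrderParams):
            return lambda t: eval_second_order(model, t)
        raise TypeError(f"unsupported model type: {type(model)!r}")

    T = law_temperature if temperature is None else temperature
    if kind == "no_decay":
        return lambda t: np.ones_like(np.asarray(t, dtype=float))
    if kind == "exponential":
        k = model.law(T)
        return lambda t: np.exp(-k * np.asarray(t, dtype=float))
    if kind == "biphasic":
        f1, f2 = model.biphasic_fractions
        r1, r2 = model.biphasic_rates
        return lambda t: (f1 * np.exp(-r1 * np.asarray(t, dtype=float))
                          + f2 * np.exp(-r2 * np.asarray(t, dtype=float)))
    if kind == "delayed":
        k = model.law(T)
        g = model.division_fraction_per_h
        dur = model.division_duration_h

        def curve(t):
            t = np.asarray(t, dtype=float)
            growth = (1.0 + g) ** np.minimum(np.floor(t), dur)
            post = np.exp(-k * np.maximum(t - dur, 0.0))
            return growth * post

        return curve
    raise ValueError(f"unknown scenario kind: {kind}")


def half_life(model, temperature: float | None = None, *,
              tol_h: float = 1e-6, t_max_h: float = 1e6) -> float:
    """Smallest t (hours) at which C(t) = C(0) / 2.

    Found by expanding-bracket bisection to ``tol_h`` absolute tolerance.
    Accepts first/second-order parameter sets or a decay scenario (for
    scenarios with a temperature law, evaluate at ``temperature``,
    default 12 degC).  Returns ``math.inf`` when the curve never reaches
    half of its initial value (e.g. no decay, k = 0).
    """
    curve = _expected_curve(model, temperature, law_temperature=12.0)
    c0 = float(curve(0.0))
    if c0 <= 0:
        raise ValueError("initial concentration must be > 0 for a half-life")
    target = 0.5 * c0

    # expand the bracket until the curve drops below half
    hi = 1.0
    while float(curve(hi)) >= target:
        hi *= 2.0
        if hi > t_max_h:
            return math.inf
    lo = 0.0
    while hi - lo > tol_h:
        mid = 0.5 * (lo + hi)
        if float(curve(mid)) >= target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

_CONC_COL = "concentration_copies_per_uL"


def _validate_series(series: pd.DataFrame) -> None:
    required = {"temperature_C", "bio_replicate", "time_h", _CONC_COL}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"decay series missing columns: {sorted(missing)}")
    if (series[_CONC_COL] < 0).any():
        raise ValueError("concentrations must be >= 0")


def _fit_one_temperature(t, c, tanks, form: str, rng: np.random.Generator):
    """Multi-start least squares for one temperature level.

    Model: C_obs = exp(delta_tank) * curve(t); the per-tank log-amplitude
    offsets are constrained to sum to zero (the last tank's offset is the
    negative sum of the others), mirroring a random intercept on
    log-amplitude for the (temperature x tank) grouping.

    The amplitudes enter linearly given the rates and offsets, so the
    nonlinear search runs only over (rates, offsets) with the amplitudes
    recovered by an exact linear solve at every step (variable
    projection); this keeps the multi-start cheap and the noiseless case
    exact to machine precision.
    """
    tank_levels = sorted(pd.unique(tanks))
    n_off = max(len(tank_levels) - 1, 0)
    tank_idx = np.searchsorted(tank_levels, tanks)
    n_rates = 1 if form == "first" else 2

    def offsets_full(d):
        if n_off == 0:
            return np.zeros(1)
        return np.concatenate([d, [-np.sum(d)]])

    def solve_amplitudes(theta):
        rates = theta[:n_rates]
        mult = np.exp(offsets_full(theta[n_rates:]))[tank_idx]
        X = mult[:, None] * np.exp(-np.outer(t, rates))
        amp, *_ = np.linalg.lstsq(X, c, rcond=None)
        return amp, X @ amp - c

    def resid(theta):
        return solve_amplitudes(theta)[1]

    rate_grid = np.geomspace(1e-3, 2.0, 6)
    if form == "first":
        starts = [[k] for k in rate_grid]
    else:
        starts = [[kf, ks] for kf in rate_grid for ks in rate_grid if kf > ks]
    lb = [0.0] * n_rates + [-np.inf] * n_off
    ub = [np.inf] * (n_rates + n_off)

    best = best_theta = None
    for s in starts:
        jitter = rng.uniform(0.95, 1.05, size=n_rates)
        theta0 = np.concatenate([np.asarray(s) * jitter, np.zeros(n_off)])
        try:
            sol = least_squares(resid, theta0, bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=300)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best, best_theta = sol, sol.x
    if best is None:
        raise ConvergenceError(
            "no least-squares start converged",
            {"n_starts": len(starts), "form": form},
        )
    amp, r = solve_amplitudes(best_theta)
    if form == "first":
        theta = np.array([amp[0], best_theta[0]])
    else:
        theta = np.array([amp[0], best_theta[0], amp[1], best_theta[1]])
    offs = (offsets_full(best_theta[n_rates:]) if n_off
            else np.zeros(len(tank_levels)))
    ssr = float(np.dot(r, r))
    return theta, dict(zip(tank_levels, offs)), ssr


def fit_decay_models(series: pd.DataFrame, form: str = "first",
                     exclude_times: Sequence[float] = (),
                     seed: int = 0) -> FitResult:
    """Fit a decay model to replicate-level concentration data.

    Temperature levels get independent fixed-effect parameter sets
    (2 per level for first order, 4 for second order); each
    (temperature, tank) group gets a log-amplitude offset constrained to
    sum to zero within its temperature.  Fitting is nonlinear least
    squares with seeded multi-starts over log-spaced rate grids; AIC is
    computed under a pooled Gaussian observation model and R^2 is
    1 - SSR/SST on the pooled observations.

    ``exclude_times`` removes whole sampling time points (hours) before
    fitting, recorded on the result.
    """
    if form not in ("first", "second"):
        raise ValueError("form must be 'first' or 'second'")
    _validate_series(series)

    data = series.copy()
    for tx in exclude_times:
        data = data[~np.isclose(data["time_h"], tx)]
    data = data.reset_index(drop=True)

    for T, grp in data.groupby("temperature_C"):
        if grp["time_h"].nunique() < 4:
            raise ValueError(
                f"temperature {T} has fewer than 4 distinct time points "
                "after exclusions"
            )

    rng = np.random.default_rng(seed)
    params: dict[float, FirstOrderParams | SecondOrderParams] = {}
    offsets: dict[tuple[float, str], float] = {}
    ssr_total = 0.0
    n_off_params = 0
    for T, grp in data.groupby("temperature_C"):
        t = grp["time_h"].to_numpy(float)
        c = grp[_CONC_COL].to_numpy(float)
        tanks = grp["bio_replicate"].to_numpy()
        theta, offs, ssr = _fit_one_temperature(t, c, tanks, form, rng)
        ssr_total += ssr
        n_off_params += max(len(offs) - 1, 0)
        if form == "first":
            params[T] = FirstOrderParams(C00=max(theta[0], 0.0), k=max(theta[1], 0.0))
        else:
            c01, k1, c02, k2 = theta
            if k1 < k2:  # report the faster component first
                c01, k1, c02, k2 = c02, k2, c01, k1
            params[T] = SecondOrderParams(C01=c01, C02=c02,
                                          k1=max(k1, 0.0), k2=max(k2, 0.0))
        for tank, d in offs.items():
            offsets[(T, tank)] = float(d)

    n = len(data)
    n_fixed = (2 if form == "first" else 4) * len(params)
    p = n_fixed + n_off_params + 1  # + residual variance
    sigma2 = max(ssr_total / n, np.finfo(float).tiny)
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    aic = -2.0 * loglik + 2.0 * p
    sst = float(np.sum((data[_CONC_COL] - data[_CONC_COL].mean()) ** 2))
    r2 = 1.0 - ssr_total / sst if sst > 0 else float("nan")

    return FitResult(model_form=form, params=params, tank_offsets=offsets,
                     aic=aic, r2=r2, n_obs=n,
                     excluded_times=list(exclude_times),
                     sigma=math.sqrt(sigma2))


# --------------------------------------------------------------------------
# pattern classification
# --------------------------------------------------------------------------

def classify_decay_pattern(series: pd.DataFrame, early_window_h: float = 6.0,
                           rise_threshold: float = 0.25,
                           rate_ratio_threshold: float = 5.0,
                           seed: int = 0) -> str:
    """Classify a single-condition decay series.

    Rules, applied in order to the per-time replicate means:

    * ``delayed`` - the early-window mean rises by more than
      ``rise_threshold`` over the initial concentration;
    * ``biphasic`` - a second-order fit with both amplitudes positive has
      a rate ratio >= ``rate_ratio_threshold`` and a lower AIC than the
      first-order fit;
    * ``exponential`` - otherwise.

    Returns ``"unclassifiable"`` when fewer than two sampling times fall
    inside the early window (the early phase cannot be assessed).
    """
    _validate_series(series)
    if series["temperature_C"].nunique() > 1:
        raise ValueError(
            "classify_decay_pattern expects a single temperature level; "
            "classify each level separately"
        )
    means = series.groupby("time_h")[_CONC_COL].mean().sort_index()
    times = means.index.to_numpy(float)

    early = times[(times > 0) & (times <= early_window_h)]
    if len(early) < 2:
        return "unclassifiable"

    c0 = means.iloc[0]
    if c0 > 0 and means.loc[early].max() > (1.0 + rise_threshold) * c0:
        return "delayed"

    fit1 = fit_decay_models(series, "first", seed=seed)
    fit2 = fit_decay_models(series, "second", seed=seed)
    (p2,) = fit2.params.values()
    rates = sorted([p2.k1, p2.k2])
    ratio = math.inf if rates[0] == 0 else rates[1] / rates[0]
    if (p2.C01 > 0 and p2.C02 > 0 and ratio >= rate_ratio_threshold
            and fit2.aic < fit1.aic):
        return "biphasic"
    return "exponential"


def decay_pattern_percentages(counts: Mapping[str, int],
                              total: int | None = None) -> dict[str, int]:
    """Percentage share of each decay pattern among reviewed studies.

    ``counts`` maps pattern name to the number of studies exhibiting it;
    percentages are of ``total`` (default: the sum of the counts), rounded
    to the nearest integer as review tallies are reported.  An explicit
    ``total`` supports shares of the full study pool when only some
    patterns are tabulated.
    """
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    return {name: round(100.0 * n / total) for name, n in counts.items()}
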