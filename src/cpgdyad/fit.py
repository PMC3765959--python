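"""Inference of 2i kinetic parameters from 5mC/5hmC time courses.

Fits the time-dependent rate schedule (maintenance relaxation, oxidation
ramp, de novo decay) to observed strand-fraction series by bounded
maximum likelihood with Latin-hypercube multistart, plus replicate
bootstrap for confidence intervals.  Predictions use the exact
per-division strand recursion, so the fitted model is the same object the
simulator propagates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import qmc

from .kinetics import DEFAULT_T_CYCLE, RateSchedule, Rates, advance_strand_fractions

#: Parameters that may be freed in a fit, with default bounds.
DEFAULT_BOUNDS = {
    "rho_lo": (0.0, 0.95),
    "tau_D": (6.0, 300.0),
    "kappa_max": (0.0, 1.0),
    "tau_T": (6.0, 300.0),
    "delta_0": (0.0, 0.5),
    "tau_delta": (2.0, 100.0),
}

#: Default fixed values (the standard demethylating 2i schedule).
DEFAULT_PARAMS = dict(
    rho_hi=0.95,
    rho_lo=0.35,
    tau_D=72.0,
    kappa_max=0.30,
    tau_T=72.0,
    delta_0=0.15,
    tau_delta=12.0,
    rho_h=0.1,
)

#: Default serum (initial-condition) rates for the standard class.
DEFAULT_SERUM = dict(rho_m=0.95, rho_h=0.1, kappa=0.02, delta=0.15)

_CLIP = 1e-9


@dataclass
class FitConfig:
    free: tuple[str, ...] = ("kappa_max",)
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    n_multistart: int = 10
    seed: int = 0
    noise: str = "gaussian"  # or "binomial"
    T_cycle: float = DEFAULT_T_CYCLE
    serum: dict = field(default_factory=lambda: dict(DEFAULT_SERUM))

    def __post_init__(self):
        unknown = set(self.free) - set(DEFAULT_BOUNDS)
        if unknown:
            raise ValueError(f"cannot free parameters {sorted(unknown)}")
        if self.n_multistart < 1:
            raise ValueError("n_multistart must be >= 1")
        if self.noise not in ("gaussian", "binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        for name in self.free:
            lo, hi = self.resolved_bounds(name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def resolved_bounds(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, DEFAULT_BOUNDS[name]))

    def full_params(self, free_values) -> dict:
        params = dict(DEFAULT_PARAMS)
        params.update(self.fixed)
        params.update(dict(zip(self.free, free_values)))
        return params


def _serum_steady(serum: dict) -> tuple[float, float]:
    """Analytic fixed point of the strand recursion under constant rates."""
    rho_m, rho_h = serum["rho_m"], serum["rho_h"]
    kappa, delta = serum["kappa"], serum["delta"]
    # m' = [((1-k)(1+rho_m) + rho_h k - delta) m + (rho_h - delta) h + delta]/2
    # h' = (k m + h)/2
    a11 = ((1 - kappa) * (1 + rho_m) + rho_h * kappa - delta) / 2.0
    a12 = (rho_h - delta) / 2.0
    b1 = delta / 2.0
    a21 = kappa / 2.0
    a22 = 0.5
    det = (1 - a11) * (1 - a22) - a12 * a21
    m = (b1 * (1 - a22)) / det
    h = a21 * m / (1 - a22)
    return m, h


def model_predict(
    params: dict,
    sample_times,
    serum: dict | None = None,
    T_cycle: float = DEFAULT_T_CYCLE,
) -> pd.DataFrame:
    """Exact-mode (5mC, 5hmC) strand fractions at the sampled times.

    ``params`` hold the 2i schedule (rho_hi, rho_lo, tau_D, kappa_max,
    tau_T, delta_0, tau_delta, rho_h); the locus starts at the serum
    steady state and divides every ``T_cycle`` hours, with the schedule
    evaluated at each cycle midpoint.
    """
    serum = serum or DEFAULT_SERUM
    schedule = RateSchedule(
        rho_hi=params["rho_hi"],
        rho_lo=params["rho_lo"],
        tau_D=params["tau_D"],
        kappa_0=0.0,
        kappa_max=params["kappa_max"],
        tau_T=params["tau_T"],
        delta_0=params["delta_0"],
        tau_delta=params["tau_delta"],
        rho_h=params["rho_h"],
        T_cycle=T_cycle,
    )
    m, h = _serum_steady(serum)
    times = sorted({float(t) for t in sample_times})
    divisions = {t: round(t / T_cycle) for t in times}
    out = {}
    max_div = max(divisions.values())
    want: dict[int, list[float]] = {}
    for t, k in divisions.items():
        want.setdefault(int(k), []).append(t)
    for t in want.get(0, []):
        out[t] = (m, h)
    for k in range(1, max_div + 1):
        rates = schedule.at((k - 0.5) * T_cycle)
        m, h = advance_strand_fractions(m, h, rates)
        for t in want.get(k, []):
            out[t] = (m, h)
    rows = [
        dict(time_h=t, frac_5mC=out[t][0], frac_5hmC=out[t][1]) for t in times
    ]
    return pd.DataFrame(rows)


def _predict_lookup(params, observed, serum, T_cycle):
    pred = model_predict(params, observed["time_h"].unique(), serum, T_cycle)
    lut = {
        (row.time_h, "5mC"): row.frac_5mC for row in pred.itertuples()
    }
    lut.update(
        {(row.time_h, "5hmC"): row.frac_5hmC for row in pred.itertuples()}
    )
    return np.array(
        [lut[(float(t), mk)] for t, mk in zip(observed["time_h"], observed["mark"])]
    )


def loss(
    params: dict,
    observed: pd.DataFrame,
    noise: str = "gaussian",
    serum: dict | None = None,
    T_cycle: float = DEFAULT_T_CYCLE,
) -> float:
    """Negative log-likelihood of an observed series under the model.

    ``observed`` columns: time_h, mark in {5mC, 5hmC}, plus value & se
    (gaussian) or k & n (binomial).  Predicted fractions are clipped to
    [1e-9, 1 - 1e-9] so the loss is always finite.
    """
    required = {"time_h", "mark"}
    if not required <= set(observed.columns):
        raise ValueError(f"observed table needs columns {sorted(required)}")
    p = np.clip(
        _predict_lookup(params, observed, serum, T_cycle), _CLIP, 1 - _CLIP
    )
    if noise == "gaussian":
        obs = observed["value"].to_numpy(dtype=float)
        se = observed["se"].to_numpy(dtype=float)
        if len(obs) != len(p):
            raise ValueError("mismatched series lengths")
        return float(np.sum(0.5 * ((obs - p) / se) ** 2))
    if noise == "binomial":
        k = observed["k"].to_numpy(dtype=float)
        n = observed["n"].to_numpy(dtype=float)
        logpmf = (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )
        return float(-np.sum(logpmf))
    raise ValueError(f"unknown noise model {noise!r}")


@dataclass
class FitResult:
    estimates: dict
    objective: float
    starts: list = field(default_factory=list)
    converged: bool = True
    identifiability_warning: bool = False
    config: FitConfig | None = None

    def full_params(self) -> dict:
        return self.config.full_params(
            [self.estimates[name] for name in self.config.free]
        )


def _objective_factory(observed, config: FitConfig):
    def f(x):
        return loss(
            config.full_params(x),
            observed,
            config.noise,
            config.serum,
            config.T_cycle,
        )

    return f


def fit_timecourse(
    observed: pd.DataFrame,
    config: FitConfig,
    init: dict | None = None,
) -> FitResult:
    """Bounded ML fit with Latin-hypercube multistart.

    ``init``, when given, replaces the first start.  All starts are logged
    in the result; the best final objective wins.
    """
    n_obs = len(observed)
    if n_obs < len(config.free):
        raise ValueError(
            f"{n_obs} observations cannot constrain {len(config.free)} parameters"
        )
    f = _objective_factory(observed, config)
    bounds = [config.resolved_bounds(name) for name in config.free]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(config.free), seed=config.seed)
    starts = lo + sampler.random(config.n_multistart) * (hi - lo)
    if init is not None:
        starts[0] = [init[name] for name in config.free]
    trace = []
    best = None
    for x0 in starts:
        res = minimize(
            f,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(ftol=1e-10, gtol=1e-8, maxiter=500),
        )
        # a failed line search at a (near-)exact minimum still returns the
        # optimum; only a non-finite objective makes a start unusable
        usable = np.isfinite(res.fun)
        trace.append(
            dict(x0=list(map(float, x0)), x=list(map(float, res.x)),
                 fun=float(res.fun), success=bool(res.success),
                 usable=bool(usable))
        )
        if usable and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"no start converged; traces: {trace}")
    ident_warn = False
    if len(config.free) >= 2:
        ident_warn = _hessian_near_singular(f, best.x, lo, hi)
        if ident_warn:
            warnings.warn(
                "near-singular Hessian at the optimum: some free parameters "
                "are weakly identifiable from this series"
            )
    return FitResult(
        estimates={name: float(v) for name, v in zip(config.free, best.x)},
        objective=float(best.fun),
        starts=trace,
        converged=bool(best.success),
        identifiability_warning=ident_warn,
        config=config,
    )


def _hessian_near_singular(f, x, lo, hi, cond_limit=1e8) -> bool:
    d = len(x)
    steps = np.maximum(1e-4 * (hi - lo), 1e-8)
    H = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        cond = np.linalg.cond(H)
    except np.linalg.LinAlgError:
        return True
    return not np.isfinite(cond) or cond > cond_limit


def bootstrap_ci(
    observed: pd.DataFrame,
    config: FitConfig,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Replicate-bootstrap percentile intervals for the free parameters.

    Replicates (column ``replicate_id``) are resampled with replacement,
    the model refit to each resample, and 2.5/97.5 percentiles of the
    bootstrap estimates reported per free parameter.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if "replicate_id" not in observed.columns:
        raise ValueError("bootstrap requires a replicate_id column")
    replicates = sorted(observed["replicate_id"].unique())
    if len(replicates) < 2:
        raise ValueError("bootstrap requires at least 2 replicates")
    rng = np.random.default_rng(seed)
    point = fit_timecourse(observed, config)
    groups = {r: observed[observed["replicate_id"] == r] for r in replicates}
    boot_estimates = {name: [] for name in config.free}
    for _ in range(n_boot):
        chosen = rng.choice(replicates, size=len(replicates), replace=True)
        resampled = pd.concat([groups[r] for r in chosen], ignore_index=True)
        res = fit_timecourse(resampled, config, init=point.estimates)
        for name in config.free:
            boot_estimates[name].append(res.estimates[name])
    intervals = {}
    for name in config.free:
        values = np.array(boot_estimates[name])
        intervals[name] = (
            float(np.percentile(values, 2.5)),
            float(np.percentile(values, 97.5)),
        )
    return dict(
        point=point.estimates,
        intervals=intervals,
        boot_estimates={k: list(map(float, v)) for k, v in boot_estimates.items()},
        n_boot=n_boot,
        seed=seed,
    )
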