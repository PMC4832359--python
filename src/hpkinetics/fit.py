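"""Maximum-likelihood fitting of the kinetic models to four-channel time series.

The four hyperpolarized signals are fit simultaneously.  Noise is Gaussian
with a separate unknown variance per channel; profiling the likelihood over
the variances leaves the cost

    cost = sum over channels of log(SSE_channel)

to be minimized over the kinetic parameters.  Minimization uses seeded
Latin-hypercube multistart, a bounded trust-region least-squares inner solver
and an iteratively-reweighted outer loop (weights 1/SSE per channel), whose
fixed points are stationary points of the log-SSE cost.

The public surface is the sklearn-style :class:`KineticsFitter` estimator;
``fit``, ``compare_models`` and ``fit_cohort`` are thin wrappers over it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc, ttest_ind
from sklearn.base import BaseEstimator, RegressorMixin

from .model import (
    CHANNELS,
    PSEUDO_RATE_NAMES,
    STATE_NAMES,
    AcquisitionSchedule,
    FirstOrderParams,
    InputParams,
    RelaxationParams,
    SecondOrderParams,
    pseudo_rates,
)
from .simulate import TimeSeries, solve_at_times

__all__ = [
    "FitResult",
    "CohortSummary",
    "ModelComparison",
    "KineticsFitter",
    "cost",
    "r_squared",
    "fit",
    "pre_post",
    "cohort_ttest",
    "compare_models",
    "fit_cohort",
    "DEFAULT_BOUNDS",
]

#: Generous physiological bounds for the free parameters.
DEFAULT_BOUNDS = {
    "k_PL": (0.0, 10.0), "k_LP": (0.0, 10.0), "k_PA": (0.0, 10.0),
    "k_AP": (0.0, 10.0), "k_PB": (0.0, 10.0),
    "T1_pyruvate": (5.0, 150.0), "T1_lactate": (5.0, 150.0),
    "T1_alanine": (5.0, 150.0), "T1_bicarbonate": (5.0, 150.0),
    "k_in": (0.0, 10.0), "t_arrival": (0.0, 60.0),
    "delta": (0.0, 10.0), "beta": (0.01, 5.0),
    "NADc0": (1e-6, 1e3), "NADHc0": (1e-6, 1e3), "Glu0": (1e-6, 1e3),
    "aKG0": (1e-6, 1e3), "NADm0": (1e-6, 1e3), "NADHm0": (1e-6, 1e3),
}

# parameter-vector layouts per model kind
_SECOND_NAMES = (
    "k_PL", "k_PA", "k_PB",
    "T1_pyruvate", "T1_lactate", "T1_alanine", "T1_bicarbonate",
    "k_in", "t_arrival", "delta", "beta",
    "NADc0", "NADHc0", "Glu0", "aKG0", "NADm0", "NADHm0",
)
_FIRST_NAMES = (
    "k_PL", "k_LP", "k_PA", "k_AP", "k_PB",
    "T1_pyruvate", "T1_lactate", "T1_alanine", "T1_bicarbonate",
    "k_in", "t_arrival", "delta", "beta",
)

# scale-type parameters: starts are drawn log-uniformly (value = lower edge of
# the sampling range) and the optimizer works on log(x) internally, which
# conditions the rate/pool valleys far better than the linear scale
_LOG_SAMPLED = {
    "k_PL": 1e-4, "k_LP": 1e-4, "k_PA": 1e-4, "k_AP": 1e-4, "k_PB": 1e-4,
    "k_in": 1e-5, "beta": None,
    "NADc0": None, "NADHc0": None, "Glu0": None, "aKG0": None,
    "NADm0": None, "NADHm0": None,
}

#: numerical floor replacing a zero lower bound on log-scale parameters
_LOG_FLOOR = 1e-8


class _LogLinearTransform:
    """Map between the physical parameter vector x and the optimizer vector z,
    with log coordinates for scale-type parameters."""

    def __init__(self, names, lo, hi):
        self.logmask = np.array([n in _LOG_SAMPLED for n in names])
        self.lo_eff = np.where(self.logmask, np.maximum(lo, _LOG_FLOOR), lo)
        self.hi = hi
        self.z_lo = np.where(self.logmask, np.log(np.where(self.logmask, self.lo_eff, 1.0)), self.lo_eff)
        self.z_hi = np.where(self.logmask, np.log(np.where(self.logmask, hi, 1.0)), hi)

    def to_x(self, z):
        return np.where(self.logmask, np.exp(np.where(self.logmask, z, 0.0)), z)

    def to_z(self, x):
        xc = np.clip(x, self.lo_eff, self.hi)
        return np.where(self.logmask, np.log(np.where(self.logmask, xc, 1.0)), xc)


def _param_names(model_kind: str):
    if model_kind == "second_order":
        return _SECOND_NAMES
    if model_kind == "first_order":
        return _FIRST_NAMES
    raise ValueError("model_kind must be 'second_order' or 'first_order'")


def _unpack(model_kind: str, x):
    names = _param_names(model_kind)
    d = dict(zip(names, (float(v) for v in x)))
    relax = RelaxationParams(
        T1_pyruvate=d["T1_pyruvate"], T1_lactate=d["T1_lactate"],
        T1_alanine=d["T1_alanine"], T1_bicarbonate=d["T1_bicarbonate"])
    inp = InputParams(k_in=d["k_in"], t_arrival=d["t_arrival"],
                      delta=d["delta"], beta=d["beta"])
    if model_kind == "second_order":
        params = SecondOrderParams(
            k_PL=d["k_PL"], k_PA=d["k_PA"], k_PB=d["k_PB"],
            NADc0=d["NADc0"], NADHc0=d["NADHc0"], Glu0=d["Glu0"],
            aKG0=d["aKG0"], NADm0=d["NADm0"], NADHm0=d["NADHm0"])
    else:
        params = FirstOrderParams(k_PL=d["k_PL"], k_LP=d["k_LP"], k_PA=d["k_PA"],
                                  k_AP=d["k_AP"], k_PB=d["k_PB"])
    return params, relax, inp


def _pack(model_kind: str, params, relax, inp):
    pool = {**dataclasses.asdict(params), **dataclasses.asdict(relax),
            **dataclasses.asdict(inp)}
    return np.array([pool[n] for n in _param_names(model_kind)])


def _sse_per_channel(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    return np.sum((predicted - observed) ** 2, axis=0)


def _eps_floor(n_points: int) -> float:
    return n_points * np.finfo(float).eps


def cost(observed: TimeSeries, predicted: TimeSeries, eps_floor: float | None = None) -> float:
    """Profiled-variance maximum-likelihood cost: sum of log channel SSEs.

    Each channel SSE is floored at ``eps_floor`` (default ``N * machine-eps``)
    so a perfect fit yields a finite, documented cost of ``4*log(eps_floor)``.

    Raises
    ------
    ValueError
        If the two series are not on the same time grid.
    """
    if observed.times.shape != predicted.times.shape or not np.allclose(
            observed.times, predicted.times):
        raise ValueError("observed and predicted series must share the same time grid")
    floor = _eps_floor(observed.times.size) if eps_floor is None else eps_floor
    sse = _sse_per_channel(observed.signals, predicted.signals)
    return float(np.sum(np.log(np.maximum(sse, floor))))


def r_squared(observed: TimeSeries, predicted: TimeSeries) -> dict:
    """Per-channel coefficient of determination (about the channel mean).

    A constant observed channel has zero total sum of squares; its R^2 is
    undefined and reported as NaN.
    """
    if observed.times.shape != predicted.times.shape or not np.allclose(
            observed.times, predicted.times):
        raise ValueError("observed and predicted series must share the same time grid")
    sse = _sse_per_channel(observed.signals, predicted.signals)
    sst = np.sum((observed.signals - observed.signals.mean(axis=0)) ** 2, axis=0)
    out = {}
    for i, ch in enumerate(CHANNELS):
        out[ch] = float(1.0 - sse[i] / sst[i]) if sst[i] > 0 else float("nan")
    return out


@dataclass
class FitResult:
    """Outcome of one model fit to one time series."""

    model_kind: str
    params: SecondOrderParams | FirstOrderParams
    relax: RelaxationParams
    inp: InputParams
    cost: float
    sse: dict
    r_squared: dict
    pseudo_rate_courses: pd.DataFrame
    pre_post: dict
    predicted: TimeSeries
    convergence: dict
    seed: int | None = None

    def to_dict(self) -> dict:
        """JSON-serializable summary (pseudo-rate courses go to CSV separately)."""
        return {
            "model_kind": self.model_kind,
            "params": dataclasses.asdict(self.params),
            "relaxation": dataclasses.asdict(self.relax),
            "input": dataclasses.asdict(self.inp),
            "cost": self.cost,
            "sse": self.sse,
            "r_squared": self.r_squared,
            "pre_post": {k: list(v) for k, v in self.pre_post.items()},
            "convergence": self.convergence,
            "seed": self.seed,
        }


@dataclass
class CohortSummary:
    """Per-heart fits plus mean, SEM and the per-parameter table."""

    fits: list
    params_table: pd.DataFrame
    mean: pd.Series
    sem: pd.Series

    def to_dict(self) -> dict:
        return {
            "n_hearts": len(self.fits),
            "mean": self.mean.to_dict(),
            "sem": self.sem.to_dict(),
            "per_heart": [f.to_dict() for f in self.fits],
        }


@dataclass
class ModelComparison:
    """Side-by-side second- vs first-order fits of the same data."""

    fit_a: FitResult
    fit_b: FitResult
    delta_r_squared: dict
    delta_cost: float

    def to_dict(self) -> dict:
        return {
            "model_a": self.fit_a.model_kind,
            "model_b": self.fit_b.model_kind,
            "delta_r_squared": self.delta_r_squared,
            "delta_cost": self.delta_cost,
            "fit_a": self.fit_a.to_dict(),
            "fit_b": self.fit_b.to_dict(),
        }


class KineticsFitter(RegressorMixin, BaseEstimator):
    """Fit a hyperpolarized-pyruvate kinetic model to a four-channel series.

    Parameters
    ----------
    model_kind : {"second_order", "first_order"}
        Which model to fit.  The second-order model frees the three
        second-order rate constants and six initial cofactor pools; only the
        products (pseudo rates) are structurally identifiable, and those are
        the primary outputs.
    schedule : AcquisitionSchedule, optional
        Acquisition metadata (repetition time, flip angle).  Defaults to the
        2 s / 10 degree schedule with ``n_points`` taken from the data.
    bounds : dict, optional
        Per-parameter (lo, hi) overrides of :data:`DEFAULT_BOUNDS`.
    n_starts : int
        Number of Latin-hypercube multistart points.
    n_polish : int
        How many of the best exploratory starts get the full reweighted
        polish.
    irls_rounds : int
        Outer reweighting rounds during polish.
    random_state : int, optional
        Seeds the multistart sampler; fixed seed gives a deterministic fit.

    Attributes
    ----------
    params_, relax_, input_ : fitted parameter dataclasses
    cost_ : float, the profiled-ML cost at the optimum
    sse_, r_squared_ : per-channel goodness of fit
    pseudo_rates_ : DataFrame of pseudo-rate time courses
    pre_post_ : dict of (pre, post) pseudo rates per reaction
    result_ : the full :class:`FitResult`
    """

    def __init__(self, model_kind="second_order", schedule=None, bounds=None,
                 n_starts=16, n_polish=3, irls_rounds=3,
                 pdh_cofactor="nadm", input_term="literal",
                 solver_rtol=1e-6, solver_atol=1e-9, polish_rtol=1e-8,
                 explore_iters=60, polish_iters=200, nested_init=True,
                 random_state=None):
        self.model_kind = model_kind
        self.schedule = schedule
        self.bounds = bounds
        self.n_starts = n_starts
        self.n_polish = n_polish
        self.irls_rounds = irls_rounds
        self.pdh_cofactor = pdh_cofactor
        self.input_term = input_term
        self.solver_rtol = solver_rtol
        self.solver_atol = solver_atol
        self.polish_rtol = polish_rtol
        self.explore_iters = explore_iters
        self.polish_iters = polish_iters
        self.nested_init = nested_init
        self.random_state = random_state

    # ------------------------------------------------------------------ data
    @staticmethod
    def _coerce_data(X, y=None) -> TimeSeries:
        if isinstance(X, TimeSeries):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if y is None:
            raise ValueError("y (an (n, 4) signal array) is required when X is a time array")
        return TimeSeries(times=X, signals=np.asarray(y, dtype=float))

    def _resolve_schedule(self, ts: TimeSeries) -> AcquisitionSchedule:
        if self.schedule is not None:
            return self.schedule
        tr = float(np.median(np.diff(ts.times))) if ts.times.size > 1 else 2.0
        return AcquisitionSchedule(repetition_time=tr, flip_angle=10.0,
                                   n_points=max(ts.times.size, 2),
                                   start_time=float(ts.times[0]))

    def _bounds_arrays(self, names):
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds or {})
        lo = np.array([merged[n][0] for n in names])
        hi = np.array([merged[n][1] for n in names])
        return lo, hi

    # ------------------------------------------------------------- internals
    def _predict_signals(self, x, times, sched, rtol=None):
        params, relax, inp = _unpack(self.model_kind, x)
        rtol = self.solver_rtol if rtol is None else rtol
        atol = self.solver_atol if rtol == self.solver_rtol else rtol * 1e-3
        return solve_at_times(self.model_kind, params, relax, sched, inp, times,
                              rtol=rtol, atol=atol,
                              pdh_cofactor=self.pdh_cofactor,
                              input_term=self.input_term)

    def _lhs_starts(self, names, lo, hi, rng):
        sampler = qmc.LatinHypercube(d=len(names), seed=rng)
        u = sampler.random(self.n_starts)
        starts = np.empty_like(u)
        for j, n in enumerate(names):
            if n in _LOG_SAMPLED:
                slo = _LOG_SAMPLED[n] if _LOG_SAMPLED[n] is not None else lo[j]
                slo = max(slo, 1e-12)
                starts[:, j] = np.exp(np.log(slo) + u[:, j] * (np.log(hi[j]) - np.log(slo)))
            else:
                starts[:, j] = lo[j] + u[:, j] * (hi[j] - lo[j])
            starts[:, j] = np.clip(starts[:, j], lo[j], hi[j])
        return starts

    def _run_ls(self, x0, obs, times, sched, weights, floor, max_nfev,
                tol=1e-8, rtol=None):
        """One bounded least-squares descent from x0; returns the optimum in
        physical coordinates."""
        sw = np.sqrt(weights)
        tf = self._tf

        def fun(z):
            try:
                pred = self._predict_signals(tf.to_x(z), times, sched, rtol=rtol)
            except RuntimeError:
                return np.full(obs.size, 1e6)
            if not np.all(np.isfinite(pred)):
                return np.full(obs.size, 1e6)
            return ((pred - obs) * sw).ravel()

        res = least_squares(fun, tf.to_z(np.asarray(x0, float)),
                            bounds=(tf.z_lo, tf.z_hi), method="trf",
                            x_scale="jac", max_nfev=max_nfev,
                            ftol=tol, xtol=tol, gtol=tol)
        return tf.to_x(res.x), res

    def _warm_start(self, x0, obs, times, sched, w_pyr, max_nfev):
        """Stage-1 warm-up: condition the bolus shape and pyruvate relaxation
        on the pyruvate channel alone (other parameters held at their draw)."""
        tf = self._tf
        idx = self._input_idx
        z_full = tf.to_z(np.asarray(x0, float))
        sw = np.sqrt(w_pyr)

        def fun(z_sub):
            z = z_full.copy()
            z[idx] = z_sub
            try:
                pred = self._predict_signals(tf.to_x(z), times, sched)
            except RuntimeError:
                return np.full(times.size, 1e6)
            if not np.all(np.isfinite(pred)):
                return np.full(times.size, 1e6)
            return (pred[:, 0] - obs[:, 0]) * sw

        res = least_squares(fun, z_full[idx], bounds=(tf.z_lo[idx], tf.z_hi[idx]),
                            method="trf", x_scale="jac", max_nfev=max_nfev)
        z_full[idx] = res.x
        return tf.to_x(z_full)

    def _cost_of(self, x, obs, times, sched, floor, rtol=None):
        try:
            pred = self._predict_signals(x, times, sched, rtol=rtol)
        except RuntimeError:
            return np.inf, None
        if not np.all(np.isfinite(pred)):
            return np.inf, None
        sse = _sse_per_channel(obs, pred)
        return float(np.sum(np.log(np.maximum(sse, floor)))), pred

    def _nested_start(self, ts, sched, names):
        """Structured start for the second-order fit from a quick first-order
        prefit: pseudo rates at arrival match the first-order constants under
        the unit-forward-pool convention."""
        pre = KineticsFitter(
            model_kind="first_order", schedule=self.schedule, bounds=self.bounds,
            n_starts=max(4, self.n_starts // 2), n_polish=2, irls_rounds=2,
            input_term=self.input_term, solver_rtol=self.solver_rtol,
            solver_atol=self.solver_atol, polish_rtol=self.solver_rtol,
            explore_iters=40, polish_iters=60, nested_init=False,
            random_state=None if self.random_state is None
            else int(self.random_state) + 104729)
        pre.fit(ts)
        fo, rx, inp = pre.params_, pre.relax_, pre.input_
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.bounds or {})

        def clip(name, v):
            lo, hi = merged[name]
            return float(np.clip(v, max(lo, _LOG_FLOOR), hi))

        tiny = 1e-6
        d = {
            "k_PL": clip("k_PL", fo.k_PL), "k_PA": clip("k_PA", fo.k_PA),
            "k_PB": clip("k_PB", fo.k_PB),
            "NADHc0": 1.0, "Glu0": 1.0, "NADm0": 1.0, "NADHm0": 0.5,
            "NADc0": clip("NADc0", fo.k_LP / max(fo.k_PL, tiny)),
            "aKG0": clip("aKG0", fo.k_AP / max(fo.k_PA, tiny)),
            "T1_pyruvate": rx.T1_pyruvate, "T1_lactate": rx.T1_lactate,
            "T1_alanine": rx.T1_alanine, "T1_bicarbonate": rx.T1_bicarbonate,
            "k_in": clip("k_in", inp.k_in), "t_arrival": inp.t_arrival,
            "delta": inp.delta, "beta": inp.beta,
        }
        return np.array([d[n] for n in names])

    # ------------------------------------------------------------------- API
    def fit(self, X, y=None):
        """Fit the model; ``X`` is a TimeSeries (or a time array with ``y``)."""
        ts = self._coerce_data(X, y)
        if ts.times.size < 2:
            raise ValueError("need at least 2 time points to fit")
        sched = self._resolve_schedule(ts)
        names = _param_names(self.model_kind)
        lo, hi = self._bounds_arrays(names)
        self._tf = _LogLinearTransform(names, lo, hi)
        obs = ts.signals
        times = ts.times
        n_par = len(names)
        floor = _eps_floor(times.size)
        rng = np.random.default_rng(self.random_state)

        degenerate = [ch for i, ch in enumerate(CHANNELS)
                      if np.allclose(obs[:, i], obs[0, i])]

        # round-0 weights: normalize channel scales (zero prediction ~ SSE = sum obs^2)
        w0 = 1.0 / np.maximum(np.sum(obs**2, axis=0), floor)

        self._input_idx = np.array([names.index(n) for n in
                                    ("k_in", "t_arrival", "delta", "beta", "T1_pyruvate")])
        starts = list(self._lhs_starts(names, lo, hi, rng))
        if self.model_kind == "second_order" and self.nested_init:
            starts.append(self._nested_start(ts, sched, names))
        explored = []
        max_nfev_explore = self.explore_iters * (n_par + 1)
        for i, x0 in enumerate(starts):
            x0 = self._warm_start(x0, obs, times, sched, w0[0], max_nfev=200)
            x_opt, res = self._run_ls(x0, obs, times, sched, w0, floor, max_nfev_explore)
            c, _ = self._cost_of(x_opt, obs, times, sched, floor)
            explored.append({"start": i, "x": x_opt, "cost": c, "nfev": int(res.nfev)})

        explored.sort(key=lambda r: r["cost"])
        if not np.isfinite(explored[0]["cost"]):
            raise RuntimeError(
                "all multistart optimizations failed; per-start record: "
                + ", ".join(f"start {r['start']}: cost={r['cost']}" for r in explored))

        max_nfev_polish = self.polish_iters * (n_par + 1)
        best_x, best_cost = None, np.inf
        polish_log = []
        rp = self.polish_rtol
        # a perfect fit has every channel SSE at the floor; once the cost is
        # within a hair of that, no further polishing can help
        cost_floor = len(CHANNELS) * np.log(floor)
        for cand in explored[: max(1, self.n_polish)]:
            x, c_best = cand["x"], np.inf
            x_best = x
            for _ in range(max(1, self.irls_rounds)):
                c_now, pred = self._cost_of(x, obs, times, sched, floor, rtol=rp)
                if pred is None:
                    break
                sse = np.maximum(_sse_per_channel(obs, pred), floor)
                x_new, _res = self._run_ls(x, obs, times, sched, 1.0 / sse, floor,
                                           max_nfev_polish, tol=1e-10, rtol=rp)
                c_new, _ = self._cost_of(x_new, obs, times, sched, floor, rtol=rp)
                # steps are only accepted when they lower the ML cost, but the
                # reweighting continues: new weights can reopen progress
                if c_new < c_best:
                    c_best, x_best = c_new, x_new
                if c_best <= cost_floor + 1e-3 or not c_new < c_now - 1e-10:
                    break
                x = x_new
            c_fin, _ = self._cost_of(x_best, obs, times, sched, floor, rtol=rp)
            polish_log.append({"start": cand["start"], "cost": c_fin})
            if c_fin < best_cost:
                best_cost, best_x = c_fin, x_best
            if best_cost <= cost_floor + 1e-3:
                break

        params, relax, inp = _unpack(self.model_kind, best_x)
        pred = self._predict_signals(best_x, times, sched, rtol=self.polish_rtol)
        predicted = TimeSeries(times=times, signals=pred, label=f"fit:{self.model_kind}")
        sse = _sse_per_channel(obs, pred)

        courses, prepost = self._rate_courses(params, relax, inp, sched, times)

        self.params_, self.relax_, self.input_ = params, relax, inp
        self.schedule_ = sched
        self.cost_ = float(np.sum(np.log(np.maximum(sse, floor))))
        self.sse_ = {ch: float(s) for ch, s in zip(CHANNELS, sse)}
        self.r_squared_ = r_squared(ts, predicted)
        self.pseudo_rates_ = courses
        self.pre_post_ = prepost
        self.convergence_ = {
            "n_starts": self.n_starts,
            "explore_costs": [float(r["cost"]) for r in explored],
            "polish": [{"start": p["start"], "cost": float(p["cost"])} for p in polish_log],
            "best_cost": float(best_cost),
            "degenerate_channels": degenerate,
        }
        self.result_ = FitResult(
            model_kind=self.model_kind, params=params, relax=relax, inp=inp,
            cost=self.cost_, sse=self.sse_, r_squared=self.r_squared_,
            pseudo_rate_courses=courses, pre_post=prepost, predicted=predicted,
            convergence=self.convergence_,
            seed=self.random_state if isinstance(self.random_state, (int, np.integer)) else None,
        )
        self.n_features_in_ = 1
        return self

    def _rate_courses(self, params, relax, inp, sched, times):
        """Pseudo-rate time courses on the acquisition grid plus (pre, post) values."""
        if self.model_kind == "second_order":
            states = solve_at_times("second_order", params, relax, sched, inp, times,
                                    rtol=self.polish_rtol, atol=self.polish_rtol * 1e-3,
                                    pdh_cofactor=self.pdh_cofactor,
                                    input_term=self.input_term, full_state=True)
            traj = pd.DataFrame(states, columns=list(STATE_NAMES),
                                index=pd.Index(times, name="time_s"))
            courses = pseudo_rates(traj, params, self.pdh_cofactor)
            # cofactors sit at their initial pools until the bolus arrives,
            # so the pre-injection pseudo rates are exact products k * Co(0)
            pdh0 = params.NADm0 if self.pdh_cofactor == "nadm" else params.NADHm0
            pre = {
                "k_PL": params.k_PL * params.NADHc0,
                "k_LP": params.k_PL * params.NADc0,
                "k_PA": params.k_PA * params.Glu0,
                "k_AP": params.k_PA * params.aKG0,
                "k_PB": params.k_PB * pdh0,
            }
            prepost = {name: (float(pre[name]), float(courses[name].iloc[-1]))
                       for name in PSEUDO_RATE_NAMES}
        else:
            const = {"k_PL": params.k_PL, "k_LP": params.k_LP, "k_PA": params.k_PA,
                     "k_AP": params.k_AP, "k_PB": params.k_PB}
            courses = pd.DataFrame({n: np.full(times.size, const[n]) for n in PSEUDO_RATE_NAMES},
                                   index=pd.Index(times, name="time_s"))
            prepost = {n: (float(const[n]), float(const[n])) for n in PSEUDO_RATE_NAMES}
        return courses, prepost

    def predict(self, X=None):
        """Predicted four-channel signals at ``X`` times (default: fitted grid)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit the estimator before calling predict")
        if X is None:
            return self.result_.predicted.signals.copy()
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return solve_at_times(self.model_kind, self.params_, self.relax_,
                              self.schedule_, self.input_, t,
                              rtol=self.polish_rtol, atol=self.polish_rtol * 1e-3,
                              pdh_cofactor=self.pdh_cofactor,
                              input_term=self.input_term)

    def score(self, X=None, y=None):
        """Mean per-channel R^2 of the fitted model on the given (or fitted) data."""
        if X is None:
            vals = np.array([v for v in self.r_squared_.values() if np.isfinite(v)])
            return float(vals.mean())
        ts = self._coerce_data(X, y)
        pred = TimeSeries(times=ts.times, signals=self.predict(ts.times))
        vals = np.array([v for v in r_squared(ts, pred).values() if np.isfinite(v)])
        return float(vals.mean())


def fit(data: TimeSeries, model_kind: str = "second_order", bounds: dict | None = None,
        multistart: int = 16, seed: int | None = None,
        schedule: AcquisitionSchedule | None = None, **kwargs) -> FitResult:
    """Functional wrapper: fit ``data`` and return the :class:`FitResult`."""
    est = KineticsFitter(model_kind=model_kind, schedule=schedule, bounds=bounds,
                         n_starts=multistart, random_state=seed, **kwargs)
    est.fit(data)
    return est.result_


def pre_post(result: FitResult) -> dict:
    """Per-reaction (pre, post) pseudo rates: at bolus arrival and at the last
    acquisition time.  For first-order fits pre == post == k."""
    return dict(result.pre_post)


def cohort_ttest(group_a, group_b, welch: bool = False):
    """Two-sample two-tailed Student's t test (pooled variance by default).

    Returns ``(t, p)``.  Raises if either group has fewer than two values or
    if both groups have zero variance (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both groups have zero variance; t statistic undefined")
    res = ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_models(data: TimeSeries, seed: int | None = None,
                   schedule: AcquisitionSchedule | None = None,
                   model_kinds=("second_order", "first_order"),
                   **fitter_kwargs) -> ModelComparison:
    """Fit two model kinds to the same data and tabulate per-channel R^2 and
    cost differences (model_a minus model_b)."""
    fits = []
    for kind in model_kinds:
        est = KineticsFitter(model_kind=kind, schedule=schedule,
                             random_state=seed, **fitter_kwargs)
        est.fit(data)
        fits.append(est.result_)
    fa, fb = fits
    delta_r2 = {ch: fa.r_squared[ch] - fb.r_squared[ch] for ch in CHANNELS}
    return ModelComparison(fit_a=fa, fit_b=fb, delta_r_squared=delta_r2,
                           delta_cost=fa.cost - fb.cost)


def _summary_row(result: FitResult) -> dict:
    row = {}
    for name, (pre, post) in result.pre_post.items():
        row[f"{name}_pre"] = pre
        row[f"{name}_post"] = post
    for f in dataclasses.fields(result.relax):
        row[f.name] = getattr(result.relax, f.name)
    row["cost"] = result.cost
    for ch in CHANNELS:
        row[f"R2_{ch}"] = result.r_squared[ch]
    return row


def fit_cohort(series, model_kind: str = "second_order", seed: int | None = None,
               schedule: AcquisitionSchedule | None = None, **fitter_kwargs) -> CohortSummary:
    """Fit every heart in a cohort and summarize parameters as mean and SEM."""
    fits = []
    base = 0 if seed is None else int(seed)
    for i, ts in enumerate(series):
        est = KineticsFitter(model_kind=model_kind, schedule=schedule,
                             random_state=base + i, **fitter_kwargs)
        est.fit(ts)
        fits.append(est.result_)
    table = pd.DataFrame([_summary_row(f) for f in fits])
    mean = table.mean()
    sem = table.std(ddof=1) / np.sqrt(len(fits)) if len(fits) > 1 else table.iloc[0] * np.nan
    return CohortSummary(fits=fits, params_table=table, mean=mean, sem=sem)
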