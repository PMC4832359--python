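"""Forward simulation and synthetic-cohort generation.

Integrates either kinetic model over an acquisition schedule, samples the four
observable hyperpolarized signals, adds per-channel Gaussian noise and
normalizes to the pyruvate maximum -- the same pre-processing applied to the
experimental peak-area series the package is designed to fit.  The cohort
generator draws per-heart parameters log-normally around a group truth to
emulate between-heart variability in an n-hearts-per-group study.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint

from .model import (
    CHANNELS,
    STATE_NAMES,
    AcquisitionSchedule,
    FirstOrderParams,
    InputParams,
    RelaxationParams,
    SecondOrderParams,
    core_and_args,
    initial_state,
)

__all__ = [
    "TimeSeries",
    "CohortSpec",
    "simulate",
    "solve_at_times",
    "add_noise",
    "normalize",
    "calibrate_input_amplitude",
    "generate_cohort",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BETWEEN_HEART_CV",
]

#: Default per-channel noise SD, as a fraction of the (normalized) pyruvate maximum.
DEFAULT_NOISE_SD = (0.005, 0.005, 0.005, 0.005)

#: Default between-heart coefficient of variation per parameter
#: (sample SD / mean, sized so an n = 5 cohort reproduces the study's SEMs).
DEFAULT_BETWEEN_HEART_CV = {
    "k_PL": 0.60, "k_PA": 0.45, "k_PB": 0.63,
    "k_LP": 0.60, "k_AP": 0.45,
    "T1_pyruvate": 0.13, "T1_lactate": 0.19,
    "T1_alanine": 0.28, "T1_bicarbonate": 0.27,
}


@dataclass
class TimeSeries:
    """Acquisition times plus the four observable hyperpolarized signals.

    ``signals`` is an (n_points, 4) array in channel order
    (pyruvate, lactate, alanine, bicarbonate), arbitrary units.
    """

    times: np.ndarray
    signals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.signals.shape != (self.times.size, len(CHANNELS)):
            raise ValueError(
                f"signals must have shape (n_points, {len(CHANNELS)}); "
                f"got {self.signals.shape} for {self.times.size} times"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return self.signals[:, CHANNELS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.signals, columns=list(CHANNELS))
        df.insert(0, "time_s", self.times)
        return df

    def copy(self, **changes) -> "TimeSeries":
        kwargs = {"times": self.times.copy(), "signals": self.signals.copy(), "label": self.label}
        kwargs.update(changes)
        return TimeSeries(**kwargs)


@dataclass
class CohortSpec:
    """Recipe for a synthetic multi-heart cohort.

    ``between_heart_cv`` may be a single fraction applied to the kinetic rate
    constants, or a dict mapping parameter names (rate constants and/or T1
    fields) to per-parameter CVs; parameters not named are left at truth.
    """

    n_hearts: int = 5
    model_kind: str = "second_order"
    truth: SecondOrderParams | FirstOrderParams = field(default_factory=SecondOrderParams)
    relax: RelaxationParams = field(default_factory=RelaxationParams)
    inp: InputParams = field(default_factory=InputParams)
    between_heart_cv: float | dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_HEART_CV))
    noise_sd: tuple = DEFAULT_NOISE_SD
    seed: int = 0
    label: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_hearts < 1:
            raise ValueError("n_hearts must be >= 1")
        if isinstance(self.between_heart_cv, dict):
            bad = [k for k, v in self.between_heart_cv.items() if v < 0]
        else:
            bad = [] if self.between_heart_cv >= 0 else ["between_heart_cv"]
        if bad:
            raise ValueError(f"between-heart CV must be >= 0 ({bad})")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")


DEFAULT_SOLVER_OPTS = {"rtol": 1e-8, "atol": 1e-10}


def solve_at_times(model_kind, params, relax, sched, inp, times,
                   rtol=1e-8, atol=1e-10, pdh_cofactor="nadm",
                   input_term="literal", full_state=False):
    """Integrate a model (LSODA) and return states at sorted ``times``.

    The state is exactly constant (zero signal, initial cofactor pools) up to
    ``t_arrival``, so integration starts there.  Returns the (n, 4) observable
    signals, or the full (n, 15) state array when ``full_state`` is set.

    Raises
    ------
    RuntimeError
        If the solver fails to converge (with the solver's diagnostics).
    """
    times = np.asarray(times, dtype=float)
    y0 = initial_state(params)
    states = np.tile(y0, (times.size, 1))
    active = times > inp.t_arrival
    if times.size and times[-1] > inp.t_arrival:
        core, args = core_and_args(model_kind, params, relax, sched, inp,
                                   pdh_cofactor, input_term)
        t_solve = np.concatenate(([inp.t_arrival], times[active]))
        with warnings.catch_warnings():
            # failures are surfaced via the info dict below; the optimizer
            # legitimately visits bad parameter regions during multistart
            warnings.simplefilter("ignore", ODEintWarning)
            out, info = odeint(core, y0, t_solve, args=args, tfirst=True,
                               rtol=rtol, atol=atol, full_output=True, mxstep=500)
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"ODE solver failed for model_kind={model_kind!r}: {info['message']}")
        states[active] = out[1:]
    if full_state:
        return states
    return states[:, :4]


def simulate(model_kind: str, params, relax: RelaxationParams,
             sched: AcquisitionSchedule, inp: InputParams,
             solver_opts: dict | None = None,
             pdh_cofactor: str = "nadm", input_term: str = "literal",
             label: str = ""):
    """Integrate a model over the schedule and sample the observables.

    All metabolite pools start at zero (no signal before bolus arrival);
    cofactor pools start at their initial values.

    Returns
    -------
    (TimeSeries, DataFrame)
        The noiseless observable series and the full 15-state trajectory
        indexed by time.

    Raises
    ------
    RuntimeError
        If the ODE solver fails to converge (with the solver's diagnostics).
    """
    opts = dict(DEFAULT_SOLVER_OPTS)
    opts.update(solver_opts or {})
    times = sched.times
    states = solve_at_times(model_kind, params, relax, sched, inp, times,
                            pdh_cofactor=pdh_cofactor, input_term=input_term,
                            full_state=True, **opts)
    trajectory = pd.DataFrame(states, columns=list(STATE_NAMES),
                              index=pd.Index(times, name="time_s"))
    ts = TimeSeries(times=times, signals=states[:, :4].copy(), label=label)
    return ts, trajectory


def add_noise(ts: TimeSeries, noise_sd, seed=None) -> TimeSeries:
    """Add independent additive Gaussian noise per channel.

    ``noise_sd`` gives the four per-channel standard deviations (a scalar is
    broadcast).  ``seed`` may be an int or a ``numpy.random.Generator``;
    a fixed seed reproduces the output exactly.
    """
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(CHANNELS),))
    if np.any(sd < 0):
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = ts.signals + rng.standard_normal(ts.signals.shape) * sd
    return ts.copy(signals=noisy)


def normalize(ts: TimeSeries) -> TimeSeries:
    """Divide all four channels by the pyruvate maximum (idempotent)."""
    m = float(np.max(ts.channel("pyruvate")))
    if m <= 0:
        raise ValueError("pyruvate channel must have a positive maximum to normalize")
    return ts.copy(signals=ts.signals / m)


def calibrate_input_amplitude(model_kind: str, params, relax: RelaxationParams,
                              sched: AcquisitionSchedule, inp: InputParams,
                              target_max: float = 1.0,
                              solver_opts: dict | None = None,
                              pdh_cofactor: str = "nadm",
                              input_term: str = "literal",
                              tol: float = 1e-9, max_iter: int = 12) -> InputParams:
    """Scale ``k_in`` so the noiseless pyruvate maximum equals ``target_max``.

    The pyruvate response is nearly (not exactly, for the second-order model)
    linear in ``k_in``, so a short fixed-point iteration suffices.  With a
    calibrated amplitude the downstream normalization step is the identity and
    generating parameters can be read off in normalized units.
    """
    cur = inp
    for _ in range(max_iter):
        ts, _ = simulate(model_kind, params, relax, sched, cur,
                         solver_opts=solver_opts, pdh_cofactor=pdh_cofactor,
                         input_term=input_term)
        m = float(np.max(ts.channel("pyruvate")))
        if m <= 0:
            raise RuntimeError("pyruvate response is non-positive; cannot calibrate k_in")
        if abs(m - target_max) <= tol * target_max:
            return cur
        cur = replace(cur, k_in=cur.k_in * target_max / m)
    return cur


def _jitter_params(truth, relax, cv, rng):
    """Draw one heart's parameters log-normally around the truth (mean-preserving)."""
    if not isinstance(cv, dict):
        cv = {name: float(cv) for name in
              ("k_PL", "k_LP", "k_PA", "k_AP", "k_PB")}

    def draw(value, c):
        if c <= 0 or value == 0:
            return value
        sigma = np.sqrt(np.log1p(c * c))
        return value * np.exp(sigma * rng.standard_normal() - 0.5 * sigma * sigma)

    p_changes = {f.name: draw(getattr(truth, f.name), cv[f.name])
                 for f in dataclasses.fields(truth) if f.name in cv}
    r_changes = {f.name: draw(getattr(relax, f.name), cv[f.name])
                 for f in dataclasses.fields(relax) if f.name in cv}
    return replace(truth, **p_changes), replace(relax, **r_changes)


def generate_cohort(spec: CohortSpec, sched: AcquisitionSchedule,
                    solver_opts: dict | None = None,
                    pdh_cofactor: str = "nadm", input_term: str = "literal"):
    """Generate a synthetic cohort: per-heart draws, simulate, noise, normalize.

    Returns
    -------
    (list[TimeSeries], dict)
        The normalized noisy series (one per heart) and a truth record with
        the group-level truth and every per-heart parameter draw.
    """
    rng = np.random.default_rng(spec.seed)
    series, per_heart = [], []
    for i in range(spec.n_hearts):
        p_i, r_i = _jitter_params(spec.truth, spec.relax, spec.between_heart_cv, rng)
        ts, _ = simulate(spec.model_kind, p_i, r_i, sched, spec.inp,
                         solver_opts=solver_opts, pdh_cofactor=pdh_cofactor,
                         input_term=input_term, label=f"{spec.label}/heart{i:02d}")
        ts = add_noise(ts, spec.noise_sd, seed=rng)
        ts = normalize(ts)
        series.append(ts)
        per_heart.append({"params": dataclasses.asdict(p_i), "relax": dataclasses.asdict(r_i)})
    truth = {
        "model_kind": spec.model_kind,
        "truth_params": dataclasses.asdict(spec.truth),
        "relax": dataclasses.asdict(spec.relax),
        "input": dataclasses.asdict(spec.inp),
        "between_heart_cv": spec.between_heart_cv,
        "noise_sd": list(np.broadcast_to(np.asarray(spec.noise_sd, float), (len(CHANNELS),))),
        "seed": spec.seed,
        "per_heart": per_heart,
    }
    return series, truth
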