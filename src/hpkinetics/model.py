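"""Kinetic models of hyperpolarized [1-13C]pyruvate metabolism in the perfused heart.

Two model variants describe the conversion of a hyperpolarized pyruvate bolus
into lactate (LDH), alanine (ALT) and bicarbonate (PDH):

* a **first-order** model with time-independent rate constants, the form
  traditionally used for hyperpolarized kinetics; and
* a **second-order** model in which each reaction rate is the product of a
  second-order rate constant and the instantaneous concentration of the
  non-hyperpolarized cofactor that the enzyme consumes
  (``k'_PL(t) = k_PL * NADH_c(t)`` etc.), so that cofactor depletion during
  the bolus produces time-dependent *pseudo* rate constants.

Every hyperpolarized pool (starred) relaxes into an MR-invisible pool of the
same metabolite, so total metabolite mass is conserved; the invisible pools
keep reacting and therefore keep consuming cofactors.  The state vector holds
8 metabolite pools, 6 cofactor pools and one accumulator for the relaxed
fraction of the input bolus (15 states in total).

Signals are in arbitrary units (normalized to the pyruvate maximum downstream);
cofactor pools are phenomenological arbitrary units -- they do not correspond
to free cofactor concentrations because enzyme-cofactor binding is not
modeled.  Second-order constants therefore carry units of
1/(cofactor-unit * s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "STATE_NAMES",
    "CHANNELS",
    "AcquisitionSchedule",
    "RelaxationParams",
    "InputParams",
    "SecondOrderParams",
    "FirstOrderParams",
    "effective_relaxation_rate",
    "input_rate",
    "second_order_rhs",
    "first_order_rhs",
    "make_rhs",
    "initial_state",
    "pseudo_rates",
    "GLUCOSE_ONLY",
    "PYRUVATE_SUPPLEMENTED",
]

#: Order of the 15 integrated states.
STATE_NAMES = (
    "Pstar", "Lstar", "Astar", "Bstar",   # hyperpolarized (MR-visible) pools
    "P", "L", "A", "B",                   # non-polarized (MR-invisible) pools
    "NADc", "NADHc",                      # cytosolic NAD+/NADH (LDH couple)
    "Glu", "aKG",                         # glutamate/alpha-ketoglutarate (ALT couple)
    "NADm", "NADHm",                      # mitochondrial NAD+/NADH (PDH couple)
    "U_relaxed",                          # accumulated relaxed input bolus U(t)
)

#: The four observable channels, in state order Pstar..Bstar.
CHANNELS = ("pyruvate", "lactate", "alanine", "bicarbonate")

#: Names of the five pseudo rate constants.
PSEUDO_RATE_NAMES = ("k_PL", "k_LP", "k_PA", "k_AP", "k_PB")

#: Numerical tolerance for "nonnegative" state components.
EPS_NEG = 1e-9


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Regular small-flip-angle acquisition grid.

    Parameters
    ----------
    repetition_time : float
        Time between successive excitations, seconds.
    flip_angle : float
        Excitation flip angle, degrees; must lie in (0, 90).
    n_points : int
        Number of acquired spectra (>= 2).
    start_time : float
        Time of the first acquisition, seconds.
    """

    repetition_time: float = 2.0
    flip_angle: float = 10.0
    n_points: int = 90
    start_time: float = 0.0

    def __post_init__(self) -> None:
        _require(self.repetition_time > 0, "repetition_time must be > 0")
        _require(0 < self.flip_angle < 90, "flip_angle must lie in (0, 90) degrees")
        _require(self.n_points >= 2, "n_points must be >= 2")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds (uniform grid)."""
        return self.start_time + self.repetition_time * np.arange(self.n_points, dtype=float)

    @property
    def duration(self) -> float:
        return self.repetition_time * (self.n_points - 1)


@dataclass(frozen=True)
class RelaxationParams:
    """Longitudinal relaxation times of the four observed metabolites, seconds."""

    T1_pyruvate: float = 76.7
    T1_lactate: float = 44.3
    T1_alanine: float = 60.0
    T1_bicarbonate: float = 50.5

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")

    def effective_rates(self, sched: AcquisitionSchedule) -> np.ndarray:
        """Effective relaxation rates ``r1 = 1/T1 - ln(cos theta)/TR`` (P, L, A, B order)."""
        return np.array(
            [
                effective_relaxation_rate(t1, sched.flip_angle, sched.repetition_time)
                for t1 in (self.T1_pyruvate, self.T1_lactate, self.T1_alanine, self.T1_bicarbonate)
            ]
        )


@dataclass(frozen=True)
class InputParams:
    """Gamma-variate bolus ``U*(t) = k_in (t - t_arrival)^delta exp(-beta (t - t_arrival))``.

    ``t_arrival`` is when hyperpolarized pyruvate is first detected; ``delta``
    and ``beta`` shape the rise and fall; ``k_in`` is the amplitude in
    signal-units/s.
    """

    k_in: float = 1.0
    t_arrival: float = 10.0
    delta: float = 2.0
    beta: float = 0.07

    def __post_init__(self) -> None:
        _require(self.k_in >= 0, "k_in must be >= 0")
        _require(self.t_arrival >= 0, "t_arrival must be >= 0")
        _require(self.delta >= 0, "delta must be >= 0")
        _require(self.beta > 0, "beta must be > 0")


@dataclass(frozen=True)
class SecondOrderParams:
    """Second-order rate constants and initial cofactor pools.

    Rate constants are per (cofactor-unit * s); pools are phenomenological
    arbitrary units.  With the convention that each *forward* cofactor pool is
    1 at bolus arrival, ``k_PL`` etc. equal the pre-injection pseudo rates
    numerically.  Defaults are the glucose-only heart group.
    """

    k_PL: float = 0.082
    k_PA: float = 0.005
    k_PB: float = 0.075
    NADc0: float = 2.0
    NADHc0: float = 1.0
    Glu0: float = 1.0
    aKG0: float = 2.0
    NADm0: float = 1.0
    NADHm0: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")

    @property
    def initial_pools(self) -> np.ndarray:
        """Initial cofactor pools in state order (NADc, NADHc, Glu, aKG, NADm, NADHm)."""
        return np.array([self.NADc0, self.NADHc0, self.Glu0, self.aKG0, self.NADm0, self.NADHm0])


@dataclass(frozen=True)
class FirstOrderParams:
    """Time-independent first-order rate constants, 1/s.

    Defaults are the glucose-only group (reverse rates follow the same
    2x-forward convention used for the second-order defaults).
    """

    k_PL: float = 0.083
    k_LP: float = 0.166
    k_PA: float = 0.007
    k_AP: float = 0.014
    k_PB: float = 0.016

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")


def effective_relaxation_rate(T1: float, flip_angle: float, repetition_time: float) -> float:
    """Effective decay rate of a hyperpolarized pool under repeated excitation.

    Combines T1 relaxation with the signal consumed by the RF pulses as a
    continuous rate: ``r1 = 1/T1 - ln(cos theta)/T_R``, which is >= 1/T1.

    Raises
    ------
    ValueError
        If ``flip_angle >= 90`` degrees (cos <= 0) or other arguments are out
        of range.
    """
    _require(T1 > 0, "T1 must be > 0")
    _require(repetition_time > 0, "repetition_time must be > 0")
    _require(flip_angle >= 0, "flip_angle must be >= 0")
    if flip_angle >= 90:
        raise ValueError("flip_angle must be < 90 degrees (cos(theta) <= 0)")
    return 1.0 / T1 - math.log(math.cos(math.radians(flip_angle))) / repetition_time


def input_rate(t, p: InputParams):
    """Gamma-variate bolus rate ``U*(t)``, signal-units/s.

    Zero before ``t_arrival``; for ``delta = 0`` the value at ``t_arrival`` is
    ``k_in`` (pure exponential limit).  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    dt = t - p.t_arrival
    with np.errstate(invalid="ignore"):
        val = np.where(dt >= 0, p.k_in * np.where(dt >= 0, dt, 0.0) ** p.delta * np.exp(-p.beta * np.where(dt >= 0, dt, 0.0)), 0.0)
    if val.ndim == 0:
        return float(val)
    return val


# The ODE right-hand sides are written against a packed parameter vector so
# that the same source compiles under numba (used by the solver hot loop) and
# runs as plain Python (the reference semantics).
#
# second-order p: [kPL, kPA, kPB, r1P, r1L, r1A, r1B, kin, ta, delta, beta,
#                  pdh_is_nadm, literal_input]
# first-order  p: [kPL, kLP, kPA, kAP, kPB, r1P, r1L, r1A, r1B, kin, ta,
#                  delta, beta, literal_input]

def _second_core(t, y, p):
    kPL, kPA, kPB = p[0], p[1], p[2]
    r1P, r1L, r1A, r1B = p[3], p[4], p[5], p[6]
    kin, ta, delta, beta = p[7], p[8], p[9], p[10]
    pdh_nadm = p[11] > 0.5
    literal = p[12] > 0.5
    Pstar, Lstar, Astar, Bstar = y[0], y[1], y[2], y[3]
    P, L, A, B = y[4], y[5], y[6], y[7]
    NADc, NADHc, Glu, aKG, NADm, NADHm, U_rel = (
        y[8], y[9], y[10], y[11], y[12], y[13], y[14])
    # cofactors are clipped at 0 only where they multiply a rate constant;
    # raw (possibly marginally negative) states are integrated as-is
    kpl = kPL * (NADHc if NADHc > 0.0 else 0.0)
    klp = kPL * (NADc if NADc > 0.0 else 0.0)
    kpa = kPA * (Glu if Glu > 0.0 else 0.0)
    kap = kPA * (aKG if aKG > 0.0 else 0.0)
    co_pdh = NADm if pdh_nadm else NADHm
    kpb = kPB * (co_pdh if co_pdh > 0.0 else 0.0)

    dt = t - ta
    ustar = kin * dt**delta * math.exp(-beta * dt) if (dt >= 0.0 and kin > 0.0) else 0.0
    u_nonpol = U_rel if literal else beta * ustar

    fPL, fLP = kpl * Pstar, klp * Lstar
    fPA, fAP = kpa * Pstar, kap * Astar
    fPB = kpb * Pstar
    gPL, gLP = kpl * P, klp * L
    gPA, gAP = kpa * P, kap * A
    gPB = kpb * P

    out = np.empty(15)
    out[0] = -fPL + fLP - fPA + fAP - fPB - r1P * Pstar + ustar
    out[1] = fPL - fLP - r1L * Lstar
    out[2] = fPA - fAP - r1A * Astar
    out[3] = fPB - r1B * Bstar
    out[4] = -gPL + gLP - gPA + gAP - gPB + r1P * Pstar + u_nonpol
    out[5] = gPL - gLP + r1L * Lstar
    out[6] = gPA - gAP + r1A * Astar
    out[7] = gPB + r1B * Bstar
    dNADc = (fPL + gPL) - (fLP + gLP)
    dGlu = -(fPA + gPA) + (fAP + gAP)
    dNADm = -(fPB + gPB)
    out[8] = dNADc
    out[9] = -dNADc
    out[10] = dGlu
    out[11] = -dGlu
    out[12] = dNADm
    out[13] = -dNADm
    out[14] = beta * ustar
    return out


def _first_core(t, y, p):
    kPL, kLP, kPA, kAP, kPB = p[0], p[1], p[2], p[3], p[4]
    r1P, r1L, r1A, r1B = p[5], p[6], p[7], p[8]
    kin, ta, delta, beta = p[9], p[10], p[11], p[12]
    literal = p[13] > 0.5
    Pstar, Lstar, Astar, Bstar = y[0], y[1], y[2], y[3]
    P, L, A, B = y[4], y[5], y[6], y[7]
    U_rel = y[14]

    dt = t - ta
    ustar = kin * dt**delta * math.exp(-beta * dt) if (dt >= 0.0 and kin > 0.0) else 0.0
    u_nonpol = U_rel if literal else beta * ustar

    fPL, fLP = kPL * Pstar, kLP * Lstar
    fPA, fAP = kPA * Pstar, kAP * Astar
    fPB = kPB * Pstar
    gPL, gLP = kPL * P, kLP * L
    gPA, gAP = kPA * P, kAP * A
    gPB = kPB * P

    out = np.zeros(15)
    out[0] = -fPL + fLP - fPA + fAP - fPB - r1P * Pstar + ustar
    out[1] = fPL - fLP - r1L * Lstar
    out[2] = fPA - fAP - r1A * Astar
    out[3] = fPB - r1B * Bstar
    out[4] = -gPL + gLP - gPA + gAP - gPB + r1P * Pstar + u_nonpol
    out[5] = gPL - gLP + r1L * Lstar
    out[6] = gPA - gAP + r1A * Astar
    out[7] = gPB + r1B * Bstar
    out[14] = beta * ustar
    return out


try:  # compiled hot path for the solver; the Python definitions stay canonical
    from numba import njit as _njit

    _second_core_fast = _njit(cache=False)(_second_core)
    _first_core_fast = _njit(cache=False)(_first_core)
except ImportError:  # pragma: no cover - numba is a standard install here
    _second_core_fast = _second_core
    _first_core_fast = _first_core


def _pack_p(model_kind: str, params, relax: "RelaxationParams",
            sched: "AcquisitionSchedule", inp: "InputParams",
            pdh_cofactor: str = "nadm", input_term: str = "literal") -> np.ndarray:
    r1 = relax.effective_rates(sched)
    literal = 1.0 if _is_literal(input_term) else 0.0
    if model_kind == "second_order":
        nadm = 1.0 if _pdh_is_nadm(pdh_cofactor) else 0.0
        return np.array([params.k_PL, params.k_PA, params.k_PB, *r1,
                         inp.k_in, inp.t_arrival, inp.delta, inp.beta,
                         nadm, literal])
    if model_kind == "first_order":
        _pdh_is_nadm(pdh_cofactor)  # validate even though unused
        return np.array([params.k_PL, params.k_LP, params.k_PA, params.k_AP,
                         params.k_PB, *r1, inp.k_in, inp.t_arrival, inp.delta,
                         inp.beta, literal])
    raise ValueError("model_kind must be 'second_order' or 'first_order'")


def core_and_args(model_kind: str, params, relax, sched, inp,
                  pdh_cofactor: str = "nadm", input_term: str = "literal",
                  fast: bool = True):
    """The ``(f(t, y, p), (p,))`` pair the ODE integrators consume."""
    p = _pack_p(model_kind, params, relax, sched, inp, pdh_cofactor, input_term)
    if model_kind == "second_order":
        core = _second_core_fast if fast else _second_core
    else:
        core = _first_core_fast if fast else _first_core
    return core, (p,)


def second_order_rhs(t, state, k: SecondOrderParams, relax: RelaxationParams,
                     sched: AcquisitionSchedule, inp: InputParams,
                     pdh_cofactor: str = "nadm", input_term: str = "literal"):
    """Time derivative of the 15-state vector under the second-order model.

    The pseudo rates are ``k'_PL = k_PL*NADH_c``, ``k'_LP = k_PL*NAD_c``,
    ``k'_PA = k_PA*Glu``, ``k'_AP = k_PA*aKG`` and (by default)
    ``k'_PB = k_PB*NAD_m``; each cofactor pair sum has exactly zero
    derivative.  ``pdh_cofactor="nadhm"`` couples PDH to NADH_m instead.
    """
    state = np.asarray(state, dtype=float)
    _require(np.all(np.isfinite(state)), "state components must be finite")
    p = _pack_p("second_order", k, relax, sched, inp, pdh_cofactor, input_term)
    return _second_core(float(t), state, p)


def first_order_rhs(t, state, k: FirstOrderParams, relax: RelaxationParams,
                    sched: AcquisitionSchedule, inp: InputParams,
                    input_term: str = "literal"):
    """Time derivative under the first-order model (cofactor pools frozen)."""
    state = np.asarray(state, dtype=float)
    _require(np.all(np.isfinite(state)), "state components must be finite")
    p = _pack_p("first_order", k, relax, sched, inp, input_term=input_term)
    return _first_core(float(t), state, p)


def _pdh_is_nadm(pdh_cofactor: str) -> bool:
    if pdh_cofactor not in ("nadm", "nadhm"):
        raise ValueError("pdh_cofactor must be 'nadm' or 'nadhm'")
    return pdh_cofactor == "nadm"


def _is_literal(input_term: str) -> bool:
    if input_term not in ("literal", "conservative"):
        raise ValueError("input_term must be 'literal' or 'conservative'")
    return input_term == "literal"


def make_rhs(model_kind: str, params, relax: RelaxationParams,
             sched: AcquisitionSchedule, inp: InputParams,
             pdh_cofactor: str = "nadm", input_term: str = "literal"):
    """Build an ``f(t, y)`` closure for the ODE solver (constants pre-bound)."""
    core, args = core_and_args(model_kind, params, relax, sched, inp,
                               pdh_cofactor, input_term)
    p = args[0]

    def rhs(t, y):
        return core(t, y, p)

    return rhs


def initial_state(params) -> np.ndarray:
    """Initial 15-state vector: zero signal everywhere, cofactors at their pools."""
    y0 = np.zeros(len(STATE_NAMES))
    if isinstance(params, SecondOrderParams):
        y0[8:14] = params.initial_pools
    return y0


def pseudo_rates(trajectory: pd.DataFrame, k: SecondOrderParams,
                 pdh_cofactor: str = "nadm") -> pd.DataFrame:
    """Pseudo rate constant time courses from a second-order trajectory.

    Parameters
    ----------
    trajectory : DataFrame
        Time-indexed states with (at least) the cofactor columns
        NADc, NADHc, Glu, aKG, NADm, NADHm.
    k : SecondOrderParams
        The second-order rate constants.

    Returns
    -------
    DataFrame with columns ``k_PL, k_LP, k_PA, k_AP, k_PB`` (units 1/s),
    indexed like ``trajectory``.  Cofactors are clipped at zero, matching the
    clipping applied inside the right-hand side.
    """
    co = trajectory[["NADc", "NADHc", "Glu", "aKG", "NADm", "NADHm"]].clip(lower=0.0)
    pdh = co["NADm"] if _pdh_is_nadm(pdh_cofactor) else co["NADHm"]
    return pd.DataFrame(
        {
            "k_PL": k.k_PL * co["NADHc"],
            "k_LP": k.k_PL * co["NADc"],
            "k_PA": k.k_PA * co["Glu"],
            "k_AP": k.k_PA * co["aKG"],
            "k_PB": k.k_PB * pdh,
        },
        index=trajectory.index,
    )


# Study-group presets (pre-injection pseudo rates with unit forward pools; T1s
# from the second-order fits; first-order constants from the same table).
GLUCOSE_ONLY = {
    "second_order": SecondOrderParams(k_PL=0.082, k_PA=0.005, k_PB=0.075),
    "first_order": FirstOrderParams(k_PL=0.083, k_LP=0.166, k_PA=0.007, k_AP=0.014, k_PB=0.016),
    "relaxation": RelaxationParams(T1_pyruvate=76.7, T1_lactate=44.3,
                                   T1_alanine=60.0, T1_bicarbonate=50.5),
}

PYRUVATE_SUPPLEMENTED = {
    "second_order": SecondOrderParams(k_PL=0.034, k_PA=0.0029, k_PB=0.0059),
    "first_order": FirstOrderParams(k_PL=0.041, k_LP=0.082, k_PA=0.003, k_AP=0.006, k_PB=0.013),
    "relaxation": RelaxationParams(T1_pyruvate=76.0, T1_lactate=40.2,
                                   T1_alanine=68.0, T1_bicarbonate=73.4),
}

GROUP_PRESETS = {"glucose": GLUCOSE_ONLY, "pyruvate": PYRUVATE_SUPPLEMENTED}
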