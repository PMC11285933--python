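"""Lumped-parameter (0-D) cardiovascular models used as synthetic-data generators.

Two closed-loop electrical-analogue models of the left heart and systemic
circulation:

* ``one_chamber`` — an actively contracting left ventricle (time-varying
  elastance), aortic and mitral valves (ideal diodes with Ohmic forward
  resistance), and a two-compartment systemic circulation (arterial and
  venous compliances joined by the systemic resistance). 9 free parameters.

* ``two_chamber`` — ventricle plus left atrium, an aortic-sinus and a
  systemic-artery compartment each with compliance/resistance/inertance,
  arteriolar and capillary series resistances, and a venous R–C return.
  20 free parameters.

Both models are integrated over 16 cardiac cycles (cycle length ``tau`` = 1 s);
the last cycle, sampled at 200 points, is the steady-state waveform set from
which continuous and discrete measurement vectors are built.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ONE_CHAMBER_PARAMS",
    "TWO_CHAMBER_PARAMS",
    "ParameterVector",
    "ModelConstants",
    "SolverSettings",
    "WaveformSet",
    "DiscreteMeasurements",
    "InvalidParameterError",
    "elastance",
    "valve_flow",
    "rhs_one_chamber",
    "rhs_two_chamber",
    "nominal_parameters",
    "default_bounds",
    "simulate",
    "discrete_measurements",
    "load_model_config",
]


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its admissible range."""


# name -> (nominal value, unit, description)
ONE_CHAMBER_PARAMS: dict[str, tuple[float, str, str]] = {
    "E_max": (1.5, "mmHg/mL", "maximal ventricular contractility"),
    "E_min": (0.03, "mmHg/mL", "minimal ventricular contractility"),
    "tau_es": (0.3, "s", "end systolic time"),
    "tau_ep": (0.45, "s", "end pulse time"),
    "Z_ao": (0.033, "mmHg.s/mL", "aortic valve resistance"),
    "R_mv": (0.006, "mmHg.s/mL", "mitral valve resistance"),
    "R_s": (1.11, "mmHg.s/mL", "systemic resistance"),
    "C_sa": (1.13, "mL/mmHg", "systemic (arterial) compliance"),
    "C_sv": (11.0, "mL/mmHg", "venous compliance"),
}

TWO_CHAMBER_PARAMS: dict[str, tuple[float, str, str]] = {
    "E_min_lv": (0.1, "mmHg/mL", "minimal ventricular contractility"),
    "E_max_lv": (2.5, "mmHg/mL", "maximal ventricular contractility"),
    "tau_es_lv": (0.3, "s", "ventricular contraction time"),
    "tau_ep_lv": (0.45, "s", "ventricular relaxation time"),
    "E_min_la": (0.15, "mmHg/mL", "minimal atrial contractility"),
    "E_max_la": (0.25, "mmHg/mL", "maximal atrial contractility"),
    "tau_es_la": (0.045, "s", "atrial contraction time"),
    "tau_ep_la": (0.09, "s", "atrial relaxation time"),
    "Z_ao": (0.033, "mmHg.s/mL", "aortic valve resistance"),
    "R_mv": (0.06, "mmHg.s/mL", "mitral valve resistance"),
    "C_sas": (0.08, "mL/mmHg", "aortic sinus compliance"),
    "R_sas": (0.06, "mmHg.s/mL", "aortic sinus resistance"),
    "L_sas": (6.2e-5, "mmHg.s^2/mL", "aortic sinus inertance"),
    "C_sat": (1.6, "mL/mmHg", "arterial compliance"),
    "R_sat": (0.05, "mmHg.s/mL", "arterial resistance"),
    "L_sat": (0.0017, "mmHg.s^2/mL", "arterial inertance"),
    "R_sar": (0.5, "mmHg.s/mL", "arteriolar resistance"),
    "R_scp": (0.52, "mmHg.s/mL", "capillary resistance"),
    "R_svn": (0.075, "mmHg.s/mL", "venous resistance"),
    "C_svn": (20.5, "mL/mmHg", "venous compliance"),
}

_MODEL_TABLES = {"one_chamber": ONE_CHAMBER_PARAMS, "two_chamber": TWO_CHAMBER_PARAMS}

# Parameters that must be strictly positive (all of them, for both models).
_TIMING_PAIRS = {
    "one_chamber": [("tau_es", "tau_ep")],
    "two_chamber": [("tau_es_lv", "tau_ep_lv"), ("tau_es_la", "tau_ep_la")],
}


@dataclass(frozen=True)
class ParameterVector:
    """Ordered named parameters of one model.

    ``values`` follows the declaration order of :data:`ONE_CHAMBER_PARAMS` /
    :data:`TWO_CHAMBER_PARAMS` (the column order used throughout the
    pipeline and the report tables).
    """

    model_id: str
    values: np.ndarray

    def __post_init__(self):
        if self.model_id not in _MODEL_TABLES:
            raise InvalidParameterError(f"unknown model_id {self.model_id!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        names = self.names
        if vals.shape != (len(names),):
            raise InvalidParameterError(
                f"{self.model_id} expects {len(names)} parameters, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise InvalidParameterError("all parameters must be finite and > 0")
        d = dict(zip(names, vals))
        for es, ep in _TIMING_PAIRS[self.model_id]:
            if not d[es] < d[ep]:
                raise InvalidParameterError(f"require {es} < {ep}")

    @property
    def names(self) -> list[str]:
        return list(_MODEL_TABLES[self.model_id])

    @property
    def units(self) -> list[str]:
        return [u for _, u, _ in _MODEL_TABLES[self.model_id].values()]

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def asdict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def with_values(self, **updates: float) -> "ParameterVector":
        d = self.asdict()
        d.update(updates)
        return ParameterVector(self.model_id, np.array([d[n] for n in self.names]))


def nominal_parameters(model_id: str) -> ParameterVector:
    """Nominal operating point of a model (the study's reference values)."""
    table = _MODEL_TABLES[model_id]
    return ParameterVector(model_id, np.array([v for v, _, _ in table.values()]))


def default_bounds(model_id: str, lo: float = 0.5, hi: float = 1.5) -> np.ndarray:
    """Per-parameter sampling bounds, (n, 2), as multiples of nominal.

    The default 0.5–1.5x multiplicative window keeps every parameter
    positive and is symmetric about the nominal point.
    """
    nom = nominal_parameters(model_id).values
    return np.column_stack([lo * nom, hi * nom])


@dataclass(frozen=True)
class ModelConstants:
    """Fixed (non-sampled) model constants.

    tau: cardiac cycle length [s]; e_shift: atrial activation shift [s]
    (0 for the one-chamber model, 0.92 s for the two-chamber model);
    v0: unstressed chamber volume [mL]; n_cycles total integrated,
    n_transient discarded before the saved cycle.
    """

    tau: float = 1.0
    e_shift: float = 0.0
    v0: float = 0.0
    n_cycles: int = 16
    n_transient: int = 15
    initial_state: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError("tau must be > 0")
        if not 0 <= self.e_shift < self.tau:
            raise InvalidParameterError("require 0 <= e_shift < tau")
        if self.v0 < 0:
            raise InvalidParameterError("v0 must be >= 0")
        if not 0 <= self.n_transient < self.n_cycles:
            raise InvalidParameterError("require 0 <= n_transient < n_cycles")


def default_constants(model_id: str) -> ModelConstants:
    return ModelConstants(e_shift=0.92 if model_id == "two_chamber" else 0.0)


# Default initial states: volumes in mL, pressures in mmHg, flows in mL/s.
# Total stressed volume is conserved by the dynamics, so these fix the
# operating point of the closed loop.
DEFAULT_STATE = {
    "one_chamber": (500.0, 70.0, 7.0),  # V_lv, P_sa, P_sv
    # V_lv, V_la, P_sas, Q_sas, P_sat, Q_sat, P_svn
    "two_chamber": (500.0, 20.0, 70.0, 0.0, 70.0, 0.0, 7.0),
}

STATE_NAMES = {
    "one_chamber": ("V_lv", "P_sa", "P_sv"),
    "two_chamber": ("V_lv", "V_la", "P_sas", "Q_sas", "P_sat", "Q_sat", "P_svn"),
}


@dataclass(frozen=True)
class SolverSettings:
    """Integrator controls: adaptive explicit Runge-Kutta, tolerances 1e-8."""

    rtol: float = 1e-8
    atol: float = 1e-8
    points_per_cycle: int = 200

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise InvalidParameterError("tolerances must be > 0")
        if self.points_per_cycle < 2:
            raise InvalidParameterError("need at least 2 saved points per cycle")


@dataclass(frozen=True)
class WaveformSet:
    """One steady-state cardiac cycle of the three measured channels.

    Channels: left-ventricular pressure [mmHg], arterial pressure [mmHg]
    (systemic arterial pressure P_sa for the one-chamber model, P_sat for the
    two-chamber model), left-ventricular volume [mL], on a uniform time grid
    spanning the saved cycle.
    """

    t: np.ndarray
    p_lv: np.ndarray
    p_art: np.ndarray
    v_lv: np.ndarray
    model_id: str = "one_chamber"

    CHANNELS = ("P_lv", "P_art", "V_lv")

    def __post_init__(self):
        for arr in (self.t, self.p_lv, self.p_art, self.v_lv):
            if not np.all(np.isfinite(arr)):
                raise ValueError("waveforms contain non-finite values")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def as_array(self) -> np.ndarray:
        """Channels stacked as (3, T)."""
        return np.stack([self.p_lv, self.p_art, self.v_lv])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"t": self.t, "P_lv": self.p_lv, "P_art": self.p_art, "V_lv": self.v_lv}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class DiscreteMeasurements:
    """Three scalar summaries: mean(P_lv), max(P_art), max(V_lv)."""

    mean_p_lv: float
    max_p_art: float
    max_v_lv: float

    def __post_init__(self):
        vals = (self.mean_p_lv, self.max_p_art, self.max_v_lv)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite discrete measurement")
        if self.max_v_lv < 0:
            raise ValueError("max V_lv must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_p_lv, self.max_p_art, self.max_v_lv])


# ---------------------------------------------------------------------------
# Elementary constitutive relations
# ---------------------------------------------------------------------------

def elastance(t, e_max, e_min, tau_es, tau_ep, tau=1.0, shift=0.0):
    """Time-varying chamber elastance E(t) [mmHg/mL].

    Double-cosine activation: a cosine rise on [0, tau_es), a cosine fall on
    [tau_es, tau_ep), baseline e = 0 on [tau_ep, tau). Time is taken modulo
    ``tau`` after subtracting ``shift`` (the atrial activation offset), so
    the only discontinuity is at the cycle wrap. Vectorised over ``t``.
    """
    if tau <= 0:
        raise InvalidParameterError("tau must be > 0")
    if tau_es <= 0 or not tau_es < tau_ep or tau_ep > tau:
        raise InvalidParameterError("require 0 < tau_es < tau_ep <= tau")
    tt = np.mod(np.asarray(t, dtype=float) - shift, tau)
    e = np.zeros_like(tt)
    rise = tt < tau_es
    fall = (~rise) & (tt < tau_ep)
    e[rise] = 0.5 * (1.0 - np.cos(np.pi * tt[rise] / tau_es))
    e[fall] = 0.5 * (1.0 + np.cos(np.pi * (tt[fall] - tau_es) / (tau_ep - tau_es)))
    out = (e_max - e_min) * e + e_min
    return float(out) if out.ndim == 0 else out


def valve_flow(p_up, p_down, r_val):
    """Ideal-diode valve: Ohmic forward flow, zero reverse flow [mL/s]."""
    if r_val <= 0:
        raise InvalidParameterError("valve resistance must be > 0")
    dp = np.asarray(p_up, dtype=float) - p_down
    q = np.where(dp > 0, dp / r_val, 0.0)
    return float(q) if q.ndim == 0 else q


# ---------------------------------------------------------------------------
# Right-hand sides (reference/plain-numpy path; the batched numba kernels in
# _kernels.py implement the same equations)
# ---------------------------------------------------------------------------

def rhs_one_chamber(t, state, params: ParameterVector | np.ndarray,
                    constants: ModelConstants | None = None):
    """d/dt of (V_lv, P_sa, P_sv) for the one-chamber model."""
    c = constants or default_constants("one_chamber")
    p = params.values if isinstance(params, ParameterVector) else np.asarray(params)
    e_max, e_min, tau_es, tau_ep, z_ao, r_mv, r_s, c_sa, c_sv = p
    v_lv, p_sa, p_sv = state
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(f"non-finite state {state} at t={t}")
    e = elastance(t, e_max, e_min, tau_es, tau_ep, c.tau, 0.0)
    p_lv = e * (v_lv - c.v0)
    q_mv = valve_flow(p_sv, p_lv, r_mv)
    q_av = valve_flow(p_lv, p_sa, z_ao)
    q_s = (p_sa - p_sv) / r_s
    return np.array([q_mv - q_av, (q_av - q_s) / c_sa, (q_s - q_mv) / c_sv])


def rhs_two_chamber(t, state, params: ParameterVector | np.ndarray,
                    constants: ModelConstants | None = None):
    """d/dt of (V_lv, V_la, P_sas, Q_sas, P_sat, Q_sat, P_svn).

    The arteriolar and capillary resistances act purely in series with the
    arterial branch resistance (R_sat + R_sar + R_scp); the venous
    compartment is an R-C return into the atrium.
    """
    c = constants or default_constants("two_chamber")
    p = params.values if isinstance(params, ParameterVector) else np.asarray(params)
    (e_min_lv, e_max_lv, tes_lv, tep_lv, e_min_la, e_max_la, tes_la, tep_la,
     z_ao, r_mv, c_sas, r_sas, l_sas, c_sat, r_sat, l_sat, r_sar, r_scp,
     r_svn, c_svn) = p
    v_lv, v_la, p_sas, q_sas, p_sat, q_sat, p_svn = state
    if not np.all(np.isfinite(state)):
        raise FloatingPointError(f"non-finite state {state} at t={t}")
    p_lv = elastance(t, e_max_lv, e_min_lv, tes_lv, tep_lv, c.tau, 0.0) * (v_lv - c.v0)
    p_la = elastance(t, e_max_la, e_min_la, tes_la, tep_la, c.tau, c.e_shift) * (v_la - c.v0)
    q_mv = valve_flow(p_la, p_lv, r_mv)
    q_av = valve_flow(p_lv, p_sas, z_ao)
    q_svn = (p_svn - p_la) / r_svn
    return np.array([
        q_mv - q_av,                                   # dV_lv
        q_svn - q_mv,                                  # dV_la
        (q_av - q_sas) / c_sas,                        # dP_sas
        (p_sas - p_sat - r_sas * q_sas) / l_sas,       # dQ_sas
        (q_sas - q_sat) / c_sat,                       # dP_sat
        (p_sat - p_svn - (r_sat + r_sar + r_scp) * q_sat) / l_sat,  # dQ_sat
        (q_sat - q_svn) / c_svn,                       # dP_svn
    ])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(model_id: str,
             params: ParameterVector | np.ndarray | None = None,
             constants: ModelConstants | None = None,
             solver: SolverSettings | None = None) -> WaveformSet:
    """Integrate a model to its saved steady-state cycle.

    Runs the closed loop from t = 0 through ``n_cycles`` cardiac cycles and
    returns the three measured channels sampled at ``points_per_cycle``
    points on the final cycle [n_transient*tau, n_cycles*tau).
    """
    from . import _kernels

    if params is None:
        params = nominal_parameters(model_id)
    if isinstance(params, ParameterVector):
        if params.model_id != model_id:
            raise InvalidParameterError("parameter vector is for a different model")
        pvals = params.values
    else:
        pvals = np.asarray(params, dtype=float)
        ParameterVector(model_id, pvals)  # validate
    c = constants or default_constants(model_id)
    s = solver or SolverSettings()
    wave, ok = _kernels.evaluate_batch(model_id, pvals[None, :], c, s)
    if not ok[0]:
        raise RuntimeError(f"integration failed for {model_id} at {pvals}")
    t0 = c.n_transient * c.tau
    t = t0 + c.tau * np.arange(s.points_per_cycle) / s.points_per_cycle
    return WaveformSet(t, wave[0, 0], wave[0, 1], wave[0, 2], model_id)


def discrete_measurements(w: WaveformSet) -> DiscreteMeasurements:
    """Reduce a waveform set to (mean P_lv, max P_art, max V_lv)."""
    if w.t.size == 0:
        raise ValueError("empty waveform")
    return DiscreteMeasurements(
        float(np.mean(w.p_lv)), float(np.max(w.p_art)), float(np.max(w.v_lv))
    )


def load_model_config(path) -> tuple[ParameterVector, ModelConstants, np.ndarray]:
    """Load (parameters, constants, bounds) from a YAML/JSON config file.

    Schema: ``model_id``, optional ``parameters`` {name: value}, optional
    ``constants`` {tau, e_shift, v0, n_cycles, n_transient}, optional
    ``bounds`` {name: [lo, hi]} (missing names fall back to 0.5-1.5x).
    """
    text = open(path).read()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    model_id = cfg["model_id"]
    pv = nominal_parameters(model_id)
    if cfg.get("parameters"):
        pv = pv.with_values(**{k: float(v) for k, v in cfg["parameters"].items()})
    const = default_constants(model_id)
    if cfg.get("constants"):
        const = replace(const, **cfg["constants"])
    bounds = default_bounds(model_id)
    for name, (lo, hi) in (cfg.get("bounds") or {}).items():
        bounds[pv.names.index(name)] = (lo, hi)
    return pv, const, bounds
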