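"""Illumination-controlled Oregonator oscillator networks.

The two-variable Oregonator is the canonical reduction of
Belousov-Zhabotinsky (BZ) kinetics: a fast autocatalytic activator ``u``
(the HBrO2 analogue) and a slow inhibitor ``v`` (the oxidised catalyst).
With a ruthenium catalyst the reaction is photosensitive, and an
illumination term ``phi(t)`` proportional to light intensity suppresses the
oscillation while it is large.  Each oscillator j in a network of n coupled
units evolves as

    eps * du_j/dt = u_j - u_j^2 - (f*v_j + phi_j(t)) * (u_j - q)/(u_j + q)
                    - eps * [(alpha + deg_j*beta) * u_j - beta * sum_{i~j} u_i]
    dv_j/dt       = u_j - v_j

where ``alpha`` is an extra first-order activator decay, ``beta`` the
activator-exchange coupling rate, and ``deg_j`` the number of coupled
neighbours.  For the all-to-all three-oscillator network this is exactly the
form -(alpha + 3*beta)*u_j + beta*(u_1+u_2+u_3) after the self terms cancel.

Illumination follows a smooth switch-off profile

    phi_j(t) = amp * (offset + tanh(-steepness * (t - t_ilum_j)))

so phi ~ amp*(offset+1) ~ 0.2 before the per-oscillator switch-off time
``t_ilum_j`` (stable steady state) and phi -> amp*(offset-1) = 1e-4 after it
(free-running oscillation).  Trajectories are integrated with classic
fixed-step RK4 and the readout is the number of activator maxima in the
observation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from ._kernels import rk4_count_batch, rk4_count_batch3, rk4_trajectory

__all__ = [
    "OregonatorParams",
    "IlluminationSchedule",
    "NetworkSpec",
    "IntegratorConfig",
    "PeakConfig",
    "Trajectory",
    "SimulationError",
    "NoOscillationError",
    "illumination",
    "rhs",
    "steady_state",
    "integrate",
    "count_maxima",
    "peak_times",
    "measure_period",
]


class SimulationError(RuntimeError):
    """Numerical instability or domain violation during integration."""


class NoOscillationError(RuntimeError):
    """Raised when a period is requested but too few maxima are present."""


@dataclass(frozen=True)
class OregonatorParams:
    """Kinetic constants of the two-variable Oregonator (all dimensionless)."""

    epsilon: float = 0.2     # time-scale ratio of u vs v
    q_const: float = 0.0002  # scaling constant of the u-nullcline
    f_stoich: float = 1.1    # stoichiometric coefficient

    def __post_init__(self) -> None:
        if not (self.epsilon > 0 and self.q_const > 0 and self.f_stoich > 0):
            raise ValueError("epsilon, q_const and f_stoich must be positive")


@dataclass
class IlluminationSchedule:
    """Per-oscillator illumination switch-off profile.

    ``phi_const``, when set, holds phi at that constant value for every
    oscillator (used e.g. to measure the free-running period at phi=1e-4);
    the tanh profile and ``t_ilum`` are then ignored.
    """

    t_ilum: np.ndarray            # switch-off time per oscillator, >= 0
    amp: float = 0.1
    offset: float = 1.001
    steepness: float = 10.0
    phi_const: float | None = None

    def __post_init__(self) -> None:
        self.t_ilum = np.atleast_1d(np.asarray(self.t_ilum, dtype=float))
        if self.t_ilum.ndim != 1:
            raise ValueError("t_ilum must be one-dimensional")
        if np.any(self.t_ilum < 0):
            raise ValueError("every t_ilum must be >= 0")
        if not (self.amp > 0 and self.steepness > 0):
            raise ValueError("amp and steepness must be positive")
        if not self.offset > 1:
            raise ValueError("offset must exceed 1 so phi stays positive")
        if self.phi_const is not None and not self.phi_const > 0:
            raise ValueError("phi_const must be positive")

    @property
    def n_osc(self) -> int:
        return self.t_ilum.size

    def phi_at(self, t, osc_index: int):
        """phi for one oscillator at time(s) t."""
        return illumination(t, float(self.t_ilum[osc_index]), self)

    def phi0(self) -> np.ndarray:
        """Initial illumination phi_j(0) for every oscillator."""
        if self.phi_const is not None:
            return np.full(self.n_osc, self.phi_const)
        return np.array([self.phi_at(0.0, j) for j in range(self.n_osc)])


def illumination(t, t_ilum: float, sched: IlluminationSchedule):
    """Smooth illumination switch-off: amp*(offset + tanh(-steepness*(t - t_ilum))).

    Monotonically non-increasing in t; tends to amp*(offset-1) (0.0001 with
    the defaults) long after the switch-off time.
    """
    if sched.phi_const is not None:
        return np.broadcast_to(np.float64(sched.phi_const), np.shape(t))[()]
    t = np.asarray(t, dtype=float)
    return sched.amp * (sched.offset + np.tanh(-sched.steepness * (t - t_ilum)))


@dataclass
class NetworkSpec:
    """Network topology and the two reaction rates shared by all links.

    ``coupling`` is a symmetric boolean adjacency matrix whose diagonal is
    ignored; ``None`` means all-to-all, the topology of the three-oscillator
    classifier.
    """

    n_osc: int
    alpha: float = 0.0   # activator decay rate, 1/time
    beta: float = 0.0    # activator-exchange coupling rate, 1/time
    coupling: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_osc < 1:
            raise ValueError("n_osc must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.coupling is None:
            self.coupling = ~np.eye(self.n_osc, dtype=bool)
        else:
            self.coupling = np.asarray(self.coupling, dtype=bool)
            if self.coupling.shape != (self.n_osc, self.n_osc):
                raise ValueError("coupling must be (n_osc, n_osc)")
            if not np.array_equal(self.coupling, self.coupling.T):
                raise ValueError("coupling must be symmetric")

    @property
    def adjacency(self) -> np.ndarray:
        """Adjacency with the diagonal cleared."""
        adj = self.coupling.copy()
        np.fill_diagonal(adj, False)
        return adj

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(float)


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step RK4 settings: step h, storage stride and window length."""

    t_max: float
    h: float = 1e-4
    store_stride: int = 100

    def __post_init__(self) -> None:
        if not (self.h > 0 and self.t_max > 0):
            raise ValueError("h and t_max must be positive")
        if self.store_stride < 1:
            raise ValueError("store_stride must be >= 1")
        steps = self.t_max / self.h
        if abs(steps - round(steps)) > 1.0:
            raise ValueError("t_max/h must round to an integer step count")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.h))


@dataclass(frozen=True)
class PeakConfig:
    """Detector for counted activator maxima (absolute height threshold)."""

    height_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.height_threshold < 1:
            raise ValueError("height_threshold must lie in (0, 1)")


@dataclass
class Trajectory:
    """Stored samples of one network integration.

    times has length n_stored; u and v are (n_stored, n_osc).
    """

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def n_osc(self) -> int:
        return self.u.shape[1]

    def to_frame(self):
        import pandas as pd

        cols = {"time": self.times}
        for j in range(self.n_osc):
            cols[f"u{j + 1}"] = self.u[:, j]
        for j in range(self.n_osc):
            cols[f"v{j + 1}"] = self.v[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path, metadata: dict | None = None) -> None:
        """Write a headered CSV; optional JSON sidecar with run parameters."""
        import json
        from pathlib import Path

        self.to_frame().to_csv(path, index=False, float_format="%.17g")
        if metadata is not None:
            side = Path(path).with_suffix(".json")
            side.write_text(json.dumps(metadata, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path)
        n = (len(df.columns) - 1) // 2
        u = df[[f"u{j + 1}" for j in range(n)]].to_numpy()
        v = df[[f"v{j + 1}" for j in range(n)]].to_numpy()
        return cls(times=df["time"].to_numpy(), u=u, v=v)


def rhs(u, v, t, params: OregonatorParams, net: NetworkSpec,
        sched: IlluminationSchedule):
    """Network right-hand side (du/dt, dv/dt) at state (u, v) and time t.

    Reference NumPy implementation used for analysis and as the oracle for
    the compiled integrator; raises SimulationError if any activator is at or
    below -q_const, where the Oregonator nonlinearity leaves its domain.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != (net.n_osc,) or v.shape != (net.n_osc,):
        raise ValueError("u and v must have length n_osc")
    if np.any(u <= -params.q_const):
        raise SimulationError("activator at or below -q_const")
    if sched.phi_const is not None:
        phi = np.full(net.n_osc, sched.phi_const)
    else:
        phi = sched.amp * (sched.offset
                           + np.tanh(-sched.steepness * (t - sched.t_ilum)))
    q = params.q_const
    adj = net.adjacency
    du = (u - u * u - (params.f_stoich * v + phi) * (u - q) / (u + q)) \
        / params.epsilon \
        - (net.alpha + net.degrees * net.beta) * u + net.beta * (adj @ u)
    dv = u - v
    return du, dv


def steady_state(phi: float, params: OregonatorParams,
                 alpha: float = 0.0) -> tuple[float, float]:
    """Fixed point (u*, v*) of a single illuminated oscillator, with v* = u*.

    Solves u - u^2 - (f*u + phi)*(u-q)/(u+q) = eps*alpha*u by bracketed
    root-finding on u in (0, 1).  Under strong illumination (phi ~ 0.2) the
    root sits just above q, the stable rest state the networks start from.
    """
    if not phi > 0:
        raise ValueError("phi must be positive")
    q = params.q_const
    f = params.f_stoich

    def g(u: float) -> float:
        return (u - u * u - (f * u + phi) * (u - q) / (u + q)
                - params.epsilon * alpha * u)

    lo, hi = 1e-12, 1.0
    if g(lo) <= 0 or g(hi) >= 0:
        raise SimulationError("no steady state bracketed in (0, 1)")
    u_star = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return float(u_star), float(u_star)


def _initial_state(params: OregonatorParams, net: NetworkSpec,
                   sched: IlluminationSchedule) -> tuple[np.ndarray, np.ndarray]:
    """Per-oscillator illuminated steady state at phi_j(0) (coupling ignored:
    at a uniform state the coupling terms cancel exactly)."""
    phi0 = sched.phi0()
    u0 = np.empty(net.n_osc)
    cache: dict[float, float] = {}
    for j, p in enumerate(phi0):
        key = float(p)
        if key not in cache:
            cache[key] = steady_state(key, params, net.alpha)[0]
        u0[j] = cache[key]
    return u0, u0.copy()


def _kernel_sched_arrays(sched: IlluminationSchedule, n: int):
    t_il = np.asarray(sched.t_ilum, dtype=float)
    if t_il.size != n:
        raise ValueError("schedule length does not match n_osc")
    if sched.phi_const is None:
        cphi = np.full(n, np.nan)
    else:
        cphi = np.full(n, float(sched.phi_const))
    return t_il, cphi


def integrate(params: OregonatorParams, net: NetworkSpec,
              sched: IlluminationSchedule, cfg: IntegratorConfig,
              init: tuple[np.ndarray, np.ndarray] | None = None) -> Trajectory:
    """Integrate one network with classic RK4 from t=0 to t_max.

    If ``init`` is omitted, the initial state is the illuminated steady state
    of each oscillator under its phi_j(0).  Samples are stored every
    ``store_stride`` steps plus the final state.
    """
    if sched.n_osc != net.n_osc:
        raise ValueError("schedule and network disagree on oscillator count")
    if init is None:
        u0, v0 = _initial_state(params, net, sched)
    else:
        u0 = np.asarray(init[0], dtype=float).copy()
        v0 = np.asarray(init[1], dtype=float).copy()
        if u0.shape != (net.n_osc,) or v0.shape != (net.n_osc,):
            raise ValueError("init state must have length n_osc")
    t_il, cphi = _kernel_sched_arrays(sched, net.n_osc)
    times, u, v, status = rk4_trajectory(
        u0, v0, t_il, cphi, sched.amp, sched.offset, sched.steepness,
        params.epsilon, params.q_const, params.f_stoich,
        net.alpha, net.beta, net.adjacency, net.degrees,
        cfg.h, cfg.n_steps, cfg.store_stride)
    if status != 0:
        raise SimulationError(
            "numerical blow-up or negative activator during integration")
    return Trajectory(times=times, u=u, v=v)


def integrate_counts(params: OregonatorParams, net: NetworkSpec,
                     t_ilum_batch: np.ndarray, cfg: IntegratorConfig,
                     pk: PeakConfig, u0: np.ndarray, v0: np.ndarray,
                     sched_template: IlluminationSchedule | None = None):
    """Batch driver: maxima counts for many records of one network.

    t_ilum_batch is (B, n_osc); u0, v0 are matching initial states.  Returns
    (counts (B, n_osc), status (B,)) without storing trajectories.
    """
    sched = sched_template or IlluminationSchedule(t_ilum=np.zeros(net.n_osc))
    B, n = t_ilum_batch.shape
    if n != net.n_osc:
        raise ValueError("t_ilum_batch width does not match n_osc")
    if sched.phi_const is None:
        cphi = np.full((B, n), np.nan)
    else:
        cphi = np.full((B, n), float(sched.phi_const))
    args = (np.ascontiguousarray(u0, dtype=float),
            np.ascontiguousarray(v0, dtype=float),
            np.ascontiguousarray(t_ilum_batch, dtype=float), cphi,
            sched.amp, sched.offset, sched.steepness,
            params.epsilon, params.q_const, params.f_stoich,
            net.alpha, net.beta)
    tail = (cfg.h, cfg.n_steps, cfg.store_stride, pk.height_threshold)
    if n == 3 and bool(net.adjacency.sum() == 6):
        # all-to-all triple: register-resident kernel, bit-identical results
        return rk4_count_batch3(*args, *tail)
    return rk4_count_batch(*args, net.adjacency, net.degrees, *tail)


def count_maxima(traj: Trajectory, osc_index: int,
                 pk: PeakConfig = PeakConfig()) -> int:
    """Count interior strict local maxima of one stored activator series.

    A sample counts iff u[i-1] < u[i] >= u[i+1] and u[i] exceeds the height
    threshold; the endpoints are never counted.
    """
    x = traj.u[:, osc_index]
    if x.size < 3:
        return 0
    mid = x[1:-1]
    hits = (x[:-2] < mid) & (mid >= x[2:]) & (mid > pk.height_threshold)
    return int(hits.sum())


def peak_times(traj: Trajectory, osc_index: int,
               pk: PeakConfig = PeakConfig()) -> np.ndarray:
    """Times of the counted maxima (stored-grid resolution)."""
    x = traj.u[:, osc_index]
    if x.size < 3:
        return np.empty(0)
    mid = x[1:-1]
    hits = (x[:-2] < mid) & (mid >= x[2:]) & (mid > pk.height_threshold)
    return traj.times[1:-1][hits]


def measure_period(params: OregonatorParams, alpha: float, phi: float,
                   cfg: IntegratorConfig,
                   pk: PeakConfig = PeakConfig()) -> float:
    """Limit-cycle period of a single oscillator at constant illumination phi.

    The oscillator starts from the strongly-illuminated steady state (the
    rest state at phi = amp*(offset+1)); phi is then held at the requested
    value for the whole window.  The period is the mean spacing of successive
    activator maxima after the first two (transient) maxima are discarded,
    with the stored-sample resolution.  Raises NoOscillationError when fewer
    than four maxima occur.
    """
    net = NetworkSpec(n_osc=1, alpha=alpha, beta=0.0)
    sched = IlluminationSchedule(t_ilum=np.zeros(1), phi_const=phi)
    rest = IlluminationSchedule(t_ilum=np.zeros(1))
    phi_bright = rest.amp * (rest.offset + 1.0)
    u0 = np.array([steady_state(phi_bright, params, alpha)[0]])
    traj = integrate(params, net, sched, cfg, init=(u0, u0.copy()))
    tpk = peak_times(traj, 0, pk)
    if tpk.size < 4:
        raise NoOscillationError(
            f"only {tpk.size} maxima in the window; no sustained oscillation")
    spacings = np.diff(tpk[2:])
    return float(spacings.mean())
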