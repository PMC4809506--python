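"""Reflected-SDE integration of channel-state occupancy, with oracles.

The occupancy-fraction vector of a Markov gating scheme evolves as

    dX_t = A X_t dt + (1/sqrt(N)) E sqrt(D(X_t)) dW + K_t

with one independent Wiener increment per transition (variance ``dt`` per
step) and a boundary process ``K_t`` keeping every component in [0, 1].  The
reflection is realised as the Euclidean projection of the post-step vector
onto the unit simplex, which enforces both the bounds and conservation in a
single operation.

Two independent oracles are provided: an exact Gillespie (SSA) sample path of
``N`` channels, and the deterministic ODE limit ``dx/dt = A x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .markov import (
    MarkovScheme,
    ChannelStateVector,
    evaluate_matrices,
    steady_state_distribution,
)

__all__ = [
    "SDEConfig",
    "Trajectory",
    "VoltageProtocol",
    "project_simplex",
    "step_reflected_em",
    "simulate_channel_sde",
    "simulate_channel_ssa",
    "simulate_channel_ode",
    "stationary_moments_sde",
]

SSA_CHANNEL_GUARD = 100_000


@dataclass(frozen=True)
class SDEConfig:
    """Numerical configuration of one reflected-SDE run.

    dt is the Euler-Maruyama step in ms; N the channel count setting the noise
    magnitude 1/sqrt(N).
    """

    dt: float = 0.01
    N: float = 1000.0
    seed: int = 0
    projection_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.N >= 1:
            raise ValueError("N must be at least 1")


@dataclass
class VoltageProtocol:
    """Piecewise-constant (t, V) schedule.

    ``times`` are segment start times (ms, strictly increasing, first 0);
    ``voltages`` the held potential of each segment; ``duration`` the total
    protocol length.
    """

    times: np.ndarray
    voltages: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.voltages = np.asarray(self.voltages, float)
        if self.times.ndim != 1 or self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must be 1-d and equally long")
        if len(self.times) and self.times[0] != 0.0:
            raise ValueError("protocol must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("protocol times must be strictly increasing")
        if self.duration < 0 or (len(self.times) and self.duration < self.times[-1]):
            raise ValueError("protocol duration inconsistent with segment times")

    @classmethod
    def step(cls, hold: float, test: float, t_step: float, duration: float
             ) -> "VoltageProtocol":
        """Holding potential then a single test step at ``t_step``."""
        return cls(np.array([0.0, t_step]), np.array([hold, test]), duration)

    @classmethod
    def constant(cls, V: float, duration: float) -> "VoltageProtocol":
        return cls(np.array([0.0]), np.array([V]), duration)

    @classmethod
    def from_json(cls, text: str) -> "VoltageProtocol":
        import json

        doc = json.loads(text)
        return cls(np.asarray(doc["times_ms"], float),
                   np.asarray(doc["voltages_mV"], float),
                   float(doc["duration_ms"]))

    def to_json(self) -> str:
        import json

        return json.dumps({"times_ms": self.times.tolist(),
                           "voltages_mV": self.voltages.tolist(),
                           "duration_ms": self.duration})

    def segments(self) -> list[tuple[float, float, float]]:
        """(t_start, t_end, V) per segment."""
        edges = np.append(self.times, self.duration)
        return [
            (float(edges[i]), float(edges[i + 1]), float(self.voltages[i]))
            for i in range(len(self.times))
            if edges[i + 1] > edges[i]
        ]


@dataclass
class Trajectory:
    """Sampled occupancy path of one scheme."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)
    open_fraction: np.ndarray
    scheme_name: str = ""

    def __post_init__(self) -> None:
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    def to_frame(self):
        """Long-run trajectories go to CSV via this tidy frame."""
        import pandas as pd

        df = pd.DataFrame({"time_ms": self.times})
        for k in range(self.states.shape[1]):
            df[f"state_{k}"] = self.states[:, k]
        df["open_fraction"] = self.open_fraction
        return df


# --------------------------------------------------------------------------
# simplex projection
# --------------------------------------------------------------------------

def project_simplex(X: np.ndarray) -> np.ndarray:
    """Euclidean projection of rows of ``X`` onto the unit simplex."""
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[1]
    U = np.sort(X, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    ks = np.arange(1, n + 1)
    cond = U - css / ks > 0
    rho = n - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(X.shape[0]), rho] / (rho + 1)
    return np.maximum(X - theta[:, None], 0.0)


@njit(cache=True)
def _project_simplex_rows(X):  # pragma: no cover - exercised via jitted callers
    m, n = X.shape
    for i in range(m):
        u = np.sort(X[i])[::-1]
        css = 0.0
        theta = 0.0
        for k in range(n):
            css += u[k]
            t = (css - 1.0) / (k + 1)
            if u[k] - t > 0:
                theta = t
        for j in range(n):
            v = X[i, j] - theta
            X[i, j] = v if v > 0.0 else 0.0
    return X


# --------------------------------------------------------------------------
# reflected Euler-Maruyama
# --------------------------------------------------------------------------

@njit(cache=True)
def _em_segment(X, rates, fr, to, coef, dt, n_steps, out, out_stride, seed):
    """Advance ``n_steps`` EM steps at constant rates; record open-state sums.

    X: (n_chains, n_states) occupancies, modified in place.
    out: (n_recorded, n_chains, n_states) buffer filled every ``out_stride``
    steps (ignored when out_stride == 0).
    """
    np.random.seed(seed)
    m, n = X.shape
    nt = len(rates)
    dbuf = np.empty(nt)
    rec = 0
    for step in range(n_steps):
        for i in range(m):
            # intensities from the pre-step state for every transition
            for k in range(nt):
                d = rates[k] * X[i, fr[k]]
                dbuf[k] = d if d > 0.0 else 0.0
            for k in range(nt):
                flux = dbuf[k] * dt
                if coef > 0.0:
                    flux += coef * np.sqrt(dbuf[k] * dt) * np.random.normal()
                X[i, fr[k]] -= flux
                X[i, to[k]] += flux
        _project_simplex_rows(X)
        if out_stride > 0 and (step + 1) % out_stride == 0:
            out[rec] = X
            rec += 1
    return rec


def step_reflected_em(
    x: ChannelStateVector | np.ndarray,
    scheme: MarkovScheme,
    V: float,
    Ca_i: float,
    cfg: SDEConfig,
    rng: np.random.Generator,
) -> ChannelStateVector:
    """One reflected Euler-Maruyama step.

    Returns ``proj(x + A x dt + (1/sqrt(N)) E sqrt(d) dW)`` with independent
    Gaussian increments of variance ``dt`` per transition and projection onto
    the unit simplex.
    """
    xv = (x.values if isinstance(x, ChannelStateVector) else np.asarray(x, float)).copy()
    rates = scheme.rates(V, Ca_i)
    fr, to = scheme.transition_indices()
    d = np.maximum(rates * xv[fr], 0.0)
    flux = d * cfg.dt
    if np.isfinite(cfg.N):
        flux = flux + np.sqrt(d * cfg.dt) / np.sqrt(cfg.N) * rng.standard_normal(len(d))
    if not np.all(np.isfinite(flux)):
        raise FloatingPointError(
            f"non-finite drift/noise in scheme {scheme.name!r} at V={V:g} mV"
        )
    np.subtract.at(xv, fr, flux)
    np.add.at(xv, to, flux)
    xv = project_simplex(xv)[0]
    return ChannelStateVector(xv, scheme.name)


def simulate_channel_sde(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    cfg: SDEConfig,
    Ca_i: float = 1e-4,
    output_stride: int = 1,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the reflected SDE along a piecewise-constant voltage protocol.

    The trajectory is sampled every ``output_stride`` steps; it is reproducible
    under an identical :class:`SDEConfig` seed.
    """
    if protocol.duration <= 0:
        return Trajectory(np.empty(0), np.empty((0, scheme.n_states)),
                          np.empty(0), scheme.name)
    fr, to = scheme.transition_indices()
    if x0 is None:
        x0 = steady_state_distribution(scheme, protocol.voltages[0], Ca_i).values
    X = np.atleast_2d(np.asarray(x0, float)).copy()
    coef = 0.0 if np.isinf(cfg.N) else 1.0 / np.sqrt(cfg.N)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(protocol.segments()))

    times: list[np.ndarray] = []
    recs: list[np.ndarray] = []
    open_idx = scheme.open_indices
    t_done = 0.0
    steps_done = 0
    for si, (t0, t1, V) in enumerate(protocol.segments()):
        n_steps = int(round((t1 - t0) / cfg.dt))
        rates = scheme.rates(V, Ca_i)
        n_rec = n_steps // output_stride
        out = np.empty((max(n_rec, 1), X.shape[0], scheme.n_states))
        rec = _em_segment(X, rates, fr, to, coef, cfg.dt, n_steps, out,
                          output_stride, int(seeds[si]) % (2**32))
        if rec:
            step_idx = steps_done + (np.arange(1, rec + 1) * output_stride)
            times.append(step_idx * cfg.dt)
            recs.append(out[:rec, 0, :])
        steps_done += n_steps
        t_done = t1
    if not recs:
        return Trajectory(np.empty(0), np.empty((0, scheme.n_states)),
                          np.empty(0), scheme.name)
    t_arr = np.concatenate(times)
    s_arr = np.concatenate(recs)
    return Trajectory(t_arr, s_arr, s_arr[:, open_idx].sum(axis=1), scheme.name)


def stationary_moments_sde(
    scheme: MarkovScheme,
    V: float,
    cfg: SDEConfig,
    t_total: float,
    burn_in: float,
    n_chains: int = 1,
    Ca_i: float = 1e-4,
    output_stride: int = 10,
) -> tuple[float, float, int]:
    """Pooled stationary mean and variance of the open fraction.

    Runs ``n_chains`` independent chains at fixed voltage, discards
    ``burn_in`` ms, and pools the remaining samples.  Returns
    ``(mean, variance, n_samples)``.
    """
    fr, to = scheme.transition_indices()
    x0 = steady_state_distribution(scheme, V, Ca_i).values
    X = np.tile(x0, (n_chains, 1))
    coef = 0.0 if np.isinf(cfg.N) else 1.0 / np.sqrt(cfg.N)
    rates = scheme.rates(V, Ca_i)
    open_idx = scheme.open_indices

    n_burn = int(round(burn_in / cfg.dt))
    dummy = np.empty((1, n_chains, scheme.n_states))
    ss = np.random.SeedSequence(cfg.seed).generate_state(2)
    _em_segment(X, rates, fr, to, coef, cfg.dt, n_burn, dummy, 0,
                int(ss[0]) % (2**32))
    n_steps = int(round((t_total - burn_in) / cfg.dt))
    n_rec = n_steps // output_stride
    out = np.empty((n_rec, n_chains, scheme.n_states))
    rec = _em_segment(X, rates, fr, to, coef, cfg.dt, n_steps, out,
                      output_stride, int(ss[1]) % (2**32))
    p = out[:rec, :, open_idx].sum(axis=-1).ravel()
    return float(p.mean()), float(p.var()), p.size


# --------------------------------------------------------------------------
# Gillespie (SSA) oracle
# --------------------------------------------------------------------------

@njit(cache=True)
def _ssa_segment(counts, rates, fr, to, t0, t1, rec_times, rec_out, rec_pos, seed):
    """Exact SSA of channel counts over [t0, t1) at constant rates.

    rec_times is the global output grid; rec_pos the index of the next output
    sample to fill.  Returns the updated rec_pos.
    """
    np.random.seed(seed)
    nt = len(rates)
    t = t0
    n_rec = len(rec_times)
    while True:
        total = 0.0
        for k in range(nt):
            total += rates[k] * counts[fr[k]]
        if total <= 0.0:
            t_next = t1
        else:
            t_next = t + np.random.exponential(1.0 / total)
        while rec_pos < n_rec and rec_times[rec_pos] < min(t_next, t1):
            rec_out[rec_pos] = counts
            rec_pos += 1
        if t_next >= t1:
            break
        u = np.random.random() * total
        acc = 0.0
        k_sel = nt - 1
        for k in range(nt):
            acc += rates[k] * counts[fr[k]]
            if u < acc:
                k_sel = k
                break
        counts[fr[k_sel]] -= 1
        counts[to[k_sel]] += 1
        t = t_next
    return rec_pos


def simulate_channel_ssa(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    N: int,
    seed: int,
    Ca_i: float = 1e-4,
    output_dt: float = 0.1,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Exact continuous-time Markov chain sample path of ``N`` channels.

    Occupancies are reported as fractions on a regular output grid.
    """
    if N > SSA_CHANNEL_GUARD:
        raise ValueError(f"N={N} exceeds the SSA tractability guard "
                         f"({SSA_CHANNEL_GUARD})")
    if N < 1:
        raise ValueError("N must be at least 1")
    if protocol.duration <= 0:
        return Trajectory(np.empty(0), np.empty((0, scheme.n_states)),
                          np.empty(0), scheme.name)

    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = steady_state_distribution(scheme, protocol.voltages[0], Ca_i).values
    counts = rng.multinomial(N, np.asarray(x0) / np.sum(x0)).astype(np.int64)
    fr, to = scheme.transition_indices()

    rec_times = np.arange(0.0, protocol.duration, output_dt)
    rec_out = np.zeros((len(rec_times), scheme.n_states), dtype=np.int64)
    rec_pos = 0
    seeds = np.random.SeedSequence(seed).generate_state(len(protocol.segments()) + 1)
    for si, (t0, t1, V) in enumerate(protocol.segments()):
        rates = scheme.rates(V, Ca_i)
        rec_pos = _ssa_segment(counts, rates, fr, to, t0, t1, rec_times,
                               rec_out, rec_pos, int(seeds[si + 1]) % (2**32))
    states = rec_out / N
    open_idx = scheme.open_indices
    return Trajectory(rec_times, states, states[:, open_idx].sum(axis=1), scheme.name)


# --------------------------------------------------------------------------
# deterministic ODE oracle
# --------------------------------------------------------------------------

def simulate_channel_ode(
    scheme: MarkovScheme,
    protocol: VoltageProtocol,
    Ca_i: float = 1e-4,
    output_dt: float = 0.1,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Deterministic limit ``dx/dt = A x`` solved per protocol segment."""
    if x0 is None:
        x0 = steady_state_distribution(scheme, protocol.voltages[0], Ca_i).values
    x = np.asarray(x0, float)
    times: list[np.ndarray] = []
    recs: list[np.ndarray] = []
    for t0, t1, V in protocol.segments():
        A, _, _ = evaluate_matrices(
            scheme, np.full(scheme.n_states, 1 / scheme.n_states), V, Ca_i
        )
        t_eval = np.arange(t0, t1, output_dt)
        sol = solve_ivp(lambda t, y: A @ y, (t0, t1), x, t_eval=t_eval,
                        rtol=1e-8, atol=1e-10, method="LSODA")
        times.append(sol.t)
        recs.append(sol.y.T)
        x = sol.y[:, -1] if sol.y.size else x
        # advance exactly to the segment end
        sol_end = solve_ivp(lambda t, y: A @ y, (t_eval[-1] if len(t_eval) else t0, t1),
                            x, rtol=1e-8, atol=1e-10, method="LSODA")
        x = sol_end.y[:, -1]
    t_arr = np.concatenate(times)
    s_arr = np.concatenate(recs)
    open_idx = scheme.open_indices
    return Trajectory(t_arr, s_arr, s_arr[:, open_idx].sum(axis=1), scheme.name)
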