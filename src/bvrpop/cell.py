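"""Canine epicardial action-potential model with stochastic Markov currents.

The cell is a reduced epicardial ventricular myocyte: a fast sodium current
(I_Na, Hodgkin-Huxley m^3 h), the inward rectifier I_K1, a small background
current, and the four repolarizing currents that carry channel noise —
I_Kr, I_Ks, I_to1 and I_CaL — each formulated as a discrete-state Markov
scheme integrated by the reflected SDE.  The I_CaL steady-state activation
uses the double-sigmoid replacement

    ACT_inf(V) = 1 / [(1 + exp(-(V - 15.3356)/10.7558))
                      (1 + exp(-(V + 12.8824)/2.1957))]

which sharpens the activation foot so the AP morphology stays realistic when
I_CaL is pharmacologically inhibited.  Gate kinetics are standard epicardial
formulations; calcium and sodium concentrations are held fixed (no calcium
subsystem), which keeps every run fast enough for population-scale stochastic
studies.  The baseline is pluggable: every downstream stage only consumes
APD sequences and channel-number vectors.

Voltage-dependent quantities are tabulated on a 0.05-mV grid over
[-120, 80] mV and looked up by nearest neighbour inside the numba pacing
kernel; the tables are built directly from the scheme objects, so the kernel
and the generic SDE engine share identical rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from numba import njit

from .markov import MarkovScheme, hh_gate_scheme, tensor_product_scheme
from .sde import SDEConfig, VoltageProtocol

__all__ = [
    "CellParams",
    "CellModelInstance",
    "BlockSpec",
    "PacingProtocol",
    "APDSequence",
    "PacingResult",
    "STOCHASTIC_CURRENTS",
    "CONDITION_BLOCKS",
    "ical_activation_inf",
    "ikr_rectification",
    "ghk_ca_driving",
    "apply_block",
    "pace_deterministic",
    "pace_stochastic",
    "apd90",
    "simulate_voltage_clamp",
    "find_diastolic_threshold",
    "cell_schemes",
    "default_state",
]

# physical constants and fixed ionic milieu
RTF = 26.712  # mV at 310 K
NA_O, NA_I = 140.0, 10.0  # mM
K_O, K_I = 5.4, 145.0
CA_O, CA_I = 1.8, 1e-4
E_K = RTF * np.log(K_O / K_I)      # ~ -87.9 mV
E_NA = RTF * np.log(NA_O / NA_I)   # ~ +70.5 mV
E_KS = E_K

STOCHASTIC_CURRENTS = ("IKr", "IKs", "Ito1", "ICaL")

#: conductance multipliers of the five calibration conditions
CONDITION_BLOCKS: dict[str, dict[str, float]] = {
    "control": {},
    "IKr_block": {"IKr": 1.0},
    "IKs_block": {"IKs": 1.0},
    "ICaL_block": {"ICaL": 0.95},
    "IKs_Ito1_block": {"IKs": 1.0, "Ito1": 0.9},
}


@dataclass(frozen=True)
class CellParams:
    """Baseline maximal conductances (mS/uF) and cell constants."""

    g_Na: float = 12.0
    g_NaL: float = 0.0065  # late (persistent) sodium; deterministic
    g_K1: float = 0.5
    g_Kr: float = 0.02
    g_Ks: float = 0.07
    g_to1: float = 0.26
    p_CaL: float = 1.9      # A/F per (mV*mM), GHK permeability scale
    g_bg: float = 0.010
    E_bg: float = -40.0
    Cm_pF: float = 150.0    # whole-cell capacitance, for pA conversions


# --------------------------------------------------------------------------
# gating formulations
# --------------------------------------------------------------------------

ACT_INF_EXPR = ("1/((1+exp(-(V-15.3356)/10.7558))"
                "*(1+exp(-(V+12.8824)/2.1957)))")


def ical_activation_inf(V):
    """Steady-state activation of I_CaL (double-sigmoid product form)."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / ((1.0 + np.exp(-(V - 15.3356) / 10.7558))
                 * (1.0 + np.exp(-(V + 12.8824) / 2.1957)))
    return float(out) if out.ndim == 0 else out


def ikr_rectification(V):
    """Instantaneous inward-rectification factor of I_Kr."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) + 9.0) / 22.4))


def ghk_ca_driving(V):
    """GHK calcium driving term (mV*mM); negative = inward."""
    V = np.asarray(V, dtype=float)
    u = 2.0 * V / RTF
    small = np.abs(u) < 1e-6
    us = np.where(small, 1.0, u)
    ratio = np.where(small, RTF / 2.0, V / np.expm1(us))
    out = ratio * (CA_I * np.exp(u) - 0.341 * CA_O)
    return float(out) if out.ndim == 0 else out


def _ab(inf: str, tau: str) -> tuple[str, str]:
    return f"({inf})/({tau})", f"(1-({inf}))/({tau})"


_GATES = {
    # I_Kr slow activation; inactivation (rectification) is instantaneous
    "xr": _ab("1/(1+exp(-(V+21.5)/7.5))", "30+300/(1+exp((V+30)/10))"),
    # I_Ks activation: slow and strongly plateau-height dependent (single
    # aggregated gate); this carries the repolarization reserve recruited
    # when I_Kr is lost
    "xs": _ab("1/(1+exp(-(V-35)/10))", "2500/(1+exp(-(V-20)/15))"),
    # I_to1 activation / inactivation (epicardial, prominent notch)
    "a": _ab("1/(1+exp((20-V)/6))", "9.5*exp(-(V+40)**2/1800)+0.8"),
    # inactivation keeps a small non-inactivating pedestal (sustained
    # component), so channel noise in I_to1 acts on the whole plateau
    "i": _ab("0.035+0.965/(1+exp((V+20)/5))",
             "85*exp(-(V+45)**2/320)+5/(1+exp((V-20)/5))+3"),
    # I_CaL activation (printed ACT_inf) / voltage inactivation
    "d": _ab(ACT_INF_EXPR,
             "(1.4/(1+exp((-35-V)/13))+0.25)*(1.4/(1+exp((V+5)/5)))"
             "+1/(1+exp((50-V)/20))"),
    "f": _ab("1/(1+exp((V+25)/5.5))",
             "25+1095*exp(-(V+27)**2/240)+35/(1+exp((25-V)/10))"),
}


@lru_cache(maxsize=1)
def cell_schemes() -> dict[str, MarkovScheme]:
    """The four Markov gating schemes of the stochastic currents."""
    gate = {k: hh_gate_scheme(f"gate_{k}", a, b) for k, (a, b) in _GATES.items()}
    return {
        "IKr": hh_gate_scheme("IKr", *_GATES["xr"]),
        "IKs": hh_gate_scheme("IKs", *_GATES["xs"]),
        "Ito1": tensor_product_scheme("Ito1", gate["a"], gate["i"]),
        "ICaL": tensor_product_scheme("ICaL", gate["d"], gate["f"]),
    }


# I_Na gates (m^3 h), Luo-Rudy formulation
def _alpha_m(V):
    x = V + 47.13
    return np.where(np.abs(x) < 1e-6, 3.2, 0.32 * x / (1.0 - np.exp(-0.1 * x)))


def _beta_m(V):
    return 0.08 * np.exp(-V / 11.0)


def _alpha_h(V):
    return np.where(V < -40.0, 0.135 * np.exp(-(80.0 + V) / 6.8), 0.0)


def _beta_h(V):
    lo = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
    hi = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    return np.where(V < -40.0, lo, hi)


def _nal_activation(V):
    """Quasi-steady activation of the late sodium current."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + 27.5) / 6.0))


def _nal_inactivation_inf(V):
    """Steady state of the slow late-sodium inactivation gate hL."""
    return 1.0 / (1.0 + np.exp((np.asarray(V, float) + 75.0) / 6.0))


NAL_TAU_H = 600.0  # ms, slow inactivation time constant of I_NaL


def _k1_inf(V):
    a = 1.02 / (1.0 + np.exp(0.2385 * (V - E_K - 59.215)))
    b = (0.49124 * np.exp(0.08032 * (V - E_K + 5.476))
         + np.exp(0.06175 * (V - E_K - 594.31))) \
        / (1.0 + np.exp(-0.5143 * (V - E_K + 4.753)))
    return a / (a + b)


# --------------------------------------------------------------------------
# voltage tables and kernel wiring
# --------------------------------------------------------------------------

V_MIN, V_MAX, DV = -120.0, 80.0, 0.05


@dataclass(frozen=True)
class _Engine:
    table: np.ndarray
    edge_i: np.ndarray     # absolute "from" state index per undirected edge
    edge_j: np.ndarray     # absolute "to" state index
    edge_cf: np.ndarray    # table column of the forward (i->j) rate
    edge_cb: np.ndarray    # table column of the backward rate (-1 if none)
    edge_sch: np.ndarray   # scheme id per edge
    sch_start: np.ndarray  # absolute offset of each scheme's block in y
    sch_n: np.ndarray
    open_abs: np.ndarray   # absolute index of each scheme's open state
    n_state: int


@lru_cache(maxsize=1)
def _engine() -> _Engine:
    schemes = cell_schemes()
    order = list(STOCHASTIC_CURRENTS)
    grid = np.arange(V_MIN, V_MAX + DV / 2, DV)
    n_trans = sum(schemes[c].n_transitions for c in order)
    n_cols = n_trans + 9
    table = np.empty((len(grid), n_cols))

    edge_i, edge_j, edge_cf, edge_cb, edge_sch = [], [], [], [], []
    sch_start, sch_n, open_abs = [], [], []
    offset = 4  # y = [V, m, h, hL, occupancies...]
    col = 0
    for s, cur in enumerate(order):
        sc = schemes[cur]
        fr, to = sc.transition_indices()
        cols = {}
        for k, t in enumerate(sc.transitions):
            table[:, col] = [t(v) for v in grid]
            cols[(int(fr[k]), int(to[k]))] = col
            col += 1
        # pair reverse transitions into undirected edges: the two Wiener
        # increments share one stoichiometry column, so their net noise is
        # a single Gaussian of variance (d_f + d_b) dt
        seen = set()
        for (a, b), cf in cols.items():
            if (a, b) in seen:
                continue
            cb = cols.get((b, a), -1)
            seen.add((a, b))
            if cb >= 0:
                seen.add((b, a))
            edge_i.append(offset + a)
            edge_j.append(offset + b)
            edge_cf.append(cf)
            edge_cb.append(cb)
            edge_sch.append(s)
        sch_start.append(offset)
        sch_n.append(sc.n_states)
        oi = sc.open_indices
        assert len(oi) == 1
        open_abs.append(offset + int(oi[0]))
        offset += sc.n_states

    table[:, col + 0] = _alpha_m(grid)
    table[:, col + 1] = _beta_m(grid)
    table[:, col + 2] = _alpha_h(grid)
    table[:, col + 3] = _beta_h(grid)
    table[:, col + 4] = _k1_inf(grid)
    table[:, col + 5] = ikr_rectification(grid)
    table[:, col + 6] = ghk_ca_driving(grid)
    table[:, col + 7] = _nal_activation(grid)
    table[:, col + 8] = _nal_inactivation_inf(grid)

    return _Engine(
        table=table,
        edge_i=np.array(edge_i, np.int64),
        edge_j=np.array(edge_j, np.int64),
        edge_cf=np.array(edge_cf, np.int64),
        edge_cb=np.array(edge_cb, np.int64),
        edge_sch=np.array(edge_sch, np.int64),
        sch_start=np.array(sch_start, np.int64),
        sch_n=np.array(sch_n, np.int64),
        open_abs=np.array(open_abs, np.int64),
        n_state=offset,
    )


@njit(cache=True)
def _pace_kernel(y, table, edge_i, edge_j, edge_cf, edge_cb, edge_sch,
                 sch_start, sch_n, open_abs, g, noise_amp, n_beats, bcl_steps,
                 dt, stim_amp, stim_steps, seed, apd_out, v_out, v_stride,
                 early_tol):
    """Paced beats of the whole cell; returns the number of beats simulated.

    g = [g_Na, g_K1, g_Kr, g_Ks, g_to1, p_CaL, g_bg, E_bg, g_NaL].
    noise_amp[s] = 1/sqrt(N_s) for stochastic schemes, 0 for deterministic.
    apd_out[b] is APD90 of beat b (NaN = repolarization failure).
    Gaussian increments come from an inline xorshift128+ / Marsaglia-polar
    generator (one increment per reversible edge; identical in distribution
    to one increment per directed transition).
    """
    # xorshift128+ state, seeded by splitmix64
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s0 = z ^ (z >> np.uint64(31))
    z = s0 + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s1 = z ^ (z >> np.uint64(31))
    have_spare = False
    spare = 0.0
    inv53 = 1.0 / 9007199254740992.0  # 2^-53

    n_edges = len(edge_i)
    n_cols = table.shape[1]
    c_am, c_bm, c_ah, c_bh = n_cols - 9, n_cols - 8, n_cols - 7, n_cols - 6
    c_k1, c_rkr, c_phi = n_cols - 5, n_cols - 4, n_cols - 3
    c_ml, c_hl = n_cols - 2, n_cols - 1
    dvinv = 1.0 / DV
    nrow = table.shape[0]
    buf = np.empty(8)
    occ = np.empty(len(y))  # pre-step occupancy snapshot for the intensities
    vpos = 0
    beats_done = 0

    for beat in range(n_beats):
        v_rest = y[0]
        v_peak = y[0]
        t_up = 0.0
        dvdt_max = -1.0e30
        crossed = False
        apd = np.nan
        for step in range(bcl_steps):
            V = y[0]
            vi = int((V - V_MIN) * dvinv + 0.5)
            if vi < 0:
                vi = 0
            elif vi >= nrow:
                vi = nrow - 1
            row = table[vi]

            m = y[1]
            h = y[2]
            hl = y[3]
            i_na = g[0] * m * m * m * h * (V - E_NA)
            i_nal = g[8] * row[c_ml] * hl * (V - E_NA)
            i_k1 = g[1] * row[c_k1] * (V - E_K)
            i_kr = g[2] * row[c_rkr] * y[open_abs[0]] * (V - E_K)
            i_ks = g[3] * y[open_abs[1]] * (V - E_KS)
            i_to = g[4] * y[open_abs[2]] * (V - E_K)
            i_ca = g[5] * y[open_abs[3]] * row[c_phi]
            i_bg = g[6] * (V - g[7])
            i_ion = i_na + i_nal + i_k1 + i_kr + i_ks + i_to + i_ca + i_bg
            i_stim = stim_amp if step < stim_steps else 0.0
            dvdt = -(i_ion + i_stim)

            y[1] = min(max(m + dt * (row[c_am] * (1.0 - m) - row[c_bm] * m), 0.0), 1.0)
            y[2] = min(max(h + dt * (row[c_ah] * (1.0 - h) - row[c_bh] * h), 0.0), 1.0)
            y[3] = min(max(hl + dt * (row[c_hl] - hl) / 600.0, 0.0), 1.0)

            for j in range(4, len(y)):
                occ[j] = y[j]
            for k in range(n_edges):
                df = row[edge_cf[k]] * occ[edge_i[k]]
                if df < 0.0:
                    df = 0.0
                db = 0.0
                if edge_cb[k] >= 0:
                    db = row[edge_cb[k]] * occ[edge_j[k]]
                    if db < 0.0:
                        db = 0.0
                flux = (df - db) * dt
                a = noise_amp[edge_sch[k]]
                if a > 0.0:
                    if have_spare:
                        xi = spare
                        have_spare = False
                    else:
                        while True:  # Marsaglia polar method
                            xa = s0
                            yb = s1
                            s0 = yb
                            xa ^= xa << np.uint64(23)
                            s1 = (xa ^ yb ^ (xa >> np.uint64(17))
                                  ^ (yb >> np.uint64(26)))
                            u = 2.0 * (float((s1 + yb) >> np.uint64(11))
                                       * inv53) - 1.0
                            xa = s0
                            yb = s1
                            s0 = yb
                            xa ^= xa << np.uint64(23)
                            s1 = (xa ^ yb ^ (xa >> np.uint64(17))
                                  ^ (yb >> np.uint64(26)))
                            v = 2.0 * (float((s1 + yb) >> np.uint64(11))
                                       * inv53) - 1.0
                            r2 = u * u + v * v
                            if 0.0 < r2 < 1.0:
                                fac = np.sqrt(-2.0 * np.log(r2) / r2)
                                xi = u * fac
                                spare = v * fac
                                have_spare = True
                                break
                    flux += a * np.sqrt((df + db) * dt) * xi
                y[edge_i[k]] -= flux
                y[edge_j[k]] += flux

            # reflect: project a scheme onto the unit simplex only when a
            # bound is actually violated (the edge updates conserve the sum)
            for s in range(len(sch_start)):
                st = sch_start[s]
                ns = sch_n[s]
                bad = False
                for j in range(ns):
                    if y[st + j] < 0.0 or y[st + j] > 1.0:
                        bad = True
                        break
                if not bad:
                    continue
                for j in range(ns):
                    buf[j] = y[st + j]
                for j in range(1, ns):  # insertion sort, descending
                    key = buf[j]
                    jj = j - 1
                    while jj >= 0 and buf[jj] < key:
                        buf[jj + 1] = buf[jj]
                        jj -= 1
                    buf[jj + 1] = key
                css = 0.0
                theta = 0.0
                for j in range(ns):
                    css += buf[j]
                    tt = (css - 1.0) / (j + 1)
                    if buf[j] - tt > 0.0:
                        theta = tt
                for j in range(ns):
                    v_ = y[st + j] - theta
                    y[st + j] = v_ if v_ > 0.0 else 0.0

            v_new = V + dt * dvdt
            y[0] = v_new
            t = (step + 1) * dt
            if dvdt > dvdt_max:
                dvdt_max = dvdt
                t_up = t - dt
            if v_new > v_peak:
                v_peak = v_new
            if (not crossed) and v_peak > v_rest + 10.0 and t > t_up and dvdt < 0.0:
                v90 = v_peak - 0.9 * (v_peak - v_rest)
                if v_new < v90 <= V:
                    tc = t - dt + dt * (V - v90) / (V - v_new)
                    apd = tc - t_up
                    crossed = True
            if v_stride > 0 and (step + 1) % v_stride == 0:
                v_out[vpos] = v_new
                vpos += 1

        apd_out[beat] = apd
        beats_done = beat + 1
        if early_tol > 0.0 and beat >= 2:
            a0, a1, a2 = apd_out[beat], apd_out[beat - 1], apd_out[beat - 2]
            if np.isnan(a0) and np.isnan(a1):
                break  # persistently non-repolarizing; no point continuing
            if abs(a0 - a1) < early_tol and abs(a1 - a2) < early_tol:
                break
    return beats_done


# --------------------------------------------------------------------------
# model instances, blocks, protocols
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """Fractional conductance inhibition per current, each in [0, 1]."""

    fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cur, f in self.fractions.items():
            if cur not in STOCHASTIC_CURRENTS:
                raise ValueError(f"cannot block unknown current {cur!r}")
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"block fraction for {cur} must be in [0, 1]")


@dataclass(frozen=True)
class CellModelInstance:
    """One member of the model population.

    ``scaling_factors`` multiply baseline maximal conductances;
    ``channel_numbers`` carry the per-current N entering the SDE noise term;
    ``block`` holds pharmacological conductance multipliers (N unchanged).
    """

    scaling_factors: dict = field(default_factory=lambda: {
        "IKr": 1.0, "IKs": 1.0, "Ito1": 1.0, "ICaL": 1.0, "IK1": 1.0})
    channel_numbers: dict | None = None
    stochastic_currents: frozenset = frozenset()
    block: dict = field(default_factory=dict)
    params: CellParams = field(default_factory=CellParams)
    model_id: str = "baseline"

    def __post_init__(self) -> None:
        for cur, s in self.scaling_factors.items():
            if s < 0:
                raise ValueError(f"scaling factor for {cur} must be >= 0")
        extra = set(self.stochastic_currents) - set(STOCHASTIC_CURRENTS)
        if extra:
            raise ValueError(f"cannot make {sorted(extra)} stochastic")
        for cur in self.stochastic_currents:
            if self.channel_numbers is None or cur not in self.channel_numbers:
                raise ValueError(f"channel number missing for stochastic {cur}")
            if self.channel_numbers[cur] < 1:
                raise ValueError(f"channel number for {cur} must be >= 1")

    def conductance_multiplier(self, current: str) -> float:
        s = self.scaling_factors.get(current, 1.0)
        return s * (1.0 - self.block.get(current, 0.0))

    def _gvec(self) -> np.ndarray:
        p = self.params
        return np.array([
            p.g_Na,
            p.g_K1 * self.scaling_factors.get("IK1", 1.0),
            p.g_Kr * self.conductance_multiplier("IKr"),
            p.g_Ks * self.conductance_multiplier("IKs"),
            p.g_to1 * self.conductance_multiplier("Ito1"),
            p.p_CaL * self.conductance_multiplier("ICaL"),
            p.g_bg,
            p.E_bg,
            p.g_NaL,
        ])

    def with_stochastic(self, currents, channel_numbers=None) -> "CellModelInstance":
        return replace(
            self,
            stochastic_currents=frozenset(currents),
            channel_numbers=channel_numbers or self.channel_numbers,
        )


def apply_block(model: CellModelInstance, block: BlockSpec) -> CellModelInstance:
    """Scale conductances by (1 - fraction); channel numbers are unchanged."""
    merged = dict(model.block)
    for cur, f in block.fractions.items():
        prev = merged.get(cur, 0.0)
        merged[cur] = 1.0 - (1.0 - prev) * (1.0 - f)
    return replace(model, block=merged)


@dataclass(frozen=True)
class PacingProtocol:
    """Steady pacing with rectangular stimulus pulses."""

    bcl: float = 1000.0          # ms
    n_beats: int = 80
    stim_amplitude: float = -60.0  # A/F, inward
    stim_duration: float = 1.0     # ms
    n_prepace_beats: int = 1000
    n_analyze: int = 30            # final beats kept for BVR quantification

    def __post_init__(self) -> None:
        if self.bcl <= 0:
            raise ValueError("BCL must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be at least 1")


@dataclass
class APDSequence:
    """Per-beat APD90 values of one pacing train."""

    apd_values: np.ndarray
    condition: str = "control"
    model_id: str = ""
    repetition: int = 0
    complete: bool = True

    def __post_init__(self) -> None:
        self.apd_values = np.asarray(self.apd_values, float)
        finite = self.apd_values[np.isfinite(self.apd_values)]
        if np.any(finite <= 0):
            raise ValueError("APD values must be positive")


@dataclass
class PacingResult:
    apds: np.ndarray
    final_state: np.ndarray
    prepace_beats: int = 0
    repolarization_failure: bool = False
    times: np.ndarray | None = None
    voltage: np.ndarray | None = None


def default_state() -> np.ndarray:
    """Resting state: V = -87 mV with all gates at their steady state."""
    from .markov import steady_state_distribution

    eng = _engine()
    v0 = -87.0
    y = np.empty(eng.n_state)
    y[0] = v0
    y[1] = float(_alpha_m(v0) / (_alpha_m(v0) + _beta_m(v0)))
    y[2] = float(_alpha_h(v0) / (_alpha_h(v0) + _beta_h(v0)))
    y[3] = float(_nal_inactivation_inf(v0))
    for cur, st, n in zip(STOCHASTIC_CURRENTS, eng.sch_start, eng.sch_n):
        y[st:st + n] = steady_state_distribution(cell_schemes()[cur], v0).values
    return y


def _noise_amp(model: CellModelInstance) -> np.ndarray:
    amp = np.zeros(len(STOCHASTIC_CURRENTS))
    for s, cur in enumerate(STOCHASTIC_CURRENTS):
        if cur in model.stochastic_currents:
            amp[s] = 1.0 / np.sqrt(float(model.channel_numbers[cur]))
    return amp


def _run(model, protocol, n_beats, dt, noise_amp, seed, y, record_v,
         early_tol=0.0):
    eng = _engine()
    bcl_steps = int(round(protocol.bcl / dt))
    stim_steps = int(round(protocol.stim_duration / dt))
    apd_out = np.full(n_beats, np.nan)
    v_stride = max(int(round(1.0 / dt)), 1) if record_v else 0
    n_v = (n_beats * bcl_steps) // v_stride if record_v else 0
    v_out = np.empty(max(n_v, 1))
    done = _pace_kernel(
        y, eng.table, eng.edge_i, eng.edge_j, eng.edge_cf, eng.edge_cb,
        eng.edge_sch, eng.sch_start, eng.sch_n, eng.open_abs, model._gvec(),
        noise_amp, n_beats, bcl_steps, dt, protocol.stim_amplitude, stim_steps,
        seed, apd_out, v_out, v_stride, early_tol,
    )
    times = voltage = None
    if record_v:
        n_rec = (done * bcl_steps) // v_stride
        times = (np.arange(1, n_rec + 1)) * (v_stride * dt)
        voltage = v_out[:n_rec]
    return apd_out[:done], times, voltage


def pace_deterministic(
    model: CellModelInstance,
    protocol: PacingProtocol,
    dt: float = 0.02,
    record_v: bool = False,
    steady_tol: float = 0.01,
    initial_state: np.ndarray | None = None,
) -> PacingResult:
    """Deterministic pacing: prepace to steady state, then ``n_beats`` beats.

    Steady state is declared when the beat-to-beat APD change stays below
    ``steady_tol`` ms (or ``n_prepace_beats`` is reached).  A beat whose
    voltage never recrosses the 90% repolarization level is flagged as a
    repolarization failure (NaN APD), not raised.
    """
    y = (initial_state if initial_state is not None else default_state()).copy()
    amp = np.zeros(len(STOCHASTIC_CURRENTS))
    pre_apds, _, _ = _run(model, protocol, protocol.n_prepace_beats, dt, amp,
                          0, y, False, early_tol=steady_tol)
    apds, times, voltage = _run(model, protocol, protocol.n_beats, dt, amp,
                                0, y, record_v)
    return PacingResult(
        apds=apds,
        final_state=y,
        prepace_beats=len(pre_apds),
        repolarization_failure=bool(np.any(~np.isfinite(apds))
                                    or np.any(~np.isfinite(pre_apds))),
        times=times,
        voltage=voltage,
    )


def pace_stochastic(
    model: CellModelInstance,
    protocol: PacingProtocol,
    cfg: SDEConfig,
    initial_state: np.ndarray | None = None,
    repetition: int = 0,
    condition: str = "control",
) -> APDSequence:
    """A stochastic pacing train; returns the last ``n_analyze`` beats.

    The currents in ``model.stochastic_currents`` are integrated by the
    reflected SDE with noise magnitude 1/sqrt(N); everything else stays
    deterministic.  When ``initial_state`` is omitted the model is first
    prepaced deterministically to steady state.  Repetitions differ only by
    the RNG substream derived from ``(cfg.seed, repetition)``.
    """
    if not model.stochastic_currents:
        raise ValueError("pace_stochastic requires at least one stochastic current")
    if initial_state is None:
        det = pace_deterministic(model, protocol, dt=min(0.02, cfg.dt * 2),
                                 initial_state=None)
        y = det.final_state.copy()
    else:
        y = initial_state.copy()
    sub = int(np.random.SeedSequence((cfg.seed, repetition)).generate_state(1)[0])
    apds, _, _ = _run(model, protocol, protocol.n_beats, cfg.dt,
                      _noise_amp(model), sub % (2**32), y, False)
    analyzed = apds[-protocol.n_analyze:]
    return APDSequence(
        apd_values=analyzed,
        condition=condition,
        model_id=model.model_id,
        repetition=repetition,
        complete=bool(np.all(np.isfinite(analyzed))
                      and len(analyzed) == protocol.n_analyze),
    )


# --------------------------------------------------------------------------
# APD90 detection on sampled traces
# --------------------------------------------------------------------------

def apd90(times: np.ndarray, voltage: np.ndarray) -> float:
    """APD at 90% repolarization of a single-beat voltage trace.

    Measured from the instant of maximum upstroke velocity to the first
    downward crossing of ``V_peak - 0.9 (V_peak - V_rest)``, linearly
    interpolated between samples.  Returns NaN (repolarization-failure flag)
    when the trace has no upstroke or never recrosses the threshold.
    """
    t = np.asarray(times, float)
    v = np.asarray(voltage, float)
    if t.ndim != 1 or t.shape != v.shape or len(t) < 3:
        raise ValueError("need matching 1-d time and voltage arrays")
    v_rest = v[0]
    i_peak = int(np.argmax(v))
    v_peak = v[i_peak]
    if v_peak - v_rest < 10.0:
        return float("nan")  # no upstroke
    dvdt = np.diff(v) / np.diff(t)
    i_up = int(np.argmax(dvdt[: max(i_peak, 1)])) if i_peak > 0 else 0
    t_up = t[i_up]  # the steepest-rise sample interval starts here
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    after = np.arange(i_peak, len(v) - 1)
    for i in after:
        if v[i] >= v90 > v[i + 1]:
            tc = t[i] + (t[i + 1] - t[i]) * (v[i] - v90) / (v[i] - v[i + 1])
            return float(tc - t_up)
    return float("nan")


# --------------------------------------------------------------------------
# voltage clamp and stimulus threshold utilities
# --------------------------------------------------------------------------

def simulate_voltage_clamp(
    model: CellModelInstance,
    current: str,
    protocol: VoltageProtocol,
    output_dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic whole-cell current (pA) of one clamped current.

    Returns ``(t, I_pA, p_open)`` under the piecewise-constant voltage
    protocol, using the drug-free scaled conductance of ``model``.
    """
    from .sde import simulate_channel_ode

    scheme = cell_schemes()[current]
    traj = simulate_channel_ode(scheme, protocol, output_dt=output_dt)
    V = np.empty_like(traj.times)
    for t0, t1, vseg in protocol.segments():
        V[(traj.times >= t0) & (traj.times < t1)] = vseg
    p = traj.open_fraction
    scale = model.scaling_factors.get(current, 1.0)
    prm = model.params
    if current == "IKs":
        i = prm.g_Ks * scale * prm.Cm_pF * p * (V - E_KS)
    elif current == "IKr":
        i = prm.g_Kr * scale * prm.Cm_pF * p * ikr_rectification(V) * (V - E_K)
    elif current == "Ito1":
        i = prm.g_to1 * scale * prm.Cm_pF * p * (V - E_K)
    elif current == "ICaL":
        i = prm.p_CaL * scale * prm.Cm_pF * p * ghk_ca_driving(V)
    else:
        raise ValueError(f"unknown clamped current {current!r}")
    return traj.times, i, p


def find_diastolic_threshold(
    model: CellModelInstance,
    protocol: PacingProtocol | None = None,
    dt: float = 0.02,
    tol: float = 0.5,
) -> float:
    """Diastolic stimulus threshold (A/F) by bisection on a single beat."""
    protocol = protocol or PacingProtocol()
    y0 = default_state()
    lo, hi = 0.0, 200.0  # |amplitude|

    def elicits(amp_abs: float) -> bool:
        p = replace(protocol, stim_amplitude=-amp_abs, n_beats=1,
                    n_prepace_beats=0)
        y = y0.copy()
        apds, _, _ = _run(model, p, 1, dt,
                          np.zeros(len(STOCHASTIC_CURRENTS)), 0, y, False)
        return bool(np.isfinite(apds).all() and len(apds) == 1
                    and np.isfinite(apds[0]))

    if not elicits(hi):
        raise RuntimeError("no AP elicited even at the maximal test stimulus")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if elicits(mid):
            hi = mid
        else:
            lo = mid
    return -hi
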