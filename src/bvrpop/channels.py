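"""Single-channel current estimation and per-model channel numbers.

For currents with usable ensemble recordings (I_Ks, I_CaL) the single-channel
current ``i`` and channel count ``N`` follow from noise (fluctuation)
analysis: with binomially gating channels the ensemble variance obeys

    sigma^2(t) = i * I(t) - I(t)^2 / N

after baseline-variance subtraction.  Channel numbers per model are then
``N_x = I_x / (i_x p_x)`` evaluated on the model's own simulated clamp
traces.  For I_to1 and I_Kr, where clean ensembles are unavailable, ``N`` is
the whole-cell maximal conductance divided by a literature unitary
conductance (gamma_to1 = 19.722 pS, gamma_Kr = 2.5331 pS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import CellModelInstance, simulate_voltage_clamp
from .sde import VoltageProtocol

__all__ = [
    "CurrentEnsemble",
    "SingleChannelEstimate",
    "UnitaryConductance",
    "FluctuationFitError",
    "DEFAULT_I_KS_PA",
    "DEFAULT_I_CAL_PA",
    "GAMMA_TO1_PS",
    "GAMMA_KR_PS",
    "nonstationary_fluctuation_fit",
    "estimate_channel_numbers",
    "channels_from_current",
    "channels_from_conductance",
    "default_vc_protocol",
]

# single-channel current estimates from canine myocyte ensembles
DEFAULT_I_KS_PA = 0.15    # at +40 mV
DEFAULT_I_CAL_PA = -0.6   # at -15 mV
# literature unitary conductances (temperature / [K+]o corrected)
GAMMA_TO1_PS = 19.722
GAMMA_KR_PS = 2.5331

#: test potential (mV) at which the single-channel current was quoted
EVAL_POTENTIAL = {"IKs": 40.0, "ICaL": -15.0}


class FluctuationFitError(RuntimeError):
    """Degenerate ensemble or non-physical variance-mean fit."""


@dataclass
class CurrentEnsemble:
    """Repeated current sweeps (pA) on a common time base (ms)."""

    times: np.ndarray
    traces: np.ndarray          # (n_sweeps, n_times)
    current: str = ""
    holding_mV: float = -40.0
    test_mV: float = 0.0
    pulse_start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.traces = np.atleast_2d(np.asarray(self.traces, float))
        if self.traces.shape[1] != len(self.times):
            raise ValueError("traces and times have mismatched lengths")
        if self.traces.shape[0] < 2:
            raise ValueError("nonstationary analysis needs at least 2 sweeps")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times})
        for k, tr in enumerate(self.traces):
            df[f"sweep_{k}"] = tr
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "CurrentEnsemble":
        sweeps = [c for c in df.columns if c.startswith("sweep_")]
        return cls(df["time_ms"].to_numpy(),
                   df[sweeps].to_numpy().T, **kwargs)


@dataclass(frozen=True)
class SingleChannelEstimate:
    """Result of a fluctuation-analysis fit."""

    i_pA: float
    N: float
    method: str
    test_mV: float
    residual_norm: float
    n_sweeps: int


@dataclass(frozen=True)
class UnitaryConductance:
    gamma_pS: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gamma_pS > 0:
            raise ValueError("unitary conductance must be positive")


def nonstationary_fluctuation_fit(
    ensemble: CurrentEnsemble,
    n_bins: int = 20,
    method: str = "nonstationary",
) -> SingleChannelEstimate:
    """Fit ``sigma^2 = i I - I^2/N`` to the ensemble variance-mean relation.

    Nonstationary mode uses the across-sweep mean and variance at each time
    point of the test pulse, after subtracting the baseline variance measured
    over the pre-pulse segment; points are pooled into ``n_bins``
    equal-occupancy bins in I before the zero-intercept least-squares fit.
    Stationary mode uses per-sweep steady-state segment means/variances with
    the same parabolic law.
    """
    t = ensemble.times
    pre = t < ensemble.pulse_start_ms
    post = ~pre
    if method == "nonstationary":
        mean_i = ensemble.traces[:, post].mean(axis=0)
        var_i = ensemble.traces[:, post].var(axis=0, ddof=1)
        baseline_var = (float(ensemble.traces[:, pre].var(axis=0, ddof=1).mean())
                        if pre.any() else 0.0)
        baseline_mean = (float(ensemble.traces[:, pre].mean()) if pre.any() else 0.0)
        I = mean_i - baseline_mean
        s2 = var_i - baseline_var
    elif method == "stationary":
        # last half of the pulse treated as the steady-state segment
        seg = post & (t >= t[post].min() + 0.5 * (t[post].max() - t[post].min()))
        I = ensemble.traces[:, seg].mean(axis=1)
        s2 = ensemble.traces[:, seg].var(axis=1, ddof=1)
        if pre.any():
            I = I - ensemble.traces[:, pre].mean()
            s2 = s2 - ensemble.traces[:, pre].var(axis=1, ddof=1)
    else:
        raise ValueError("method must be 'nonstationary' or 'stationary'")

    if np.allclose(s2, 0.0, atol=1e-12) or np.ptp(I) < 1e-12:
        raise FluctuationFitError("degenerate ensemble: no excess variance")

    # equal-occupancy binning in I stabilizes the parabola fit
    order = np.argsort(np.abs(I))
    I, s2 = I[order], s2[order]
    n_bins = min(n_bins, len(I))
    bins = np.array_split(np.arange(len(I)), n_bins)
    Ib = np.array([I[b].mean() for b in bins])
    s2b = np.array([s2[b].mean() for b in bins])

    # sigma^2 = i*I - I^2/N  ->  least squares on columns [I, -I^2]
    design = np.column_stack([Ib, -Ib**2])
    coef, res, _, _ = np.linalg.lstsq(design, s2b, rcond=None)
    i_hat, inv_n = coef
    if inv_n <= 0:
        raise FluctuationFitError("fitted channel count is non-positive")
    resid = float(np.sqrt(res[0])) if len(res) else float(
        np.linalg.norm(design @ coef - s2b))
    return SingleChannelEstimate(
        i_pA=float(i_hat),
        N=float(1.0 / inv_n),
        method=method,
        test_mV=ensemble.test_mV,
        residual_norm=resid,
        n_sweeps=ensemble.traces.shape[0],
    )


def channels_from_current(I_pA: float, i_pA: float, p_open: float) -> int:
    """N = I / (i p), rounded to the nearest integer (at least 1)."""
    if p_open < 1e-6:
        raise ValueError("open probability too small for a stable estimate")
    n = I_pA / (i_pA * p_open)
    if n <= 0:
        raise ValueError("estimated channel number is non-positive")
    return max(int(round(n)), 1)


def channels_from_conductance(g_nS: float, gamma_pS: float) -> int:
    """N = g / gamma with g in nS and gamma in pS, rounded (at least 1)."""
    if gamma_pS <= 0:
        raise ValueError("unitary conductance must be positive")
    n = g_nS * 1e3 / gamma_pS
    if n <= 0:
        raise ValueError("estimated channel number is non-positive")
    return max(int(round(n)), 1)


def default_vc_protocol(current: str, test_mV: float) -> VoltageProtocol:
    """Holding at -40 mV then a test pulse, as in the clamp experiments."""
    pulse = 300.0 if current == "ICaL" else 5000.0
    return VoltageProtocol.step(hold=-40.0, test=test_mV, t_step=50.0,
                                duration=50.0 + pulse)


def estimate_channel_numbers(
    model: CellModelInstance,
    i_Ks: float = DEFAULT_I_KS_PA,
    i_CaL: float = DEFAULT_I_CAL_PA,
    gamma_to1: float = GAMMA_TO1_PS,
    gamma_Kr: float = GAMMA_KR_PS,
) -> dict[str, int]:
    """Channel numbers (N_Kr, N_Ks, N_to1, N_CaL) for one model.

    I_Ks and I_CaL clamp traces are simulated at the potentials where the
    experimental single-channel currents were quoted (+40 / -15 mV) and
    ``N = I/(i p)`` is evaluated at the instant of peak |I| during the test
    pulse.  N_to1 and N_Kr divide the model's scaled whole-cell maximal
    conductance by the literature unitary conductance.
    """
    numbers: dict[str, int] = {}
    for cur, i_single in (("IKs", i_Ks), ("ICaL", i_CaL)):
        proto = default_vc_protocol(cur, EVAL_POTENTIAL[cur])
        t, I, p = simulate_voltage_clamp(model, cur, proto, output_dt=1.0)
        in_pulse = t >= 50.0
        k = int(np.argmax(np.abs(I[in_pulse])))
        idx = np.flatnonzero(in_pulse)[k]
        numbers[f"N_{cur[1:]}"] = channels_from_current(I[idx], i_single, p[idx])
    prm = model.params
    g_to1 = prm.g_to1 * model.scaling_factors.get("Ito1", 1.0) * prm.Cm_pF
    g_kr = prm.g_Kr * model.scaling_factors.get("IKr", 1.0) * prm.Cm_pF
    numbers["N_to1"] = channels_from_conductance(g_to1, gamma_to1)
    numbers["N_Kr"] = channels_from_conductance(g_kr, gamma_Kr)
    return {
        "IKr": numbers["N_Kr"],
        "IKs": numbers["N_Ks"],
        "Ito1": numbers["N_to1"],
        "ICaL": numbers["N_CaL"],
    }
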