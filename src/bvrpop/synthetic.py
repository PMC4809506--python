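"""Synthetic experimental inputs with known ground truth.

Every measured input of the study pipeline can be emulated: voltage-clamp
current ensembles with channel noise (generated by the exact Gillespie
oracle, so they are independent of the SDE estimator under test),
calibration statistics (either configured directly or computed from a known
reference-model subset, enabling parameter-recovery tests), and Gaussian
AR(1) APD sequences with configurable moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import BLOCK_CONDITIONS, ExperimentalStats, condition_apds
from .cell import APDSequence, CONDITION_BLOCKS, PacingProtocol, cell_schemes
from .channels import CurrentEnsemble
from .markov import MarkovScheme
from .sde import VoltageProtocol, simulate_channel_ssa

__all__ = [
    "SyntheticVCConfig",
    "SyntheticCalibrationConfig",
    "generate_vc_ensemble",
    "generate_calibration_targets",
    "generate_apd_sequences",
    "fluctuation_test_scheme",
]


def fluctuation_test_scheme(tau_ms: float = 20.0, p_inf: float = 0.65):
    """Two-state activation gate for fluctuation-analysis recovery tests.

    Closed at the holding potential, opens at depolarized potentials with
    time constant ``tau_ms`` toward ``p_inf``.  The fast kinetics give each
    sweep many decorrelation times, so a 50-sweep ensemble carries enough
    information for the variance-mean fit; currents with second-scale
    activation (such as the slow delayed rectifier) would need far longer
    records for the same precision.
    """
    from .markov import hh_gate_scheme

    alpha = p_inf / tau_ms
    beta = (1.0 - p_inf) / tau_ms
    return hh_gate_scheme(
        "vc_test_gate",
        f"({alpha!r})/(1+exp(-(V-0.0)/5.0))",
        f"{beta!r}",
    )


@dataclass(frozen=True)
class SyntheticVCConfig:
    """Ground truth for one synthetic clamp ensemble."""

    scheme: str = "IKs"          # name of a cell scheme, or a MarkovScheme
    N_true: int = 1000
    i_true_pA: float = 0.15
    hold_mV: float = -40.0
    test_mV: float = 40.0
    pulse_start_ms: float = 50.0
    pulse_ms: float = 2000.0
    n_pulses: int = 1            # repeated test pulses per sweep
    inter_pulse_ms: float = 150.0  # holding gap letting gating reset
    sweeps: int = 7
    baseline_sd_pA: float = 0.5
    output_dt: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sweeps < 2:
            raise ValueError("need at least 2 sweeps")
        if self.N_true < 1:
            raise ValueError("N_true must be at least 1")


def generate_vc_ensemble(cfg: SyntheticVCConfig,
                         scheme: MarkovScheme | None = None) -> CurrentEnsemble:
    """Clamp sweeps of ``N_true`` channels: i * (open count) + baseline noise.

    Each sweep is an independent Gillespie sample path, so the ensemble mean
    approaches ``N i p(t)`` and the excess variance obeys the binomial law
    ``sigma^2 = i I - I^2/N`` exactly.
    """
    scheme = scheme or cell_schemes()[cfg.scheme]
    times = [0.0]
    volts = [cfg.hold_mV]
    t = cfg.pulse_start_ms
    for k in range(cfg.n_pulses):
        times.append(t)
        volts.append(cfg.test_mV)
        t += cfg.pulse_ms
        if k < cfg.n_pulses - 1:
            times.append(t)
            volts.append(cfg.hold_mV)
            t += cfg.inter_pulse_ms
    proto = VoltageProtocol(np.array(times), np.array(volts), t)
    rng = np.random.default_rng(cfg.seed)
    sweep_seeds = rng.integers(0, 2**31 - 1, size=cfg.sweeps)
    traces = []
    times = None
    for s in range(cfg.sweeps):
        traj = simulate_channel_ssa(scheme, proto, cfg.N_true,
                                    int(sweep_seeds[s]), output_dt=cfg.output_dt)
        times = traj.times
        open_count = traj.open_fraction * cfg.N_true
        noise = rng.normal(0.0, cfg.baseline_sd_pA, size=len(times)) \
            if cfg.baseline_sd_pA > 0 else 0.0
        traces.append(cfg.i_true_pA * open_count + noise)
    return CurrentEnsemble(
        times=times,
        traces=np.array(traces),
        current=cfg.scheme if isinstance(cfg.scheme, str) else scheme.name,
        holding_mV=cfg.hold_mV,
        test_mV=cfg.test_mV,
        pulse_start_ms=cfg.pulse_start_ms,
    )


# --------------------------------------------------------------------------
# calibration statistics
# --------------------------------------------------------------------------

def _default_apd_means() -> dict[str, float]:
    # plausible canine-epicardial APD90 scale at 1 Hz
    return {"control": 230.0, "IKr_block": 330.0, "IKs_block": 245.0,
            "ICaL_block": 160.0, "IKs_Ito1_block": 270.0}


@dataclass(frozen=True)
class SyntheticCalibrationConfig:
    """Configured stand-in for the experimental calibration ranges.

    Default SDs are 10% of the means, which yields non-trivial acceptance
    fractions over the [0, 2] scaling cube.
    """

    apd_means: dict = field(default_factory=_default_apd_means)
    apd_sds: dict | None = None
    dapd_means: dict | None = None
    dapd_sds: dict | None = None
    conductance_mean: float = 1.0
    conductance_sd: float = 0.3
    sd_floor_ms: float = 0.0
    seed: int = 0

    def resolved(self) -> ExperimentalStats:
        apd_sds = self.apd_sds or {c: 0.1 * m for c, m in self.apd_means.items()}
        dapd_means = self.dapd_means or {
            c: self.apd_means[c] - self.apd_means["control"]
            for c in BLOCK_CONDITIONS}
        dapd_sds = self.dapd_sds or {c: max(0.1 * abs(m), 5.0)
                                     for c, m in dapd_means.items()}
        return ExperimentalStats(
            conductance={c: (self.conductance_mean, self.conductance_sd)
                         for c in ("IKr", "IKs", "Ito1", "ICaL", "IK1")},
            apd={c: (m, max(apd_sds[c], self.sd_floor_ms))
                 for c, m in self.apd_means.items()},
            dapd={c: (m, max(dapd_sds[c], self.sd_floor_ms))
                  for c, m in dapd_means.items()},
        )


def generate_calibration_targets(
    cfg: SyntheticCalibrationConfig | None = None,
    reference_models: list | None = None,
    protocol: PacingProtocol | None = None,
    dt: float = 0.02,
    sd_floor_ms: float = 0.0,
    on_failure: str = "raise",
) -> ExperimentalStats:
    """Experimental-style calibration statistics.

    With ``reference_models`` the means and SDs are computed from those
    models' own deterministic APDs/ΔAPDs (the parameter-recovery setup);
    otherwise the configured values are used.  A reference model with
    repolarization failure under any condition raises by default, or is
    dropped with ``on_failure="skip"``.
    """
    if reference_models:
        protocol = protocol or PacingProtocol(n_beats=5)
        apds: dict[str, list[float]] = {c: [] for c in CONDITION_BLOCKS}
        dapds: dict[str, list[float]] = {c: [] for c in BLOCK_CONDITIONS}
        n_used = 0
        for model in reference_models:
            apd, dapd, failed = condition_apds(model, protocol, dt=dt)
            if failed:
                if on_failure == "skip":
                    continue
                raise ValueError(
                    f"reference model {model.model_id} fails to repolarize")
            n_used += 1
            for c in apds:
                apds[c].append(apd[c])
            for c in dapds:
                dapds[c].append(dapd[c])
        if n_used < 2:
            raise ValueError("fewer than 2 usable reference models")

        def stat(vals: list[float]) -> tuple[float, float]:
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            return float(arr.mean()), max(sd, sd_floor_ms)

        cond_sd = (cfg.conductance_sd if cfg else 0.3)
        cond_mean = (cfg.conductance_mean if cfg else 1.0)
        return ExperimentalStats(
            conductance={c: (cond_mean, cond_sd)
                         for c in ("IKr", "IKs", "Ito1", "ICaL", "IK1")},
            apd={c: stat(v) for c, v in apds.items()},
            dapd={c: stat(v) for c, v in dapds.items()},
        )
    if cfg is None:
        raise ValueError("need either a configuration or reference models")
    return cfg.resolved()


# --------------------------------------------------------------------------
# APD sequences
# --------------------------------------------------------------------------

def generate_apd_sequences(
    n_sequences: int,
    length: int = 30,
    mean: float = 250.0,
    sd: float = 5.0,
    correlation: float = 0.0,
    seed: int = 0,
    condition: str = "synthetic",
) -> list[APDSequence]:
    """Gaussian AR(1) APD sequences with stationary mean/SD and lag-1 rho."""
    if not abs(correlation) < 1.0:
        raise ValueError("lag-1 correlation must satisfy |rho| < 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    innov_sd = sd * np.sqrt(1.0 - correlation**2)
    for k in range(n_sequences):
        x = np.empty(length)
        x[0] = mean + sd * rng.standard_normal()
        for n in range(1, length):
            x[n] = mean + correlation * (x[n - 1] - mean) \
                + innov_sd * rng.standard_normal()
        out.append(APDSequence(x, condition=condition, model_id=f"synthetic_{k}",
                               repetition=k))
    return out
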