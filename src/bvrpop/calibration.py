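"""Population construction and experimental calibration.

Candidate models are generated by Latin hypercube sampling of conductance
scaling factors in [0, 2] (plus or minus 100% of baseline) for I_Kr, I_Ks,
I_to1, I_CaL and I_K1.  Calibration is accept/reject: a candidate is kept
only if (a) every scaling factor lies within 2.35 standard deviations of the
mean of the normalized experimental maximal-current sample, and (b) its
deterministic APD under control and four pharmacological blocks, and the
four block-induced APD changes, all lie within 2.35 standard deviations of
the corresponding experimental means (covering ~98% of a Gaussian sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .cell import (
    BlockSpec,
    CellModelInstance,
    CONDITION_BLOCKS,
    PacingProtocol,
    apply_block,
    pace_deterministic,
)

__all__ = [
    "ScalingSample",
    "ExperimentalStats",
    "CalibratedSet",
    "SCALED_CURRENTS",
    "BLOCK_CONDITIONS",
    "latin_hypercube_sample",
    "conductance_bound_filter",
    "calibrate_population",
    "condition_apds",
]

SCALED_CURRENTS = ("IKr", "IKs", "Ito1", "ICaL", "IK1")
BLOCK_CONDITIONS = ("IKr_block", "IKs_block", "ICaL_block", "IKs_Ito1_block")
SD_MULTIPLE = 2.35


@dataclass(frozen=True)
class ScalingSample:
    """One conductance scaling vector, each multiplier in [0, 2]."""

    factors: dict

    def __post_init__(self) -> None:
        for cur, v in self.factors.items():
            if not 0.0 <= v <= 2.0:
                raise ValueError(f"scaling factor for {cur} outside [0, 2]")


@dataclass(frozen=True)
class ExperimentalStats:
    """Mean and SD of every calibration quantity.

    ``conductance``: per current, normalized maximal-current (mean, sd) on the
    scaling-factor scale (baseline = 1).  ``apd``: per condition (ms).
    ``dapd``: per block condition, APD_drug - APD_control (ms).
    """

    conductance: dict = field(default_factory=dict)
    apd: dict = field(default_factory=dict)
    dapd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group in (self.conductance, self.apd, self.dapd):
            for key, (_, sd) in group.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {key}")

    def window(self, group: str, key: str) -> tuple[float, float]:
        mean, sd = getattr(self, group)[key]
        return mean - SD_MULTIPLE * sd, mean + SD_MULTIPLE * sd

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group in ("conductance", "apd", "dapd"):
            for key, (m, s) in getattr(self, group).items():
                rows.append({"quantity": group, "condition": key,
                             "mean": m, "sd": s})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentalStats":
        groups: dict[str, dict] = {"conductance": {}, "apd": {}, "dapd": {}}
        for _, row in df.iterrows():
            groups[str(row["quantity"])][str(row["condition"])] = (
                float(row["mean"]), float(row["sd"]))
        return cls(**groups)


@dataclass
class CalibratedSet:
    """Accepted models with their per-condition APD records."""

    models: list
    records: pd.DataFrame  # one row per candidate, accepted or not

    def __len__(self) -> int:
        return len(self.models)

    @property
    def accepted_ids(self) -> list[str]:
        return [m.model_id for m in self.models]


def latin_hypercube_sample(
    n: int, dims: int, lo: float = 0.0, hi: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Stratified Latin hypercube sample: one point per equal bin per axis."""
    if n < 1:
        raise ValueError("need at least one sample")
    if not lo < hi:
        raise ValueError("lo must be smaller than hi")
    sampler = qmc.LatinHypercube(d=dims, seed=seed)
    return lo + (hi - lo) * sampler.random(n)


def conductance_bound_filter(
    samples: list[ScalingSample] | np.ndarray,
    stats: ExperimentalStats,
    currents: tuple[str, ...] = SCALED_CURRENTS,
) -> np.ndarray:
    """Boolean mask: sample accepted iff every factor is within mean +- 2.35 SD.

    Interval boundaries are inclusive ("up to 2.35 standard deviations").
    """
    missing = [c for c in currents if c not in stats.conductance]
    if missing:
        raise KeyError(f"no conductance stats for {missing}")
    mask = []
    for s in samples:
        factors = s.factors if isinstance(s, ScalingSample) else dict(
            zip(currents, np.asarray(s, float)))
        ok = True
        for cur in currents:
            lo, hi = stats.window("conductance", cur)
            if not lo <= factors[cur] <= hi:
                ok = False
                break
        mask.append(ok)
    return np.array(mask, dtype=bool)


def condition_apds(
    model: CellModelInstance,
    protocol: PacingProtocol,
    dt: float = 0.02,
    conditions: dict[str, dict[str, float]] | None = None,
) -> tuple[dict[str, float], dict[str, float], bool]:
    """Deterministic APD per condition and ΔAPD per block for one model.

    APD is the mean over the final ``protocol.n_beats`` beats after
    steady-state pacing; ΔAPD = APD(drug) - APD(control).  Returns
    ``(apd, dapd, failed)`` where ``failed`` marks repolarization failure
    under any condition.
    """
    conditions = conditions if conditions is not None else CONDITION_BLOCKS
    apd: dict[str, float] = {}
    failed = False
    for cond, fractions in conditions.items():
        m = apply_block(model, BlockSpec(fractions)) if fractions else model
        res = pace_deterministic(m, protocol, dt=dt)
        if res.repolarization_failure or not len(res.apds):
            failed = True
            apd[cond] = float("nan")
        else:
            apd[cond] = float(np.mean(res.apds))
    dapd = {c: apd[c] - apd["control"] for c in conditions if c != "control"}
    return apd, dapd, failed


def calibrate_population(
    candidates: list[CellModelInstance],
    stats: ExperimentalStats,
    protocol: PacingProtocol | None = None,
    dt: float = 0.02,
) -> CalibratedSet:
    """Pace every candidate under the five conditions and apply the APD filters.

    A candidate is accepted iff its five APD values and four ΔAPD values all
    fall inside the corresponding mean +- 2.35 SD windows (inclusive) and no
    condition shows repolarization failure.  The nine criteria are a pure
    conjunction, so evaluation order does not matter.
    """
    protocol = protocol or PacingProtocol(n_beats=5, n_prepace_beats=1000)
    needed_apd = set(CONDITION_BLOCKS)
    if not needed_apd <= set(stats.apd):
        raise KeyError(f"missing APD stats for {sorted(needed_apd - set(stats.apd))}")
    if not set(BLOCK_CONDITIONS) <= set(stats.dapd):
        raise KeyError("missing ΔAPD stats for some block condition")

    rows = []
    accepted = []
    for model in candidates:
        apd, dapd, failed = condition_apds(model, protocol, dt=dt)
        row: dict = {"model_id": model.model_id, "failed": failed}
        ok = not failed
        for cond in ("control",) + BLOCK_CONDITIONS:
            lo, hi = stats.window("apd", cond)
            passed = (not np.isnan(apd[cond])) and lo <= apd[cond] <= hi
            row[f"APD_{cond}"] = apd[cond]
            row[f"pass_APD_{cond}"] = passed
            ok = ok and passed
        for cond in BLOCK_CONDITIONS:
            lo, hi = stats.window("dapd", cond)
            passed = (not np.isnan(dapd[cond])) and lo <= dapd[cond] <= hi
            row[f"dAPD_{cond}"] = dapd[cond]
            row[f"pass_dAPD_{cond}"] = passed
            ok = ok and passed
        row["accepted"] = ok
        rows.append(row)
        if ok:
            accepted.append(model)
    return CalibratedSet(models=accepted, records=pd.DataFrame(rows))
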