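"""Beat-to-beat repolarization variability (BVR) quantification.

Over an L-beat APD sequence (L = 30 in the standard protocol):

    STV = sum_{n=2}^{L} |APD_n - APD_{n-1}| / (2 (L-1))
    LTV = sum_{n=2}^{L} |APD_n + APD_{n-1} - 2 mean(APD)| / (2 (L-1))
    ran = max(APD) - min(APD)
    var = variance of the APD values

STV and LTV are the mean distances perpendicular to and along the identity
line of the Poincare plot (APD_n vs APD_{n+1}).  Contribution analysis
re-runs the stochastic trains with noise restricted to single currents and
expresses each measure as a percentage of the all-currents-stochastic case.
Attribution uses linear partial correlation between per-model channel
numbers and BVR, controlling for the other channel numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .cell import (
    APDSequence,
    BlockSpec,
    CellModelInstance,
    PacingProtocol,
    apply_block,
    pace_deterministic,
    pace_stochastic,
)
from .sde import SDEConfig

__all__ = [
    "BVRMeasures",
    "PartialCorrelationResult",
    "MEASURE_NAMES",
    "bvr_measures",
    "poincare",
    "contribution_analysis",
    "run_condition_trains",
    "partial_correlation",
    "partial_correlation_analysis",
]

log = logging.getLogger(__name__)

MEASURE_NAMES = ("ran_APD", "var_APD", "STV_APD", "LTV_APD")


@dataclass(frozen=True)
class BVRMeasures:
    """The four BVR measures of one sequence (ms, ms^2, ms, ms)."""

    ran_APD: float
    var_APD: float
    STV_APD: float
    LTV_APD: float
    n_beats: int

    def as_dict(self) -> dict[str, float]:
        return {"ran_APD": self.ran_APD, "var_APD": self.var_APD,
                "STV_APD": self.STV_APD, "LTV_APD": self.LTV_APD}


def _values(seq) -> np.ndarray:
    if isinstance(seq, APDSequence):
        if not seq.complete:
            raise ValueError("sequence contains failure-flagged beats")
        return seq.apd_values
    return np.asarray(seq, float)


def bvr_measures(seq, expected_length: int | None = None) -> BVRMeasures:
    """Compute (ran, var, STV, LTV) for one APD sequence.

    ``expected_length`` (default: accept any L >= 2) enforces the standard
    30-beat window; denominators generalize to 2 (L-1).
    """
    x = _values(seq)
    if expected_length is not None and len(x) != expected_length:
        raise ValueError(f"expected {expected_length} beats, got {len(x)}")
    if len(x) < 2:
        raise ValueError("need at least 2 beats")
    if np.any(~np.isfinite(x)):
        raise ValueError("sequence contains non-finite APD values")
    L = len(x)
    diffs = np.diff(x)
    stv = float(np.sum(np.abs(diffs)) / (2.0 * (L - 1)))
    ltv = float(np.sum(np.abs(x[1:] + x[:-1] - 2.0 * x.mean())) / (2.0 * (L - 1)))
    return BVRMeasures(
        ran_APD=float(np.ptp(x)),
        var_APD=float(np.var(x)),
        STV_APD=stv,
        LTV_APD=ltv,
        n_beats=L,
    )


def poincare(seq) -> tuple[np.ndarray, float | None]:
    """Poincare pairs (APD_n, APD_{n+1}) and the STV/LTV ratio.

    The ratio is ``None`` (flagged missing) when LTV = 0.
    """
    x = _values(seq)
    if len(x) < 2:
        raise ValueError("Poincare plot needs at least 2 beats")
    pairs = np.column_stack([x[:-1], x[1:]])
    m = bvr_measures(x)
    ratio = None if m.LTV_APD == 0.0 else m.STV_APD / m.LTV_APD
    return pairs, ratio


# --------------------------------------------------------------------------
# contribution analysis
# --------------------------------------------------------------------------

def run_condition_trains(
    models: list[CellModelInstance],
    subset: frozenset | set,
    protocol: PacingProtocol,
    cfg: SDEConfig,
    n_reps: int,
    block: dict[str, float] | None = None,
    condition: str = "control",
    det_cache: dict | None = None,
) -> pd.DataFrame:
    """Stochastic trains for every (model, repetition) with one noise subset.

    Returns one row per model with each measure averaged over repetitions
    (and the number of excluded failed trains).  With an empty subset the
    deterministic limit is returned (all measures identically 0).
    ``det_cache`` memoizes the deterministic prepace per model across noise
    subsets of the same condition.
    """
    rows = []
    for model in models:
        m = apply_block(model, BlockSpec(block)) if block else model
        if det_cache is not None and model.model_id in det_cache:
            det = det_cache[model.model_id]
        else:
            det = pace_deterministic(m, protocol, dt=0.02)
            if det_cache is not None:
                det_cache[model.model_id] = det
        failures = 0
        if not subset:
            zero = {k: 0.0 for k in MEASURE_NAMES}
            rows.append({"model_id": model.model_id, **zero, "n_failed": 0,
                         "mean_APD": float(np.mean(det.apds))})
            continue
        ms = m.with_stochastic(subset)
        per_rep = []
        for rep in range(n_reps):
            seq = pace_stochastic(ms, protocol, cfg,
                                  initial_state=det.final_state,
                                  repetition=rep, condition=condition)
            if not seq.complete:
                failures += 1
                continue
            per_rep.append(bvr_measures(seq).as_dict())
        if failures:
            log.warning("%s/%s: excluded %d failed trains under %s",
                        model.model_id, sorted(subset), failures, condition)
        if not per_rep:
            rows.append({"model_id": model.model_id,
                         **{k: np.nan for k in MEASURE_NAMES},
                         "n_failed": failures, "mean_APD": np.nan})
            continue
        df = pd.DataFrame(per_rep)
        rows.append({"model_id": model.model_id,
                     **df.mean().to_dict(), "n_failed": failures,
                     "mean_APD": float(np.mean(det.apds))})
    return pd.DataFrame(rows)


def contribution_analysis(
    models: list[CellModelInstance],
    subsets: list[frozenset],
    protocol: PacingProtocol,
    cfg: SDEConfig,
    n_reps: int,
    block: dict[str, float] | None = None,
    condition: str = "control",
) -> tuple[pd.DataFrame, dict[frozenset, pd.DataFrame]]:
    """Per-subset contribution of channel noise to each BVR measure.

    For each model x subset, ``n_reps`` trains are run and each measure is
    averaged over repetitions; the table reports mean and SD across models
    and the percentage of the all-currents-stochastic mean.  ``subsets`` must
    include the all-currents subset.
    """
    subsets = [frozenset(s) for s in subsets]
    full = max(subsets, key=len)
    if any(s - full for s in subsets):
        raise ValueError("subsets must include the all-currents subset")
    det_cache: dict = {}
    per_subset: dict[frozenset, pd.DataFrame] = {}
    for s in subsets:
        per_subset[s] = run_condition_trains(
            models, s, protocol, cfg, n_reps, block=block, condition=condition,
            det_cache=det_cache)
    ref = per_subset[full][list(MEASURE_NAMES)].mean()
    rows = []
    for s in subsets:
        df = per_subset[s]
        row: dict = {"subset": "+".join(sorted(s)) if s else "none"}
        for meas in MEASURE_NAMES:
            row[f"{meas}_mean"] = df[meas].mean()
            row[f"{meas}_sd"] = df[meas].std(ddof=1)
            row[f"{meas}_pct"] = (100.0 * df[meas].mean() / ref[meas]
                                  if ref[meas] > 0 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows), per_subset


# --------------------------------------------------------------------------
# partial correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrelationResult:
    variable: str
    measure: str
    coefficient: float
    p_value: float
    significant: bool
    n: int


def partial_correlation(x: np.ndarray, y: np.ndarray, Z: np.ndarray
                        ) -> tuple[float, float]:
    """Pearson correlation of x and y after regressing out the columns of Z.

    The p-value is the t-transform with ``n - 2 - k`` degrees of freedom,
    where k is the number of controlling variables.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.shape[0] != len(x):
        Z = Z.T
    n, k = Z.shape
    if len(y) != n or n - 2 - k < 1:
        raise ValueError("insufficient degrees of freedom for partial correlation")
    design = np.column_stack([np.ones(n), Z])
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise np.linalg.LinAlgError("collinear control design "
                                    f"(condition number {cond:.2g})")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ValueError("constant residuals: partial correlation undefined")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * sstats.t.sf(abs(tstat), dof)
    return r, float(p)


def partial_correlation_analysis(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    measure: str = "",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[PartialCorrelationResult]:
    """Partial correlation of each channel-number column with a BVR measure.

    For each column, the other columns are the controls.  Significance is a
    per-test p <= alpha; an optional Benjamini-Hochberg switch (off by
    default) adjusts across the columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    if (X.nunique() <= 1).any():
        raise ValueError("constant channel-number column in the design")
    out = []
    for col in X.columns:
        controls = X.drop(columns=[col]).to_numpy()
        r, p = partial_correlation(X[col].to_numpy(), y, controls)
        out.append([col, r, p])
    pvals = np.array([row[2] for row in out])
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        sig = pvals <= alpha
    return [
        PartialCorrelationResult(variable=str(col), measure=measure,
                                 coefficient=r, p_value=p,
                                 significant=bool(s), n=len(y))
        for (col, r, p), s in zip(out, sig)
    ]
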