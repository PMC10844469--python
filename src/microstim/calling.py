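"""Calibration-cutoff activation calling and fraction-activated estimation.

A calibration sample of resting cells defines the activation cutoff as the
95th percentile of resting nuclear/cytoplasmic ratios; cells strictly above
the cutoff are called activated, so a resting population is called at a
~5% false-positive rate by construction.  The fraction activated in an
experiment carries bootstrap uncertainty (resampling cells with
replacement).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "ExperimentResult",
    "fit_cutoff",
    "call_activation",
    "fraction_activated",
    "serial_dilution_factor",
]

MIN_CALIBRATION_N = 20


@dataclass(frozen=True)
class CalibrationModel:
    """Resting-population ratio sample and the derived activation cutoff.

    The cutoff is the empirical ``quantile`` of the resting sample, computed
    with the linear-interpolation convention (numpy's default "linear"
    method between order statistics).
    """

    resting_sample: np.ndarray
    cutoff: float
    quantile: float = 0.95

    def to_json(self, path) -> None:
        sample = np.asarray(self.resting_sample, dtype=float)
        payload = {
            "quantile": self.quantile,
            "cutoff": self.cutoff,
            "resting_sample": sample.tolist(),
            "sample_sha256": hashlib.sha256(sample.tobytes()).hexdigest(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        sample = np.asarray(payload["resting_sample"], dtype=float)
        digest = hashlib.sha256(sample.tobytes()).hexdigest()
        if digest != payload["sample_sha256"]:
            raise ValueError("calibration file corrupted: sample hash mismatch")
        return cls(resting_sample=sample, cutoff=payload["cutoff"], quantile=payload["quantile"])


def fit_cutoff(resting_ratios, quantile: float = 0.95) -> CalibrationModel:
    """Fit the activation cutoff at the top (1 - quantile) of resting ratios.

    Requires at least 20 positive resting ratios; with the default
    quantile of 0.95 a fresh resting sample is called activated at ~5%.
    """
    sample = np.asarray(resting_ratios, dtype=float)
    if sample.size < MIN_CALIBRATION_N:
        raise ValueError(
            f"calibration needs at least {MIN_CALIBRATION_N} resting ratios, got {sample.size}"
        )
    if not np.all(np.isfinite(sample)) or np.any(sample <= 0):
        raise ValueError("resting ratios must be positive and finite")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be strictly between 0 and 1")
    cutoff = float(np.quantile(sample, quantile, method="linear"))
    return CalibrationModel(resting_sample=sample, cutoff=cutoff, quantile=quantile)


def call_activation(cells: pd.DataFrame, model: CalibrationModel) -> pd.DataFrame:
    """Write activation calls (ratio strictly above cutoff) to ``called``.

    Ties at the cutoff are conservatively not called.  Only the ``called``
    column is touched; ground-truth flags are untouched.
    """
    missing = cells.index[cells["nuc_cyt_ratio"].isna()]
    if len(missing):
        ids = cells.loc[missing, "cell_id"].tolist()
        raise ValueError(f"cells missing nuc_cyt_ratio: {ids}")
    out = cells.copy()
    out["called"] = pd.array(
        cells["nuc_cyt_ratio"].to_numpy(dtype=float) > model.cutoff, dtype="boolean"
    )
    return out


@dataclass(frozen=True)
class ExperimentResult:
    """Fraction activated with bootstrap uncertainty for one experiment/group."""

    n_cells: int
    n_activated: int
    fraction_activated: float
    bootstrap_se: float
    ci_low: float
    ci_high: float
    condition: dict = field(default_factory=dict)
    flagged: bool = False  # e.g. empty selection

    def __post_init__(self) -> None:
        if self.n_cells and not (
            0 <= self.fraction_activated <= 1 and self.n_activated <= self.n_cells
        ):
            raise ValueError("inconsistent activation counts")


def _extract_calls(cells) -> np.ndarray:
    if isinstance(cells, pd.DataFrame):
        called = cells["called"]
        if called.isna().any():
            raise ValueError("cells carry no activation calls; run call_activation first")
        return called.to_numpy(dtype=bool)
    return np.asarray(cells, dtype=bool)


def fraction_activated(
    cells,
    n_boot: int = 5000,
    seed: int | None = 0,
    condition: dict | None = None,
) -> ExperimentResult:
    """Point estimate and bootstrap uncertainty of the activated fraction.

    ``cells`` is a called per-cell table or a boolean array of calls.
    Bootstrap resamples cells with replacement; the standard error is the
    standard deviation of resampled fractions and the CI the 2.5/97.5
    percentiles.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    calls = _extract_calls(cells)
    n = calls.size
    if n == 0:
        return ExperimentResult(0, 0, float("nan"), float("nan"), float("nan"), float("nan"),
                                condition or {}, flagged=True)
    k = int(calls.sum())
    frac = k / n
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = calls[idx].mean(axis=1)
    se = float(boot.std(ddof=0))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ExperimentResult(
        n_cells=n,
        n_activated=k,
        fraction_activated=frac,
        bootstrap_se=se,
        ci_low=float(min(lo, frac)),
        ci_high=float(max(hi, frac)),
        condition=condition or {},
    )


def serial_dilution_factor(
    well_volume: float, removed_volume: float, added_volume: float, n_rounds: int
) -> float:
    """Cumulative fold-dilution of residual agonist after serial partial washes.

    Each round removes ``removed_volume`` from the well (the residual agonist
    stays proportionally) and adds ``added_volume`` fresh medium.  With equal
    removed/added volumes this is (V / (V - removed))**n_rounds; e.g. four
    rounds of replacing 250 of 300 uL give 6**4 = 1296 (~1:1000).
    """
    if well_volume <= 0 or removed_volume <= 0 or added_volume <= 0:
        raise ValueError("volumes must be positive")
    if removed_volume >= well_volume:
        raise ValueError("removed_volume must be smaller than the well volume")
    if n_rounds < 0:
        raise ValueError("n_rounds must be non-negative")
    factor = 1.0
    volume = well_volume
    for _ in range(int(n_rounds)):
        remaining = volume - removed_volume
        new_volume = remaining + added_volume
        factor *= new_volume / remaining
        volume = new_volume
        if removed_volume >= volume:
            raise ValueError("removed_volume exceeds the well volume after refilling")
    return factor
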