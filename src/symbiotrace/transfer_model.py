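"""Host-vs-endosymbiont enrichment regression and transfer mass balance.

For cells where both the diazoplast and host(N) excess 15N enrichments are
measured, the slope s of host excess on diazoplast excess, combined with the
diazoplast : host(N) volume ratio v, yields the fraction of newly fixed
nitrogen residing in the host:

    f = s * V_h / (s * V_h + V_d) = s / (s + v)

under the assumption that compartments share a common nitrogen density per
volume, so that newly fixed N in a compartment is proportional to its excess
atom fraction times its volume. The regression is through the origin by
default — a cell whose diazoplast fixed nothing has no transferred nitrogen —
with an optional intercept. Uncertainty comes from a cell-level bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .isotope_quant import NaturalAbundanceCalibration


class TransferError(ValueError):
    """Raised on degenerate regression or mass-balance inputs."""


@dataclass(frozen=True)
class CellRecord:
    """Paired per-cell excess enrichments (atom fraction above baseline).

    Excesses may be slightly negative from counting noise; they are used
    as-is, unclamped.
    """

    cell_id: str
    x_d: float  # diazoplast excess
    x_h: float  # host(N) excess


def excess_enrichment(
    atom_pct: float, calibration: NaturalAbundanceCalibration
) -> float:
    """Atom fraction above the calibrated natural-abundance mean.

    (atom% - control mean%) / 100; negative values pass through unclamped.
    """
    return (atom_pct - calibration.mean_pct) / 100.0


def records_from_table(df: pd.DataFrame) -> list[CellRecord]:
    """Build CellRecords from a frame with cell_id, x_d, x_h columns."""
    return [
        CellRecord(str(r.cell_id), float(r.x_d), float(r.x_h))
        for r in df.itertuples(index=False)
    ]


def fit_host_vs_diazoplast(
    cells: Sequence[CellRecord], intercept: bool = False
) -> tuple[float, float]:
    """Least-squares slope of host excess on diazoplast excess, with R².

    Through-origin by default: slope = sum(x y) / sum(x²) and R² uses the
    uncentered total sum of squares. With an intercept, ordinary centered
    least squares and centered R².
    """
    if len(cells) < 3:
        raise TransferError("need >= 3 paired cells")
    x = np.array([c.x_d for c in cells], dtype=float)
    y = np.array([c.x_h for c in cells], dtype=float)
    if np.ptp(x) == 0:
        raise TransferError("degenerate design: all diazoplast excesses equal")
    if intercept:
        slope, b0 = np.polyfit(x, y, 1)
        resid = y - (slope * x + b0)
        sstot = np.sum((y - y.mean()) ** 2)
    else:
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise TransferError("degenerate design: all diazoplast excesses zero")
        slope = float(np.sum(x * y)) / sxx
        resid = y - slope * x
        sstot = float(np.sum(y**2))
    if sstot == 0:
        raise TransferError("degenerate response: all host excesses zero")
    r2 = 1.0 - float(np.sum(resid**2)) / sstot
    return float(slope), float(r2)


def transfer_fraction(slope: float, volume_ratio: float) -> float:
    """Fraction of newly fixed nitrogen located in the host compartment.

    f = s / (s + v) with s the host:diazoplast excess-enrichment slope and
    v = V_d / V_h the volume ratio; monotone increasing in s, decreasing in
    v, and confined to [0, 1] for non-negative inputs.
    """
    if slope < 0:
        raise TransferError("slope must be >= 0 for the mass balance")
    if volume_ratio < 0:
        raise TransferError("volume_ratio must be >= 0")
    if slope == 0 and volume_ratio == 0:
        raise TransferError("transfer fraction undefined at s = v = 0")
    return slope / (slope + volume_ratio)


@dataclass
class TransferEstimate:
    """Regression slope, fit quality, and mass-balance transfer fraction."""

    slope: float
    r2: float
    volume_ratio: float
    transfer_frac: float
    ci_low: float
    ci_high: float
    n_cells: int
    n_bootstrap: int
    seed: int
    intercept: bool = False

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "r2": self.r2,
            "volume_ratio": self.volume_ratio,
            "transfer_frac": self.transfer_frac,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cells": self.n_cells,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "intercept": self.intercept,
        }


def bootstrap_transfer(
    cells: Sequence[CellRecord],
    volume_ratio: float = 0.06,
    n_bootstrap: int = 1000,
    seed: int = 0,
    intercept: bool = False,
) -> TransferEstimate:
    """Percentile bootstrap CI for the transfer fraction, resampling cells.

    Fails if more than 10% of resamples are degenerate (e.g. all-equal
    diazoplast excesses), which indicates the data cannot support the fit.
    """
    if n_bootstrap < 100:
        raise TransferError("n_bootstrap must be >= 100")
    if len(cells) < 5:
        raise TransferError("need >= 5 cells for the bootstrap")
    slope, r2 = fit_host_vs_diazoplast(cells, intercept=intercept)
    f = transfer_fraction(max(slope, 0.0), volume_ratio)

    rng = np.random.default_rng(seed)
    n = len(cells)
    fs = []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        sample = [cells[i] for i in idx]
        try:
            s_b, _ = fit_host_vs_diazoplast(sample, intercept=intercept)
            fs.append(transfer_fraction(max(s_b, 0.0), volume_ratio))
        except TransferError:
            failures += 1
    if failures > 0.1 * n_bootstrap:
        raise TransferError(
            f"{failures}/{n_bootstrap} bootstrap resamples degenerate"
        )
    lo, hi = np.percentile(fs, [2.5, 97.5])
    return TransferEstimate(
        slope=slope,
        r2=r2,
        volume_ratio=volume_ratio,
        transfer_frac=f,
        ci_low=float(lo),
        ci_high=float(hi),
        n_cells=n,
        n_bootstrap=n_bootstrap,
        seed=seed,
        intercept=intercept,
    )
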