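"""Delta-notation arithmetic for bulk isotope-ratio mass spectrometry.

d (per mil) = 1000 * (R_sample / R_standard - 1), with R the heavy/light
isotope ratio. The default standard is VPDB for carbon (13C/12C =
0.0111802). Condition comparison reuses the control-mean + 3 SD enrichment
convention applied elsewhere in the package, with Welch t-tests as
annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: VPDB 13C/12C ratio.
R_VPDB_13C = 0.0111802


class DeltaError(ValueError):
    pass


@dataclass(frozen=True)
class DeltaMeasurement:
    """One bulk measurement in per-mil delta notation."""

    delta: float  # per mil vs standard
    condition: str = ""
    standard_ratio: float = R_VPDB_13C

    def __post_init__(self) -> None:
        if self.delta <= -1000:
            raise DeltaError("delta <= -1000 per mil implies a non-positive ratio")
        if self.standard_ratio <= 0:
            raise DeltaError("standard_ratio must be > 0")


def delta_to_ratio(delta: float, standard_ratio: float = R_VPDB_13C) -> float:
    """Isotope ratio from delta: R = R_std * (1 + delta/1000)."""
    if delta <= -1000:
        raise DeltaError("delta must exceed -1000 per mil")
    return standard_ratio * (1.0 + delta / 1000.0)


def ratio_to_delta(ratio: float, standard_ratio: float = R_VPDB_13C) -> float:
    """Exact inverse of :func:`delta_to_ratio`."""
    if ratio < 0:
        raise DeltaError("ratio must be >= 0")
    return 1000.0 * (ratio / standard_ratio - 1.0)


def ratio_to_atom_percent(ratio: float) -> float:
    """Heavy atom percent from the heavy/light ratio: 100 * R / (1 + R)."""
    if ratio < 0:
        raise DeltaError("ratio must be >= 0")
    return 100.0 * ratio / (1.0 + ratio)


def atom_percent_to_ratio(atom_pct: float) -> float:
    """Exact inverse of :func:`ratio_to_atom_percent` for atom% < 100."""
    if not 0 <= atom_pct < 100:
        raise DeltaError("atom percent must be in [0, 100)")
    frac = atom_pct / 100.0
    return frac / (1.0 - frac)


def delta_to_atom_percent(delta: float, standard_ratio: float = R_VPDB_13C) -> float:
    """Convenience composition linking the delta scale to atom percent."""
    return ratio_to_atom_percent(delta_to_ratio(delta, standard_ratio))


def compare_conditions(
    samples: dict[str, np.ndarray | list[float]],
    control: str = "control",
) -> dict:
    """Summarize per-condition deltas and call enrichment vs a control.

    A condition is called enriched when its mean delta exceeds the control
    mean + 3 * control SD (the same convention used for single-cell atom%
    thresholds; an internal convention, not a hypothesis test). Pairwise
    Welch t-tests against the control are reported as annotation.

    Returns {"summary": DataFrame, "threshold": float, "welch": dict}.
    """
    if len(samples) < 2:
        raise DeltaError("need at least two conditions to compare")
    if control not in samples:
        raise DeltaError(f"control condition {control!r} missing")
    for cond, vals in samples.items():
        if len(vals) < 2:
            raise DeltaError(f"condition {cond!r} needs >= 2 samples")
    ctrl = np.asarray(samples[control], dtype=float)
    threshold = float(ctrl.mean() + 3.0 * ctrl.std(ddof=1))
    rows, welch = [], {}
    for cond, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        enriched = bool(arr.mean() > threshold) if cond != control else False
        rows.append(
            {
                "condition": cond,
                "n": len(arr),
                "mean_delta": float(arr.mean()),
                "sd_delta": float(arr.std(ddof=1)),
                "enriched": enriched,
            }
        )
        if cond != control:
            t, p = stats.ttest_ind(arr, ctrl, equal_var=False)
            welch[cond] = {"t": float(t), "p": float(p)}
    summary = pd.DataFrame(rows).set_index("condition")
    return {"summary": summary, "threshold": threshold, "welch": welch}
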