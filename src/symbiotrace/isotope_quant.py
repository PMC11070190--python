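"""Per-ROI isotope quantification, calibration, and activity classification.

The heavy-isotope atom percent of an ROI is estimated as a ratio of pooled
isotopologue counts, 100 * heavy / (heavy + light) — counts are summed over
the ROI's pixels *before* the ratio is taken, because per-pixel ratios are
undefined or badly biased at low counts. Under the Poisson-thinning count
model the heavy count is binomial given the total, so the standard error of
the ratio is the exact binomial one.

Natural abundance is calibrated from unlabeled control ROIs: the enrichment
threshold is the control mean atom% plus three control standard deviations,
with the SD taken *across* control ROIs so that it captures instrument
scatter, not just counting noise. An ROI is "enriched" only when its atom%
strictly exceeds that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .sims_io import ROI, IonCountImage, KNOWN_CHANNELS

#: heavy / light channel pairs per isotope
ISOTOPE_CHANNELS = {"15N": ("C15N", "C14N"), "13C": ("C13C", "C2")}


class QuantError(ValueError):
    """Raised on invalid quantification inputs."""


@dataclass(frozen=True)
class AtomPercent:
    """Point estimate and counting-statistics SE of a heavy-atom percentage."""

    atom_pct: float
    se_pct: float
    heavy: int
    light: int

    @property
    def defined(self) -> bool:
        return self.heavy + self.light > 0


def atom_percent(heavy_counts: int, light_counts: int) -> AtomPercent:
    """Heavy-isotope atom percent from pooled isotopologue counts.

    atom% = 100 * heavy / (heavy + light); SE = 100 * sqrt(p (1-p) / n) with
    p the estimated fraction and n the total count. A zero total yields a
    flagged undefined result (NaN estimate), never an exception.
    """
    if heavy_counts < 0 or light_counts < 0:
        raise QuantError("counts must be non-negative")
    total = heavy_counts + light_counts
    if total == 0:
        return AtomPercent(math.nan, math.nan, 0, 0)
    p = heavy_counts / total
    se = 100.0 * math.sqrt(p * (1.0 - p) / total)
    return AtomPercent(100.0 * p, se, int(heavy_counts), int(light_counts))


@dataclass
class ROIQuant:
    """Pooled counts and atom% estimates for one ROI."""

    cell_id: str
    roi_id: int
    compartment: str
    area_px: int
    counts: dict[str, int] = field(default_factory=dict)
    atom15N_pct: float = math.nan
    se15N_pct: float = math.nan
    atom13C_pct: float = math.nan
    se13C_pct: float = math.nan
    enriched_15N: bool | None = None
    enriched_13C: bool | None = None

    def atom_pct(self, isotope: str) -> float:
        return self.atom15N_pct if isotope == "15N" else self.atom13C_pct

    def defined(self, isotope: str) -> bool:
        return not math.isnan(self.atom_pct(isotope))


def quantify_rois(image: IonCountImage, rois: Sequence[ROI]) -> list[ROIQuant]:
    """Pool channel counts over each ROI's pixels and compute both atom%.

    An isotope whose channels are absent from the image is left NaN
    (unavailable) rather than failing the whole quantification.
    """
    out = []
    for roi in rois:
        counts = {
            ch: int(image.counts(ch)[roi.pixels].sum())
            for ch in KNOWN_CHANNELS
            if image.has_channel(ch)
        }
        q = ROIQuant(
            cell_id=roi.cell_id,
            roi_id=roi.roi_id,
            compartment=roi.compartment,
            area_px=roi.area_px,
            counts=counts,
        )
        if {"C15N", "C14N"} <= counts.keys():
            ap = atom_percent(counts["C15N"], counts["C14N"])
            q.atom15N_pct, q.se15N_pct = ap.atom_pct, ap.se_pct
        if {"C13C", "C2"} <= counts.keys():
            ap = atom_percent(counts["C13C"], counts["C2"])
            q.atom13C_pct, q.se13C_pct = ap.atom_pct, ap.se_pct
        out.append(q)
    return out


@dataclass(frozen=True)
class NaturalAbundanceCalibration:
    """Control-derived baseline for one isotope.

    ``threshold = mean + 3 * sd`` is the enrichment cutoff: the natural
    abundance band observed in unlabeled samples.
    """

    isotope: str
    mean_pct: float
    sd_pct: float
    n_controls: int

    @property
    def threshold_pct(self) -> float:
        return self.mean_pct + 3.0 * self.sd_pct


def calibrate_natural_abundance(
    control_quants: Iterable[ROIQuant], isotope: str
) -> NaturalAbundanceCalibration:
    """Unweighted mean and SD of control ROI atom% for one isotope.

    Requires at least three control ROIs with a defined atom% so the
    across-ROI SD is meaningful.
    """
    if isotope not in ISOTOPE_CHANNELS:
        raise QuantError(f"unknown isotope {isotope!r}")
    vals = [q.atom_pct(isotope) for q in control_quants if q.defined(isotope)]
    if len(vals) < 3:
        raise QuantError(f"need >= 3 control ROIs, got {len(vals)}")
    arr = np.asarray(vals)
    return NaturalAbundanceCalibration(
        isotope=isotope,
        mean_pct=float(arr.mean()),
        sd_pct=float(arr.std(ddof=1)),
        n_controls=len(vals),
    )


def classify_enrichment(
    quant: ROIQuant, calibration: NaturalAbundanceCalibration
) -> bool | None:
    """Strictly-above-threshold enrichment call; None when atom% undefined."""
    if not quant.defined(calibration.isotope):
        return None
    return bool(quant.atom_pct(calibration.isotope) > calibration.threshold_pct)


def _pool_cell_quant(quants: list[ROIQuant], isotope: str) -> ROIQuant | None:
    """Pool counts across a cell's ROIs of one compartment into one quant."""
    if not quants:
        return None
    heavy_ch, light_ch = ISOTOPE_CHANNELS[isotope]
    heavy = sum(q.counts.get(heavy_ch, 0) for q in quants)
    light = sum(q.counts.get(light_ch, 0) for q in quants)
    ap = atom_percent(heavy, light)
    pooled = ROIQuant(
        cell_id=quants[0].cell_id,
        roi_id=-1,
        compartment=quants[0].compartment,
        area_px=sum(q.area_px for q in quants),
        counts={heavy_ch: heavy, light_ch: light},
    )
    if isotope == "15N":
        pooled.atom15N_pct, pooled.se15N_pct = ap.atom_pct, ap.se_pct
    else:
        pooled.atom13C_pct, pooled.se13C_pct = ap.atom_pct, ap.se_pct
    return pooled


@dataclass
class ActivitySummary:
    """Population-level activity fractions with Wilson 95% intervals."""

    n_cells: int
    n_with_diazoplast: int
    frac_active_15N: float
    ci_active_15N: tuple[float, float]
    frac_fixing_13C: float
    ci_fixing_13C: tuple[float, float]
    co_table: pd.DataFrame  # 2x2: 15N active x 13C fixing
    per_cell: pd.DataFrame


def activity_summary(
    quants: Iterable[ROIQuant],
    calibration_15N: NaturalAbundanceCalibration,
    calibration_13C: NaturalAbundanceCalibration | None = None,
) -> ActivitySummary:
    """Classify each cell's nitrogen and carbon fixation and summarize.

    A cell is 15N-active when the counts pooled over its diazoplast ROIs are
    enriched above the 15N threshold, and 13C-fixing when its pooled host(N)
    ROIs are enriched above the 13C threshold. Fractions come with Wilson
    95% score intervals; the joint 2x2 table covers cells classifiable on
    both axes.
    """
    by_cell: dict[str, dict[str, list[ROIQuant]]] = {}
    for q in quants:
        by_cell.setdefault(q.cell_id, {}).setdefault(q.compartment, []).append(q)

    rows = []
    for cell_id, comps in sorted(by_cell.items()):
        d = _pool_cell_quant(comps.get("diazoplast", []), "15N")
        active = classify_enrichment(d, calibration_15N) if d else None
        fixing = None
        if calibration_13C is not None:
            h = _pool_cell_quant(comps.get("host_N", []), "13C")
            fixing = classify_enrichment(h, calibration_13C) if h else None
        rows.append(
            {
                "cell_id": cell_id,
                "active_15N": active,
                "fixing_13C": fixing,
                "diazoplast_atom15N_pct": d.atom15N_pct if d else math.nan,
            }
        )
    per_cell = pd.DataFrame(rows)
    with_d = per_cell["active_15N"].notna()
    if not with_d.any():
        raise QuantError("no cell has a classified diazoplast ROI")

    def frac_ci(mask):
        n = int(mask.notna().sum())
        k = int(mask.fillna(False).astype(bool).sum())
        if n == 0:
            return math.nan, (math.nan, math.nan), 0
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        return k / n, (float(lo), float(hi)), n

    fa, ci_a, n_a = frac_ci(per_cell["active_15N"])
    fc, ci_c, _ = frac_ci(per_cell["fixing_13C"])

    both = per_cell.dropna(subset=["active_15N", "fixing_13C"]) if calibration_13C else per_cell.iloc[0:0]
    co = pd.DataFrame(
        0,
        index=pd.Index([True, False], name="active_15N"),
        columns=pd.Index([True, False], name="fixing_13C"),
    )
    for _, r in both.iterrows():
        co.loc[bool(r["active_15N"]), bool(r["fixing_13C"])] += 1

    return ActivitySummary(
        n_cells=len(per_cell),
        n_with_diazoplast=n_a,
        frac_active_15N=fa,
        ci_active_15N=ci_a,
        frac_fixing_13C=fc,
        ci_fixing_13C=ci_c,
        co_table=co,
        per_cell=per_cell,
    )
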