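"""Acetylene-reduction (nitrogenase activity) and RT-qPCR processing.

Nitrogenase activity is proxied by the acetylene reduction assay (ARA):
ethylene produced per µg chlorophyll per hour. Diel series are summarized
into day/night phase means, a day:night ratio, the peak timepoint, and a
"no clear diel pattern" flag; photosynthesis-inhibition experiments are
summarized as a percent reduction with a bootstrap CI and a Welch t-test
annotation.

Relative expression uses the efficiency-corrected quantification-cycle
model: relative level = E^(Cq_ref - Cq_target), which reduces to the
classical 2^-ddCt when E = 2. Fold changes between conditions are geometric
means, matching the log-scale symmetry of expression ratios; multiple
reference genes are combined by the geometric mean of their implied levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AssayError(ValueError):
    pass


REQUIRED_DIEL_COLUMNS = {"time_h", "phase", "replicate", "rate"}


@dataclass
class DielSeries:
    """Long-format diel activity series.

    ``data`` columns: time_h (hours into the diel cycle, [0, 24)), phase
    ("day" | "night"), replicate, rate (activity per µg chlorophyll per
    hour, >= 0). ``label`` names the organism or treatment.
    """

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        missing = REQUIRED_DIEL_COLUMNS - set(self.data.columns)
        if missing:
            raise AssayError(f"diel series missing columns: {sorted(missing)}")
        if (self.data["rate"] < 0).any():
            raise AssayError("rates must be >= 0")
        t = self.data["time_h"]
        if ((t < 0) | (t >= 24)).any():
            raise AssayError("timepoints must lie in [0, 24)")


def normalize_rate(raw_activity: float, chlorophyll_ug: float, duration_h: float) -> float:
    """Ethylene amount -> rate per µg chlorophyll per hour."""
    if chlorophyll_ug <= 0 or duration_h <= 0:
        raise AssayError("chlorophyll and duration must be > 0")
    return raw_activity / (chlorophyll_ug * duration_h)


def diel_contrast(series: DielSeries, ratio_cut: float = 2.0) -> dict:
    """Day/night phase means, ratio, peak timepoint, and diel-pattern flag.

    The series is flagged "no clear diel pattern" when the day:night mean
    ratio lies within [1/ratio_cut, ratio_cut]. Requires >= 2 timepoints in
    each phase.
    """
    df = series.data
    for phase in ("day", "night"):
        if df.loc[df["phase"] == phase, "time_h"].nunique() < 2:
            raise AssayError(f"need >= 2 timepoints in phase {phase!r}")
    phase_means = df.groupby("phase")["rate"].mean()
    day_mean = float(phase_means["day"])
    night_mean = float(phase_means["night"])
    if night_mean == 0 and day_mean == 0:
        ratio = 1.0
    elif night_mean == 0:
        ratio = math.inf
    else:
        ratio = day_mean / night_mean
    tp_means = df.groupby(["time_h", "phase"])["rate"].mean()
    peak_time, peak_phase = tp_means.idxmax()
    no_diel = bool((1.0 / ratio_cut) <= ratio <= ratio_cut)
    return {
        "day_mean": day_mean,
        "night_mean": night_mean,
        "day_night_ratio": ratio,
        "peak_time_h": float(peak_time),
        "peak_phase": str(peak_phase),
        "no_diel_pattern": no_diel,
    }


def treatment_effect(
    control: DielSeries,
    treated: DielSeries,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """Percent reduction of activity under treatment, with bootstrap CI.

    reduction% = 100 * (1 - mean_treated / mean_control), computed over all
    matched timepoints; the CI resamples replicate measurements within each
    series. Welch's t-test on the pooled rates is reported as annotation.
    Scale-invariant: rescaling both series by a common factor leaves the
    estimate unchanged.
    """
    c = control.data
    t = treated.data
    if set(c["time_h"].unique()) != set(t["time_h"].unique()):
        raise AssayError("control and treated series must share timepoints")
    if c["replicate"].nunique() < 2 or t["replicate"].nunique() < 2:
        raise AssayError("need >= 2 replicates per series")
    mc = float(c["rate"].mean())
    mt = float(t["rate"].mean())
    if mc == 0:
        raise AssayError("control mean is zero; reduction undefined")
    reduction = 100.0 * (1.0 - mt / mc)

    rng = np.random.default_rng(seed)
    cv = c["rate"].to_numpy()
    tv = t["rate"].to_numpy()
    reds = []
    for _ in range(n_bootstrap):
        cb = cv[rng.integers(0, cv.size, cv.size)].mean()
        tb = tv[rng.integers(0, tv.size, tv.size)].mean()
        if cb > 0:
            reds.append(100.0 * (1.0 - tb / cb))
    lo, hi = np.percentile(reds, [2.5, 97.5])
    tstat, p = stats.ttest_ind(tv, cv, equal_var=False)
    return {
        "reduction_pct": reduction,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "welch_t": float(tstat),
        "welch_p": float(p),
        "n_control": int(cv.size),
        "n_treated": int(tv.size),
    }


REQUIRED_QPCR_COLUMNS = {"gene", "condition", "Cq_target", "Cq_reference", "efficiency"}


def relative_expression(records: pd.DataFrame) -> dict:
    """Efficiency-corrected relative levels and night:day fold changes.

    Input: long-format records with gene, condition, Cq_target,
    Cq_reference, efficiency (amplification factor per cycle, in (1, 2]).
    A record may carry several reference genes as extra rows sharing the
    same (gene, condition, replicate); here each row holds one reference Cq
    and multiple references should be pre-combined by their geometric-mean
    level, i.e. arithmetic-mean Cq.

    Returns per-(gene, condition) geometric-mean relative levels and, for
    genes measured in both conditions, the night/day fold change (geometric
    mean ratio).
    """
    missing = REQUIRED_QPCR_COLUMNS - set(records.columns)
    if missing:
        raise AssayError(f"qPCR records missing columns: {sorted(missing)}")
    eff = records["efficiency"]
    if ((eff <= 1.0) | (eff > 2.0)).any():
        raise AssayError("efficiency must lie in (1, 2]")
    if records["Cq_reference"].isna().any():
        raise AssayError("every record needs a reference Cq")

    df = records.copy()
    df["level"] = df["efficiency"] ** (df["Cq_reference"] - df["Cq_target"])
    levels = (
        df.groupby(["gene", "condition"])["level"]
        .apply(lambda v: float(np.exp(np.log(v).mean())))
        .rename("relative_level")
        .reset_index()
    )
    folds = {}
    for gene, sub in levels.groupby("gene"):
        by_cond = dict(zip(sub["condition"], sub["relative_level"]))
        if {"day", "night"} <= by_cond.keys():
            folds[gene] = by_cond["night"] / by_cond["day"]
    return {"levels": levels, "night_day_fold": folds}
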