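"""Synthetic measurements with full ground-truth bookkeeping.

The analysis in this package targets dual-label (15N2 + 13C-bicarbonate)
nanoSIMS imaging of a pennate diatom that carries obligate nitrogen-fixing
endosymbionts ("diazoplasts"), alongside bulk IRMS, acetylene-reduction, and
RT-qPCR assays. No raw rasters accompany the study, so this module generates
images and assay tables with the statistical structure the analysis assumes:

* one focal cell per raster: a ~20 µm prolate-spheroid host containing a few
  spherical diazoplasts and nitrogen-depleted storage compartments;
* per-pixel Poisson ion counts, with the CN- (and C2-) count of each pixel
  split between light and heavy isotopologues by binomial thinning at the
  compartment's true atom fraction — the counting model under which the
  pooled-ratio estimator and its binomial standard error are exact;
* population heterogeneity: each cell is active with a fixed probability, and
  active cells draw a lognormal (strictly positive, right-skewed) diazoplast
  excess enrichment; host excess is a fixed multiple of diazoplast excess.

Every generated image is paired with a :class:`GroundTruth` record so that
segmentation and quantification can be scored by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .sims_io import (
    CLASS_BACKGROUND,
    CLASS_DIAZOPLAST,
    CLASS_HOST_MINUS_N,
    CLASS_HOST_N,
    CLASS_NAMES,
    IonCountImage,
)

#: Physical natural abundances (atom fraction) of the heavy isotopes.
NAT_15N_AIR = 0.003663
NAT_13C_VPDB = 0.0111


class GeometryError(RuntimeError):
    """Compartment geometry could not be placed within the grid."""


def _default_densities() -> dict[str, dict[str, float]]:
    # Expected counts / pixel / channel group, accumulated over the full
    # acquisition depth. CN- tracks protein (highest in the diazoplast,
    # above background in host cytoplasm, background-level in the
    # nitrogen-depleted storage compartments); C2- tracks carbon and is
    # highest in the storage compartments; S32- is tied to CN- below.
    return {
        "diazoplast": {"CN": 2000.0, "C2": 500.0},
        "host_N": {"CN": 800.0, "C2": 500.0},
        "host_minusN": {"CN": 40.0, "C2": 1500.0},
        "background": {"CN": 20.0, "C2": 20.0},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell nanoSIMS experiment.

    Geometry defaults give a 20 x 10 µm host ellipse holding four 1.55 µm
    radius diazoplasts, i.e. a diazoplast/host volume ratio of ~6% under the
    sphere/spheroid model. Isotopic defaults place unlabeled material at the
    *measured* control baselines (0.377 atom% 15N, 1.74 atom% 13C), modelled
    as physical natural abundance plus a constant instrument offset.

    frac_active is the probability that a cell's diazoplast fixed nitrogen
    during the incubation; active cells draw a lognormal excess 15N atom
    fraction with mean ``enrichment_mean`` and coefficient of variation
    ``enrichment_cv``, and their host compartment receives ``host_ratio``
    times the diazoplast excess (the transferred fraction seen in the host).
    """

    grid_size: tuple[int, int] = (128, 128)
    pixel_size: float = 0.2  # µm
    host_axes: tuple[float, float] = (10.0, 5.0)  # semi-major, semi-minor, µm
    n_diazoplasts: int = 4
    diazoplast_radius: float = 1.55  # µm
    vacuole_fraction: float = 0.08  # fraction of host projected area
    vacuole_radius: float = 1.2  # µm
    count_density: dict[str, dict[str, float]] = field(
        default_factory=_default_densities
    )
    s32_per_cn: float = 0.5  # S32- density as a multiple of CN- density
    nat_15N: float = NAT_15N_AIR
    nat_13C: float = NAT_13C_VPDB
    instrument_offset_15N: float = 0.00377 - NAT_15N_AIR
    instrument_offset_13C: float = 0.0174 - NAT_13C_VPDB
    frac_active: float = 0.7
    frac_c_fixing: float = 0.9
    enrichment_mean: float = 0.01  # mean diazoplast excess 15N atom fraction
    enrichment_cv: float = 0.5
    c13_enrichment_mean: float = 0.01  # mean host_N excess 13C atom fraction
    host_ratio: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vacuole_fraction", "frac_active", "frac_c_fixing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.host_ratio < 0:
            raise ValueError("host_ratio must be >= 0")
        for comp, groups in self.count_density.items():
            if comp not in CLASS_NAMES.values():
                raise ValueError(f"unknown compartment {comp!r} in count_density")
            for g, d in groups.items():
                if d < 0:
                    raise ValueError(f"count_density[{comp}][{g}] must be >= 0")
        a, b = self.host_axes
        if self.n_diazoplasts > 0 and self.diazoplast_radius >= min(a, b):
            raise ValueError("diazoplast radius must fit strictly inside the host")
        if self.enrichment_mean <= 0 or self.enrichment_cv < 0:
            raise ValueError("enrichment_mean > 0 and enrichment_cv >= 0 required")

    @property
    def baseline_15N(self) -> float:
        """Atom fraction measured on unlabeled material (natural + offset)."""
        return self.nat_15N + self.instrument_offset_15N

    @property
    def baseline_13C(self) -> float:
        return self.nat_13C + self.instrument_offset_13C


@dataclass
class GroundTruth:
    """Everything known by construction about one simulated cell."""

    cell_id: str
    labels: np.ndarray  # class-code raster, partitions the grid
    atom_frac_15N: dict[str, float]  # true atom fraction per compartment
    atom_frac_13C: dict[str, float]
    active: bool
    fixing_carbon: bool
    volumes_um3: dict[str, float]
    excess_15N_diazoplast: float = 0.0
    excess_15N_host: float = 0.0

    @property
    def volume_ratio(self) -> float:
        """Diazoplast : host(N) volume ratio under the sphere/spheroid model."""
        return self.volumes_um3["diazoplast"] / self.volumes_um3["host_N"]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _disc_mask(shape, center, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def make_cell_geometry(
    config: SimConfig,
    cell_index: int = 0,
    rng: np.random.Generator | None = None,
    max_tries: int = 100,
) -> GroundTruth:
    """Lay out one cell: host ellipse, diazoplast discs, storage discs.

    Diazoplasts and storage ("host(-N)") compartments are placed by rejection
    sampling strictly inside the host ellipse without mutual overlap; after
    ``max_tries`` failed placements a :class:`GeometryError` is raised.
    Volumes are computed analytically: prolate spheroid for the host, spheres
    for diazoplasts and storage discs; the host(N) volume is the spheroid
    minus its inclusions.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, cell_index)))
    nrow, ncol = config.grid_size
    px = config.pixel_size
    a_px = config.host_axes[0] / px
    b_px = config.host_axes[1] / px
    if 2 * a_px > ncol or 2 * b_px > nrow:
        raise GeometryError("host ellipse does not fit within the grid")
    c0 = ((nrow - 1) / 2.0, (ncol - 1) / 2.0)

    rr, cc = np.ogrid[:nrow, :ncol]
    host = ((cc - c0[1]) / a_px) ** 2 + ((rr - c0[0]) / b_px) ** 2 <= 1.0
    labels = np.full(config.grid_size, CLASS_BACKGROUND, dtype=np.int64)
    labels[host] = CLASS_HOST_N

    def place_discs(n, radius_um, avoid_centers, margin_px=3.0):
        # inclusions keep a few pixels of host cytoplasm between themselves
        # and the cell boundary
        r_px = radius_um / px
        m = r_px + margin_px
        centers = []
        for _ in range(n):
            for attempt in range(max_tries):
                u, v = rng.uniform(-1, 1, 2)
                if u**2 + v**2 > 1:
                    continue
                cy = c0[0] + v * max(b_px - m, 0)
                cx = c0[1] + u * max(a_px - m, 0)
                inside = ((cx - c0[1]) / (a_px - m)) ** 2 + (
                    (cy - c0[0]) / (b_px - m)
                ) ** 2 <= 1.0
                if not inside:
                    continue
                clear = all(
                    math.hypot(cy - oy, cx - ox) > r_px + orad + 1
                    for oy, ox, orad in avoid_centers + centers
                )
                if clear:
                    centers.append((cy, cx, r_px))
                    break
            else:
                raise GeometryError(
                    f"could not place disc of radius {radius_um} µm "
                    f"after {max_tries} tries"
                )
        return centers

    host_area_px = int(host.sum())
    n_vac = 0
    if config.vacuole_fraction > 0 and config.vacuole_radius > 0:
        vac_area = math.pi * (config.vacuole_radius / px) ** 2
        n_vac = max(1, round(config.vacuole_fraction * host_area_px / vac_area))

    # a single unlucky placement order can wedge; restart the whole layout a
    # bounded number of times before declaring the geometry infeasible
    last_err: GeometryError | None = None
    for restart in range(10):
        try:
            diazo_centers = place_discs(
                config.n_diazoplasts, config.diazoplast_radius, []
            )
            vac_centers = (
                place_discs(n_vac, config.vacuole_radius, diazo_centers)
                if n_vac
                else []
            )
            break
        except GeometryError as err:
            last_err = err
    else:
        raise GeometryError(f"geometry infeasible after 10 layout restarts: {last_err}")

    for cy, cx, r_px in diazo_centers:
        labels[_disc_mask(config.grid_size, (cy, cx), r_px)] = CLASS_DIAZOPLAST
    for cy, cx, r_px in vac_centers:
        labels[_disc_mask(config.grid_size, (cy, cx), r_px)] = CLASS_HOST_MINUS_N

    sphere = lambda r: 4.0 / 3.0 * math.pi * r**3
    v_host_total = 4.0 / 3.0 * math.pi * config.host_axes[0] * config.host_axes[1] ** 2
    v_diazo = config.n_diazoplasts * sphere(config.diazoplast_radius)
    v_vac = n_vac * sphere(config.vacuole_radius)
    volumes = {
        "host_total": v_host_total,
        "diazoplast": v_diazo,
        "host_minusN": v_vac,
        "host_N": v_host_total - v_diazo - v_vac,
    }
    base = {
        "diazoplast": config.baseline_15N,
        "host_N": config.baseline_15N,
        "host_minusN": config.baseline_15N,
        "background": config.baseline_15N,
    }
    base13 = {k: config.baseline_13C for k in base}
    return GroundTruth(
        cell_id=f"cell{cell_index:04d}",
        labels=labels,
        atom_frac_15N=base,
        atom_frac_13C=base13,
        active=False,
        fixing_carbon=False,
        volumes_um3=volumes,
    )


# ---------------------------------------------------------------------------
# Ion images
# ---------------------------------------------------------------------------


def simulate_ion_image(
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> IonCountImage:
    """Draw one multi-channel Poisson count raster for a cell.

    Per pixel, the total CN- count is Poisson at the compartment's CN density
    and is split into C14N/C15N by binomial thinning at the compartment's true
    15N atom fraction; C2- counts are split into C2/C13C the same way at the
    13C fraction. S32- is an independent Poisson channel whose density is
    ``s32_per_cn`` times the CN density, emulating the empirical coupling of
    sulfur and protein signal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    labels = truth.labels
    shape = labels.shape

    def density_map(group: str) -> np.ndarray:
        out = np.zeros(shape)
        for code, name in CLASS_NAMES.items():
            d = config.count_density.get(name, {}).get(group, 0.0)
            out[labels == code] = d
        return out

    def fraction_map(table: dict[str, float]) -> np.ndarray:
        out = np.zeros(shape)
        for code, name in CLASS_NAMES.items():
            out[labels == code] = table.get(name, 0.0)
        return out

    cn_total = rng.poisson(density_map("CN"))
    c15 = rng.binomial(cn_total, fraction_map(truth.atom_frac_15N))
    c2_total = rng.poisson(density_map("C2"))
    c13 = rng.binomial(c2_total, fraction_map(truth.atom_frac_13C))
    s32 = rng.poisson(config.s32_per_cn * density_map("CN"))
    data = {
        "C14N": cn_total - c15,
        "C15N": c15,
        "C2": c2_total - c13,
        "C13C": c13,
        "S32": s32,
    }
    return IonCountImage(
        data, config.pixel_size, {"cell_id": truth.cell_id, "synthetic": True}
    )


def expectation_ion_image(truth: GroundTruth, config: SimConfig) -> IonCountImage:
    """Noise-free image whose counts equal the (rounded) Poisson expectations.

    Used to check that segmentation reproduces the ground-truth partition
    exactly when shot noise is absent.
    """
    labels = truth.labels
    shape = labels.shape

    def fill(values: dict[str, float]) -> np.ndarray:
        out = np.zeros(shape)
        for code, name in CLASS_NAMES.items():
            out[labels == code] = values.get(name, 0.0)
        return out

    cn = fill({k: v.get("CN", 0.0) for k, v in config.count_density.items()})
    c2 = fill({k: v.get("C2", 0.0) for k, v in config.count_density.items()})
    f15 = fill(truth.atom_frac_15N)
    f13 = fill(truth.atom_frac_13C)
    data = {
        "C14N": np.rint(cn * (1 - f15)).astype(np.int64),
        "C15N": np.rint(cn * f15).astype(np.int64),
        "C2": np.rint(c2 * (1 - f13)).astype(np.int64),
        "C13C": np.rint(c2 * f13).astype(np.int64),
        "S32": np.rint(config.s32_per_cn * cn).astype(np.int64),
    }
    return IonCountImage(
        data, config.pixel_size, {"cell_id": truth.cell_id, "synthetic": True}
    )


def simulate_population(
    config: SimConfig, n_cells: int
) -> list[tuple[IonCountImage, GroundTruth]]:
    """Simulate a labeled population of single-cell images.

    Each cell is independently active (nitrogen-fixing) with probability
    ``frac_active`` and carbon-fixing with probability ``frac_c_fixing``.
    Active cells draw a lognormal diazoplast excess 15N atom fraction; the
    host(N) compartment receives ``host_ratio`` times that excess, the
    storage compartment none. Carbon-fixing cells enrich host(N) by a
    lognormal excess 13C fraction, the storage compartment by twice it
    (fixed carbon accumulates in storage), and the diazoplast by half of it
    (carbon arrives there only via transfer).

    Deterministic given ``config.seed``: cell ``i`` uses the seed sequence
    ``(seed, i)`` so populations of different sizes share their prefix.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    out = []
    for i in range(n_cells):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, i)))
        truth = make_cell_geometry(config, i, rng=rng)
        active = bool(rng.random() < config.frac_active)
        fixing_c = bool(rng.random() < config.frac_c_fixing)
        if active:
            x_d = _lognormal(rng, config.enrichment_mean, config.enrichment_cv)
            x_h = config.host_ratio * x_d
            truth = replace(
                truth,
                active=True,
                excess_15N_diazoplast=x_d,
                excess_15N_host=x_h,
                atom_frac_15N={
                    "diazoplast": config.baseline_15N + x_d,
                    "host_N": config.baseline_15N + x_h,
                    "host_minusN": config.baseline_15N,
                    "background": config.baseline_15N,
                },
            )
        if fixing_c:
            x_c = _lognormal(rng, config.c13_enrichment_mean, config.enrichment_cv)
            truth = replace(
                truth,
                fixing_carbon=True,
                atom_frac_13C={
                    "host_N": config.baseline_13C + x_c,
                    "host_minusN": config.baseline_13C + 2 * x_c,
                    "diazoplast": config.baseline_13C + 0.5 * x_c,
                    "background": config.baseline_13C,
                },
            )
        image = simulate_ion_image(truth, config, rng=rng)
        out.append((image, truth))
    return out


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw lognormal with given arithmetic mean and coefficient of variation."""
    if cv == 0:
        return mean
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def simulate_control_population(
    config: SimConfig, n_cells: int
) -> list[tuple[IonCountImage, GroundTruth]]:
    """Unlabeled controls: the same population with every cell inactive."""
    ctrl = replace(config, frac_active=0.0, frac_c_fixing=0.0)
    return simulate_population(ctrl, n_cells)


# ---------------------------------------------------------------------------
# Tabular cell records (regression-scale simulation)
# ---------------------------------------------------------------------------


def simulate_cell_records(
    n_cells: int,
    host_ratio: float = 0.9,
    enrichment_mean: float = 0.01,
    enrichment_cv: float = 0.5,
    rel_noise: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (diazoplast, host) excess enrichments without image synthesis.

    Diazoplast excess is lognormal; host excess is ``host_ratio`` times it,
    and both observations carry multiplicative Gaussian noise of relative
    standard deviation ``rel_noise``. Columns: cell_id, x_d, x_h.
    """
    rng = np.random.default_rng(seed)
    sigma2 = math.log1p(enrichment_cv**2)
    x_true = rng.lognormal(
        math.log(enrichment_mean) - sigma2 / 2, math.sqrt(sigma2), n_cells
    )
    x_d = x_true * (1 + rel_noise * rng.standard_normal(n_cells))
    x_h = host_ratio * x_true * (1 + rel_noise * rng.standard_normal(n_cells))
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i:04d}" for i in range(n_cells)],
            "x_d": x_d,
            "x_h": x_h,
        }
    )


def simulate_control_counts(
    n_rois: int,
    atom_fraction: float,
    total_counts: float = 1e6,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled isotopologue counts for unlabeled control ROIs.

    Each ROI draws a Poisson total of expectation ``total_counts`` which is
    binomially thinned at ``atom_fraction`` into heavy/light. Columns:
    roi_id, heavy, light.
    """
    rng = np.random.default_rng(seed)
    totals = rng.poisson(total_counts, n_rois)
    heavy = rng.binomial(totals, atom_fraction)
    return pd.DataFrame(
        {"roi_id": np.arange(n_rois), "heavy": heavy, "light": totals - heavy}
    )


# ---------------------------------------------------------------------------
# Bulk and assay simulators
# ---------------------------------------------------------------------------


def simulate_bulk_irms(
    true_delta: float, noise_sd: float, n: int, seed: int = 0
) -> np.ndarray:
    """Gaussian replicate d13C measurements (per mil vs VPDB)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return true_delta + noise_sd * rng.standard_normal(n)


def simulate_diel_ara(
    base_profile: Sequence[float],
    timepoints: Sequence[float] | None = None,
    phases: Sequence[str] | None = None,
    treatment_factor: float = 1.0,
    noise_cv: float = 0.1,
    n_replicates: int = 6,
    seed: int = 0,
):
    """Control and treated diel activity series with multiplicative noise.

    ``base_profile`` gives the control mean rate at each timepoint; the
    treated series mean is ``treatment_factor`` times the control mean.
    Returns a (control, treated) pair of :class:`~symbiotrace.assay_models.
    DielSeries`. Default timepoints 1/4/8/11 h into each of day and night.
    """
    from .assay_models import DielSeries
    base = np.asarray(base_profile, dtype=float)
    if np.any(base < 0):
        raise ValueError("rates must be >= 0")
    if treatment_factor < 0:
        raise ValueError("treatment_factor must be >= 0")
    if timepoints is None:
        timepoints = [1, 4, 8, 11, 13, 16, 20, 23][: len(base)]
    if phases is None:
        phases = ["day" if t < 12 else "night" for t in timepoints]
    rng = np.random.default_rng(seed)

    def draw(means, label):
        rows = []
        for t, ph, m in zip(timepoints, phases, means):
            vals = m * (1 + noise_cv * rng.standard_normal(n_replicates))
            for r, v in enumerate(vals):
                rows.append(
                    {
                        "time_h": t,
                        "phase": ph,
                        "replicate": r,
                        "rate": max(v, 0.0),
                        "series": label,
                    }
                )
        return pd.DataFrame(rows)

    control = DielSeries(draw(base, "control"), label="control")
    treated = DielSeries(draw(treatment_factor * base, "treated"), label="treated")
    return control, treated


def simulate_qpcr(
    true_fold: float,
    efficiency: float = 2.0,
    cq_ref: float = 20.0,
    noise_sd: float = 0.2,
    n: int = 3,
    seed: int = 0,
    gene: str = "gene",
) -> pd.DataFrame:
    """Two-condition qPCR table implementing the Cq offset model.

    The night-condition target Cq is offset from the day condition by
    ``-log_efficiency(true_fold)`` cycles (more template -> earlier
    quantification cycle), plus Gaussian cycle noise. Returns long-format
    records: gene, condition, replicate, Cq_target, Cq_reference, efficiency.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    rng = np.random.default_rng(seed)
    dcq = -math.log(true_fold) / math.log(efficiency)
    rows = []
    for cond, offset in (("day", 0.0), ("night", dcq)):
        for r in range(n):
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "replicate": r,
                    "Cq_target": cq_ref + 2.0 + offset + noise_sd * rng.standard_normal(),
                    "Cq_reference": cq_ref + noise_sd * rng.standard_normal(),
                    "efficiency": efficiency,
                }
            )
    return pd.DataFrame(rows)
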