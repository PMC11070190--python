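"""Compartment segmentation of single-cell ion-count rasters.

The nitrogen (CN-) channel partitions a cell into three compartments: the
endosymbiont ("diazoplast") appears as compact near-spherical regions with
the highest CN- counts; the nitrogen-containing host cytoplasm ("host(N)")
has intermediate counts; and nitrogen-depleted storage bodies ("host(-N)",
likely lipid droplets or vacuoles) sit at background CN- levels but carry a
high carbon (C2-) signal. Segmentation is fully deterministic: Gaussian
smoothing to tame Poisson shot noise, Otsu thresholds for the cell outline
and the diazoplast/cytoplasm split, and rule-based carbon gating for the
storage class.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .sims_io import (
    CLASS_BACKGROUND,
    CLASS_DIAZOPLAST,
    CLASS_HOST_MINUS_N,
    CLASS_HOST_N,
    CLASS_NAMES,
    ROI,
    CompartmentMask,
    IonCountImage,
)


class SegmentationError(RuntimeError):
    """Raised when an image cannot be segmented (e.g. no cell present)."""


@dataclass
class SegmentationParams:
    """Tunable segmentation thresholds.

    smoothing_sigma
        Gaussian sigma in pixels applied to count rasters before
        thresholding; raw single-pixel Poisson counts are too noisy to
        threshold directly.
    background_method / background_level
        "otsu" separates cell from background on the smoothed total-CN
        raster; "fixed" uses ``background_level`` counts/pixel.
    diazoplast_method / diazoplast_quantile
        Within-cell threshold for diazoplast candidates: "otsu" (default;
        adapts to the bimodal diazoplast/cytoplasm split whatever the area
        fraction) or the "quantile" of within-cell smoothed CN.
    diazoplast_contrast_min
        Minimum ratio of mean CN above the diazoplast threshold to mean CN
        below it; guards against splitting a unimodal cytoplasm (a cell with
        no diazoplast) on noise alone.
    min/max_diazoplast_area, circularity_min
        Component filters implementing the "compact, near-spherical" shape
        criterion; circularity is 4*pi*A/P^2.
    cn_low_frac
        Pixels below this fraction of the within-cell median CN count as
        "background-level CN" for the storage class.
    c2_ratio_min
        Storage pixels must additionally carry at least this multiple of the
        within-cell median C2 density.
    """

    smoothing_sigma: float = 1.0
    background_method: str = "otsu"
    background_level: float = 0.0
    diazoplast_method: str = "otsu"
    diazoplast_quantile: float = 0.90
    diazoplast_contrast_min: float = 1.5
    min_diazoplast_area: int = 20
    max_diazoplast_area: int = 100_000
    circularity_min: float = 0.6
    cn_low_frac: float = 0.5
    c2_ratio_min: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.diazoplast_quantile <= 1:
            raise ValueError("diazoplast_quantile must be in (0, 1]")
        if not 0 < self.circularity_min <= 1:
            raise ValueError("circularity_min must be in (0, 1]")
        if self.min_diazoplast_area > self.max_diazoplast_area:
            raise ValueError("min_diazoplast_area > max_diazoplast_area")
        if self.background_method not in {"otsu", "fixed"}:
            raise ValueError("background_method must be 'otsu' or 'fixed'")
        if self.diazoplast_method not in {"otsu", "quantile"}:
            raise ValueError("diazoplast_method must be 'otsu' or 'quantile'")


def _smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return arr.astype(float)
    return ndimage.gaussian_filter(arr.astype(float), sigma)


def _total_cn(image: IonCountImage) -> np.ndarray:
    if not image.has_channel("C14N"):
        raise SegmentationError("image lacks the C14N channel")
    total = image.counts("C14N").astype(np.int64)
    if image.has_channel("C15N"):
        total = total + image.counts("C15N")
    return total


def segment_cell(image: IonCountImage, params: SegmentationParams) -> np.ndarray:
    """Boolean mask of the focal cell from the smoothed total-CN raster.

    The largest connected above-background component is retained and its
    holes (low-CN storage bodies) filled. Raises ``SegmentationError`` when
    no above-background structure exists.
    """
    cn = _smooth(_total_cn(image), params.smoothing_sigma)
    if params.background_method == "otsu":
        if np.ptp(cn) == 0:
            raise SegmentationError("empty image: uniform CN signal")
        thr = threshold_otsu(cn)
    else:
        thr = params.background_level
    fg = cn > thr
    if not fg.any():
        raise SegmentationError("empty image: no above-background pixels")
    # bridge thin low-CN corridors (storage bodies abutting the cell edge)
    # before hole filling
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)), iterations=2)
    comps, n = cc_label(fg, return_num=True)
    if n == 0:
        raise SegmentationError("empty image: no components")
    sizes = np.bincount(comps.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    mask = ndimage.binary_fill_holes(comps == keep)
    return mask


def _split_touching(cand: np.ndarray, min_sep: int) -> np.ndarray:
    """Watershed-split touching near-circular blobs in a candidate mask.

    Markers are local maxima of the Euclidean distance transform at least
    ``min_sep`` pixels apart, so two abutting discs are separated at their
    waist instead of merging into one non-circular component.
    """
    if not cand.any():
        return np.zeros(cand.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(cand)
    peaks = peak_local_max(dist, min_distance=min_sep, labels=cand, exclude_border=False)
    if len(peaks) == 0:
        return cc_label(cand).astype(np.int32)
    markers = np.zeros(cand.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=cand)


def segment_compartments(
    image: IonCountImage,
    cell_mask: np.ndarray,
    params: SegmentationParams,
) -> CompartmentMask:
    """Partition the cell mask into diazoplast / host(N) / host(-N).

    Diazoplast candidates are connected components above the within-cell CN
    threshold that pass the area and circularity filters; storage pixels are
    background-level CN with high C2 density; everything else inside the
    cell is host(N). The three classes are disjoint and cover the cell mask
    exactly. An image with no acceptable diazoplast component is valid
    output (zero diazoplast ROIs).
    """
    if not cell_mask.any():
        raise SegmentationError("empty cell mask")
    cn = _smooth(_total_cn(image), params.smoothing_sigma)
    labels = np.full(image.shape, CLASS_BACKGROUND, dtype=np.int64)
    labels[cell_mask] = CLASS_HOST_N

    # diazoplast: bright, compact, near-circular CN components
    cn_cell = cn[cell_mask]
    if params.diazoplast_method == "otsu" and np.ptp(cn_cell) > 0:
        thr_d = threshold_otsu(cn_cell)
    else:
        thr_d = np.quantile(cn_cell, params.diazoplast_quantile)
    cand = (cn > thr_d) & cell_mask
    # a cell with no diazoplast still yields an Otsu split (cytoplasm vs
    # storage, or pure noise); require candidates to stand out against the
    # cytoplasm level, i.e. the within-cell median
    if cand.any():
        contrast = cn[cand].mean() / max(float(np.median(cn_cell)), 1e-12)
        if contrast < params.diazoplast_contrast_min:
            cand[:] = False
    comps = _split_touching(cand, min_sep=max(int(round(np.sqrt(params.min_diazoplast_area))), 3))
    for prop in regionprops(comps):
        area = prop.area
        perim = max(prop.perimeter, 1.0)
        circ = 4 * np.pi * area / perim**2
        ok = (
            params.min_diazoplast_area <= area <= params.max_diazoplast_area
            and circ >= params.circularity_min
        )
        if ok:
            labels[comps == prop.label] = CLASS_DIAZOPLAST

    # host(-N): background-level CN but high C2 density
    if image.has_channel("C2"):
        c2 = image.counts("C2").astype(np.int64)
        if image.has_channel("C13C"):
            c2 = c2 + image.counts("C13C")
        c2s = _smooth(c2, params.smoothing_sigma)
        host_like = labels == CLASS_HOST_N
        cn_med = float(np.median(cn[host_like]))
        c2_med = float(np.median(c2s[host_like]))
        low_n = host_like & (cn < params.cn_low_frac * cn_med)
        storage = low_n & (c2s >= params.c2_ratio_min * c2_med)
        labels[storage] = CLASS_HOST_MINUS_N

    return CompartmentMask(
        labels,
        provenance={"params": asdict(params), "op": "segment_compartments"},
    )


def extract_rois(
    mask: CompartmentMask,
    pixel_size: float = 1.0,
    cell_id: str = "cell0000",
) -> list[ROI]:
    """One ROI per connected component per non-background class."""
    rois: list[ROI] = []
    roi_id = 0
    for code, name in CLASS_NAMES.items():
        if code == CLASS_BACKGROUND:
            continue
        comps, n = cc_label(mask.labels == code, return_num=True)
        for k in range(1, n + 1):
            pix = np.nonzero(comps == k)
            rois.append(
                ROI(
                    cell_id=cell_id,
                    compartment=name,
                    roi_id=roi_id,
                    pixels=pix,
                    pixel_size=pixel_size,
                )
            )
            roi_id += 1
    return rois


def sulfur_correlation(
    image: IonCountImage,
    rois: list[ROI],
) -> dict:
    """Pearson correlation of per-ROI S32- vs CN- mean densities.

    Evaluated across diazoplast and host(N) ROIs (the protein-containing
    compartments); a strong correlation indicates the CN- signal tracks
    protein abundance. Returns a dict with keys ``status`` ("ok",
    "skipped_missing_channel", or "undefined_constant"), ``r``, ``p``, and
    ``n_rois``.
    """
    if not image.has_channel("S32"):
        return {"status": "skipped_missing_channel", "r": None, "p": None, "n_rois": 0}
    use = [r for r in rois if r.compartment in {"diazoplast", "host_N"}]
    if len(use) < 3:
        raise SegmentationError("sulfur_correlation requires >= 3 ROIs")
    cn = _total_cn(image)
    s32 = image.counts("S32")
    x = np.array([cn[r.pixels].mean() for r in use])
    y = np.array([s32[r.pixels].mean() for r in use])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"status": "undefined_constant", "r": None, "p": None, "n_rois": len(use)}
    r, p = stats.pearsonr(x, y)
    return {"status": "ok", "r": float(r), "p": float(p), "n_rois": len(use)}
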