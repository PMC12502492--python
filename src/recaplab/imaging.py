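"""Automated RAD51-focus quantification on multichannel IF images.

The chain mirrors a standard organoid immunofluorescence workflow: organoids
are isolated on the DAPI channel, nuclei segmented within them, proliferating
(Cyclin A2-positive) nuclei called by a difference-of-Gaussians band-pass on
the FITC channel followed by geodesic (morphological) reconstruction against
the nucleus mask, and RAD51 foci detected on the CY3 channel as bright
Laplacian-of-Gaussian blobs.  Only foci whose centroids fall inside
Cyclin A2-positive nuclei enter the downstream per-nucleus counts.

Segmentation is deliberately classical (Otsu + distance-transform watershed)
behind a pluggable interface so the whole chain is deterministic and
dependency-light; trained segmenters can be dropped in via ``Segmenter``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import reconstruction, remove_small_objects
from skimage.feature import peak_local_max
from skimage.segmentation import watershed


class ImagingConfigError(ValueError):
    """Invalid imaging configuration (e.g. sigma_small >= sigma_large)."""


@dataclass(frozen=True)
class ImagingConfig:
    """Tunable parameters of the quantification chain (all in pixels
    or image-intensity units)."""

    organoid_blur_sigma: float = 12.0
    organoid_min_area: int = 2000
    nucleus_blur_sigma: float = 1.5
    nucleus_min_area: int = 30
    nucleus_peak_min_distance: int = 5
    dog_sigma_small: float = 2.0
    dog_sigma_large: float = 8.0
    dog_floor_k: float = 2.0          # amplitude floor, x robust background SD
    log_sigma: float = 2.0
    log_threshold: float = 0.02       # scale-normalized -LoG response units

    def validate(self):
        if self.dog_sigma_small >= self.dog_sigma_large:
            raise ImagingConfigError(
                f"dog_sigma_small ({self.dog_sigma_small}) must be < "
                f"dog_sigma_large ({self.dog_sigma_large})")
        if self.log_sigma <= 0:
            raise ImagingConfigError("log_sigma must be positive")
        return self


#: A segmenter maps a single-channel image to a labeled map; the default
#: classical implementations below satisfy it, trained models may replace them.
Segmenter = Callable[[np.ndarray], np.ndarray]


def _otsu_foreground(img, sigma):
    sm = ndi.gaussian_filter(np.asarray(img, float), sigma)
    if np.ptp(sm) == 0:
        return np.zeros(img.shape, bool)
    return sm > threshold_otsu(sm)


def detect_organoids(dapi: np.ndarray, *, blur_sigma: float = 12.0,
                     min_area: int = 2000) -> np.ndarray:
    """Label organoid regions on the DAPI channel.

    Heavy Gaussian blur merges the nuclei of an organoid into one blob;
    Otsu thresholding, hole filling and a minimum-area filter follow.
    An all-zero image yields zero regions.
    """
    fg = _otsu_foreground(dapi, blur_sigma)
    fg = ndi.binary_fill_holes(fg)
    fg = remove_small_objects(fg, max_size=min_area - 1)
    return cc_label(fg)


def segment_nuclei(dapi: np.ndarray, *, blur_sigma: float = 1.5,
                   min_area: int = 30, peak_min_distance: int = 5) -> np.ndarray:
    """Label nuclei: smoothed Otsu foreground split by a distance-transform
    watershed, with sub-minimum-area labels removed."""
    fg = _otsu_foreground(dapi, blur_sigma)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(dapi.shape, np.int32)
    dist = ndi.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=peak_min_distance, labels=fg,
                           exclude_border=False)
    markers = np.zeros(dapi.shape, np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=fg)
    labels = remove_small_objects(labels, max_size=min_area - 1)
    return _relabel(labels)


def _relabel(labels):
    out = np.zeros_like(labels, np.int32)
    for i, lab in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == lab] = i
    return out


def call_cyclinA2_positive(fitc: np.ndarray, nuclei: np.ndarray, *,
                           sigma_small: float = 2.0, sigma_large: float = 8.0,
                           floor_k: float = 2.0) -> frozenset:
    """Call proliferation-marker-positive nuclei.

    A difference of Gaussians (small minus large) band-passes the FITC
    channel; pixels above ``floor_k`` times the robust background SD of the
    response are marker-positive.  Morphological reconstruction by dilation
    (8-connected geodesic reconstruction) of the nucleus foreground from the
    marker-positive-inside-nucleus pixels then propagates positivity to whole
    nuclei: a nucleus is positive iff any of its pixels is reconstructed.
    """
    if fitc.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: fitc {fitc.shape} vs nuclei {nuclei.shape}")
    if sigma_small >= sigma_large:
        raise ImagingConfigError("sigma_small must be < sigma_large")
    f = np.asarray(fitc, float)
    dog = ndi.gaussian_filter(f, sigma_small) - ndi.gaussian_filter(f, sigma_large)
    bg = dog[nuclei == 0]
    sd = 1.4826 * np.median(np.abs(bg - np.median(bg))) if bg.size else 0.0
    positive_px = dog > max(floor_k * sd, 1e-12)

    nuc_fg = nuclei > 0
    marker_img = (positive_px & nuc_fg).astype(np.uint8)
    if not marker_img.any():
        return frozenset()
    rec = reconstruction(marker_img, nuc_fg.astype(np.uint8),
                         method="dilation",
                         footprint=np.ones((3, 3), np.uint8))
    return frozenset(int(l) for l in np.unique(nuclei[rec > 0]) if l != 0)


def detect_rad51_foci(cy3: np.ndarray, *, sigma: float = 2.0,
                      threshold: float = 0.02) -> np.ndarray:
    """Detect bright punctate foci as scale-normalized -LoG maxima.

    Returns an (n, 2) float array of (row, col) centroids.  Dark spots on a
    bright background give a negative response and are never detected.
    Non-maximum suppression uses a radius of one ``sigma``.
    """
    if sigma <= 0:
        raise ImagingConfigError("sigma must be positive")
    img = np.asarray(cy3, float)
    resp = -(sigma ** 2) * ndi.gaussian_laplace(img, sigma)
    peaks = peak_local_max(resp, min_distance=max(1, int(round(sigma))),
                           threshold_abs=threshold, exclude_border=False)
    if len(peaks):
        # a dark blob's negated-LoG response has a positive surround ring;
        # gate peaks on being brighter than the image's typical level
        sm = ndi.gaussian_filter(img, sigma)
        bright = sm[tuple(peaks.T)] > np.median(sm)
        peaks = peaks[bright]
    return peaks.astype(float)


def count_foci_per_nucleus(foci: np.ndarray, nuclei: np.ndarray,
                           positives: frozenset):
    """Assign each focus to the nucleus containing its centroid and count.

    Returns ``(table, assignment)`` where ``table`` has one row per
    Cyclin A2-positive nucleus (nucleus, cyca2_positive, focus_count) and
    ``assignment`` records where every detection went: assigned, in a
    marker-negative nucleus (recorded but excluded), or on background —
    the three always sum to the number of detections.
    """
    foci = np.asarray(foci, float).reshape(-1, 2)
    counts = dict.fromkeys(sorted(positives), 0)
    n_bg = n_neg = n_assigned = 0
    for r, c in foci:
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < nuclei.shape[0] and 0 <= ci < nuclei.shape[1]):
            n_bg += 1
            continue
        lab = int(nuclei[ri, ci])
        if lab == 0:
            n_bg += 1
        elif lab in positives:
            counts[lab] += 1
            n_assigned += 1
        else:
            n_neg += 1
    table = pd.DataFrame({"nucleus": list(counts), "cyca2_positive": True,
                          "focus_count": [counts[k] for k in counts]})
    assignment = {"assigned": n_assigned, "negative_nucleus": n_neg,
                  "background": n_bg}
    return table, assignment


def _nucleus_organoid(nuclei, organoids):
    """Majority-overlap assignment of each nucleus to one organoid (0 = none)."""
    out = {}
    for lab in np.unique(nuclei[nuclei > 0]):
        vals, cnts = np.unique(organoids[nuclei == lab], return_counts=True)
        out[int(lab)] = int(vals[np.argmax(cnts)])
    return out


def quantify_slide(image: np.ndarray, config: Optional[ImagingConfig] = None,
                   *, model: str = "", condition: str = "",
                   nucleus_segmenter: Optional[Segmenter] = None) -> pd.DataFrame:
    """Full quantification of one 3-channel (DAPI, FITC, CY3) field.

    Output is one row per Cyclin A2-positive nucleus:
    (model, condition, organoid, nucleus, cyca2_positive, focus_count).
    """
    cfg = (config or ImagingConfig()).validate()
    if image.ndim != 3 or image.shape[0] != 3:
        raise ImagingConfigError(
            f"expected a (3, H, W) DAPI/FITC/CY3 stack, got shape {image.shape}")
    dapi, fitc, cy3 = image

    organoids = detect_organoids(dapi, blur_sigma=cfg.organoid_blur_sigma,
                                 min_area=cfg.organoid_min_area)
    if nucleus_segmenter is None:
        nuclei = segment_nuclei(dapi, blur_sigma=cfg.nucleus_blur_sigma,
                                min_area=cfg.nucleus_min_area,
                                peak_min_distance=cfg.nucleus_peak_min_distance)
    else:
        nuclei = nucleus_segmenter(dapi)
    positives = call_cyclinA2_positive(fitc, nuclei,
                                       sigma_small=cfg.dog_sigma_small,
                                       sigma_large=cfg.dog_sigma_large,
                                       floor_k=cfg.dog_floor_k)
    foci = detect_rad51_foci(cy3, sigma=cfg.log_sigma,
                             threshold=cfg.log_threshold)
    table, _ = count_foci_per_nucleus(foci, nuclei, positives)
    org_of = _nucleus_organoid(nuclei, organoids)
    table.insert(0, "model", model)
    table.insert(1, "condition", condition)
    table.insert(2, "organoid", table["nucleus"].map(org_of).fillna(0).astype(int))
    return table


def quantify_cohort(cohort, config: Optional[ImagingConfig] = None) -> pd.DataFrame:
    """Quantify every image of a synthetic cohort into one FociTable."""
    parts = []
    for model, conds in cohort.images.items():
        for cond, (img, _gt) in conds.items():
            parts.append(quantify_slide(img, config, model=model, condition=cond))
    return pd.concat(parts, ignore_index=True)
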