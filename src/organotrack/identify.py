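"""Single-organoid identification from a probability map.

The network is trained with a 2-pixel boundary drawn between organoids in
contact, so its predictions are marginally less confident along contact lines.
The identification pipeline exploits this: a Canny-style edge detector (Sobel
gradient → Gaussian blur → hysteresis threshold) finds those low-confidence
contours, removing them from the thresholded detection mask leaves one seed
region per organoid, and a watershed transform on the inverted probability map
grows each seed back out to the full organoid contour.  Small and
border-touching objects are then discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

#: connectivity used for connected components and seeds throughout
CONNECTIVITY = 2  # 8-connectivity


@dataclass(frozen=True)
class IdentifyParams:
    """Tunable parameters of the identification pipeline.

    Defaults reproduce the standard pipeline: probability threshold 0.5,
    opening with a radius-1 disk, Sobel gradient smoothed with a Gaussian
    (sigma = 2 px) and hysteresis-thresholded at 0.05 / 0.005 (units:
    probability per pixel), minimum organoid area 200 px, border-touching
    organoids removed.  ``seed_min_area`` (10 px) drops noise-split seeds
    before the watershed.
    """

    prob_threshold: float = 0.5
    gaussian_sigma: float = 2.0
    hysteresis_high: float = 0.05
    hysteresis_low: float = 0.005
    min_area: int = 200
    remove_border: bool = True
    opening_radius: int = 1
    seed_min_area: int = 10

    def __post_init__(self):
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.hysteresis_low >= self.hysteresis_high:
            raise ValueError("hysteresis_low must be < hysteresis_high")


def _check_prob(prob: np.ndarray) -> np.ndarray:
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim != 2:
        raise ValueError("probability map must be 2-D")
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    return prob


def threshold_and_open(prob: np.ndarray, params: IdentifyParams = IdentifyParams()) -> np.ndarray:
    """Binary detection mask: threshold then morphological opening (disk)."""
    prob = _check_prob(prob)
    mask = prob > params.prob_threshold
    if params.opening_radius > 0:
        mask = ndi.binary_opening(mask, structure=morphology.disk(params.opening_radius))
    return mask


def detect_edges(prob: np.ndarray, params: IdentifyParams = IdentifyParams()) -> np.ndarray:
    """Edge mask of low-confidence contours in the probability map.

    Sobel gradient magnitude, Gaussian-smoothed (sigma), then hysteresis
    thresholding: weak edges survive only when connected to strong ones.
    """
    prob = _check_prob(prob)
    grad = filters.sobel(prob)
    grad = ndi.gaussian_filter(grad, params.gaussian_sigma)
    return filters.apply_hysteresis_threshold(grad, params.hysteresis_low,
                                              params.hysteresis_high)


def find_seeds(mask: np.ndarray, edges: np.ndarray,
               params: IdentifyParams = IdentifyParams()) -> np.ndarray:
    """Label organoid centres: components of the mask with edges removed.

    Components smaller than ``seed_min_area`` are dropped so that noise
    fragments cannot split one organoid into several watershed basins.
    """
    mask = np.asarray(mask, dtype=bool)
    edges = np.asarray(edges, dtype=bool)
    if mask.shape != edges.shape:
        raise ValueError("mask and edge shapes differ")
    seeds = cc_label(mask & ~edges, connectivity=CONNECTIVITY)
    if params.seed_min_area > 1 and seeds.max() > 0:
        areas = np.bincount(seeds.ravel())
        kill = np.flatnonzero(areas < params.seed_min_area)
        seeds[np.isin(seeds, kill)] = 0
        seeds = _renumber_raster(seeds)
    return seeds


def watershed_separate(prob: np.ndarray, mask: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Assign every mask pixel to a seed by watershed on the inverted map.

    The probability map serves as an inverted heightmap (basins at confident
    interiors); each resulting label is then morphologically filled.
    """
    prob = _check_prob(prob)
    mask = np.asarray(mask, dtype=bool)
    seeds = np.asarray(seeds)
    if seeds.max() == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    labeled = watershed(-prob, markers=seeds, mask=mask, connectivity=CONNECTIVITY)
    out = labeled.astype(np.int32)
    for lab in np.unique(out):
        if lab == 0:
            continue
        filled = ndi.binary_fill_holes(out == lab)
        out[filled & (out == 0)] = lab
    return out


def filter_labels(labeled: np.ndarray, params: IdentifyParams = IdentifyParams()) -> np.ndarray:
    """Remove labels below ``min_area`` (strictly) and, optionally, labels
    touching the image border; renumber survivors 1..k by decreasing area."""
    labeled = np.asarray(labeled)
    out = labeled.copy()
    if out.max() == 0:
        return out.astype(np.int32)
    areas = np.bincount(out.ravel())
    kill = set(np.flatnonzero(areas < params.min_area)) - {0}
    if params.remove_border:
        border = np.concatenate([out[0, :], out[-1, :], out[:, 0], out[:, -1]])
        kill |= set(np.unique(border)) - {0}
    if kill:
        out[np.isin(out, list(kill))] = 0
    return _renumber_by_area(out)


def identify(prob: np.ndarray, params: IdentifyParams = IdentifyParams()) -> np.ndarray:
    """Full pipeline: probability map → labeled single-organoid image."""
    mask = threshold_and_open(prob, params)
    edges = detect_edges(prob, params)
    seeds = find_seeds(mask, edges, params)
    labeled = watershed_separate(prob, mask, seeds)
    return filter_labels(labeled, params)


def _renumber_raster(labeled: np.ndarray) -> np.ndarray:
    """Renumber labels consecutively from 1 in first-appearance raster order."""
    out = np.zeros_like(labeled, dtype=np.int32)
    ids = labeled.ravel()
    order = {}
    for lab in ids[ids > 0]:
        if lab not in order:
            order[lab] = len(order) + 1
    for lab, new in order.items():
        out[labeled == lab] = new
    return out


def _renumber_by_area(labeled: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k by decreasing area; ties broken by the raster
    position of each label's topmost-leftmost pixel (deterministic)."""
    labeled = np.asarray(labeled)
    ids = np.unique(labeled)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labeled.astype(np.int32)
    areas = np.bincount(labeled.ravel())
    first_pix = {}
    flat = labeled.ravel()
    seen = set()
    for pos, lab in enumerate(flat):
        if lab > 0 and lab not in seen:
            first_pix[lab] = pos
            seen.add(lab)
    ranked = sorted(ids, key=lambda lab: (-areas[lab], first_pix[lab]))
    out = np.zeros_like(labeled, dtype=np.int32)
    for new, lab in enumerate(ranked, start=1):
        out[labeled == lab] = new
    return out
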