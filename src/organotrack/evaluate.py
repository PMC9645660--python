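"""Validation metrics: IOU, Lin's concordance correlation, Bland–Altman
agreement, and tracking accuracy.

These quantify how well automated detections agree with ground truth (IOU on
pixel masks) and how well automated measurements agree with manual ones (CCC
and Bland–Altman on paired measurements, with a logit transform for metrics
bounded in (0, 1) such as circularity).  An IOU above 0.5 is the conventional
benchmark for a good segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from .track import MISSING, TrackTable


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    A probability map passed as ``pred`` is binarised at 0.5 first.  Two empty
    masks score 1 (no organoids, correctly predicted none).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    p = pred > 0.5 if np.issubdtype(pred.dtype, np.floating) else pred.astype(bool)
    t = truth > 0.5 if np.issubdtype(truth.dtype, np.floating) else truth.astype(bool)
    union = np.count_nonzero(p | t)
    if union == 0:
        return 1.0
    return np.count_nonzero(p & t) / union


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float


def ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2); it equals the
    Pearson correlation only when the two measurements share mean and
    variance, penalising location and scale shifts.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    n = x.size
    vx, vy = x.var(), y.var()
    if vx == 0 and vy == 0:
        raise ValueError("both measurements are constant")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    dmean = x.mean() - y.mean()
    rho_c = 2 * sxy / (vx + vy + dmean ** 2)
    rho_c = float(np.clip(rho_c, -1.0, 1.0))
    if abs(rho_c) >= 1.0 or vx == 0 or vy == 0:
        return CCCResult(rho_c, rho_c, rho_c)
    # Lin (1989) variance of the z-transformed coefficient
    r = sxy / np.sqrt(vx * vy)
    u = dmean / (vx * vy) ** 0.25
    r2 = max(r ** 2, 1e-12)
    one = 1 - rho_c ** 2
    var_z = ((1 - r2) * rho_c ** 2 / (r2 * one ** 2)
             + 2 * rho_c ** 3 * (1 - rho_c) * u ** 2 / (r * one ** 2)
             - rho_c ** 4 * u ** 4 / (2 * r2 * one ** 2)) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(rho_c)
    half = norm.ppf(1 - alpha / 2) * np.sqrt(var_z)
    return CCCResult(rho_c, float(np.tanh(z - half)), float(np.tanh(z + half)))


def logit_ccc(x, y, eps: float = 1e-3) -> CCCResult:
    """CCC of logit-transformed pairs, for metrics bounded in (0, 1).

    Values are clamped to [eps, 1-eps] before the transform so exact 0/1
    (e.g. a clipped circularity of 1.0) remain finite.
    """
    x = np.clip(np.asarray(x, dtype=np.float64), eps, 1 - eps)
    y = np.clip(np.asarray(y, dtype=np.float64), eps, 1 - eps)
    lx = np.log(x / (1 - x))
    ly = np.log(y / (1 - y))
    return ccc(lx, ly)


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman agreement between paired measurements x and y."""

    bias: float                       # mean(x - y)
    limits: tuple[float, float]       # bias -/+ 1.96 * SD(x - y)
    sd_diff: float
    n: int


def bland_altman(x, y) -> AgreementReport:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(bias, (bias - 1.96 * sd, bias + 1.96 * sd), sd, d.size)


def _align_track_ids(auto: TrackTable, reference: TrackTable) -> dict[int, int]:
    """One-to-one auto→reference track-id map maximising total agreement.

    Automated and reference track ids are arbitrary, so before scoring we find
    the id correspondence (Hungarian on per-pair agreement counts) that gives
    the reference the best case.
    """
    a_ids = auto.track_ids()
    r_ids = reference.track_ids()
    agree = np.zeros((len(a_ids), len(r_ids)))
    for i, a in enumerate(a_ids):
        for j, r in enumerate(r_ids):
            common = 0
            for f, lab in auto.entries[a].items():
                if lab != MISSING and reference.entries[r].get(f) == lab:
                    common += 1
            agree[i, j] = common
    rows, cols = linear_sum_assignment(-agree)
    return {a_ids[r]: r_ids[c] for r, c in zip(rows, cols) if agree[r, c] > 0}


def tracking_accuracy(auto: TrackTable, reference: TrackTable) -> dict[int, float]:
    """Per-frame fraction of organoids whose track assignment agrees with the
    reference, after optimal global alignment of the two tables' track ids."""
    mapping = _align_track_ids(auto, reference)
    frames = sorted({f for tr in reference.entries.values() for f, lab in tr.items()
                     if lab != MISSING})
    out = {}
    for f in frames:
        ref_at = reference.labels_at(f)           # ref tid -> label
        auto_at = auto.labels_at(f)               # auto tid -> label
        mapped = {mapping[a]: lab for a, lab in auto_at.items() if a in mapping}
        total = len(ref_at)
        if total == 0:
            continue
        agree = sum(1 for rtid, lab in ref_at.items() if mapped.get(rtid) == lab)
        out[f] = agree / total
    return out
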