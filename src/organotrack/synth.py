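"""Synthetic organoid-image fixtures with known ground truth.

Generates everything the test-bench needs without real microscopy data:

* brightfield-like intensity images of elliptical, irregular-contour blobs
  (textured interiors, dark rims, optional bubble/debris distractors),
* ground-truth instance label images,
* probability-like maps that mimic a trained network's output — confident
  interiors, low-confidence 2-pixel valleys where organoids touch — so the
  identification pipeline can be exercised against exact truth,
* time-lapse sequences with per-organoid drift, growth, scheduled
  disappearances/appearances and exponential fluorescence, with the true
  track table recorded,
* dose-response tables drawn from a 4-parameter logistic with known EC50.

The generator emulates the statistical structure the pipeline relies on (a
thresholdable foreground, reduced boundary confidence, frame-to-frame pixel
overlap), not microscope optics; all stochastic choices flow from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.segmentation import find_boundaries

from .track import TrackTable


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic scene.

    Probability levels mirror a well-trained network: 0.9 inside organoids,
    0.05 outside, with ``valley_depth`` (0.5) subtracted along a
    ``valley_width``-pixel (2) band wherever two organoids touch — the
    boundary-confidence dip that seeds the separation pipeline.
    ``noise_sd`` is per-pixel sensor noise on the intensity image;
    ``prob_noise_sd`` / ``prob_noise_scale`` control the smooth, spatially
    correlated confidence ripple added to the probability map.
    """

    image_size: int = 384
    n_organoids: int = 8
    radius_range: tuple[float, float] = (12.0, 28.0)
    touching_pairs: int = 0
    valley_width: int = 2
    valley_depth: float = 0.5
    background_level: float = 0.05
    interior_level: float = 0.9
    noise_sd: float = 0.02
    prob_noise_sd: float = 0.005
    prob_noise_scale: float = 4.0
    boundary_irregularity: float = 0.08
    min_gap: float = 12.0
    border_margin: float = 12.0
    distractors: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_organoids < 2 * self.touching_pairs:
            raise ValueError("touching_pairs requires 2 organoids each")
        if not 0 < self.interior_level - self.valley_depth < self.interior_level:
            raise ValueError("valley must stay within (0, interior_level)")


@dataclass
class Blob:
    """One organoid: a radially perturbed ellipse."""

    cy: float
    cx: float
    a: float            # semi-major axis, px
    b: float            # semi-minor axis, px
    theta: float        # orientation, rad
    harmonics: np.ndarray  # (k, amplitude, phase) rows perturbing the radius

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        phi = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        pert = np.ones_like(phi)
        for k, amp, ph in self.harmonics:
            pert += amp * np.cos(k * phi + ph)
        ry = self.a * np.sin(phi) * pert
        rx = self.b * np.cos(phi) * pert
        c, s = np.cos(self.theta), np.sin(self.theta)
        rows = self.cy + c * ry - s * rx
        cols = self.cx + s * ry + c * rx
        rr, cc = draw_polygon(rows, cols, shape=shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out

    @property
    def r_max(self) -> float:
        return max(self.a, self.b) * (1 + float(np.abs(self.harmonics[:, 1]).sum()))


def _sample_blob(rng: np.random.Generator, spec: FixtureSpec, cy: float, cx: float) -> Blob:
    r_lo, r_hi = spec.radius_range
    a = rng.uniform(r_lo, r_hi)
    b = a * rng.uniform(0.6, 1.0)
    harmonics = np.array([[k, rng.uniform(0, spec.boundary_irregularity), rng.uniform(0, 2 * np.pi)]
                          for k in (2, 3, 4)])
    return Blob(cy, cx, a, b, rng.uniform(0, np.pi), harmonics)


def _place_blobs(rng: np.random.Generator, spec: FixtureSpec,
                 extra_clearance: float = 0.0) -> list[Blob]:
    """Rejection-sample blob positions: touching pairs first (centres at
    ~90% of the sum of effective radii so masks abut), then isolated blobs
    separated by at least ``min_gap`` plus any growth/drift clearance."""
    size = spec.image_size
    blobs: list[Blob] = []
    pair_partner: dict[int, int] = {}

    def fits(cand: Blob, ignore: set[int]) -> bool:
        m = spec.border_margin + cand.r_max
        if not (m < cand.cy < size - m and m < cand.cx < size - m):
            return False
        for i, other in enumerate(blobs):
            if i in ignore:
                continue
            d = np.hypot(cand.cy - other.cy, cand.cx - other.cx)
            if d < cand.r_max + other.r_max + spec.min_gap + extra_clearance:
                return False
        return True

    n_isolated = spec.n_organoids - 2 * spec.touching_pairs
    shape = (size, size)
    for _ in range(spec.touching_pairs):
        for attempt in range(3000):
            first = _sample_blob(rng, spec, rng.uniform(0, size), rng.uniform(0, size))
            if not fits(first, set()):
                continue
            ang = rng.uniform(0, 2 * np.pi)
            second = _sample_blob(rng, spec, 0.0, 0.0)
            # walk the second blob inward until the rasterised masks first
            # overlap, so the pair abuts without either shape being swallowed
            m1 = first.mask(shape)
            d = first.r_max + second.r_max + 2
            touched = False
            while d > 2:
                second.cy = first.cy + d * np.sin(ang)
                second.cx = first.cx + d * np.cos(ang)
                if (m1 & second.mask(shape)).sum() >= 2:
                    touched = True
                    break
                d -= 1.0
            if not touched:
                continue
            blobs.append(first)
            if fits(second, {len(blobs) - 1}):
                pair_partner[len(blobs) - 1] = len(blobs)
                blobs.append(second)
                break
            blobs.pop()
        else:
            raise RuntimeError("could not place a touching pair; spec too crowded")
    for _ in range(n_isolated):
        for attempt in range(3000):
            cand = _sample_blob(rng, spec, rng.uniform(0, size), rng.uniform(0, size))
            if fits(cand, set()):
                blobs.append(cand)
                break
        else:
            raise RuntimeError("could not place all organoids; spec too crowded")
    return blobs


def _label_blobs(blobs: list[Blob], shape: tuple[int, int]) -> np.ndarray:
    """Truth labels in placement order; overlap pixels keep the earlier id."""
    labels = np.zeros(shape, dtype=np.int32)
    for i, blob in enumerate(blobs, start=1):
        m = blob.mask(shape)
        labels[m & (labels == 0)] = i
    return labels


def _contact_band(labels: np.ndarray, width: int) -> np.ndarray:
    """Pixels within width/2 of any boundary between two different labels."""
    band = np.zeros(labels.shape, dtype=bool)
    ids = [int(v) for v in np.unique(labels) if v > 0]
    n_dil = max(1, round(width / 2))
    dil = {}
    for i in ids:
        dil[i] = ndi.binary_dilation(labels == i, iterations=n_dil)
    for idx, i in enumerate(ids):
        for j in ids[idx + 1:]:
            band |= dil[i] & dil[j]
    return band & (labels > 0)


def _probability_map(labels: np.ndarray, spec: FixtureSpec,
                     rng: np.random.Generator) -> np.ndarray:
    prob = np.full(labels.shape, spec.background_level)
    prob[labels > 0] = spec.interior_level
    if spec.touching_pairs > 0 or len(np.unique(labels)) > 2:
        band = _contact_band(labels, spec.valley_width)
        prob[band] = spec.interior_level - spec.valley_depth
    if spec.prob_noise_sd > 0:
        # network outputs are smooth and saturated, so their fluctuations are
        # spatially correlated confidence ripple, not per-pixel sensor noise
        ripple = ndi.gaussian_filter(rng.normal(0, 1.0, labels.shape),
                                     spec.prob_noise_scale)
        sd = ripple.std()
        if sd > 0:
            prob = prob + ripple * (spec.prob_noise_sd / sd)
    return np.clip(prob, 0.0, 1.0)


def _intensity_image(labels: np.ndarray, spec: FixtureSpec,
                     rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    img = 0.75 + 0.05 * (xx - size / 2) / size + 0.03 * (yy - size / 2) / size
    texture = ndi.gaussian_filter(rng.normal(0, 1.0, labels.shape), 2.0)
    for i in [int(v) for v in np.unique(labels) if v > 0]:
        m = labels == i
        img[m] = rng.uniform(0.38, 0.52) + 0.08 * texture[m]
    rim = find_boundaries(labels, mode="inner")
    img[rim] = 0.28
    if spec.distractors:
        for _ in range(3):  # bubbles: bright disc with a dark ring
            r = rng.uniform(6, 12)
            cy, cx = rng.uniform(r + 2, size - r - 2, size=2)
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img[d2 < r ** 2] = 0.92
            img[(d2 >= (r - 1.5) ** 2) & (d2 < (r + 1.5) ** 2)] = 0.2
        speck = rng.random(labels.shape) < 0.0015  # debris speckle
        img[speck & (labels == 0)] = 0.25
    img = img + rng.normal(0, spec.noise_sd, labels.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def make_scene(spec: FixtureSpec = FixtureSpec()
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One synthetic scene: (intensity image, truth labels, probability map)."""
    rng = np.random.default_rng(spec.seed)
    blobs = _place_blobs(rng, spec)
    shape = (spec.image_size, spec.image_size)
    labels = _label_blobs(blobs, shape)
    prob = _probability_map(labels, spec, rng)
    img = _intensity_image(labels, spec, rng)
    return img, labels, prob


@dataclass(frozen=True)
class TimelapseSpec:
    """Conditions for a synthetic time-lapse.

    Drift is a per-frame random-walk step (px); growth multiplies each
    organoid's axes per frame.  ``disappearance_schedule`` /
    ``appearance_schedule`` map frame index → organoid identities removed /
    number of organoids added at that frame.  ``fluor_rates`` gives per-identity
    exponential growth rates of the uniform fluorescence intensity
    (default_rate applies where unspecified); ``fluor_baselines`` sets each
    identity's frame-0 intensity.
    """

    n_frames: int = 10
    drift_per_frame: float = 2.0
    growth_rate: float = 0.02
    disappearance_schedule: dict[int, tuple[int, ...]] = field(default_factory=dict)
    appearance_schedule: dict[int, int] = field(default_factory=dict)
    fluor_rates: dict[int, float] = field(default_factory=dict)
    default_fluor_rate: float = 0.05
    fluor_baselines: dict[int, float] = field(default_factory=dict)
    default_fluor_baseline: float = 20.0
    seed: int = 0


@dataclass
class Timelapse:
    """A generated sequence plus its ground truth."""

    images: list[np.ndarray]
    probs: list[np.ndarray]
    labels: list[np.ndarray]          # truth instance labels per frame
    table: TrackTable                 # truth tracks (track id = identity)
    fluor: list[np.ndarray]
    identity_maps: list[dict[int, int]]  # per frame: label -> identity


def make_timelapse(ts: TimelapseSpec = TimelapseSpec(),
                   scene: FixtureSpec = FixtureSpec(n_organoids=5)) -> Timelapse:
    """Synthesise a drifting/growing time-lapse with known tracks.

    Placement reserves clearance for the full growth and drift budget so
    organoids stay distinct; truth labels are rendered per frame and the truth
    TrackTable records each identity's label in every frame it is present.
    """
    rng = np.random.default_rng(ts.seed if ts.seed else scene.seed)
    growth_total = (1 + ts.growth_rate) ** ts.n_frames
    r_hi = scene.radius_range[1]
    clearance = 2 * r_hi * (growth_total - 1) + 2 * ts.drift_per_frame * np.sqrt(ts.n_frames)
    blobs = _place_blobs(rng, scene, extra_clearance=clearance)
    shape = (scene.image_size, scene.image_size)

    alive: dict[int, Blob] = {i + 1: b for i, b in enumerate(blobs)}
    next_identity = len(blobs) + 1
    table = TrackTable()
    images, probs, labels_seq, fluor_seq, id_maps = [], [], [], [], []
    tid_of: dict[int, int] = {}

    for t in range(ts.n_frames):
        for gid in ts.disappearance_schedule.get(t, ()):  # removals first
            alive.pop(gid, None)
        for _ in range(ts.appearance_schedule.get(t, 0)):
            for attempt in range(3000):
                cand = _sample_blob(rng, scene, rng.uniform(0, scene.image_size),
                                    rng.uniform(0, scene.image_size))
                ok = scene.border_margin + cand.r_max < cand.cy < scene.image_size - scene.border_margin - cand.r_max \
                    and scene.border_margin + cand.r_max < cand.cx < scene.image_size - scene.border_margin - cand.r_max \
                    and all(np.hypot(cand.cy - b.cy, cand.cx - b.cx)
                            > cand.r_max + b.r_max + scene.min_gap + clearance / 2
                            for b in alive.values())
                if ok:
                    alive[next_identity] = cand
                    next_identity += 1
                    break
            else:
                raise RuntimeError("could not place appearing organoid")

        gids = sorted(alive)
        frame_labels = _label_blobs([alive[g] for g in gids], shape)
        id_map = {lab: gid for lab, gid in enumerate(gids, start=1)}
        for lab, gid in id_map.items():
            if gid not in tid_of:
                tid_of[gid] = table.new_track(t, lab)
            else:
                table.record(tid_of[gid], t, lab)
        prob = _probability_map(frame_labels, scene, rng)
        img = _intensity_image(frame_labels, scene, rng)
        fluor = np.zeros(shape, dtype=np.float64)
        for lab, gid in id_map.items():
            base = ts.fluor_baselines.get(gid, ts.default_fluor_baseline)
            rate = ts.fluor_rates.get(gid, ts.default_fluor_rate)
            fluor[frame_labels == lab] = base * np.exp(rate * t)
        images.append(img)
        probs.append(prob)
        labels_seq.append(frame_labels)
        fluor_seq.append(fluor)
        id_maps.append(id_map)

        for gid in gids:  # evolve for the next frame
            b = alive[gid]
            ang = rng.uniform(0, 2 * np.pi)
            b.cy += ts.drift_per_frame * np.sin(ang)
            b.cx += ts.drift_per_frame * np.cos(ang)
            b.a *= 1 + ts.growth_rate
            b.b *= 1 + ts.growth_rate
    return Timelapse(images, probs, labels_seq, table, fluor_seq, id_maps)


def make_dose_response(ec50: float = 25.0, hill: float = 1.0,
                       doses=(3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
                       replicates: int = 6, noise_sd: float = 0.0,
                       top: float = 1.0, bottom: float = 0.0,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """4PL dose-response table with multiplicative noise and recorded truth.

    Response = bottom + (top - bottom) / (1 + (dose/ec50)^hill), so ``top`` is
    the low-dose asymptote (e.g. full viability).  Returns (table, truth).
    """
    doses = np.asarray(doses, dtype=np.float64)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        clean = bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)
        for r in range(replicates):
            noisy = clean * (1.0 + rng.normal(0, noise_sd)) if noise_sd > 0 else clean
            rows.append({"dose": d, "replicate": r, "response": noisy})
    truth = {"ec50": ec50, "hill": hill, "top": top, "bottom": bottom}
    return pd.DataFrame(rows), truth
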