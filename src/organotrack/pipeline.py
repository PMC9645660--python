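"""End-to-end pipeline: images → probability maps → labels → tracks → CSV.

``run_pipeline`` ties the modules together and writes every artifact a run
produces (probability TIFFs, labeled TIFFs, track CSV, measurement CSV,
overlay PNGs and a JSON run manifest) into one output directory.  Given the
same inputs, weights and seed, a re-run is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .identify import IdentifyParams, identify
from .measure import fluorescence_per_area, normalize_to_first_detection, region_properties
from .track import TrackTable, relabel_stack, track_sequence
from .unet import load_model, predict


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults match the pipeline's
    standard parameters; see IdentifyParams)."""

    input_path: str = ""
    output_dir: str = "organotrack_out"
    weights: str | None = None
    inputs_are_probabilities: bool = False
    fluorescence_path: str | None = None
    identify_params: IdentifyParams = field(default_factory=IdentifyParams)
    track: bool = True
    pad_cost: float = 1.0
    max_missing: int = 1
    pixel_scale: float | None = None
    seed: int = 0


def measurement_table(labels_seq: list[np.ndarray], table: TrackTable | None = None,
                      fluor_seq: list[np.ndarray] | None = None,
                      pixel_scale: float | None = None) -> pd.DataFrame:
    """One row per (frame, instance label) with morphometrics, the track id
    (when tracked), fluorescence density and its first-detection-normalised
    value (when a fluorescence channel is given)."""
    label_to_track = {}
    if table is not None:
        for t in range(len(labels_seq)):
            for tid, lab in table.labels_at(t).items():
                label_to_track[(t, lab)] = tid
    densities = {}
    if fluor_seq is not None:
        for t, (lab_img, fl) in enumerate(zip(labels_seq, fluor_seq)):
            for lab, dens in fluorescence_per_area(lab_img, fl).items():
                densities[(t, lab)] = dens
    norm = {}
    if table is not None and fluor_seq is not None:
        for tid, series in normalize_to_first_detection(table, densities).items():
            for f, v in series.items():
                norm[(tid, f)] = v
    rows = []
    for t, lab_img in enumerate(labels_seq):
        for rec in region_properties(lab_img, pixel_scale):
            tid = label_to_track.get((t, rec.id))
            rows.append({
                "frame": t, "label": rec.id, "track_id": tid,
                "area_px2": rec.area, "area_um2": rec.area_um2,
                "perimeter_px": rec.perimeter, "perimeter_um": rec.perimeter_um,
                "centroid_row": rec.centroid[0], "centroid_col": rec.centroid[1],
                "circularity": rec.circularity, "solidity": rec.solidity,
                "eccentricity": rec.eccentricity,
                "touches_border": rec.touches_border,
                "fluor_density": densities.get((t, rec.id)),
                "fluor_norm_first_detection": norm.get((tid, t)) if tid else None,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write artifacts; returns artifact paths.

    Raises before writing anything if inputs are unreadable or weights are
    missing when prediction is requested.
    """
    frames, names = oio.read_stack_or_dir(config.input_path)
    if config.inputs_are_probabilities:
        probs = [np.clip(np.asarray(f, dtype=np.float64), 0, 1) for f in frames]
        model = None
    else:
        if not config.weights:
            raise ValueError("weights file required to predict from intensity images "
                             "(or set inputs_are_probabilities)")
        model = load_model(config.weights)
        probs = [predict(f, model) for f in frames]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_seq = [identify(p, config.identify_params) for p in probs]

    artifacts: dict[str, object] = {}
    for name, p, lab, img in zip(names, probs, labels_seq, frames):
        oio.write_probability(out / f"{name}_prob.tif", p)
        oio.write_labeled(out / f"{name}_labels.tif", lab)
        oio.write_overlay(out / f"{name}_overlay.png", np.asarray(img, dtype=np.float64), lab)
    artifacts["labeled"] = [str(out / f"{n}_labels.tif") for n in names]

    table = None
    fluor_seq = None
    if config.fluorescence_path:
        fluor_seq, _ = oio.read_stack_or_dir(config.fluorescence_path)
        if len(fluor_seq) != len(frames):
            raise ValueError("fluorescence frame count does not match input frames")
    if config.track and len(labels_seq) >= 1:
        table = track_sequence(labels_seq, pad_cost=config.pad_cost,
                               max_missing=config.max_missing)
        table.to_dataframe().to_csv(out / "tracks.csv", index=False)
        stack = np.stack(relabel_stack(labels_seq, table))
        oio.write_labeled(out / "tracked_labels.tif", stack)
        artifacts["tracks"] = str(out / "tracks.csv")

    mtab = measurement_table(labels_seq, table, fluor_seq, config.pixel_scale)
    mtab.to_csv(out / "measurements.csv", index=False)
    artifacts["measurements"] = str(out / "measurements.csv")

    manifest = {
        "config": {**asdict(config), "identify_params": asdict(config.identify_params)},
        "n_frames": len(frames),
        "frame_names": names,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


def _versions() -> dict:
    import numpy, scipy, skimage
    from . import __version__
    return {"organotrack": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "scikit-image": skimage.__version__}
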