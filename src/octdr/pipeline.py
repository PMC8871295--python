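"""Orchestration glue: manifest -> segmentation -> features -> diagnosis."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, mgrf, propagation
from .io_formats import BScanVolume, LayerLabelMap, RunConfig, read_labelmap, read_volume


def subject_features(
    volume: BScanVolume,
    labelmap: LayerLabelMap,
    config: RunConfig,
    segment: bool = True,
    class_label: str = "",
) -> pd.DataFrame:
    """Feature rows for one subject.

    With ``segment=True`` only the mid scan of ``labelmap`` is trusted and
    the rest of the volume is labeled by propagation (the full pipeline);
    otherwise the provided labels are used for every scan.
    """
    if segment and volume.n_scans > 1:
        mid = labelmap.labels[volume.mid_index]
        labelmap = propagation.propagate_volume(volume, mid, config.propagation)
    return mgrf.extract_volume_features(volume, labelmap, config.mgrf, class_label)


def cohort_features(
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
    segment: bool = True,
    base_dir: Path | str | None = None,
) -> pd.DataFrame:
    """Feature table for a whole manifest (subject_id, class, paths)."""
    config = config or RunConfig()
    base = Path(base_dir) if base_dir is not None else None
    tables = []
    for _, row in manifest.iterrows():
        vp = Path(row["volume_path"])
        lp = Path(row["labelmap_path"])
        if base is not None and not vp.is_absolute():
            vp, lp = base / vp, base / lp
        volume = read_volume(vp, config.q_levels, subject_id=row["subject_id"])
        labelmap = read_labelmap(lp)
        tables.append(
            subject_features(volume, labelmap, config, segment, row["class"])
        )
    return pd.concat(tables, ignore_index=True)


def predict_subject(
    ensemble: classify.EnsembleModel,
    volume: BScanVolume,
    mid_labels: np.ndarray,
    config: RunConfig,
) -> dict:
    """Segment, featurize and diagnose one unseen volume."""
    labelmap = propagation.propagate_volume(volume, mid_labels, config.propagation)
    features = mgrf.extract_volume_features(volume, labelmap, config.mgrf)
    features["class"] = "healthy"  # placeholder; posteriors ignore it
    _, _, post = classify.ensemble_posteriors(ensemble, features)
    cls, votes, mean_post = classify.majority_vote(post[0])
    return {
        "subject_id": volume.subject_id,
        "diagnosis": cls,
        "votes": {"healthy": votes[0], "DR": votes[1]},
        "mean_posterior": {"healthy": mean_post[0], "DR": mean_post[1]},
        "layer_posteriors": {
            str(l): {"healthy": post[0, l - 1, 0], "DR": post[0, l - 1, 1]}
            for l in range(1, 13)
        },
    }
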