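"""End-to-end helpers gluing the pipeline stages together.

These functions operate on in-memory `TrajectoryRecord` lists and are shared
by the command-line interface, the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import trajectory_to_array
from .matching import TemplateLibrary, build_template, classify
from .posture_map import DEFAULT_DEPTH_FRAC, PostureMap, build_posture_map
from .som import TrainingSchedule, train
from .synthetic_motion import TrajectoryRecord
from .trajmap import collapse_repetitions, encode, render_trajectory_map

__all__ = [
    "record_features",
    "train_posture_map",
    "build_library",
    "encode_record",
    "classify_record",
    "EvaluationReport",
    "evaluate",
]


def record_features(records: list[TrajectoryRecord]) -> list[np.ndarray]:
    """Per-record (n_frames, 71) scaled feature arrays."""
    return [trajectory_to_array(r.frames) for r in records]


def train_posture_map(
    records: list[TrajectoryRecord],
    M: int = 10,
    N: int = 10,
    schedule: TrainingSchedule | None = None,
    depth_frac: float = DEFAULT_DEPTH_FRAC,
    max_train_frames: int = 6000,
    feature_arrays: list[np.ndarray] | None = None,
) -> PostureMap:
    """Train the map on all frames of ``records`` and segment it.

    When the corpus exceeds ``max_train_frames`` frames, a seeded uniform
    subsample is used for map training (the map only needs coverage of
    posture space, not every frame).
    """
    if schedule is None:
        schedule = TrainingSchedule()
    if feature_arrays is None:
        feature_arrays = record_features(records)
    data = np.concatenate(feature_arrays, axis=0)
    if data.shape[0] > max_train_frames:
        rng = np.random.default_rng(schedule.seed)
        idx = rng.choice(data.shape[0], size=max_train_frames, replace=False)
        data = data[np.sort(idx)]
    grid = train(data, M, N, schedule)
    return build_posture_map(grid, data, depth_frac=depth_frac)


def encode_record(pmap: PostureMap, feats: np.ndarray):
    """Collapsed posture sequence of one feature array."""
    return collapse_repetitions(encode(pmap, feats))


def build_library(
    pmap: PostureMap,
    records: list[TrajectoryRecord],
    instances_per_label: int | None = 5,
    threshold: float = 0.5,
    feature_arrays: list[np.ndarray] | None = None,
) -> TemplateLibrary:
    """One LCS template per label.

    Instances are picked round-robin across subjects (first each subject's
    first repetition, then second repetitions, ...) so a 5-instance template
    reflects five different subjects when five are available.
    """
    if feature_arrays is None:
        feature_arrays = record_features(records)
    by_label: dict[str, list[tuple[int, int, np.ndarray]]] = {}
    for rec, feats in zip(records, feature_arrays):
        by_label.setdefault(rec.label, []).append((rec.rep, rec.subject, feats))
    lib = TemplateLibrary(threshold=threshold)
    for label in sorted(by_label):
        ordered = [f for _, _, f in sorted(by_label[label], key=lambda t: (t[0], t[1]))]
        if instances_per_label is not None:
            ordered = ordered[:instances_per_label]
        lib.add(build_template(pmap, label, ordered))
    return lib


def classify_record(pmap: PostureMap, lib: TemplateLibrary, feats: np.ndarray):
    seq = encode_record(pmap, feats)
    tmap = render_trajectory_map(pmap, seq)
    return classify(tmap, lib)


@dataclass
class EvaluationReport:
    rows: list[dict] = field(default_factory=list)  # label, predicted, score, rejected
    accuracy: float | None = None
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.rows)


def evaluate(
    pmap: PostureMap,
    lib: TemplateLibrary,
    records: list[TrajectoryRecord],
    feature_arrays: list[np.ndarray] | None = None,
) -> EvaluationReport:
    """Classify every record; accuracy counts rejections as errors."""
    if feature_arrays is None:
        feature_arrays = record_features(records)
    report = EvaluationReport()
    n_correct = 0
    for rec, feats in zip(records, feature_arrays):
        result = classify_record(pmap, lib, feats)
        predicted = result.label if not result.rejected else "REJECT"
        report.rows.append(
            {
                "label": rec.label,
                "subject": rec.subject,
                "rep": rec.rep,
                "predicted": predicted,
                "score": result.score,
                "rejected": result.rejected,
            }
        )
        key = (rec.label, predicted)
        report.confusion[key] = report.confusion.get(key, 0) + 1
        if predicted == rec.label:
            n_correct += 1
    if report.rows:
        report.accuracy = n_correct / len(report.rows)
    return report
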