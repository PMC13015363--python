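"""End-to-end orchestration: detect -> correct -> associate -> stitch -> divisions.

The pipeline can start from raw intensity volumes (running per-frame
detection) or from a precomputed detection set / label series.  Long
recordings are processed in overlapping frame batches that are corrected
and associated independently, then stitched by mutual nearest neighbours;
division detection runs once on the stitched forest so that its
track-length gates see full-length tracks.  A whole-scene run is simply
the single-batch special case of the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .correct import CorrectionReport, iterate_correction
from .detect import DetectionSet, detect_series, detections_from_labels
from .forest import LineageForest
from .io import LabelSeries, VolumeSeries
from .lineage import (
    DivisionCandidate,
    associate_tracklets,
    detect_divisions,
    stitch_batches,
    tracks_to_forest,
)


@dataclass
class PipelineResult:
    forest: LineageForest
    detections: DetectionSet
    reports: list[CorrectionReport] = field(default_factory=list)
    division_candidates: list[DivisionCandidate] = field(default_factory=list)
    batches: list[tuple[int, int]] = field(default_factory=list)


def _restrict(dets: DetectionSet, a: int, b: int) -> DetectionSet:
    """Deep copy of a detection set restricted to frames [a, b]."""
    labels = dets.labels
    frames = [
        f.copy() if a <= t <= b else np.zeros_like(f)
        for t, f in enumerate(labels.frames)
    ]
    out = DetectionSet(LabelSeries(frames, labels.voxel_size_um))
    for t, i in dets.all_keys():
        if a <= t <= b:
            d = dets.get(t, i)
            out.add(
                type(d)(
                    d.id, d.frame, d.centroid_um.copy(), d.volume_um3,
                    d.voxel_count, d.mean_intensity, d.z_score, d.scale_um,
                )
            )
    return out


def plan_batches(n_frames: int, batch_size: int, overlap: int) -> list[tuple[int, int]]:
    """Overlapping batch spans covering [0, n_frames)."""
    if batch_size <= 0 or batch_size >= n_frames:
        return [(0, n_frames - 1)]
    if overlap < 1 or overlap >= batch_size:
        raise ValueError("overlap must be in [1, batch_size)")
    spans = []
    start = 0
    while True:
        end = min(start + batch_size - 1, n_frames - 1)
        spans.append((start, end))
        if end >= n_frames - 1:
            break
        start = end - overlap + 1
    return spans


def run_tracking(
    series: VolumeSeries,
    config: PipelineConfig,
    detections: DetectionSet | None = None,
    labels: LabelSeries | None = None,
) -> PipelineResult:
    """Run the full pipeline and return the assembled lineage forest."""
    from .preprocess import estimate_flow_series, preprocess_series

    series = preprocess_series(series, config)
    flow = None
    if config.preprocess.flow.enabled:
        flow = estimate_flow_series(series, config.preprocess.flow.block_size)

    if detections is None:
        if labels is not None:
            detections = detections_from_labels(series, labels)
        else:
            detections = detect_series(series, config)

    spans = plan_batches(
        series.n_frames, config.lineage.batch_size, config.lineage.batch_overlap
    )
    forests = []
    reports = []
    final_dets = detections
    for a, b in spans:
        sub = _restrict(detections, a, b) if len(spans) > 1 else detections
        sub, tracklets, report = iterate_correction(series, sub, config, flow_field=flow)
        merged = associate_tracklets(tracklets, sub, config)
        forests.append(tracks_to_forest(merged, sub))
        reports.append(report)
        if len(spans) == 1:
            final_dets = sub
    forest = (
        forests[0]
        if len(forests) == 1
        else stitch_batches(
            forests, config.lineage.batch_overlap, config.link.gating_radius_um
        )
    )
    candidates = detect_divisions(forest, config)
    forest.validate()
    return PipelineResult(
        forest=forest,
        detections=final_dets,
        reports=reports,
        division_candidates=candidates,
        batches=spans,
    )
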