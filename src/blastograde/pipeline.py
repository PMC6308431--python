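"""End-to-end orchestration: image in, grade out.

``grade_image`` runs standardize -> two-stage circle detection; when
detection fails and rescue is allowed, the smartphone rescaling path is
tried and detection re-run on the expanded image.  A successful
segmentation feeds feature extraction, reduction to the ensemble's input
schema, and the three-network mode vote.  ``batch_grade`` applies this
over a manifest and summarises segmentation counts and agreement with a
reference grading column when present.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from . import rescale as rsc
from . import segmentation as seg
from .grading import GradePrediction, TrainedANN, ensemble_predict
from .imaging import RawImage, load_image, standardize
from .stats import agreement_rate

logger = logging.getLogger("blastograde")


@dataclass
class PipelineConfig:
    allow_rescue: bool = True
    min_strength: float = seg.MIN_STRENGTH
    fill_threshold: float = seg.DEFAULT_FILL_THRESHOLD
    target_radius: float = rsc.TARGET_RADIUS
    seed: int = 0

    def snapshot(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineReport:
    image_id: str
    source_tag: str
    rescued: bool = False
    status: str = "none"
    feature_vector: Optional[feat.FeatureVector] = None
    prediction: Optional[GradePrediction] = None
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def grade(self) -> Optional[int]:
        return self.prediction.final_grade if self.prediction is not None else None


def _reduce_vector(fv: feat.FeatureVector, kept_names: Sequence[str]) -> np.ndarray:
    d = fv.as_dict()
    try:
        return np.array([d[name] for name in kept_names])
    except KeyError as exc:
        raise feat.ExtractionError(f"feature {exc} missing from extracted vector")


def grade_image(image: str | Path | RawImage, models: Sequence[TrainedANN],
                config: Optional[PipelineConfig] = None) -> PipelineReport:
    """Grade a single embryo image with the three-network ensemble."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    if isinstance(image, (str, Path)):
        raw = load_image(image)
        image_id = str(image)
    else:
        raw = image
        image_id = raw.origin_path
    report = PipelineReport(image_id=image_id, source_tag=raw.source_tag,
                            config=config.snapshot())

    std = standardize(raw)
    circle = seg.detect_circle(std, min_strength=config.min_strength)
    if circle is None and config.allow_rescue:
        logger.info("stage=rescue image=%s outcome=attempting", image_id)
        res = rsc.rescale_image(raw, target_radius=config.target_radius)
        if res.found_by != "not_found":
            report.rescued = True
            std = res.output
            circle = seg.detect_circle(std, min_strength=config.min_strength)
    report.timings["detect_s"] = time.perf_counter() - t0

    if circle is None:
        logger.info("stage=segment image=%s outcome=none", image_id)
        return report

    try:
        segmentation = seg.isolate_regions(std, circle)
    except seg.DegenerateRegionError:
        return report
    segmentation.status = seg.classify_status(segmentation,
                                              fill_threshold=config.fill_threshold)
    report.status = segmentation.status
    if segmentation.status == "none":
        return report

    fv = feat.extract_features(segmentation)
    report.feature_vector = fv
    if models:
        kept = models[0].input_schema
        x = _reduce_vector(fv, kept) if len(kept) != len(fv.values) else fv.values
        report.prediction = ensemble_predict(models, x)
    report.timings["total_s"] = time.perf_counter() - t0
    logger.info("stage=grade image=%s status=%s grade=%s", image_id,
                report.status, report.grade)
    return report


@dataclass
class BatchSummary:
    reports: list[PipelineReport]
    counts: dict[str, int]
    agreement: Optional[tuple[float, int, int]] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            row = {"image_id": r.image_id, "source_tag": r.source_tag,
                   "rescued": r.rescued, "status": r.status, "grade": r.grade}
            if r.prediction is not None:
                row.update({f"ann{k+1}_grade": g for k, g in enumerate(r.prediction.per_ann)})
                row["mode_grade"] = r.prediction.mode_grade
            rows.append(row)
        return pd.DataFrame(rows)


def batch_grade(manifest: str | Path | pd.DataFrame, models: Sequence[TrainedANN],
                config: Optional[PipelineConfig] = None,
                image_root: Optional[Path] = None) -> BatchSummary:
    """Grade every image listed in a manifest (CSV: path[,grade,...]).

    Per-row failures are logged and the batch continues; the summary's
    segmentation counts always sum to the number of rows.
    """
    config = config or PipelineConfig()
    if isinstance(manifest, pd.DataFrame):
        df = manifest
    else:
        df = pd.read_csv(manifest)
        if image_root is None:
            image_root = Path(manifest).parent
    if df.empty:
        logger.warning("empty manifest; nothing to grade")
        return BatchSummary(reports=[], counts={"full": 0, "partial": 0, "none": 0})

    reports = []
    for _, row in df.iterrows():
        path = Path(row["path"])
        if image_root is not None and not path.is_absolute():
            path = image_root / path
        try:
            reports.append(grade_image(path, models, config))
        except Exception as exc:  # keep the batch alive
            logger.error("image=%s failed: %s", path, exc)
            reports.append(PipelineReport(image_id=str(path), source_tag="unknown",
                                          status="none"))
    counts = {s: sum(1 for r in reports if r.status == s)
              for s in ("full", "partial", "none")}
    agreement = None
    if "grade" in df.columns:
        mask = [r.grade is not None for r in reports]
        preds = [r.grade for r, m in zip(reports, mask) if m]
        refs = [int(g) for g, m in zip(df["grade"], mask) if m]
        if preds:
            agreement = agreement_rate(preds, refs)
    return BatchSummary(reports=reports, counts=counts, agreement=agreement)
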