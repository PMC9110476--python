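"""Error metrics and per-subset reporting.

Per plane, two errors are computed against the ground-truth pose: the
Euclidean distance between plane centres in mm (normalised translations
are converted against the evaluated volume's own extent) and the geodesic
rotation error in degrees.  Reports aggregate median/min/max per subset
(random planes ``RP`` vs near-standard-plane ``SP``), with the full
per-record table always emitted so error distributions can be re-plotted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DatasetManifest
from .regressor import PlanePoseRegressor, load_manifest_arrays
from .rotations import Pose, geodesic_distance_deg
from .volume import denormalize_translation

__all__ = [
    "EvalReport",
    "translation_error_mm",
    "rotation_error_deg",
    "aggregate_stats",
    "evaluate_predictions",
    "evaluate_checkpoint",
]

logger = logging.getLogger(__name__)


def translation_error_mm(pred: Pose, gt: Pose, extent: np.ndarray) -> float:
    """``||t_pred - t_gt||_2`` after denormalising both against ``extent``."""
    d = (denormalize_translation(pred.translation, extent)
         - denormalize_translation(gt.translation, extent))
    return float(np.linalg.norm(d))


def rotation_error_deg(pred: Pose, gt: Pose) -> float:
    """Geodesic distance between the two orientations, degrees in [0, 180]."""
    return float(geodesic_distance_deg(pred.rotation, gt.rotation))


def aggregate_stats(values) -> dict:
    """Median/min/max of a non-empty sequence (even-length median is the
    midpoint of the central pair)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty sequence")
    return {"median": float(np.median(values)),
            "min": float(values.min()),
            "max": float(values.max())}


@dataclass
class EvalReport:
    """Per-subset summary plus the full per-record error table."""

    records: pd.DataFrame
    summary: dict
    extent_mm: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"summary": self.summary, "extent_mm": self.extent_mm,
                           "config": self.config}, indent=2)

    def table(self) -> str:
        """Human-readable summary table (one row per subset)."""
        lines = [f"{'Subset':<8}{'n':>6}  {'Trans med/min/max [mm]':>28}  "
                 f"{'Rot med/min/max [deg]':>26}"]
        for subset, stats in self.summary.items():
            t, r = stats["translation_mm"], stats["rotation_deg"]
            lines.append(
                f"{subset:<8}{stats['n']:>6}  "
                f"{t['median']:>8.3f}/{t['min']:>7.3f}/{t['max']:>9.3f}  "
                f"{r['median']:>8.3f}/{r['min']:>7.3f}/{r['max']:>7.3f}")
        return "\n".join(lines)


def evaluate_predictions(
    pred_poses: list[Pose],
    gt_poses: list[Pose],
    subsets,
    extent: np.ndarray,
    image_paths=None,
) -> EvalReport:
    """Build an :class:`EvalReport` from matched pose lists."""
    if len(pred_poses) != len(gt_poses):
        raise ValueError("prediction and ground-truth counts differ")
    subsets = list(subsets)
    if image_paths is None:
        image_paths = [f"record_{i:06d}" for i in range(len(gt_poses))]
    rows = []
    for path, subset, pred, gt in zip(image_paths, subsets, pred_poses, gt_poses):
        rows.append({
            "image_path": path, "subset": subset,
            "trans_err_mm": translation_error_mm(pred, gt, extent),
            "rot_err_deg": rotation_error_deg(pred, gt),
        })
    records = pd.DataFrame(rows, columns=["image_path", "subset",
                                          "trans_err_mm", "rot_err_deg"])
    summary: dict = {}
    for subset in ("RP", "SP"):
        sub = records[records["subset"] == subset]
        if len(sub) == 0:
            logger.warning("subset %s is empty; omitted from the report", subset)
            continue
        summary[subset] = {
            "n": int(len(sub)),
            "translation_mm": aggregate_stats(sub["trans_err_mm"]),
            "rotation_deg": aggregate_stats(sub["rot_err_deg"]),
        }
    return EvalReport(records=records, summary=summary,
                      extent_mm=[float(e) for e in np.asarray(extent, float)])


def evaluate_checkpoint(
    est: PlanePoseRegressor,
    manifest: DatasetManifest,
    root_dir: str | Path,
    volume_extent: np.ndarray,
    out_dir: str | Path | None = None,
) -> EvalReport:
    """Predict every manifest row and aggregate Table-style statistics.

    When ``out_dir`` is given, writes ``eval_summary.json`` and the
    per-record ``eval_records.csv`` there.
    """
    X, y, subsets = load_manifest_arrays(manifest, root_dir)
    theta = est.predict(X)
    pred_poses = [Pose.from_target(t) for t in theta]
    gt_poses = [Pose.from_target(t) for t in y]
    report = evaluate_predictions(pred_poses, gt_poses, subsets, volume_extent,
                                  image_paths=list(manifest.rows["image_path"]))
    report.config = {"image_size": est.image_size, "backbone": est.backbone,
                     "lambda_weight": est.lambda_weight}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "eval_summary.json").write_text(report.to_json())
        report.records.to_csv(out / "eval_records.csv", index=False)
    return report
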