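"""End-to-end orchestration: generate → segment → detect → measure → stage →
evaluate, plus inter-rater comparison.

``run_end_to_end`` ties the modules together on a synthetic dataset.  Masks
and apexes can each come either from ground truth (isolating the geometry
and staging stages from model quality) or from the trained segmenter /
reference blob detector.  All randomness flows from the single seed in the
pipeline config, and the resolved configuration is written next to the
outputs so a run can be reproduced exactly.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import measurement as meas
from .apex_detection import detect_apexes_blob
from .image_io import Point2D, preprocess
from .measurement import CalibrationConfig
from .metrics import RaterTable, classification_report, error_metrics, icc_2_1
from .segmentation import UNet, predict_mask
from .staging import DEFAULT_THRESHOLDS, StageGradeThresholds, assess_patient
from .synthetic import SyntheticConfig, generate_case

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_end_to_end", "compare_raters", "measure_case"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run needs, serializable to one YAML."""

    n_cases: int = 50
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    thresholds: StageGradeThresholds = DEFAULT_THRESHOLDS
    use_truth_masks: bool = True
    use_truth_apexes: bool = True
    min_region_area: int = 20
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["synthetic"] = SyntheticConfig(**{
            **d.get("synthetic", {}),
            "thresholds": StageGradeThresholds(**d.get("synthetic", {}).get("thresholds", {})),
        })
        d["calibration"] = CalibrationConfig(**d.get("calibration", {}))
        d["thresholds"] = StageGradeThresholds(**d.get("thresholds", {}))
        return cls(**d)


def measure_case(
    mask: np.ndarray,
    apexes: List[Point2D],
    jaw: str,
    calib: CalibrationConfig,
    min_region_area: int = 20,
) -> List[meas.ToothMeasurement]:
    """Mask + apex points → retained per-tooth measurements."""
    regions = meas.find_bl_regions(mask, min_area=min_region_area)
    pairs, _, _ = meas.associate_regions_to_apexes(regions, apexes, jaw)
    results = []
    for region, apex in pairs:
        m = meas.measure_tooth(region, apex, jaw, calib)
        if m is not None:
            results.append(m)
    results.sort(key=lambda m: m.cej_center.x)  # stable left-to-right tooth ids
    return results


def run_end_to_end(
    config: PipelineConfig,
    out_dir=None,
    model: Optional[UNet] = None,
) -> Dict:
    """Run the full pipeline on ``config.n_cases`` synthetic patients.

    Returns a dict with the measurements and assessments DataFrames and the
    stage/grade classification reports against ground truth.  When
    ``use_truth_masks`` is False a trained ``model`` must be supplied.
    """
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not config.use_truth_masks and model is None:
        raise ValueError("a trained model is required when use_truth_masks=False")

    t0 = time.time()
    meas_rows, assess_rows = [], []
    truth_stage, pred_stage, truth_grade, pred_grade = [], [], [], []
    for cid in range(config.n_cases):
        case = generate_case(config.synthetic, cid)
        if config.use_truth_masks:
            mask = case.mask
        else:
            mask = predict_mask(model, preprocess(case.image, model.input_shape))
        if config.use_truth_apexes:
            apexes = [b.center for b in case.apex_boxes]
        else:
            det_img = preprocess(
                case.image,
                (config.synthetic.image_height, config.synthetic.image_width),
                equalize=False,
            )
            apexes = [b.center for b in detect_apexes_blob(det_img)]
        measurements = measure_case(
            mask, apexes, case.jaw, config.calibration, config.min_region_area
        )
        for ti, m in enumerate(measurements):
            meas_rows.append({
                "case_id": cid, "tooth_id": ti,
                "cej_x": m.cej_center.x, "cej_y": m.cej_center.y,
                "apex_x": m.apex_center.x, "apex_y": m.apex_center.y,
                "max_bl_px": m.max_bl_px, "root_len_px": m.root_length_px,
                "bl_percent": m.bl_percent,
            })
        assessment = assess_patient(
            (m.bl_percent for m in measurements), case.age,
            patient_id=str(cid), thresholds=config.thresholds,
        )
        row = {"patient_id": cid, "age": case.age,
               "truth_stage": case.truth.stage, "truth_grade": case.truth.grade}
        if assessment is None:
            row.update({"max_bl_percent": np.nan, "stage": "no assessable BL",
                        "grade": "no assessable BL"})
        else:
            row.update({"max_bl_percent": assessment.max_bl_percent,
                        "stage": assessment.stage, "grade": assessment.grade})
            truth_stage.append(case.truth.stage)
            pred_stage.append(assessment.stage)
            truth_grade.append(case.truth.grade)
            pred_grade.append(assessment.grade)
        assess_rows.append(row)

    measurements_df = pd.DataFrame(meas_rows)
    assessments_df = pd.DataFrame(assess_rows)
    stage_report = (classification_report(truth_stage, pred_stage)
                    if truth_stage else None)
    grade_report = (classification_report(truth_grade, pred_grade)
                    if truth_grade else None)
    logger.info("pipeline: %d cases in %.1fs", config.n_cases, time.time() - t0)

    result = {
        "measurements": measurements_df,
        "assessments": assessments_df,
        "stage_report": stage_report,
        "grade_report": grade_report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        measurements_df.to_csv(out / "measurements.csv", index=False)
        assessments_df.to_csv(out / "assessments.csv", index=False)
        config.to_yaml(out / "config.resolved.yaml")
    return result


def compare_raters(tables: Dict[str, pd.DataFrame],
                   value_column: str = "bl_percent") -> pd.DataFrame:
    """Pairwise agreement between measurement sources.

    ``tables`` maps rater name → DataFrame with case_id, tooth_id and the
    value column.  Rows are aligned on (case_id, tooth_id) by inner join;
    each rater pair gets ICC(2,1) with F and 95% CI, plus MAE and RMSE.
    """
    if len(tables) < 2:
        raise ValueError("need at least two raters to compare")
    aligned = None
    for name, df in tables.items():
        sub = df[["case_id", "tooth_id", value_column]].rename(
            columns={value_column: name}
        )
        aligned = sub if aligned is None else aligned.merge(
            sub, on=["case_id", "tooth_id"], how="inner"
        )
    if len(aligned) < 2:
        raise ValueError("fewer than 2 common subjects across raters")
    rows = []
    for a, b in itertools.combinations(tables.keys(), 2):
        table = RaterTable(aligned[[a, b]].to_numpy(), (a, b))
        icc = icc_2_1(table)
        mae, rmse = error_metrics(aligned[a], aligned[b])
        rows.append({
            "rater_a": a, "rater_b": b, "n": len(aligned),
            "icc": icc.icc, "f_value": icc.f_value,
            "ci95_low": icc.ci95[0], "ci95_high": icc.ci95[1],
            "mae": mae, "rmse": rmse,
        })
    return pd.DataFrame(rows)
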