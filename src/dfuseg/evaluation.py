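"""Segmentation evaluation: per-case and cohort-aggregated Dice.

The aggregated DSC pools overlap and size counts across the whole cohort
before forming the ratio,

    DSC_agg(c) = 2 * sum_cases |P_c ∩ R_c| / sum_cases (|P_c| + |R_c|),

which weights cases by lesion size and does not reward trivially perfect
scores on empty cases, unlike the per-case mean (also reported).  A case
empty in both prediction and reference has per-case DSC defined as 1 and
contributes zeros to the pooled sums.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import read_volume

__all__ = [
    "dsc_per_case",
    "aggregated_dsc",
    "MetricReport",
    "compute_report",
    "evaluate_cohort",
    "LESION_CLASSES",
]

LESION_CLASSES = {1: "GTVp", 2: "GTVn"}


def dsc_per_case(pred: np.ndarray, ref: np.ndarray, class_id: int
                 ) -> tuple[int, int, int, float]:
    """Return (intersection, |P|, |R|, DSC) for one class of one case."""
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    p = pred == class_id
    r = ref == class_id
    np_, nr = int(p.sum()), int(r.sum())
    if np_ == 0 and nr == 0:
        return 0, 0, 0, 1.0
    inter = int(np.logical_and(p, r).sum())
    return inter, np_, nr, 2.0 * inter / (np_ + nr)


def aggregated_dsc(rows) -> float:
    """Pooled-count Dice over (intersection, pred_count, ref_count) rows.

    If every case is empty on both sides the pooled denominator is zero and
    the score is defined as 1.
    """
    inter = sum(r[0] for r in rows)
    denom = sum(r[1] + r[2] for r in rows)
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


@dataclass
class MetricReport:
    per_case: pd.DataFrame
    aggregated: dict[int, float]
    mean_per_case: dict[int, float]
    mean_aggregated: float

    def to_json(self) -> str:
        return json.dumps({
            "aggregated": {LESION_CLASSES.get(c, str(c)): v
                           for c, v in self.aggregated.items()},
            "mean_per_case": {LESION_CLASSES.get(c, str(c)): v
                              for c, v in self.mean_per_case.items()},
            "mean_aggregated": self.mean_aggregated,
        }, indent=2)

    def save(self, csv_path: str | Path, json_path: str | Path | None = None):
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(self.to_json())


def compute_report(cases: dict[str, tuple[np.ndarray, np.ndarray]],
                   classes=(1, 2)) -> MetricReport:
    """Build a MetricReport from {case_id: (pred, ref)} label arrays."""
    rows = []
    for case_id, (pred, ref) in sorted(cases.items()):
        for c in classes:
            inter, np_, nr, dsc = dsc_per_case(pred, ref, c)
            rows.append({
                "case_id": case_id, "class": c,
                "intersection_voxels": inter,
                "pred_voxels": np_, "ref_voxels": nr,
                "dsc": dsc,
                "empty_both": np_ == 0 and nr == 0,
            })
    df = pd.DataFrame(rows)
    agg, mean_pc = {}, {}
    for c in classes:
        sub = df[df["class"] == c]
        agg[c] = aggregated_dsc(
            sub[["intersection_voxels", "pred_voxels", "ref_voxels"]].values)
        mean_pc[c] = float(sub["dsc"].mean())
    return MetricReport(
        per_case=df,
        aggregated=agg,
        mean_per_case=mean_pc,
        mean_aggregated=float(np.mean([agg[c] for c in classes])),
    )


def evaluate_cohort(pred_dir: str | Path, ref_dir: str | Path,
                    classes=(1, 2), pattern: str = "*.nii.gz",
                    out_csv: str | Path | None = None,
                    out_json: str | Path | None = None) -> MetricReport:
    """Score a directory of predicted label maps against references.

    Files are matched by name; a case present on only one side is an error.
    """
    pred_dir, ref_dir = Path(pred_dir), Path(ref_dir)
    preds = {p.name: p for p in sorted(pred_dir.glob(pattern))}
    refs = {p.name: p for p in sorted(ref_dir.glob(pattern))}
    missing = sorted(set(preds) ^ set(refs))
    if missing:
        raise FileNotFoundError(
            f"unmatched case files between pred and ref: {missing}")
    cases = {
        name: (read_volume(preds[name], as_labels=True).data,
               read_volume(refs[name], as_labels=True).data)
        for name in preds
    }
    report = compute_report(cases, classes)
    if out_csv is not None:
        report.save(out_csv, out_json)
    return report
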