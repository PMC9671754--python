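"""Readers and writers for the pipeline's interchange files.

Plain-text formats throughout: CSV for the sample sheet, beta matrix, qPCR
plate and score tables; BED for candidate regions; JSON for thresholds, QC
and evaluation reports.  Every writer's output is re-readable by the
matching reader.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import BetaMatrix, CandidateRegion
from .scoring import UNDETERMINED, is_undetermined
from .thresholds import Thresholds

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "group", "age", "menopausal_status", "stage", "grade",
    "histology", "collection", "months_to_event",
]
QPCR_COLUMNS = ["sample_id", "assay_id", "replicate", "ct", "is_calibrator"]


class SchemaError(ValueError):
    """An input table violates its documented schema."""


def write_sample_sheet(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort sample sheet.

    Required columns are the CohortMeta fields; extra columns (for example
    the ``ultrasound_mm`` and ``n_mutations`` comparators) are preserved as
    opaque covariates.
    """
    sheet = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SchemaError(f"sample sheet is missing required columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample_id values: {dupes}")
    bad_group = set(sheet["group"]) - {"case", "control"}
    if bad_group:
        raise SchemaError(f"unknown group labels: {sorted(bad_group)}")
    months = pd.to_numeric(sheet["months_to_event"], errors="coerce")
    if (months.dropna() < 0).any():
        raise SchemaError("months_to_event must be non-negative where present")
    sheet["months_to_event"] = months
    return sheet


def write_beta_matrix(beta: BetaMatrix, values_path: str | Path,
                      annotation_path: str | Path) -> None:
    frame = pd.DataFrame(beta.values, index=pd.Index(beta.sample_ids, name="sample_id"),
                         columns=beta.cpg_ann["id"])
    frame.to_csv(values_path)
    beta.cpg_ann.to_csv(annotation_path, index=False)


def read_beta_matrix(values_path: str | Path,
                     annotation_path: str | Path) -> BetaMatrix:
    frame = pd.read_csv(values_path, index_col="sample_id")
    ann = pd.read_csv(annotation_path)
    for col in ("id", "chrom", "pos"):
        if col not in ann.columns:
            raise SchemaError(f"CpG annotation is missing column {col!r}")
    if list(frame.columns) != list(ann["id"]):
        raise SchemaError("beta matrix columns do not match annotation CpG ids")
    return BetaMatrix(values=frame.to_numpy(dtype=float),
                      sample_ids=[str(s) for s in frame.index],
                      cpg_ann=ann)


def write_qpcr_csv(plate: pd.DataFrame, path: str | Path) -> None:
    out = plate.copy()
    out["ct"] = [UNDETERMINED if is_undetermined(c) else repr(float(c))
                 for c in out["ct"]]
    out.to_csv(path, index=False)


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR plate export; 'Undetermined' (any case) is the no-signal
    sentinel, numeric Cts must be positive."""
    raw = pd.read_csv(path, dtype={"ct": str})
    missing = [c for c in QPCR_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"qPCR table is missing columns: {missing}")
    cts: list[object] = []
    for row_number, value in enumerate(raw["ct"], start=2):  # header is line 1
        text = str(value).strip()
        if text.lower() == "undetermined":
            cts.append(UNDETERMINED)
            continue
        try:
            ct = float(text)
        except ValueError as exc:
            raise SchemaError(f"line {row_number}: unparseable ct {text!r}") from exc
        if not ct > 0:
            raise SchemaError(f"line {row_number}: ct must be positive, got {ct}")
        cts.append(ct)
    out = raw.copy()
    out["ct"] = cts
    out["replicate"] = out["replicate"].astype(int)
    out["is_calibrator"] = out["is_calibrator"].astype(int)
    return out


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    scores = pd.read_csv(path)
    for col in ("sample_id", "sum_pmr", "valid", "reference_ct"):
        if col not in scores.columns:
            raise SchemaError(f"score table is missing column {col!r}")
    scores["valid"] = scores["valid"].astype(bool)
    return scores


def write_regions_bed(regions: Sequence[CandidateRegion], path: str | Path) -> None:
    """BED5 export; the score column carries AUC scaled to 0–1000."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            score = 0 if math.isnan(r.auc) else int(round(1000 * r.auc))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{score}\n")


def read_regions_bed(path: str | Path) -> list[CandidateRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, _name, score = line.rstrip("\n").split("\t")
            regions.append(CandidateRegion(
                chrom=chrom, start=int(start), end=int(end),
                member_cpg_ids=(), auc=int(score) / 1000.0,
            ))
    return regions


def write_thresholds_json(thresholds: Thresholds, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(thresholds.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_thresholds_json(path: str | Path) -> Thresholds:
    with open(path) as fh:
        return Thresholds.from_dict(json.load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
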