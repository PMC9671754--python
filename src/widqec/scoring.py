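"""MethyLight PMR computation and the WID-qEC score.

The WID-qEC score is the sum of PMR (percentage of methylated reference)
values over a three-reaction methylation-specific qPCR panel (one region in
*ZSCAN12*, two in *GYPC*).  PMR compares the target/reference quantity ratio
in a specimen against the same ratio in a fully methylated calibrator DNA:

    PMR = 100 * [Q(sample_target) / Q(sample_ref)]
              / [Q(calibrator_target) / Q(calibrator_ref)]

with Q(ct) = efficiency**(-ct) and perfect doubling (efficiency 2) assumed
by default.  A well that never amplifies ("Undetermined") carries quantity
zero; an undetermined *reference* well means the specimen yielded too little
DNA and fails QC instead of scoring zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used in CSV exports for wells that never crossed threshold.
UNDETERMINED = "Undetermined"

#: Reference-reaction Ct above which a specimen is deemed DNA-insufficient.
DEFAULT_MAX_REF_CT = 38.0

#: Assumed per-cycle amplification factor (perfect doubling).
DEFAULT_EFFICIENCY = 2.0


class AssayFailureError(RuntimeError):
    """The fully methylated calibrator failed to amplify for an assay."""


class IncompletePanelError(ValueError):
    """A sample is missing one or more of the panel's reactions."""


def is_undetermined(ct: object) -> bool:
    """True if ``ct`` encodes a well with no amplification signal."""
    if ct is None:
        return True
    if isinstance(ct, str):
        return ct.strip().lower() == "undetermined"
    if isinstance(ct, (int, float, np.floating, np.integer)):
        return bool(math.isnan(float(ct)))
    return False


def _as_ct(ct: object, what: str = "ct") -> float:
    """Validate a numeric Ct (positive cycle count)."""
    value = float(ct)  # type: ignore[arg-type]
    if not value > 0:
        raise ValueError(f"{what} must be a positive cycle number, got {value}")
    return value


def ct_to_quantity(ct: object, efficiency: float = DEFAULT_EFFICIENCY) -> float:
    """Relative template quantity implied by a Ct value.

    Parameters
    ----------
    ct
        Cycle-threshold value (> 0), or the undetermined sentinel
        (``"Undetermined"``, ``None`` or NaN) which maps to quantity 0.
    efficiency
        Fold amplification per cycle; must exceed 1.

    Returns
    -------
    float
        ``efficiency ** (-ct)``, or 0.0 for undetermined wells.
    """
    if not efficiency > 1:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    if is_undetermined(ct):
        return 0.0
    return float(efficiency) ** (-_as_ct(ct))


def compute_pmr(
    sample_target_ct: object,
    sample_ref_ct: object,
    calibrator_target_ct: object,
    calibrator_ref_ct: object,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> float:
    """Percentage of methylated reference for one (sample, assay) pair.

    Equivalent to ``100 * efficiency**-(dCt_sample - dCt_calibrator)`` where
    ``dCt = target_ct - ref_ct``.  An undetermined sample target yields
    PMR 0; an undetermined calibrator target is an assay failure.  Values
    above 100 are retained: the score is a sum of ratios, not a proportion.
    """
    if is_undetermined(calibrator_target_ct):
        raise AssayFailureError(
            "calibrator target well is undetermined; the fully methylated "
            "control must amplify for PMR to be defined"
        )
    cal_ratio = ct_to_quantity(calibrator_target_ct, efficiency) / ct_to_quantity(
        calibrator_ref_ct, efficiency
    )
    if is_undetermined(sample_target_ct):
        return 0.0
    sample_ratio = ct_to_quantity(sample_target_ct, efficiency) / ct_to_quantity(
        sample_ref_ct, efficiency
    )
    return 100.0 * sample_ratio / cal_ratio


def qc_sample(sample_ref_ct: object, max_ref_ct: float = DEFAULT_MAX_REF_CT) -> bool:
    """DNA-sufficiency check on the reference reaction.

    A specimen is valid iff its reference Ct is numeric and does not exceed
    ``max_ref_ct`` (boundary inclusive).  Invalid specimens are excluded
    from performance denominators downstream.
    """
    if is_undetermined(sample_ref_ct):
        return False
    return _as_ct(sample_ref_ct, "reference ct") <= max_ref_ct


def collapse_replicates(cts: Sequence[object]) -> object:
    """Collapse replicate Cts of one (sample, assay) well group.

    Numeric replicates are averaged.  If an undetermined replicate sits
    alongside numeric ones, the numeric mean is used and a warning logged;
    all-undetermined groups collapse to the sentinel.
    """
    numeric = [float(c) for c in cts if not is_undetermined(c)]
    n_undet = len(cts) - len(numeric)
    if not numeric:
        return UNDETERMINED
    if n_undet:
        logger.warning(
            "mixed replicate group: %d undetermined alongside %d numeric Cts; "
            "using the numeric mean",
            n_undet,
            len(numeric),
        )
    return float(np.mean(numeric))


@dataclass(frozen=True)
class PmrResult:
    """PMR for one sample and one assay, with the Cts that produced it."""

    sample_id: str
    assay_id: str
    pmr: float
    used_cts: tuple = ()

    def __post_init__(self) -> None:
        if not (self.pmr >= 0 and math.isfinite(self.pmr)):
            raise ValueError(f"pmr must be finite and >= 0, got {self.pmr}")


@dataclass(frozen=True)
class WidQecScore:
    """Per-sample Σ PMR over the three-reaction panel plus QC state."""

    sample_id: str
    sum_pmr: float
    valid: bool
    reference_ct: float = math.nan
    pmrs: tuple = field(default_factory=tuple)


def sum_score(
    pmrs: Mapping[str, float] | Sequence[float],
    sample_id: str = "",
    valid: bool = True,
    reference_ct: float = math.nan,
    panel_size: int = 3,
) -> WidQecScore:
    """Form the WID-qEC score as the exact sum of the panel's PMRs.

    Raises :class:`IncompletePanelError` unless exactly ``panel_size`` PMR
    values are supplied (one per panel reaction).
    """
    values = list(pmrs.values()) if isinstance(pmrs, Mapping) else list(pmrs)
    if len(values) != panel_size:
        raise IncompletePanelError(
            f"expected {panel_size} panel PMR values, got {len(values)}"
        )
    if any(not math.isfinite(v) or v < 0 for v in values):
        raise ValueError(f"PMR values must be finite and >= 0: {values}")
    return WidQecScore(
        sample_id=sample_id,
        sum_pmr=float(sum(values)),
        valid=valid,
        reference_ct=reference_ct,
        pmrs=tuple(values),
    )


def score_plate(
    plate: pd.DataFrame,
    panel_assays: Sequence[str],
    reference_assay: str,
    efficiency: float = DEFAULT_EFFICIENCY,
    max_ref_ct: float = DEFAULT_MAX_REF_CT,
) -> pd.DataFrame:
    """Score every sample on a qPCR plate.

    Parameters
    ----------
    plate
        Long-format well table with columns ``sample_id, assay_id,
        replicate, ct, is_calibrator`` (the ``QpcrPlate`` interchange
        format).  Calibrator wells carry the fully methylated control.
    panel_assays
        The three marker reactions summed into Σ PMR.
    reference_assay
        The input-amount normalisation reaction.

    Returns
    -------
    pandas.DataFrame
        One row per sample: ``sample_id``, one ``pmr_<assay>`` column per
        panel reaction, ``sum_pmr``, ``valid``, ``reference_ct``.  QC-failed
        samples keep NaN PMRs and ``valid=False``.
    """
    required = {"sample_id", "assay_id", "replicate", "ct", "is_calibrator"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate is missing columns: {sorted(missing)}")

    cal = plate[plate["is_calibrator"].astype(bool)]
    samples = plate[~plate["is_calibrator"].astype(bool)]

    present = set(plate["assay_id"])
    absent = [a for a in [*panel_assays, reference_assay] if a not in present]
    if absent:
        raise IncompletePanelError(f"plate has no wells for assays {absent}")

    cal_cts: dict[str, object] = {}
    for assay in [*panel_assays, reference_assay]:
        wells = cal.loc[cal["assay_id"] == assay, "ct"]
        if wells.empty:
            raise AssayFailureError(f"no calibrator wells for assay {assay!r}")
        cal_cts[assay] = collapse_replicates(list(wells))
        if assay != reference_assay and is_undetermined(cal_cts[assay]):
            raise AssayFailureError(f"calibrator failed to amplify for {assay!r}")

    rows = []
    for sample_id, group in samples.groupby("sample_id", sort=True):
        cts = {
            assay: collapse_replicates(list(sub["ct"]))
            for assay, sub in group.groupby("assay_id")
        }
        for assay in [*panel_assays, reference_assay]:
            if assay not in cts:
                raise IncompletePanelError(
                    f"sample {sample_id!r} has no wells for assay {assay!r}"
                )
        ref_ct = cts[reference_assay]
        valid = qc_sample(ref_ct, max_ref_ct)
        row: dict[str, object] = {
            "sample_id": sample_id,
            "valid": valid,
            "reference_ct": math.nan if is_undetermined(ref_ct) else float(ref_ct),
        }
        if valid:
            pmrs = {
                assay: compute_pmr(
                    cts[assay], ref_ct, cal_cts[assay], cal_cts[reference_assay],
                    efficiency,
                )
                for assay in panel_assays
            }
            score = sum_score(
                pmrs, sample_id=str(sample_id), valid=True,
                reference_ct=float(row["reference_ct"]),
                panel_size=len(panel_assays),
            )
            for assay in panel_assays:
                row[f"pmr_{assay}"] = pmrs[assay]
            row["sum_pmr"] = score.sum_pmr
        else:
            for assay in panel_assays:
                row[f"pmr_{assay}"] = math.nan
            row["sum_pmr"] = math.nan
        rows.append(row)

    columns = (
        ["sample_id"]
        + [f"pmr_{a}" for a in panel_assays]
        + ["sum_pmr", "valid", "reference_ct"]
    )
    return pd.DataFrame(rows, columns=columns)


def qc_report(scores: pd.DataFrame) -> dict:
    """Summarise DNA-sufficiency QC over a scored plate."""
    n = int(len(scores))
    n_invalid = int((~scores["valid"]).sum())
    return {
        "n_samples": n,
        "n_valid": n - n_invalid,
        "n_invalid": n_invalid,
        "invalid_rate": (n_invalid / n) if n else 0.0,
        "invalid_sample_ids": scores.loc[~scores["valid"], "sample_id"].tolist(),
    }
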