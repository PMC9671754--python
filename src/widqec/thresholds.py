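"""Dual decision thresholds on the Σ PMR score.

The test ships with two prespecified cutoffs fixed on a small development
(pilot) set and then frozen: threshold 1 trades specificity for sensitivity
and serves symptomatic/high-risk settings, threshold 2 does the reverse for
screening-like settings where false positives are costly.  A score at or
above the applied cutoff calls the sample positive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluation import CASE, CONTROL, NEGATIVE, POSITIVE


class ThresholdError(ValueError):
    """Thresholds cannot be fixed on the given development data."""


class QcRefusalError(ValueError):
    """Classification refused for a QC-invalid sample."""


@dataclass(frozen=True)
class Thresholds:
    """The two fixed Σ PMR cutoffs plus their development provenance."""

    threshold1: float  # high-sensitivity cutoff (symptomatic/high-risk use)
    threshold2: float  # high-specificity cutoff (screening-like use)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold1 < 0 or self.threshold2 < 0:
            raise ValueError("thresholds must be non-negative")
        if self.threshold2 < self.threshold1:
            raise ValueError("threshold2 must be >= threshold1")

    def to_dict(self) -> dict:
        return {
            "threshold1": self.threshold1,
            "threshold2": self.threshold2,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        return cls(
            threshold1=float(d["threshold1"]),
            threshold2=float(d["threshold2"]),
            provenance=dict(d.get("provenance", {})),
        )


def _operating_point(
    scores: np.ndarray, is_case: np.ndarray, cutoff: float
) -> tuple:
    positive = scores >= cutoff
    sens = float(positive[is_case].mean())
    spec = float((~positive[~is_case]).mean())
    return sens, spec


def candidate_cutoffs(scores: Sequence[float]) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus edge sentinels.

    The sentinels (below the minimum, above the maximum) realise the
    all-positive and all-negative rules, so every achievable operating
    point appears exactly once.
    """
    distinct = np.unique(np.asarray(scores, dtype=float))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    below = distinct[0] - 1.0
    above = distinct[-1] + 1.0
    return np.concatenate([[below], mids, [above]])


def fix_thresholds(
    dev_scores: Sequence[float],
    dev_labels: Sequence[str],
    target_sensitivity: float = 0.95,
    target_specificity: float = 0.95,
    dev_set_id: str = "development",
) -> Thresholds:
    """Fix the dual cutoffs on development-set scores.

    Threshold 1 maximises specificity among cutoffs achieving sensitivity
    >= ``target_sensitivity``; threshold 2 maximises sensitivity among
    cutoffs achieving specificity >= ``target_specificity``.  Ties resolve
    toward the lower cutoff.  Provenance (a hash of the development scores
    and the rule parameters) is recorded so the frozen cutoffs remain
    auditable.
    """
    scores = np.asarray(dev_scores, dtype=float)
    labels = np.asarray(dev_labels)
    is_case = labels == CASE
    if int(is_case.sum()) < 5 or int((labels == CONTROL).sum()) < 5:
        raise ThresholdError("need at least 5 cases and 5 controls")
    if np.unique(scores).size < 2:
        raise ThresholdError("all development scores identical; no cutoff exists")

    cuts = candidate_cutoffs(scores)
    points = [_operating_point(scores, is_case, c) for c in cuts]

    def _best(constraint_idx: int, objective_idx: int, target: float) -> float:
        feasible = [
            (c, pt) for c, pt in zip(cuts, points) if pt[constraint_idx] >= target
        ]
        if not feasible:
            best_c, best_pt = max(
                zip(cuts, points), key=lambda cp: cp[1][constraint_idx]
            )
            raise ThresholdError(
                f"no cutoff reaches the target; best achievable operating "
                f"point is sens={best_pt[0]:.3f}, spec={best_pt[1]:.3f} at "
                f"cutoff {best_c:.6g}"
            )
        best_obj = max(pt[objective_idx] for _, pt in feasible)
        # ties toward the lower cutoff
        return float(min(c for c, pt in feasible if pt[objective_idx] == best_obj))

    t1 = _best(constraint_idx=0, objective_idx=1, target=target_sensitivity)
    t2 = _best(constraint_idx=1, objective_idx=0, target=target_specificity)

    digest = hashlib.sha256(
        json.dumps({"scores": scores.tolist(), "labels": labels.tolist()},
                   sort_keys=True).encode()
    ).hexdigest()[:16]
    prov = {
        "dev_set_id": dev_set_id,
        "dev_set_hash": digest,
        "n_cases": int(is_case.sum()),
        "n_controls": int((~is_case).sum()),
        "target_sensitivity": target_sensitivity,
        "target_specificity": target_specificity,
        "rule": "score >= cutoff is positive; midpoint candidates with edge sentinels",
    }
    if t1 > t2:
        # both cutoffs then meet both targets (the constraint regions
        # overlap); order them so the high-sensitivity cutoff sits lower
        t1, t2 = t2, t1
        prov["reordered"] = True
    # cutoffs are clamped at 0: Σ PMR is non-negative, so any negative
    # sentinel encodes the same all-positive rule as cutoff 0
    return Thresholds(threshold1=max(t1, 0.0), threshold2=max(t2, 0.0),
                      provenance=prov)


def classify(score: float, cutoff: float, valid: bool = True) -> str:
    """Dichotomise one Σ PMR score; refuses QC-invalid samples."""
    if not valid:
        raise QcRefusalError("sample failed DNA-sufficiency QC; cannot classify")
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    return POSITIVE if score >= cutoff else NEGATIVE


def classify_scores(
    scores: Sequence[float], cutoff: float, valid: Sequence[bool] | None = None
) -> np.ndarray:
    """Vectorised :func:`classify` over a score table."""
    scores = np.asarray(scores, dtype=float)
    if valid is not None and not all(valid):
        raise QcRefusalError("QC-invalid samples present; filter them first")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    return np.where(scores >= cutoff, POSITIVE, NEGATIVE)
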