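"""Marker-region discovery from an epigenome-wide methylation screen.

Cervicovaginal specimens are a mixture of (mostly) epithelial cells and
infiltrating immune cells, and the immune fraction varies hugely between
women.  A CpG that is hypermethylated in tumour epithelium can therefore
look unremarkable in a specimen dominated by immune DNA.  The discovery
screen here mirrors that logic: estimate each specimen's immune fraction
from a two-component reference mixture, keep CpGs that are unmethylated in
immune cells and in control epithelium, score case/control association with
the immune fraction as a covariate, cluster top CpGs into regions (±500 bp),
and rank candidate regions by ROC AUC of their mean methylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import roc_auc

DEFAULT_WINDOW_BP = 500
DEFAULT_IMMUNE_CAP = 0.2
DEFAULT_CONTROL_CAP = 0.2
DEFAULT_TOP_K = 3


@dataclass
class BetaMatrix:
    """Samples × CpGs methylation-fraction matrix with genomic annotation.

    ``cpg_ann`` must carry columns ``id``, ``chrom``, ``pos`` (0-based),
    aligned column-wise with ``values``.
    """

    values: np.ndarray
    sample_ids: list[str]
    cpg_ann: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x CpGs array")
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError("sample_ids length does not match values rows")
        if m != len(self.cpg_ann):
            raise ValueError("cpg_ann length does not match values columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.cpg_ann["id"].duplicated().any():
            raise ValueError("duplicate CpG ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def columns_for(self, cpg_ids: Sequence[str]) -> np.ndarray:
        index = pd.Index(self.cpg_ann["id"])
        locs = index.get_indexer(list(cpg_ids))
        if (locs < 0).any():
            absent = [c for c, l in zip(cpg_ids, locs) if l < 0]
            raise KeyError(f"CpGs absent from matrix: {absent}")
        return locs


@dataclass(frozen=True)
class CandidateRegion:
    """A clustered candidate marker region (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    member_cpg_ids: tuple
    auc: float = math.nan

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("region end must exceed start")

    @property
    def n_cpgs(self) -> int:
        return len(self.member_cpg_ids)


def estimate_immune_fraction(
    beta_row: np.ndarray,
    epithelial_mean: np.ndarray,
    immune_mean: np.ndarray,
) -> float:
    """Least-squares immune fraction of a specimen under a 2-component mix.

    Minimises ``|| beta - ((1-f) * epithelial + f * immune) ||^2`` over
    ``f in [0, 1]``; the unconstrained solution is closed-form and gets
    projected onto the unit interval.  Returns NaN when the two reference
    profiles coincide at every CpG (the fraction is unidentifiable).
    """
    beta_row = np.asarray(beta_row, dtype=float)
    epi = np.asarray(epithelial_mean, dtype=float)
    imm = np.asarray(immune_mean, dtype=float)
    if beta_row.shape != epi.shape or epi.shape != imm.shape:
        raise ValueError("beta_row and reference profiles must align")
    if beta_row.size < 10:
        raise ValueError("need at least 10 CpGs to estimate the immune fraction")
    direction = imm - epi
    denom = float(direction @ direction)
    if denom == 0.0:
        return math.nan
    f = float(direction @ (beta_row - epi)) / denom
    return min(1.0, max(0.0, f))


def estimate_immune_fractions(
    beta: BetaMatrix, epithelial_mean: np.ndarray, immune_mean: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`estimate_immune_fraction` over all samples."""
    epi = np.asarray(epithelial_mean, dtype=float)
    imm = np.asarray(immune_mean, dtype=float)
    direction = imm - epi
    denom = float(direction @ direction)
    if denom == 0.0:
        return np.full(beta.n_samples, np.nan)
    f = (beta.values - epi) @ direction / denom
    return np.clip(f, 0.0, 1.0)


def rank_cpgs(
    beta: BetaMatrix,
    labels: Sequence[str],
    immune_fractions: Sequence[float],
    immune_cap: float = DEFAULT_IMMUNE_CAP,
    control_cap: float = DEFAULT_CONTROL_CAP,
) -> pd.DataFrame:
    """Rank CpGs by immune-adjusted case/control association.

    For every CpG a least-squares model ``beta ~ 1 + case + immune_fraction``
    is fitted over all samples and the CpG scored by the t-statistic of the
    case indicator.  Compartment endpoints are estimated from the controls
    alone by regressing beta on immune fraction: the fit at fraction 0 is the
    control epithelial methylation, the fit at fraction 1 the immune-cell
    methylation.  Only CpGs with both endpoints at or below their caps are
    eligible for ranking — the marker concept requires sites silent in
    immune cells and in healthy epithelium, so that any signal is
    cancer-derived.

    Returns a DataFrame aligned with ``beta.cpg_ann`` carrying ``statistic``,
    ``rank`` (1 = best, NaN for ineligible CpGs), ``eligible``,
    ``immune_reference_methylation`` and ``control_epithelial_methylation``.
    """
    labels = np.asarray(labels)
    f = np.asarray(immune_fractions, dtype=float)
    is_case = (labels == "case").astype(float)
    n_cases = int(is_case.sum())
    n_controls = len(labels) - n_cases
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    if beta.n_samples != len(labels) or beta.n_samples != len(f):
        raise ValueError("labels/immune_fractions must align with samples")

    Y = beta.values  # n x m

    # Control-only regression beta ~ 1 + f gives the two compartment endpoints.
    ctrl = is_case == 0
    Xc = np.column_stack([np.ones(ctrl.sum()), f[ctrl]])
    coef_c, *_ = np.linalg.lstsq(Xc, Y[ctrl], rcond=None)
    control_epithelial = coef_c[0]
    immune_reference = coef_c[0] + coef_c[1]

    # Full model beta ~ 1 + case + f; score = t-statistic of the case term.
    X = np.column_stack([np.ones(len(labels)), is_case, f])
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = len(labels) - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef[1] / se, 0.0)
    # a CpG with identical values in every sample carries no information;
    # its residual variance is pure rounding noise, so force the score to 0
    tstat[np.ptp(Y, axis=0) == 0] = 0.0

    eligible = (immune_reference <= immune_cap) & (control_epithelial <= control_cap)

    ranking = beta.cpg_ann[["id", "chrom", "pos"]].copy()
    ranking["statistic"] = tstat
    ranking["immune_reference_methylation"] = immune_reference
    ranking["control_epithelial_methylation"] = control_epithelial
    ranking["eligible"] = eligible
    ranking["rank"] = np.nan
    # descending statistic; genomic order breaks exact ties deterministically
    order = ranking.loc[eligible].sort_values(
        ["statistic", "chrom", "pos"], ascending=[False, True, True]
    ).index
    ranking.loc[order, "rank"] = np.arange(1, len(order) + 1, dtype=float)
    return ranking


def build_regions(
    ranking: pd.DataFrame,
    top_n: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_cpgs: int = 3,
) -> list[CandidateRegion]:
    """Cluster the top-ranked CpGs into candidate regions.

    Each of the ``top_n`` best-ranked CpGs seeds a cluster of ranked CpGs
    within ``±window_bp``; clusters sharing members on the same chromosome
    merge transitively, and clusters with fewer than ``min_cpgs`` members
    are dropped.  Intervals are 0-based half-open (BED semantics) spanning
    min to max member position + 1.
    """
    ranked = ranking.dropna(subset=["rank"]).sort_values("rank")
    if ranked.empty:
        return []
    seeds = ranked.head(top_n)

    clusters: list[set] = []
    for _, seed in seeds.iterrows():
        near = ranked[
            (ranked["chrom"] == seed["chrom"])
            & (np.abs(ranked["pos"] - seed["pos"]) <= window_bp)
        ]
        members = set(near["id"])
        overlapping = [c for c in clusters if c & members]
        for c in overlapping:
            clusters.remove(c)
            members |= c
        clusters.append(members)

    lookup = ranked.set_index("id")
    regions = []
    for members in clusters:
        if len(members) < min_cpgs:
            continue
        sub = lookup.loc[sorted(members)].sort_values("pos")
        regions.append(
            CandidateRegion(
                chrom=str(sub["chrom"].iloc[0]),
                start=int(sub["pos"].min()),
                end=int(sub["pos"].max()) + 1,
                member_cpg_ids=tuple(sub.index),
            )
        )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def region_score(beta: BetaMatrix, region: CandidateRegion) -> np.ndarray:
    """Per-sample mean methylation over a region's member CpGs.

    This is the array surrogate for a MethyLight reaction interrogating
    the region.
    """
    cols = beta.columns_for(region.member_cpg_ids)
    return beta.values[:, cols].mean(axis=1)


def rank_reactions_by_auc(
    scores: dict[CandidateRegion, np.ndarray] | list[tuple[CandidateRegion, np.ndarray]],
    labels: Sequence[str],
) -> list[CandidateRegion]:
    """Order candidate regions by empirical AUC (case vs control), best first.

    Ties break by genomic order (chrom, then start).  Callers take the top
    k (k = 3 for the WID-qEC panel).
    """
    items = list(scores.items()) if isinstance(scores, dict) else list(scores)
    if not items:
        raise ValueError("need at least one candidate region")
    truth = np.asarray(labels)
    scored = []
    for region, s in items:
        auc = roc_auc(np.asarray(s, dtype=float), truth).auc
        scored.append(CandidateRegion(
            chrom=region.chrom, start=region.start, end=region.end,
            member_cpg_ids=region.member_cpg_ids, auc=auc,
        ))
    scored.sort(key=lambda r: (-r.auc, r.chrom, r.start))
    return scored


def discover_regions(
    beta: BetaMatrix,
    labels: Sequence[str],
    immune_fractions: Sequence[float],
    top_n_cpgs: int = 30,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_cpgs: int = 3,
    immune_cap: float = DEFAULT_IMMUNE_CAP,
    control_cap: float = DEFAULT_CONTROL_CAP,
) -> list[CandidateRegion]:
    """Full discovery stage: rank CpGs, build regions, order by AUC."""
    ranking = rank_cpgs(beta, labels, immune_fractions, immune_cap, control_cap)
    regions = build_regions(ranking, top_n_cpgs, window_bp, min_cpgs)
    if not regions:
        return []
    scores = [(r, region_score(beta, r)) for r in regions]
    return rank_reactions_by_auc(scores, labels)
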