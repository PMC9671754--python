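"""Synthetic cervicovaginal methylation cohorts and qPCR plates.

Everything downstream of the wet lab is testable against this module: it
generates two-compartment (epithelial/immune) reference methylation
profiles, mixed-cell beta matrices with cancer hypermethylation planted in
the epithelial compartment at a small set of clustered regions, cohort
sample sheets, comparator modalities (endometrial thickness, somatic
mutation counts), and qPCR plates whose Ct values encode ground-truth PMR
levels plus noise and DNA-insufficiency dropouts.

The mixture model per sample ``i`` and CpG ``j`` is

    beta[i, j] = clip((1 - f_i) * epi_ij + f_i * immune_j + eps, 0, 1)

where ``f_i`` is the specimen's immune fraction, ``eps`` is Gaussian beta
noise, and ``epi_ij`` is the epithelial baseline plus the planted effect
size for cases at marker CpGs.  With zero noise and a pure compartment the
identities are exact, which the QC and deconvolution tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .discovery import BetaMatrix, CandidateRegion
from .scoring import UNDETERMINED, DEFAULT_MAX_REF_CT

#: CpGs per pre-formed discoverable cluster in the reference profiles.
CLUSTER_SIZE = 8

REFERENCE_ASSAY = "REF"
CALIBRATOR_ID = "CALIBRATOR"


@dataclass
class ReferenceProfiles:
    """Per-CpG epithelial and immune methylation baselines with coordinates.

    Discoverable CpGs (low methylation in both healthy compartments, hence
    capable of carrying a cancer-specific signal) are pre-arranged in
    clusters of :data:`CLUSTER_SIZE` sites spanning under 500 bp, the
    geometry a MethyLight reaction needs; ``cluster_id`` is -1 elsewhere.
    """

    cpg_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    epithelial_mean: np.ndarray
    immune_mean: np.ndarray
    cluster_id: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.epithelial_mean, self.immune_mean):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("methylation fractions must lie in [0, 1]")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("cpg_ids must be unique")
        if (self.pos < 0).any():
            raise ValueError("positions must be non-negative")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions must be sorted within {c}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def discoverable(self) -> np.ndarray:
        return self.cluster_id >= 0

    def annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.cpg_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults are the package's reference study conditions: 100 cases and
    100 controls on a 2,000-CpG screen with 3 planted marker regions (full
    discoverable clusters of :data:`CLUSTER_SIZE` CpGs), a 0.3
    methylation-fraction effect confined to the epithelial compartment, a
    broad Beta(2, 5) immune-fraction spread, and 0.05 beta noise.  Planting
    fewer CpGs than a cluster holds leaves the cluster's unplanted tail
    eligible for discovery, so recovered intervals may then extend past the
    planted ones.
    """

    n_cases: int = 100
    n_controls: int = 100
    n_cpgs: int = 2000
    n_true_regions: int = 3
    cpgs_per_region: int = CLUSTER_SIZE
    region_span_bp: int = 500
    effect_size: float = 0.3
    immune_fraction_distribution: tuple = (2.0, 5.0)  # Beta(a, b) parameters
    noise_sd: float = 0.05
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        # 0 is allowed: a null simulation with planted-region bookkeeping
        # but no case effect, used for false-discovery checks
        if not (0 <= self.effect_size <= 1):
            raise ValueError("effect_size must lie in [0, 1]")
        for name in ("n_cases", "n_controls", "n_cpgs", "n_true_regions",
                     "cpgs_per_region", "region_span_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_reference_profiles(n_cpgs: int, seed: int) -> ReferenceProfiles:
    """Generate two-compartment reference methylation profiles.

    Roughly 4% of CpGs are discoverable — unmethylated (< 0.1) in both the
    epithelial and immune compartments — and laid out in clusters of
    :data:`CLUSTER_SIZE` sites with 30–60 bp spacing (span < 500 bp);
    background CpGs get independent arbitrary baselines and 0.8–2 kb gaps.
    Deterministic given the seed.
    """
    if n_cpgs < 100:
        raise ValueError("n_cpgs must be at least 100")
    rng = np.random.default_rng(seed)

    n_clusters = max(3, int(round(0.04 * n_cpgs / CLUSTER_SIZE)))
    n_chrom = min(6, max(1, n_cpgs // 300))
    chrom_of = np.repeat(np.arange(n_chrom), math.ceil(n_cpgs / n_chrom))[:n_cpgs]

    # choose cluster anchor indices, spaced so clusters never touch
    anchors: list[int] = []
    candidates = np.arange(n_cpgs - CLUSTER_SIZE)
    rng.shuffle(candidates)
    for idx in candidates:
        if len(anchors) == n_clusters:
            break
        if chrom_of[idx] != chrom_of[idx + CLUSTER_SIZE - 1]:
            continue
        if all(abs(idx - a) > 2 * CLUSTER_SIZE for a in anchors):
            anchors.append(int(idx))
    anchors.sort()

    cluster_id = np.full(n_cpgs, -1, dtype=int)
    for k, a in enumerate(anchors):
        cluster_id[a : a + CLUSTER_SIZE] = k

    gaps = rng.integers(800, 2000, size=n_cpgs).astype(float)
    gaps[cluster_id >= 0] = rng.integers(30, 60, size=int((cluster_id >= 0).sum()))
    # first CpG of each cluster keeps a background gap to its neighbour
    for a in anchors:
        gaps[a] = rng.integers(1200, 2000)
    pos = np.zeros(n_cpgs, dtype=int)
    for c in range(n_chrom):
        mask = chrom_of == c
        pos[mask] = np.cumsum(gaps[mask]).astype(int)

    epithelial = rng.uniform(0.05, 0.95, size=n_cpgs)
    immune = rng.uniform(0.05, 0.95, size=n_cpgs)
    disc = cluster_id >= 0
    epithelial[disc] = rng.uniform(0.02, 0.10, size=int(disc.sum()))
    immune[disc] = rng.uniform(0.02, 0.10, size=int(disc.sum()))

    return ReferenceProfiles(
        cpg_ids=np.array([f"cg{i:07d}" for i in range(n_cpgs)]),
        chrom=np.array([f"chr{c + 1}" for c in chrom_of]),
        pos=pos,
        epithelial_mean=epithelial,
        immune_mean=immune,
        cluster_id=cluster_id,
    )


def simulate_beta_matrix(
    config: SimulationConfig,
    profiles: ReferenceProfiles,
    predictive: bool = False,
) -> tuple:
    """Simulate a mixed-cell methylation cohort with planted marker regions.

    Returns ``(beta, meta, truth_regions, immune_fractions)`` where
    ``truth_regions`` are the planted :class:`~widqec.discovery.CandidateRegion`
    intervals for recovery tests.  With ``predictive=True`` cases carry a
    months-to-diagnosis lead time (uniform over 0–36 months, the nested
    screening design); otherwise ``months_to_event`` is NA.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls

    available = [
        k for k in range(profiles.cluster_id.max() + 1)
        if (profiles.cluster_id == k).sum() >= config.cpgs_per_region
    ]
    if len(available) < config.n_true_regions:
        raise ValueError(
            f"profiles provide {len(available)} usable discoverable clusters, "
            f"need {config.n_true_regions}"
        )
    chosen = sorted(rng.choice(available, size=config.n_true_regions, replace=False))

    truth_regions = []
    planted_cols = []
    for k in chosen:
        idx = np.flatnonzero(profiles.cluster_id == k)[: config.cpgs_per_region]
        span = int(profiles.pos[idx].max() - profiles.pos[idx].min())
        if span > config.region_span_bp:
            raise ValueError("planted cluster exceeds region_span_bp")
        planted_cols.extend(idx.tolist())
        truth_regions.append(
            CandidateRegion(
                chrom=str(profiles.chrom[idx[0]]),
                start=int(profiles.pos[idx].min()),
                end=int(profiles.pos[idx].max()) + 1,
                member_cpg_ids=tuple(profiles.cpg_ids[idx]),
            )
        )
    planted_cols = np.asarray(planted_cols)

    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    a, b = config.immune_fraction_distribution
    immune_fractions = rng.beta(a, b, size=n)

    epi = np.tile(profiles.epithelial_mean, (n, 1))
    epi[np.ix_(group == "case", planted_cols)] = np.clip(
        profiles.epithelial_mean[planted_cols] + config.effect_size, 0.0, 1.0
    )
    f = immune_fractions[:, None]
    signal = (1 - f) * epi + f * profiles.immune_mean
    noise = (
        rng.normal(0.0, config.noise_sd, size=(n, profiles.n_cpgs))
        if config.noise_sd > 0
        else 0.0
    )
    values = np.clip(signal + noise, 0.0, 1.0)

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    beta = BetaMatrix(values=values, sample_ids=sample_ids,
                      cpg_ann=profiles.annotation())
    meta = _simulate_meta(sample_ids, group, rng, predictive)
    return beta, meta, truth_regions, immune_fractions


def _simulate_meta(
    sample_ids: list, group: np.ndarray, rng: np.random.Generator,
    predictive: bool,
) -> pd.DataFrame:
    """Cohort sample sheet with age-matched controls and case pathology."""
    n = len(sample_ids)
    is_case = group == "case"
    age = np.clip(rng.normal(65, 9, size=n), 35, 90).round(0)
    meno = np.where(age + rng.normal(0, 2, size=n) >= 51, "post", "pre")

    stage = np.full(n, "NA", dtype=object)
    grade = np.full(n, "NA", dtype=object)
    histology = np.full(n, "NA", dtype=object)
    k = int(is_case.sum())
    stage[is_case] = rng.choice(["I", "II", "III", "IV"], size=k,
                                p=[0.70, 0.10, 0.15, 0.05])
    grade[is_case] = rng.choice(["1", "2", "3"], size=k, p=[0.45, 0.30, 0.25])
    histology[is_case] = rng.choice(
        ["endometrioid", "serous", "other"], size=k, p=[0.80, 0.10, 0.10]
    )

    months = np.full(n, np.nan)
    if predictive:
        months[is_case] = rng.uniform(0.0, 36.0, size=k)
        months[~is_case] = rng.uniform(12.0, 48.0, size=n - k)

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "age": age,
            "menopausal_status": meno,
            "stage": stage,
            "grade": grade,
            "histology": histology,
            "collection": "smear",
            "months_to_event": months,
        }
    )


def simulate_comparators(meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Attach comparator modality columns to a sample sheet.

    ``ultrasound_mm`` emulates endometrial thickness (sensitive but
    unspecific at the usual >= 5 mm rule) and ``n_mutations`` a five-gene
    somatic panel (specific, moderately sensitive at >= 1 mutation).
    """
    rng = np.random.default_rng(seed)
    out = meta.copy()
    is_case = (out["group"] == "case").to_numpy()
    n = len(out)
    thickness = np.where(
        is_case,
        rng.lognormal(mean=np.log(12.0), sigma=0.5, size=n),
        rng.lognormal(mean=np.log(4.5), sigma=0.6, size=n),
    )
    out["ultrasound_mm"] = thickness.round(1)
    out["n_mutations"] = np.where(
        is_case, rng.poisson(1.6, size=n), rng.poisson(0.08, size=n)
    )
    return out


def pmr_truth_from_regions(
    beta: BetaMatrix, regions: Sequence[CandidateRegion]
) -> pd.DataFrame:
    """Ground-truth PMR per sample and region as 100 x mean regional beta.

    Fully methylated calibrator DNA corresponds to beta 1, so the regional
    methylation fraction maps directly onto the PMR percentage scale.
    """
    data = {}
    for i, region in enumerate(regions):
        cols = beta.columns_for(region.member_cpg_ids)
        data[f"A{i + 1}"] = 100.0 * beta.values[:, cols].mean(axis=1)
    return pd.DataFrame(data, index=pd.Index(beta.sample_ids, name="sample_id"))


def simulate_qpcr_plate(
    true_pmr: pd.DataFrame,
    ref_ct_range: tuple = (24.0, 32.0),
    ct_noise_sd: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    max_ref_ct: float = DEFAULT_MAX_REF_CT,
) -> pd.DataFrame:
    """Simulate a MethyLight plate from ground-truth PMR values.

    Each sample draws a reference-assay Ct uniformly in ``ref_ct_range``;
    each marker well gets ``ref_ct - log2(pmr / 100) + noise`` (perfect
    doubling, calibrator ratio 1), a PMR of exactly 0 mapping to an
    undetermined well.  Dropout samples — insufficient input DNA — instead
    get a reference Ct 1–5 cycles beyond ``max_ref_ct`` and undetermined
    marker wells.  The calibrator runs every assay at Ct 25.  Output is the
    long-format ``QpcrPlate`` table.
    """
    if (true_pmr.to_numpy() < 0).any():
        raise ValueError("true PMR values must be non-negative")
    if not (0 <= dropout_rate < 1):
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    assays = list(true_pmr.columns)
    rows = []
    for assay in [*assays, REFERENCE_ASSAY]:
        rows.append(
            {"sample_id": CALIBRATOR_ID, "assay_id": assay, "replicate": 1,
             "ct": 25.0, "is_calibrator": 1}
        )

    lo, hi = ref_ct_range
    for sample_id, pmrs in true_pmr.iterrows():
        dropped = rng.random() < dropout_rate
        if dropped:
            ref_ct = max_ref_ct + rng.uniform(1.0, 5.0)
        else:
            ref_ct = rng.uniform(lo, hi)
        rows.append(
            {"sample_id": sample_id, "assay_id": REFERENCE_ASSAY, "replicate": 1,
             "ct": float(ref_ct), "is_calibrator": 0}
        )
        for assay in assays:
            pmr = float(pmrs[assay])
            if dropped or pmr == 0.0:
                ct: object = UNDETERMINED
            else:
                ct = ref_ct - math.log2(pmr / 100.0)
                if ct_noise_sd > 0:
                    ct += rng.normal(0.0, ct_noise_sd)
                ct = float(max(ct, 1e-6))
            rows.append(
                {"sample_id": sample_id, "assay_id": assay, "replicate": 1,
                 "ct": ct, "is_calibrator": 0}
            )
    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate",
                                       "ct", "is_calibrator"])
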