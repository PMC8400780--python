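"""Synthetic cohorts and PRM-style chromatograms.

Emulates the study conditions of the cirrhosis-vs-HCC haptoglobin cohort:
15 patients per arm (3M/12F vs 7M/8F), TNM staging of the HCC arm,
log-normal AFP with group medians 2.9 and 6.0 ng/mL, and site-specific
glycoform abundance profiles whose Asn207 class means shift between groups
(sialylated down, sialylated-fucosylated up in HCC) while Asn184 and Asn241
stay put. Abundances are compositional: group class means are split across
each site's isomer entries, perturbed with logistic-normal noise, and
renormalized per site. Chromatograms render each isomer entry as a Gaussian
elution peak split over the six quantifier fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glyco_model import GlycanClass, GlycopeptideTarget, classify_glycan
from .quant import ChromatogramSet

__all__ = [
    "CohortConfig",
    "PeakModel",
    "PatientRecord",
    "CohortDataset",
    "generate_cohort",
    "render_chromatograms",
    "simulate_afp",
    "allocate_tnm",
]

CIRRHOSIS = "cirrhosis"
HCC = "HCC"

#: Default per-site class-mean profiles (sialylated, sialylated_fucosylated,
#: other). Asn207 is calibrated to the published group pies (87.2/12.1/0.7 %
#: cirrhosis vs 77.5/21.7/0.8 % HCC); Asn184/Asn241 use one sialylated-
#: dominated profile for both groups, since those sites showed no group
#: difference.
DEFAULT_CLASS_MEANS: Mapping[str, Mapping[str, tuple[float, float, float]]] = {
    "Asn184": {CIRRHOSIS: (0.85, 0.10, 0.05), HCC: (0.85, 0.10, 0.05)},
    "Asn207": {CIRRHOSIS: (0.872, 0.121, 0.007), HCC: (0.775, 0.217, 0.008)},
    "Asn241": {CIRRHOSIS: (0.88, 0.07, 0.05), HCC: (0.88, 0.07, 0.05)},
}

_CLASS_ORDER = (
    GlycanClass.SIALYLATED,
    GlycanClass.SIALYLATED_FUCOSYLATED,
    GlycanClass.OTHER,
)


@dataclass(frozen=True)
class PeakModel:
    """Gaussian elution-peak rendering conventions (all config-exposed)."""

    sigma_min: float = 0.3            # peak width (Gaussian sigma), minutes
    isomer_rt_spacing: float = 2.0    # ΔRT between isomers of one form, minutes
    sampling_interval: float = 0.02   # time-grid step, minutes
    fragment_split: tuple[float, ...] = (0.35, 0.20, 0.15, 0.12, 0.10, 0.08)
    baseline: float = 50.0            # flat baseline counts per fragment trace
    multiplicative_noise_sd: float = 0.05
    total_scale: float = 1e6          # summed peak area per site, per patient
    time_range: tuple[float, float] = (40.0, 90.0)

    def __post_init__(self) -> None:
        if self.sigma_min <= 0 or self.sampling_interval <= 0:
            raise ValueError("sigma and sampling interval must be positive")
        if abs(sum(self.fragment_split) - 1.0) > 1e-9:
            raise ValueError("fragment_split must sum to 1")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_per_group: tuple[int, int] = (15, 15)            # (cirrhosis, HCC)
    gender_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {CIRRHOSIS: (3, 12), HCC: (7, 8)}  # (M, F)
    )
    tnm_distribution: tuple[float, float, float, float] = (0.47, 0.0, 0.40, 0.13)
    afp_median: Mapping[str, float] = field(
        default_factory=lambda: {CIRRHOSIS: 2.9, HCC: 6.0}  # ng/mL
    )
    afp_log_sd: float = 1.0  # natural-log scale
    class_means: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: DEFAULT_CLASS_MEANS
    )
    #: Within-class allocation weight multipliers, keyed by form key
    #: ("site|code") or entry key ("site|code|isomer"), then by group.
    target_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    abundance_noise_sd: float = 0.15  # logistic-normal sd on log-abundances
    peaks: PeakModel = field(default_factory=PeakModel)
    seed: int = 0

    def validate(self) -> None:
        for group, (m, f) in self.gender_counts.items():
            if m < 0 or f < 0:
                raise ValueError(f"negative gender count for {group}")
        if abs(sum(self.tnm_distribution) - 1.0) > 1e-9:
            raise ValueError("tnm_distribution must sum to 1")
        if any(p < 0 or p > 1 for p in self.tnm_distribution):
            raise ValueError("tnm_distribution proportions must lie in [0, 1]")
        for site, by_group in self.class_means.items():
            for group, means in by_group.items():
                if abs(sum(means) - 1.0) > 1e-6:
                    raise ValueError(f"class means for {site}/{group} must sum to 1")
                if any(m < 0 for m in means):
                    raise ValueError(f"negative class mean for {site}/{group}")
        if self.abundance_noise_sd < 0 or self.afp_log_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    group: str            # cirrhosis | HCC
    gender: str           # M | F
    afp_ng_ml: float
    tnm_stage: str        # I..IV for HCC, NA for cirrhosis

    def __post_init__(self) -> None:
        if (self.tnm_stage == "NA") != (self.group == CIRRHOSIS):
            raise ValueError("tnm_stage must be NA exactly for cirrhosis patients")


@dataclass
class CohortDataset:
    patients: list[PatientRecord]
    targets: list[GlycopeptideTarget]
    #: rows = patient_id, cols = entry key "site|code|isomer"; per patient and
    #: site the entries sum to 1.
    true_abundances: pd.DataFrame
    chromatograms: dict[str, ChromatogramSet] = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, str]:
        return {p.patient_id: p.group for p in self.patients}

    def metadata(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "group": [p.group for p in self.patients],
                "gender": [p.gender for p in self.patients],
                "afp_ng_ml": [p.afp_ng_ml for p in self.patients],
                "tnm_stage": [p.tnm_stage for p in self.patients],
            }
        )
        return df.set_index("patient_id")


def simulate_afp(group: str, config: CohortConfig, rng: np.random.Generator) -> float:
    """One log-normal AFP draw whose distribution median is the group median."""
    mu = math.log(config.afp_median[group])
    return float(rng.lognormal(mean=mu, sigma=config.afp_log_sd))


def allocate_tnm(proportions: Sequence[float], n: int) -> list[int]:
    """Integer stage counts by largest-remainder rounding of ``n``×proportions."""
    raw = [p * n for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def _override_weight(config: CohortConfig, t: GlycopeptideTarget, group: str) -> float:
    ov = config.target_overrides.get(t.entry_key) or config.target_overrides.get(t.key) or {}
    return float(ov.get(group, 1.0))


def _entry_mean_profile(
    targets: Sequence[GlycopeptideTarget], config: CohortConfig, group: str
) -> pd.Series:
    """Group-mean relative abundance per isomer entry (sums to 1 per site)."""
    means: dict[str, float] = {}
    by_site: dict[str, list[GlycopeptideTarget]] = {}
    for t in targets:
        by_site.setdefault(t.site.site_id, []).append(t)
    for site_id, site_targets in by_site.items():
        class_means = dict(zip(_CLASS_ORDER, config.class_means[site_id][group]))
        by_class: dict[GlycanClass, list[GlycopeptideTarget]] = {}
        for t in site_targets:
            by_class.setdefault(classify_glycan(t.composition), []).append(t)
        for cls, members in by_class.items():
            weights = np.array([_override_weight(config, t, group) for t in members])
            weights = weights / weights.sum()
            for t, w in zip(members, weights):
                means[t.entry_key] = class_means[cls] * w
        # classes absent from a site simply contribute no entries; renormalize
        site_total = sum(means[t.entry_key] for t in site_targets)
        for t in site_targets:
            means[t.entry_key] /= site_total
    return pd.Series(means)


def generate_cohort(
    config: CohortConfig, targets: Sequence[GlycopeptideTarget]
) -> CohortDataset:
    """Sample patients and their true per-entry relative abundances.

    Deterministic under a fixed ``config.seed``. Chromatograms are rendered
    separately by :func:`render_chromatograms`.
    """
    if not targets:
        raise ValueError("target list is empty")
    config.validate()
    rng = np.random.default_rng([config.seed, 0xC0]) if config.seed is not None else np.random.default_rng()

    patients: list[PatientRecord] = []
    n_cir, n_hcc = config.n_per_group
    for group, n in ((CIRRHOSIS, n_cir), (HCC, n_hcc)):
        m, f = config.gender_counts[group]
        if m + f != n:
            raise ValueError(f"gender counts for {group} must sum to {n}")
        genders = ["M"] * m + ["F"] * f
        if group == HCC:
            stage_counts = allocate_tnm(config.tnm_distribution, n)
            stages = [s for s, c in zip(("I", "II", "III", "IV"), stage_counts) for _ in range(c)]
        else:
            stages = ["NA"] * n
        order = rng.permutation(n)
        prefix = "CIR" if group == CIRRHOSIS else "HCC"
        for i in range(n):
            patients.append(
                PatientRecord(
                    patient_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    gender=genders[order[i]],
                    afp_ng_ml=simulate_afp(group, config, rng),
                    tnm_stage=stages[order[i]],
                )
            )

    profiles = {g: _entry_mean_profile(targets, config, g) for g in (CIRRHOSIS, HCC)}
    entry_keys = list(profiles[CIRRHOSIS].index)
    site_of = {t.entry_key: t.site.site_id for t in targets}
    rows = {}
    for p in patients:
        mean = profiles[p.group]
        if config.abundance_noise_sd > 0:
            noisy = mean * np.exp(rng.normal(0.0, config.abundance_noise_sd, size=len(mean)))
        else:
            noisy = mean.copy()
        # renormalize within each site (logistic-normal / compositional)
        out = noisy.copy()
        for site_id in {site_of[k] for k in entry_keys}:
            cols = [k for k in entry_keys if site_of[k] == site_id]
            out[cols] = noisy[cols] / noisy[cols].sum()
        rows[p.patient_id] = out
    abund = pd.DataFrame(rows).T.reindex(columns=entry_keys)
    abund.index.name = "patient_id"
    return CohortDataset(patients=patients, targets=list(targets), true_abundances=abund)


def render_chromatograms(
    dataset: CohortDataset, config: CohortConfig
) -> dict[str, ChromatogramSet]:
    """Render per-patient fragment traces from the true abundances.

    Each isomer entry contributes a Gaussian peak at its expected RT to each
    of its fragment traces, with amplitude
    ``total_scale × abundance × fragment_split / (σ√(2π))`` so the noise-free
    trapezoid area of a fragment trace equals ``total_scale × abundance ×
    split``. A flat baseline and multiplicative Gaussian noise are added on
    top. Fills and returns ``dataset.chromatograms``.
    """
    pm = config.peaks
    rng = np.random.default_rng([config.seed, 0xC1]) if config.seed is not None else np.random.default_rng()
    t0, t1 = pm.time_range
    time = np.arange(t0, t1 + pm.sampling_interval / 2, pm.sampling_interval)
    norm = pm.sigma_min * math.sqrt(2.0 * math.pi)

    forms: dict[str, list[GlycopeptideTarget]] = {}
    for t in dataset.targets:
        forms.setdefault(t.key, []).append(t)

    chromatograms: dict[str, ChromatogramSet] = {}
    for p in dataset.patients:
        abund = dataset.true_abundances.loc[p.patient_id]
        traces: dict[tuple[str, float], np.ndarray] = {}
        for key, entries in forms.items():
            frags = entries[0].fragment_mzs
            split = pm.fragment_split[: len(frags)]
            # shared shape: sum of this form's isomer Gaussians, unit area
            shape = np.zeros_like(time)
            for e in entries:
                amp = pm.total_scale * abund[e.entry_key] / norm
                if amp > 0:
                    lo = np.searchsorted(time, e.expected_rt - 6 * pm.sigma_min)
                    hi = np.searchsorted(time, e.expected_rt + 6 * pm.sigma_min)
                    shape[lo:hi] += amp * np.exp(
                        -0.5 * ((time[lo:hi] - e.expected_rt) / pm.sigma_min) ** 2
                    )
            for frac, mz in zip(split, frags):
                trace = pm.baseline + frac * shape
                if pm.multiplicative_noise_sd > 0:
                    trace = trace * np.clip(
                        1.0 + rng.normal(0.0, pm.multiplicative_noise_sd, size=len(trace)),
                        0.0,
                        None,
                    )
                traces[(key, mz)] = trace
        chromatograms[p.patient_id] = ChromatogramSet(time=time, traces=traces)
    dataset.chromatograms = chromatograms
    return chromatograms
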