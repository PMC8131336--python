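"""Synthetic patient cohorts with the structure of a fibrosis screening study.

The generator emulates a single-center cross-sectional cohort of 141
adults who received both a portal venous CT and MR elastography (MRE),
of whom 122 fall below and 19 at or above the 3.5 kPa stiffness cutoff
for clinically significant fibrosis (≈ histologic stage F2).  Strata
over six stiffness bands, group-wise volume medians and the ordinal
LVCA distribution follow the published descriptive statistics of that
cohort; everything else (distribution families, spreads) is a modeling
choice documented in ``docs/methods.md``.

Key structural choices:

* Stratified sampling — group sizes match the configuration exactly,
  they are never binomial draws.
* Volumes are log-normal around group medians (strictly positive,
  right-skewed; the log-normal median is its scale parameter, so the
  configured medians are population medians by construction).
* The LVCA is *not* sampled directly: a latent category choice drives
  vein/IVC HU values and the contrasted flag, and the downstream
  classifier recovers the category from those measurements.  This keeps
  the classification rule on the tested path.
* Stiffness–score dependence is induced only through group membership;
  within a group, scores and stiffness are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .exceptions import ConfigError
from .phantom import LabeledVolume, PhantomSpec, generate_phantom

#: MRE stiffness cutoff (kPa) for clinically significant fibrosis.
DEFAULT_STIFFNESS_THRESHOLD_KPA = 3.5


@dataclass(frozen=True)
class PatientRecord:
    """One patient's measurements.

    Group membership (fibrotic vs not) is always *derived* from
    ``stiffness_kpa`` against a threshold, never stored.
    """

    id: str
    stiffness_kpa: float
    vol_i_iii: float
    vol_iv_viii: float
    splenic_volume: float | None
    vein_hu: tuple[float, ...]
    ivc_hu: float | None
    veins_contrasted: bool
    covariates: dict = field(default_factory=dict)

    def is_positive(self, threshold_kpa: float = DEFAULT_STIFFNESS_THRESHOLD_KPA) -> bool:
        """True when stiffness is at or above the fibrosis threshold."""
        return self.stiffness_kpa >= threshold_kpa


@dataclass(frozen=True)
class LogNormal:
    """Log-normal with an explicit median (= scale) and log-sd ``sigma``."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class GroupParams:
    """Per-group volume distributions and LVCA category mix.

    ``lvca_probs`` are the probabilities of latent categories 1–4 that
    drive the vein/IVC attenuation generator.
    """

    vol_i_iii: LogNormal
    vol_iv_viii: LogNormal
    splenic_volume: LogNormal
    lvca_probs: tuple[float, float, float, float]


# Spreads are calibrated so generated IQRs bracket the study's printed
# IQRs: sigma = ln(q3/q1) / (2 * 0.6745) per variable and group.
_NEGATIVE_DEFAULTS = GroupParams(
    vol_i_iii=LogNormal(333.0, 0.31),
    vol_iv_viii=LogNormal(1237.0, 0.20),
    splenic_volume=LogNormal(229.0, 0.42),
    lvca_probs=(0.60, 0.30, 0.08, 0.02),
)
_POSITIVE_DEFAULTS = GroupParams(
    vol_i_iii=LogNormal(449.0, 0.43),
    vol_iv_viii=LogNormal(1160.0, 0.33),
    splenic_volume=LogNormal(442.0, 0.52),
    lvca_probs=(0.05, 0.10, 0.25, 0.60),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    The default strata counts (90/20/12/5/4/10 over the stiffness bands
    <2.5, 2.5–2.9, 2.9–3.5, 3.5–4, 4–5, ≥5 kPa) reproduce the study
    population: 141 patients, 122 below and 19 at or above 3.5 kPa.
    Stiffness is uniform within a band; the open ≥5 kPa band uses a
    shifted exponential capped at 8 kPa.
    """

    strata_counts: tuple[int, ...] = (90, 20, 12, 5, 4, 10)
    strata_lower_kpa: tuple[float, ...] = (1.5, 2.5, 2.9, 3.5, 4.0, 5.0)
    tail_scale_kpa: float = 1.0
    tail_cap_kpa: float = 8.0
    threshold_kpa: float = DEFAULT_STIFFNESS_THRESHOLD_KPA
    negative: GroupParams = _NEGATIVE_DEFAULTS
    positive: GroupParams = _POSITIVE_DEFAULTS
    ivc_hu_mean: float = 100.0
    ivc_hu_sd: float = 5.0
    vein_jitter_sd_hu: float = 2.0
    # delta = mean vein HU - IVC HU ranges per latent category 1/2/3;
    # margins keep noise away from the ±20 HU decision boundary
    delta_hu_ranges: tuple[tuple[float, float], ...] = (
        (25.0, 60.0),
        (-14.0, 14.0),
        (-60.0, -25.0),
    )
    splenic_missing_negative: int = 7
    include_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.strata_counts) != len(self.strata_lower_kpa):
            raise ConfigError("strata_counts and strata_lower_kpa lengths differ")
        if any(c < 0 for c in self.strata_counts):
            raise ConfigError("strata counts must be non-negative")
        if list(self.strata_lower_kpa) != sorted(self.strata_lower_kpa):
            raise ConfigError("strata band edges must be increasing")
        for grp in (self.negative, self.positive):
            for ln in (grp.vol_i_iii, grp.vol_iv_viii, grp.splenic_volume):
                if not ln.median > 0:
                    raise ConfigError(f"log-normal median must be positive, got {ln.median}")
                if ln.sigma < 0:
                    raise ConfigError("log-normal sigma must be non-negative")
            if abs(sum(grp.lvca_probs) - 1.0) > 1e-9 or any(p < 0 for p in grp.lvca_probs):
                raise ConfigError("lvca_probs must be a probability vector over 4 categories")
        if self.splenic_missing_negative < 0:
            raise ConfigError("splenic_missing_negative must be non-negative")

    @property
    def n_total(self) -> int:
        return sum(self.strata_counts)


def _sample_stiffness(cfg: CohortConfig, stratum: int, rng: np.random.Generator) -> float:
    lo = cfg.strata_lower_kpa[stratum]
    if stratum + 1 < len(cfg.strata_lower_kpa):
        hi = cfg.strata_lower_kpa[stratum + 1]
        return float(rng.uniform(lo, hi))
    return float(min(lo + rng.exponential(cfg.tail_scale_kpa), cfg.tail_cap_kpa))


def _sample_attenuation(
    grp: GroupParams, cfg: CohortConfig, rng: np.random.Generator
) -> tuple[tuple[float, ...], float | None, bool]:
    category = int(rng.choice(4, p=grp.lvca_probs)) + 1
    ivc = float(rng.normal(cfg.ivc_hu_mean, cfg.ivc_hu_sd))
    if category == 4:
        return (), ivc, False
    lo, hi = cfg.delta_hu_ranges[category - 1]
    delta = rng.uniform(lo, hi)
    veins = tuple(
        float(ivc + delta + rng.normal(0.0, cfg.vein_jitter_sd_hu)) for _ in range(3)
    )
    return veins, ivc, True


def _sample_covariates(positive: bool, rng: np.random.Generator) -> dict:
    # Group-shifted defaults loosely matching the study's clinical table;
    # pass-through fields for the generic group-comparison tests only.
    if positive:
        return {
            "age_years": float(np.clip(rng.normal(56.0, 8.0), 18, 70)),
            "sex": "M" if rng.random() < 0.84 else "F",
            "bmi_kg_m2": float(27.7 * np.exp(0.15 * rng.standard_normal())),
            "ast_u_l": float(37.0 * np.exp(0.45 * rng.standard_normal())),
            "ggt_u_l": float(109.0 * np.exp(0.55 * rng.standard_normal())),
            "apri": float(0.9 * np.exp(0.9 * rng.standard_normal())),
        }
    return {
        "age_years": float(np.clip(rng.normal(53.0, 11.0), 18, 70)),
        "sex": "M" if rng.random() < 0.51 else "F",
        "bmi_kg_m2": float(25.3 * np.exp(0.12 * rng.standard_normal())),
        "ast_u_l": float(22.0 * np.exp(0.25 * rng.standard_normal())),
        "ggt_u_l": float(23.0 * np.exp(0.50 * rng.standard_normal())),
        "apri": float(0.2 * np.exp(0.60 * rng.standard_normal())),
    }


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate one stratified synthetic cohort.

    Deterministic for a fixed ``config.seed``; group sizes equal the
    configured strata counts exactly.
    """
    cfg = config if config is not None else CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[PatientRecord] = []
    idx = 0
    for stratum, count in enumerate(cfg.strata_counts):
        for _ in range(count):
            idx += 1
            stiffness = _sample_stiffness(cfg, stratum, rng)
            positive = stiffness >= cfg.threshold_kpa
            grp = cfg.positive if positive else cfg.negative
            veins, ivc, contrasted = _sample_attenuation(grp, cfg, rng)
            records.append(
                PatientRecord(
                    id=f"P{idx:04d}",
                    stiffness_kpa=stiffness,
                    vol_i_iii=float(grp.vol_i_iii.sample(rng, 1)[0]),
                    vol_iv_viii=float(grp.vol_iv_viii.sample(rng, 1)[0]),
                    splenic_volume=float(grp.splenic_volume.sample(rng, 1)[0]),
                    vein_hu=veins,
                    ivc_hu=ivc,
                    veins_contrasted=contrasted,
                    covariates=_sample_covariates(positive, rng) if cfg.include_covariates else {},
                )
            )
    # A handful of scans do not cover the whole spleen; emulate the
    # resulting missing splenic volumes in the negative group.
    negatives = [i for i, r in enumerate(records) if not r.is_positive(cfg.threshold_kpa)]
    n_missing = min(cfg.splenic_missing_negative, len(negatives))
    if n_missing:
        for i in rng.choice(negatives, size=n_missing, replace=False):
            records[i] = replace(records[i], splenic_volume=None)
    return records


def cohort_to_phantoms(
    cohort: Iterable[PatientRecord],
    shape: tuple[int, int, int] = (96, 96, 96),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    base_seed: int = 0,
) -> list[LabeledVolume]:
    """Voxelize each record into a labeled phantom.

    The phantom's measured volumes and attenuations round-trip to the
    record within the voxelization tolerances of the imaging module.
    Capacity errors are re-raised with the patient id attached.
    """
    phantoms = []
    for i, rec in enumerate(cohort):
        spec = PhantomSpec(
            vol_i_iii=rec.vol_i_iii,
            vol_iv_viii=rec.vol_iv_viii,
            splenic_volume=rec.splenic_volume if rec.splenic_volume else 250.0,
            vein_hu=float(np.mean(rec.vein_hu)) if rec.vein_hu else 0.0,
            ivc_hu=rec.ivc_hu if rec.ivc_hu is not None else 100.0,
            veins_contrasted=rec.veins_contrasted,
            shape=shape,
            spacing=spacing,
            seed=(base_seed + i) % (2**31 - 1),
        )
        try:
            phantoms.append(generate_phantom(spec))
        except Exception as exc:
            raise type(exc)(f"patient {rec.id}: {exc}") from exc
    return phantoms
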