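"""CT fibrosis scores: LVCA, LSVR and the composite LSVAR.

The three scores quantify two morphologic consequences of chronic liver
disease visible on a portal venous CT scan:

* **LSVR** (liver segmental volume ratio) — cirrhotic remodeling causes
  hypertrophy of the left/caudate lobe (Couinaud segments I–III) and
  atrophy of the right lobe (segments IV–VIII), so the ratio
  ``vol(I–III) / vol(IV–VIII)`` rises with fibrosis stage.
* **LVCA** (liver vein to cava attenuation) — delayed hepatic
  microperfusion shifts the enhancement of the hepatic veins relative to
  the inferior vena cava (IVC).  The score is ordinal:
  1 = veins hyperattenuating, 2 = isoattenuating (mean vein density
  within ±20 HU of the IVC), 3 = hypoattenuating, 4 = veins not
  contrasted at all.
* **LSVAR** — the composite ``LSVR × LVCA``, which couples the volume
  redistribution with the perfusion signal.

All functions here are pure; they operate on small frozen dataclasses
and raise the package's typed exceptions on invalid input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .exceptions import (
    InvalidMeasurementError,
    InvalidScoreError,
    InvalidVolumeError,
)

logger = logging.getLogger(__name__)

#: Valid Hounsfield-unit range for a 12-bit CT reconstruction.
HU_MIN = -1024.0
HU_MAX = 3071.0

#: Default iso-attenuation tolerance (HU) for the LVCA rule.
DEFAULT_TOLERANCE_HU = 20.0


def _check_hu(value: float, what: str) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise InvalidMeasurementError(f"{what} is not finite: {value!r}")
    if not (HU_MIN <= v <= HU_MAX):
        raise InvalidMeasurementError(
            f"{what} = {v} HU outside the valid range [{HU_MIN}, {HU_MAX}]"
        )
    return v


@dataclass(frozen=True)
class AttenuationMeasurement:
    """ROI attenuation readings for the LVCA.

    Parameters
    ----------
    vein_hu
        Mean densities (HU) of up to three hepatic veins, each measured
        1 cm proximal to the vein confluence.  May be empty when
        ``veins_contrasted`` is False.
    ivc_hu
        Mean density (HU) of the inferior vena cava 1 cm below the
        confluence.  May be None only when ``veins_contrasted`` is
        False (the comparison is then moot).
    veins_contrasted
        False means the hepatic veins show no visible contrast at all,
        which forces LVCA category 4 regardless of any HU readings.
    """

    vein_hu: tuple[float, ...]
    ivc_hu: float | None
    veins_contrasted: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vein_hu", tuple(_check_hu(v, "vein HU") for v in self.vein_hu)
        )
        if self.ivc_hu is not None:
            object.__setattr__(self, "ivc_hu", _check_hu(self.ivc_hu, "IVC HU"))
        if self.veins_contrasted:
            if len(self.vein_hu) == 0:
                raise InvalidMeasurementError(
                    "veins_contrasted is True but no vein HU values were given"
                )
            if self.ivc_hu is None:
                raise InvalidMeasurementError(
                    "veins_contrasted is True but no IVC HU value was given"
                )
        if len(self.vein_hu) > 3:
            raise InvalidMeasurementError(
                f"at most 3 hepatic vein readings expected, got {len(self.vein_hu)}"
            )

    @property
    def mean_vein_hu(self) -> float:
        if not self.vein_hu:
            raise InvalidMeasurementError("no vein HU values present")
        return sum(self.vein_hu) / len(self.vein_hu)


@dataclass(frozen=True)
class LvcaScore:
    """Ordinal LVCA category in {1, 2, 3, 4}."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4):
            raise InvalidScoreError(f"LVCA must be in {{1,2,3,4}}, got {self.value!r}")

    def __int__(self) -> int:
        return self.value


@dataclass(frozen=True)
class SegmentalVolumes:
    """Couinaud lobe volumes in ml (left I–III, right IV–VIII)."""

    vol_i_iii: float
    vol_iv_viii: float
    splenic_volume: float | None = None

    def __post_init__(self) -> None:
        for name in ("vol_i_iii", "vol_iv_viii"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidVolumeError(f"{name} must be a positive finite volume, got {v!r}")
        if self.splenic_volume is not None and not (
            math.isfinite(self.splenic_volume) and self.splenic_volume > 0
        ):
            raise InvalidVolumeError(
                f"splenic_volume must be positive when present, got {self.splenic_volume!r}"
            )

    @property
    def total_liver_volume(self) -> float:
        return self.vol_i_iii + self.vol_iv_viii


@dataclass(frozen=True)
class ScorePanel:
    """Derived per-patient scores; ``lsvar == lsvr * lvca`` by construction."""

    lvca: LvcaScore
    lsvr: float
    lsvar: float
    splenic_volume: float | None = None

    def __post_init__(self) -> None:
        if self.lsvar != self.lsvr * self.lvca.value:
            raise InvalidScoreError(
                f"inconsistent panel: lsvar={self.lsvar} != lsvr*lvca="
                f"{self.lsvr * self.lvca.value}"
            )


def classify_lvca(
    m: AttenuationMeasurement, tolerance_hu: float = DEFAULT_TOLERANCE_HU
) -> LvcaScore:
    """Classify the liver vein to cava attenuation into its four categories.

    Uncontrasted veins are category 4.  Otherwise the signed difference
    ``d = mean(vein_hu) - ivc_hu`` is compared against the tolerance:
    ``|d| <= tolerance_hu`` is isoattenuating (2), ``d > tolerance_hu``
    hyperattenuating (1), ``d < -tolerance_hu`` hypoattenuating (3).
    The boundary ``|d| == tolerance_hu`` counts as isoattenuating.

    Fewer than three vein readings are accepted (hepatic venous anatomy
    varies); the mean is then taken over the available veins and a
    warning is logged.
    """
    if not tolerance_hu > 0:
        raise InvalidMeasurementError(f"tolerance_hu must be > 0, got {tolerance_hu}")
    if not m.veins_contrasted:
        return LvcaScore(4)
    if len(m.vein_hu) < 3:
        logger.warning(
            "LVCA computed from %d vein reading(s) instead of 3", len(m.vein_hu)
        )
    d = m.mean_vein_hu - m.ivc_hu
    if abs(d) <= tolerance_hu:
        return LvcaScore(2)
    return LvcaScore(1) if d > 0 else LvcaScore(3)


def compute_lsvr(v: SegmentalVolumes) -> float:
    """Liver segmental volume ratio: vol(I–III) / vol(IV–VIII), unrounded."""
    return v.vol_i_iii / v.vol_iv_viii


def compute_lsvar(lsvr: float, lvca: LvcaScore | int) -> float:
    """Composite score ``LSVR × LVCA``."""
    value = int(lvca)
    if value not in (1, 2, 3, 4):
        raise InvalidScoreError(f"LVCA must be in {{1,2,3,4}}, got {lvca!r}")
    if not (math.isfinite(lsvr) and lsvr > 0):
        raise InvalidVolumeError(f"LSVR must be a positive ratio, got {lsvr!r}")
    return lsvr * value


def score_patient(record) -> ScorePanel:
    """Compute the full score panel for one patient record.

    ``record`` must expose ``vein_hu``, ``ivc_hu``, ``veins_contrasted``,
    ``vol_i_iii``, ``vol_iv_viii`` and optionally ``splenic_volume`` and
    ``id`` (used only to contextualize errors).  Works for
    :class:`~lsvar.cohort.PatientRecord` and for any duck-typed object.
    """
    pid = getattr(record, "id", "<unknown>")
    try:
        volumes = SegmentalVolumes(
            vol_i_iii=record.vol_i_iii,
            vol_iv_viii=record.vol_iv_viii,
            splenic_volume=getattr(record, "splenic_volume", None),
        )
        measurement = AttenuationMeasurement(
            vein_hu=tuple(record.vein_hu),
            ivc_hu=record.ivc_hu,
            veins_contrasted=record.veins_contrasted,
        )
        lvca = classify_lvca(measurement)
        lsvr = compute_lsvr(volumes)
        lsvar = compute_lsvar(lsvr, lvca)
    except (InvalidMeasurementError, InvalidVolumeError, InvalidScoreError) as exc:
        raise type(exc)(f"patient {pid}: {exc}") from exc
    return ScorePanel(
        lvca=lvca, lsvr=lsvr, lsvar=lsvar, splenic_volume=volumes.splenic_volume
    )
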