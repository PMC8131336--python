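"""Study orchestration: cohort → scores → diagnostics → report.

Reproduces the analysis flow of a CT fibrosis-score evaluation study:
score every patient, compare score distributions between the stiffness
groups (descriptive block), evaluate each score against the stiffness
reference with ROC/Youden/confusion statistics (diagnostic block), and
optionally summarize interrater reliability with ICC(1) (reliability
block).  Reports serialize to JSON at full precision and to plain-text
tables at the field's customary precision (ratios to 2 decimals,
percentages as integers, half-up).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .cohort import CohortConfig, PatientRecord, generate_cohort
from .exceptions import DegenerateStudyError, SchemaError
from .phantom import load_labeled_volume, measure_patient
from .scores import DEFAULT_TOLERANCE_HU, ScorePanel, score_patient

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "id",
    "stiffness_kpa",
    "vol_i_iii_ml",
    "vol_iv_viii_ml",
    "splenic_volume_ml",
    "vein1_hu",
    "vein2_hu",
    "vein3_hu",
    "ivc_hu",
    "veins_contrasted",
)

DEFAULT_FIXED_CUTOFFS: dict[str, tuple[float, ...]] = {
    "lsvr": (0.34,),
    "lsvar": (0.67, 0.47),
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one study run.

    Exactly one input mode is used: an existing cohort CSV, a phantom
    directory (paired NIfTI volumes plus a ``stiffness.csv``), or —
    when both are None — a synthetic cohort from ``cohort_config``
    (defaulting to the study-structured cohort seeded with ``seed``).
    ``fixed_cutoffs`` are tabulated in addition to the Youden-optimal
    cutoff of each score.
    """

    input_csv: str | None = None
    phantom_dir: str | None = None
    cohort_config: CohortConfig | None = None
    threshold_kpa: float = 3.5
    scores: tuple[str, ...] = ("lsvr", "lsvar", "lvca", "splenic_volume")
    fixed_cutoffs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FIXED_CUTOFFS.items()}
    )
    ci_method: str = "delong"
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.threshold_kpa > 0:
            raise SchemaError(f"threshold_kpa must be positive, got {self.threshold_kpa}")
        for score, cuts in self.fixed_cutoffs.items():
            if any(not math.isfinite(c) for c in cuts):
                raise SchemaError(f"non-finite fixed cutoff for {score}: {cuts}")


@dataclass(frozen=True)
class StudyReport:
    """Structured study results; see module docstring for the blocks."""

    descriptive: dict
    diagnostics: dict
    reliability: dict | None
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "descriptive": self.descriptive,
            "diagnostics": self.diagnostics,
            "reliability": self.reliability,
            "provenance": self.provenance,
        }

    def to_text(self) -> str:
        return _render_text(self)


# ---------------------------------------------------------------------------
# Cohort I/O

def _parse_bool(value, row: int) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise SchemaError(f"row {row}: veins_contrasted must be boolean-like, got {value!r}")


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a cohort table; unknown columns become covariates.

    Malformed rows raise :class:`~lsvar.exceptions.SchemaError` with the
    1-based data row number (the header is row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty cohort file") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {', '.join(missing)}")
    if len(df) == 0:
        raise SchemaError(f"{path}: cohort table has no rows")
    covariate_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            stiffness = float(d["stiffness_kpa"])
            vol_i_iii = float(d["vol_i_iii_ml"])
            vol_iv_viii = float(d["vol_iv_viii_ml"])
            if not stiffness > 0:
                raise SchemaError(f"stiffness_kpa must be positive, got {stiffness}")
            if not (vol_i_iii > 0 and vol_iv_viii > 0):
                raise SchemaError(
                    f"volumes must be positive, got {vol_i_iii}/{vol_iv_viii}"
                )
            splenic = d["splenic_volume_ml"]
            splenic = None if pd.isna(splenic) else float(splenic)
            if splenic is not None and not splenic > 0:
                raise SchemaError(f"splenic_volume_ml must be positive, got {splenic}")
            veins = tuple(
                float(d[c]) for c in ("vein1_hu", "vein2_hu", "vein3_hu") if pd.notna(d[c])
            )
            ivc = None if pd.isna(d["ivc_hu"]) else float(d["ivc_hu"])
            contrasted = _parse_bool(d["veins_contrasted"], i)
            if contrasted and (not veins or ivc is None):
                raise SchemaError("contrasted veins require vein and IVC HU values")
            covariates = {
                c: (d[c] if not isinstance(d[c], float) or not math.isnan(d[c]) else None)
                for c in covariate_cols
            }
            covariates = {k: v for k, v in covariates.items() if v is not None}
            records.append(
                PatientRecord(
                    id=str(d["id"]),
                    stiffness_kpa=stiffness,
                    vol_i_iii=vol_i_iii,
                    vol_iv_viii=vol_iv_viii,
                    splenic_volume=splenic,
                    vein_hu=veins,
                    ivc_hu=ivc,
                    veins_contrasted=contrasted,
                    covariates=covariates,
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path} row {i}: {exc}") from exc
    return records


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    """Write a cohort table (round-trips exactly through ``read_cohort_csv``)."""
    rows = []
    covariate_names: list[str] = []
    for r in records:
        for name in r.covariates:
            if name not in covariate_names:
                covariate_names.append(name)
    for r in records:
        veins = list(r.vein_hu) + [None] * (3 - len(r.vein_hu))
        row = {
            "id": r.id,
            "stiffness_kpa": r.stiffness_kpa,
            "vol_i_iii_ml": r.vol_i_iii,
            "vol_iv_viii_ml": r.vol_iv_viii,
            "splenic_volume_ml": r.splenic_volume,
            "vein1_hu": veins[0],
            "vein2_hu": veins[1],
            "vein3_hu": veins[2],
            "ivc_hu": r.ivc_hu,
            "veins_contrasted": r.veins_contrasted,
        }
        for name in covariate_names:
            row[name] = r.covariates.get(name)
        rows.append(row)
    # shortest round-tripping float representation keeps read(write(x)) == x
    pd.DataFrame(rows).to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_phantom_dir(path: str | Path) -> list[PatientRecord]:
    """Measure every phantom pair in a directory into patient records.

    The directory must contain ``<id>_hu.nii.gz`` / ``<id>_labels.nii.gz``
    pairs and a ``stiffness.csv`` with columns ``id`` and
    ``stiffness_kpa`` supplying the reference standard.
    """
    path = Path(path)
    stiff_file = path / "stiffness.csv"
    if not stiff_file.exists():
        raise SchemaError(f"{path}: missing stiffness.csv reference table")
    stiff = pd.read_csv(stiff_file)
    if not {"id", "stiffness_kpa"} <= set(stiff.columns):
        raise SchemaError(f"{stiff_file}: needs columns id, stiffness_kpa")
    records = []
    for _, row in stiff.iterrows():
        pid = str(row["id"])
        vol = load_labeled_volume(path, prefix=pid)
        volumes, att = measure_patient(vol)
        records.append(
            PatientRecord(
                id=pid,
                stiffness_kpa=float(row["stiffness_kpa"]),
                vol_i_iii=volumes.vol_i_iii,
                vol_iv_viii=volumes.vol_iv_viii,
                splenic_volume=volumes.splenic_volume,
                vein_hu=att.vein_hu,
                ivc_hu=att.ivc_hu,
                veins_contrasted=att.veins_contrasted,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Study computation

def _median_iqr(values: np.ndarray) -> dict:
    return {
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "n": int(len(values)),
    }


_MEASURES = (
    "lvca",
    "lsvr",
    "lsvar",
    "vol_i_iii_ml",
    "vol_iv_viii_ml",
    "total_liver_volume_ml",
    "splenic_volume_ml",
)


def _measure_values(records: list[PatientRecord], panels: list[ScorePanel], name: str) -> np.ndarray:
    if name == "lvca":
        return np.array([float(p.lvca.value) for p in panels])
    if name == "lsvr":
        return np.array([p.lsvr for p in panels])
    if name == "lsvar":
        return np.array([p.lsvar for p in panels])
    if name == "vol_i_iii_ml":
        return np.array([r.vol_i_iii for r in records])
    if name == "vol_iv_viii_ml":
        return np.array([r.vol_iv_viii for r in records])
    if name == "total_liver_volume_ml":
        return np.array([r.vol_i_iii + r.vol_iv_viii for r in records])
    if name == "splenic_volume_ml":
        return np.array(
            [np.nan if r.splenic_volume is None else r.splenic_volume for r in records]
        )
    raise KeyError(name)


_SCORE_KEYS = {"lsvr", "lsvar", "lvca", "splenic_volume"}


def _score_values(records, panels, score: str) -> np.ndarray:
    if score == "splenic_volume":
        return _measure_values(records, panels, "splenic_volume_ml")
    return _measure_values(records, panels, score)


def _cutoff_block(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> dict:
    cm = dx.confusion_at_cutoff(scores, labels, cutoff)
    sens = dx.sensitivity_pct(cm)
    spec = dx.specificity_pct(cm)
    return {
        "cutoff": float(cutoff),
        "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
        "sensitivity_pct": sens,
        "specificity_pct": spec,
        "sensitivity_pct_reported": dx.round_half_up_pct(sens),
        "specificity_pct_reported": dx.round_half_up_pct(spec),
    }


def evaluate_scores(
    records: list[PatientRecord],
    panels: list[ScorePanel],
    labels: np.ndarray,
    score_names=("lsvr", "lsvar", "lvca", "splenic_volume"),
    fixed_cutoffs: dict[str, tuple[float, ...]] | None = None,
    ci_method: str = "delong",
    seed: int | None = None,
) -> dict:
    """Diagnostic block: per-score ROC/AUC/CI, Youden cutoff, confusions.

    Patients with a missing splenic volume are excluded from the
    splenic-volume ROC only; the score ROCs always use the full cohort.
    """
    fixed_cutoffs = fixed_cutoffs or {}
    out = {}
    for name in score_names:
        if name not in _SCORE_KEYS:
            raise SchemaError(f"unknown score {name!r}; choose from {sorted(_SCORE_KEYS)}")
        values = _score_values(records, panels, name)
        keep = ~np.isnan(values)
        vals, labs = values[keep], labels[keep]
        roc = dx.empirical_roc(vals, labs, ci_method=ci_method, seed=seed)
        block = {
            "n": int(keep.sum()),
            "auc": roc.auc,
            "auc_ci95": list(roc.auc_ci95),
            "youden": _cutoff_block(vals, labs, roc.youden_cutoff)
            | {"youden_j": roc.youden_j},
            "fixed_cutoffs": [
                _cutoff_block(vals, labs, c) for c in fixed_cutoffs.get(name, ())
            ],
            "roc": {
                "thresholds": [float(t) for t in roc.thresholds],
                "sensitivity": roc.sensitivity.tolist(),
                "specificity": roc.specificity.tolist(),
            },
        }
        out[name] = block
    return out


def describe_groups(
    records: list[PatientRecord], panels: list[ScorePanel], labels: np.ndarray
) -> dict:
    """Descriptive block: per-group median [IQR] and Mann–Whitney p-values."""
    out = {}
    for name in _MEASURES:
        values = _measure_values(records, panels, name)
        keep = ~np.isnan(values)
        neg = values[keep & ~labels]
        pos = values[keep & labels]
        entry = {
            "negative": _median_iqr(neg) if len(neg) else None,
            "positive": _median_iqr(pos) if len(pos) else None,
        }
        if len(neg) and len(pos):
            _, p = dx.mann_whitney_u(neg, pos)
            entry["p_mann_whitney"] = p
        out[name] = entry
    return out


def second_reader_ratings(
    records: list[PatientRecord],
    n_subjects: int = 20,
    seed: int = 0,
    volume_cv: float = 0.05,
    hu_sd: float = 5.0,
) -> dict[str, np.ndarray]:
    """Simulate a second reader re-measuring a random patient subset.

    Rater 1 reports the recorded measurements; rater 2 re-measures with
    multiplicative log-normal volume error (default 5% CV) and additive
    HU error before rescoring.  Returns subjects × 2 ratings tables for
    LVCA, LSVR and LSVAR, for the interrater reliability block.
    """
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(records), size=min(n_subjects, len(records)), replace=False)
    tables = {"lvca": [], "lsvr": [], "lsvar": []}
    for i in sorted(chosen):
        r = records[i]
        p1 = score_patient(r)
        r2 = dataclasses.replace(
            r,
            vol_i_iii=r.vol_i_iii * float(np.exp(volume_cv * rng.standard_normal())),
            vol_iv_viii=r.vol_iv_viii * float(np.exp(volume_cv * rng.standard_normal())),
            vein_hu=tuple(v + float(rng.normal(0, hu_sd)) for v in r.vein_hu),
            ivc_hu=None if r.ivc_hu is None else r.ivc_hu + float(rng.normal(0, hu_sd)),
        )
        p2 = score_patient(r2)
        tables["lvca"].append([p1.lvca.value, p2.lvca.value])
        tables["lsvr"].append([p1.lsvr, p2.lsvr])
        tables["lsvar"].append([p1.lsvar, p2.lsvar])
    return {k: np.asarray(v, dtype=float) for k, v in tables.items()}


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_records(cfg: RunConfig) -> list[PatientRecord]:
    if cfg.input_csv is not None:
        return read_cohort_csv(cfg.input_csv)
    if cfg.phantom_dir is not None:
        return read_phantom_dir(cfg.phantom_dir)
    cohort_cfg = cfg.cohort_config
    if cohort_cfg is None:
        cohort_cfg = CohortConfig(seed=cfg.seed, threshold_kpa=cfg.threshold_kpa)
    return generate_cohort(cohort_cfg)


def run_study(
    cfg: RunConfig, ratings: dict[str, np.ndarray] | None = None
) -> StudyReport:
    """Run the full analysis and return a :class:`StudyReport`.

    Deterministic given ``cfg`` (including its seed).  Raises
    :class:`~lsvar.exceptions.DegenerateStudyError` when thresholding
    leaves a single stiffness class.
    """
    logger.info(
        "run_study: threshold=%.2f kPa, LVCA tolerance=%.0f HU, CI method=%s, "
        "Youden ties -> smallest cutoff, positivity: score >= cutoff",
        cfg.threshold_kpa,
        DEFAULT_TOLERANCE_HU,
        cfg.ci_method,
    )
    records = load_records(cfg)
    labels = np.array([r.is_positive(cfg.threshold_kpa) for r in records])
    if labels.all() or not labels.any():
        raise DegenerateStudyError(
            f"cohort has a single class at threshold {cfg.threshold_kpa} kPa "
            f"({int(labels.sum())}/{len(labels)} positive)"
        )
    panels = [score_patient(r) for r in records]
    descriptive = describe_groups(records, panels, labels)
    diagnostics = evaluate_scores(
        records,
        panels,
        labels,
        score_names=cfg.scores,
        fixed_cutoffs=cfg.fixed_cutoffs,
        ci_method=cfg.ci_method,
        seed=cfg.seed,
    )
    reliability = None
    if ratings is not None:
        reliability = {}
        for name, table in ratings.items():
            icc = dx.icc_oneway(table)
            reliability[name] = {
                "icc": icc.value,
                "band": icc.band,
                "n_subjects": int(np.asarray(table).shape[0]),
                "n_raters": int(np.asarray(table).shape[1]),
            }
    provenance = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "threshold_kpa": cfg.threshold_kpa,
        "n_patients": len(records),
        "n_positive": int(labels.sum()),
        "n_negative": int((~labels).sum()),
        "package_version": _package_version(),
    }
    return StudyReport(
        descriptive=descriptive,
        diagnostics=diagnostics,
        reliability=reliability,
        provenance=provenance,
    )


def _package_version() -> str:
    try:
        return version("lsvar")
    except PackageNotFoundError:  # pragma: no cover - source tree use
        return "unknown"


# ---------------------------------------------------------------------------
# Report rendering

def _fmt(value: float, decimals: int = 2) -> str:
    return f"{value:.{decimals}f}"


def _render_text(report: StudyReport) -> str:
    lines = []
    prov = report.provenance
    lines.append("Study report")
    lines.append(
        f"  n = {prov['n_patients']} patients "
        f"({prov['n_negative']} below / {prov['n_positive']} at or above "
        f"{prov['threshold_kpa']} kPa)"
    )
    lines.append(f"  config {prov['config_hash']}  seed {prov['seed']}")
    lines.append("")
    lines.append("Score distributions by stiffness group (median [IQR], Mann-Whitney p)")
    for name, entry in report.descriptive.items():
        neg, pos = entry["negative"], entry["positive"]
        p = entry.get("p_mann_whitney")
        dec = 2 if name in ("lvca", "lsvr", "lsvar") else 0
        def cell(g):
            if g is None:
                return "-"
            return (
                f"{_fmt(g['median'], dec)} "
                f"[{_fmt(g['q1'], dec)}-{_fmt(g['q3'], dec)}] (n={g['n']})"
            )
        ptxt = "p<0.001" if p is not None and p < 0.001 else (f"p={p:.3f}" if p is not None else "")
        lines.append(f"  {name:<22} {cell(neg):>30}  vs  {cell(pos):>30}  {ptxt}")
    lines.append("")
    lines.append("Diagnostic accuracy (positivity: score >= cutoff)")
    for name, block in report.diagnostics.items():
        ci = block["auc_ci95"]
        lines.append(
            f"  {name}: AUC {_fmt(block['auc'])} "
            f"(95% CI {_fmt(ci[0])}-{_fmt(ci[1])}, n={block['n']})"
        )
        for cb in [block["youden"], *block["fixed_cutoffs"]]:
            tag = "Youden" if "youden_j" in cb else "fixed"
            cm = cb["confusion"]
            lines.append(
                f"    cutoff {_fmt(cb['cutoff'])} ({tag}): "
                f"sens {cb['sensitivity_pct_reported']}% "
                f"spec {cb['specificity_pct_reported']}% "
                f"(TP {cm['tp']} TN {cm['tn']} FP {cm['fp']} FN {cm['fn']})"
            )
    if report.reliability:
        lines.append("")
        lines.append("Interrater reliability (one-way random-effects ICC)")
        for name, entry in report.reliability.items():
            lines.append(
                f"  {name}: ICC {_fmt(entry['icc'])} ({entry['band']}, "
                f"{entry['n_subjects']} subjects x {entry['n_raters']} raters)"
            )
    return "\n".join(lines) + "\n"


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write report.json, report.txt and per-score ROC coordinate CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    (outdir / "report.txt").write_text(report.to_text())
    for name, block in report.diagnostics.items():
        roc = block["roc"]
        pd.DataFrame(
            {
                "threshold": roc["thresholds"],
                "sensitivity": roc["sensitivity"],
                "specificity": roc["specificity"],
            }
        ).to_csv(outdir / f"roc_{name}.csv", index=False)
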