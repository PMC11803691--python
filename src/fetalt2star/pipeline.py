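"""End-to-end orchestration: images + masks → maps → metrics → statistics.

``run_subject`` processes one fetus (fit the T2* map, compute the placental
mean T2*, volume, texture, morphology and maximum thickness, and the brain
mean T2*); ``run_cohort`` iterates a manifest and feeds the resulting table
into the statistical stage.  Subject-level failures degrade gracefully: the
affected metric is flagged and left NaN while the run continues, mirroring a
retrospective-cohort workflow where exclusions are recorded rather than
fatal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import StatResult, StatsPlan, run_statistics
from .errors import ConfigurationError, DegenerateInputError, FormatError
from .io import (
    BinaryMask,
    CohortTable,
    MultiEchoVolume,
    RoiMetrics,
    SubjectRecord,
    read_mask,
    read_multiecho,
    write_cohort_table,
    write_scalar_map,
)
from .morphometrics import morphology_metrics
from .relaxometry import (
    DEFAULT_REPORT_THRESHOLD,
    DEFAULT_T2STAR_CAP,
    fit_t2star_map,
    mean_t2star,
)
from .texture import TextureParams, placental_texture

__all__ = ["RunConfig", "run_subject", "run_cohort", "report_to_json"]

log = logging.getLogger("fetalt2star")

MANIFEST_COLUMNS = (
    "id", "group", "ga_weeks", "maternal_age_years",
    "image", "sidecar", "placenta_mask", "brain_mask",
)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with the pinned analysis parameters."""

    threshold_msec: float = DEFAULT_REPORT_THRESHOLD
    fit_cap_msec: float = DEFAULT_T2STAR_CAP
    texture: TextureParams = field(default_factory=TextureParams)
    stats_plan: StatsPlan = field(default_factory=StatsPlan)
    out_dir: Path | None = None
    save_maps: bool = False
    select_largest_component: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_msec <= 0 or self.fit_cap_msec <= 0:
            raise ConfigurationError("threshold and fit cap must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tex = TextureParams(**raw.pop("texture", {}))
        plan_raw = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw.pop("stats_plan", {}).items()}
        plan = StatsPlan(**plan_raw)
        out_dir = raw.pop("out_dir", None)
        return cls(texture=tex, stats_plan=plan,
                   out_dir=Path(out_dir) if out_dir else None, **raw)


def run_subject(
    volume: MultiEchoVolume,
    placenta_mask: BinaryMask,
    brain_mask: BinaryMask | None,
    config: RunConfig = RunConfig(),
    subject_id: str = "subject",
    group: str = "control",
    ga_weeks: float = 32.0,
    maternal_age_years: float = 33.0,
) -> SubjectRecord:
    """Process one fetus into a :class:`SubjectRecord`.

    Any stage failure flags the affected metric (NaN + entry in
    ``record.flags``) and processing continues with the remaining metrics.
    """
    flags: list[str] = []
    t0 = time.perf_counter()

    roi = placenta_mask.as_bool()
    if brain_mask is not None:
        roi = roi | brain_mask.as_bool()
    fit_roi = BinaryMask(data=roi.astype(np.uint8), geometry=volume.geometry, label="placenta")
    t2map, _s0map = fit_t2star_map(volume, roi=fit_roi, cap=config.fit_cap_msec)
    log.info("%s: fit %d voxels in %.2fs", subject_id, fit_roi.n_voxels, time.perf_counter() - t0)

    pl_mean = np.nan
    volume_mm3 = np.nan
    texture_val = np.nan
    morph_score = np.nan
    thick = np.nan
    if placenta_mask.is_empty:
        flags.append("placenta_mask_empty")
    else:
        pl_mean = mean_t2star(t2map, placenta_mask, config.threshold_msec)
        if not np.isfinite(pl_mean):
            flags.append("placenta_mean_undefined")
        try:
            morph = morphology_metrics(
                placenta_mask, select_largest=config.select_largest_component
            )
            volume_mm3 = morph.volume_mm3
            morph_score = morph.morphology_score
            thick = morph.max_thickness_mm
        except DegenerateInputError:
            flags.append("placenta_morphometrics_failed")
        texture_val = placental_texture(t2map, placenta_mask, config.texture)
        if not np.isfinite(texture_val):
            flags.append("placenta_texture_degenerate")

    brain_mean = np.nan
    if brain_mask is None or brain_mask.is_empty:
        flags.append("brain_mask_missing")
    else:
        brain_mean = mean_t2star(t2map, brain_mask, config.threshold_msec)
        if not np.isfinite(brain_mean):
            flags.append("brain_mean_undefined")

    if config.save_maps and config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        write_scalar_map(t2map, config.out_dir / ("%s_t2star.nii.gz" % subject_id))

    return SubjectRecord(
        id=subject_id, group=group, ga_weeks=ga_weeks,
        maternal_age_years=maternal_age_years,
        placenta_metrics=RoiMetrics(
            mean_t2star_msec=float(pl_mean), volume_mm3=float(volume_mm3),
            texture=float(texture_val), morphology=float(morph_score),
            max_thickness_mm=float(thick),
        ),
        brain_mean_t2star=float(brain_mean),
        flags=tuple(flags),
    )


def run_cohort(manifest: str | Path | pd.DataFrame, config: RunConfig = RunConfig()):
    """Process every subject of a manifest, then run the statistical stage.

    The manifest is a CSV (or DataFrame) with columns ``id, group, ga_weeks,
    maternal_age_years, image, sidecar, placenta_mask, brain_mask``.
    Returns ``(CohortTable, report)``; the report carries a config echo,
    seed, software version and per-family FDR.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype={"id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError("manifest is missing columns: %r" % missing)

    records = []
    for _, row in manifest.iterrows():
        try:
            volume = read_multiecho(row["image"], row["sidecar"])
            pmask = read_mask(row["placenta_mask"], volume.geometry, label="placenta")
            try:
                bmask = read_mask(row["brain_mask"], volume.geometry, label="brain")
            except (FormatError, FileNotFoundError):
                bmask = None
            rec = run_subject(
                volume, pmask, bmask, config,
                subject_id=str(row["id"]), group=str(row["group"]),
                ga_weeks=float(row["ga_weeks"]),
                maternal_age_years=float(row["maternal_age_years"]),
            )
        except (FormatError, ConfigurationError, FileNotFoundError) as exc:
            log.warning("subject %s failed: %s", row["id"], exc)
            rec = SubjectRecord(
                id=str(row["id"]), group=str(row["group"]),
                ga_weeks=float(row["ga_weeks"]),
                maternal_age_years=float(row["maternal_age_years"]),
                flags=("subject_failed:%s" % type(exc).__name__,),
            )
        records.append(rec)
    if all(len(r.flags) > 0 and r.flags[0].startswith("subject_failed") for r in records):
        raise FormatError("every subject failed; nothing to analyse")

    table = CohortTable(records=tuple(records))
    report = run_statistics(table, config.stats_plan)
    report["provenance"] = {
        "software": "fetalt2star %s" % __version__,
        "seed": config.seed,
        "threshold_msec": config.threshold_msec,
        "fit_cap_msec": config.fit_cap_msec,
        "texture_params": dataclasses.asdict(config.texture),
        "n_subjects": len(table),
    }
    if config.out_dir is not None:
        config.out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_table(table, config.out_dir / "cohort_table.csv")
        with open(config.out_dir / "stats_report.json", "w") as fh:
            json.dump(report_to_json(report), fh, indent=1, sort_keys=True)
    return table, report


def _jsonify(obj):
    if isinstance(obj, StatResult):
        return {
            "method": obj.method, "estimate": _num(obj.estimate),
            "p_value": _num(obj.p_value), "p_fdr": _num(obj.p_fdr),
            "n": obj.n, "adjusted_for": list(obj.adjusted_for),
        }
    if hasattr(obj, "group_means"):  # EmmResult
        return {"group_means": {k: _num(v) for k, v in obj.group_means.items()},
                "se": {k: _num(v) for k, v in obj.se.items()},
                "covariate_at": _num(obj.covariate_at)}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return _num(obj) if isinstance(obj, (int, float, np.floating, np.integer)) else obj


def _num(x):
    if x is None:
        return None
    x = float(x)
    return x if np.isfinite(x) else None


def report_to_json(report: dict) -> dict:
    """Convert a stats report (with StatResult/EmmResult leaves) to plain JSON."""
    return _jsonify(report)
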