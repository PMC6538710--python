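"""End-to-end orchestration: synthesize/ingest a cohort, extract features,
search classifiers and summarize, under a single validated configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features, preprocess, roi, synth

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "PhantomSpec",
    "PipelineConfig",
    "PipelineResult",
    "validate_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class PhantomSpec:
    """Reference phantom used to derive depth correction curves.

    ``gain`` is a (top, bottom) pair; the amplitude gain varies linearly
    with depth between them.
    """

    grid_shape: tuple[int, int] = (520, 81)
    sample_spacing_mm: float = 0.0385
    line_pitch_mm: float = 0.25
    nak: float = 1.0
    gain: tuple[float, float] = (1.0, 1.0)
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    rim_width_mm: float = 5.0
    window_mm: float = 1.0
    overlap: float = 0.92
    db_range: tuple[float, float] = (20.0, 100.0)
    gray_levels: int = 20
    displacement_mm: float = 0.3
    entropy_bins: int = 40
    k: int = 4
    correction: str = "off"  # off | multiplicative | additive
    seed: int = 0
    max_subset_size: int | None = None
    cohort: synth.CohortSpec | None = None
    cohort_dir: str | None = None
    phantom: PhantomSpec | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError([f"unknown config key: {k}" for k in sorted(unknown)])
        if data.get("cohort") is not None:
            data["cohort"] = _cohort_from_dict(data["cohort"])
        if data.get("phantom") is not None:
            data["phantom"] = PhantomSpec(**_listify(data["phantom"]))
        if data.get("db_range") is not None:
            data["db_range"] = tuple(data["db_range"])
        return cls(**data)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _listify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def _scene_from_dict(d: dict) -> synth.SceneSpec:
    d = dict(d)
    if d.get("lesion_ellipse") is not None:
        c, s, r = d["lesion_ellipse"]
        d["lesion_ellipse"] = (tuple(c), tuple(s), r)
    for key in ("grid_shape", "mean_power"):
        if key in d:
            d[key] = tuple(d[key])
    return synth.SceneSpec(**d)


def _cohort_from_dict(d: dict) -> synth.CohortSpec:
    d = dict(d)
    d["benign_scene"] = _scene_from_dict(d["benign_scene"])
    d["malignant_scene"] = _scene_from_dict(d["malignant_scene"])
    return synth.CohortSpec(**d)


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Range-check every field; collect all problems into one error."""
    errors = []
    if config.rim_width_mm <= 0:
        errors.append("rim_width_mm must be positive")
    if config.window_mm <= 0:
        errors.append("window_mm must be positive")
    if not 0 <= config.overlap < 1:
        errors.append("overlap must be in [0, 1)")
    low, high = config.db_range
    if low >= high:
        errors.append("db_range must satisfy low < high")
    if config.gray_levels < 2:
        errors.append("gray_levels must be >= 2")
    if config.displacement_mm <= 0:
        errors.append("displacement_mm must be positive")
    if config.entropy_bins < 1:
        errors.append("entropy_bins must be >= 1")
    if config.k < 1:
        errors.append("k must be >= 1")
    if config.correction not in ("off", "multiplicative", "additive"):
        errors.append("correction must be off, multiplicative, or additive")
    if config.max_subset_size is not None and config.max_subset_size < 1:
        errors.append("max_subset_size must be >= 1 or null")
    if config.cohort is None and config.cohort_dir is None:
        errors.append("either a synthetic cohort spec or a cohort directory is required")
    if config.correction != "off" and config.phantom is None:
        errors.append("correction requires a phantom spec")
    if errors:
        raise ConfigError(errors)
    return config


@dataclass(frozen=True)
class PipelineResult:
    features: pd.DataFrame
    searches: dict  # roi_group -> SearchResult
    comparison: classify.ComparisonResult
    summary: dict


def _config_hash(config: PipelineConfig, fields: tuple[str, ...]) -> str:
    d = config.to_dict()
    payload = json.dumps({k: d[k] for k in fields}, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


_EXTRACT_FIELDS = (
    "rim_width_mm",
    "window_mm",
    "overlap",
    "db_range",
    "gray_levels",
    "displacement_mm",
    "entropy_bins",
    "correction",
    "seed",
    "cohort",
    "cohort_dir",
    "phantom",
)


def _correction_curves(config: PipelineConfig) -> dict:
    """Estimate per-parameter depth correction curves from the phantom."""
    p = config.phantom
    z_end = (p.grid_shape[0] - 1) * p.sample_spacing_mm
    frame = synth.make_reference_phantom(
        p.grid_shape,
        nak=p.nak,
        depth_gain=lambda z: p.gain[0] + (p.gain[1] - p.gain[0]) * z / z_end,
        seed=p.seed,
        sample_spacing_mm=p.sample_spacing_mm,
        line_pitch_mm=p.line_pitch_mm,
    )
    env = preprocess.detect_envelope(frame)
    bmode = preprocess.log_compress(env, db_range=config.db_range)
    windows = roi.place_windows(env.values.shape, env.pixel_mm, config.window_mm, config.overlap)
    maps = features.estimate_maps(
        env,
        bmode,
        windows,
        features.PARAMETERS,
        entropy_bins=config.entropy_bins,
        displacement_mm=config.displacement_mm,
        gray_levels=config.gray_levels,
    )
    curves = {}
    for name, pmap in maps.items():
        # correlation features change sign, so a ratio-based curve is
        # ill-defined for them; they are always corrected additively
        mode = "additive" if name.startswith("COR") else config.correction
        curves[name] = preprocess.estimate_correction_curve(pmap, mode=mode)
    return curves


class _LoadedLesion:
    def __init__(self, record: dict):
        self.lesion_id = record["lesion_id"]
        self.label = record["label"]
        self.planes = record["planes"]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full study: cohort -> features -> searches -> comparison.

    When ``outdir`` is given, stage outputs are written there and the
    feature-extraction stage is cached under a hash of the stage-relevant
    configuration, so reruns with an unchanged configuration skip it.
    """
    validate_config(config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    cache_path = None
    table = None
    if outdir is not None:
        cache_path = outdir / "cache" / f"features_{_config_hash(config, _EXTRACT_FIELDS)}.csv"
        if cache_path.exists():
            logger.info("feature extraction: cache hit at %s", cache_path)
            table = pd.read_csv(cache_path)

    if table is None:
        if config.cohort is not None:
            lesions = synth.make_cohort(config.cohort).lesions
        else:
            lesions = [_LoadedLesion(rec) for rec in synth.read_cohort(config.cohort_dir)]
        curves = _correction_curves(config) if config.correction != "off" else None
        table = features.extract_features(
            lesions,
            rim_width_mm=config.rim_width_mm,
            window_mm=config.window_mm,
            overlap=config.overlap,
            db_range=config.db_range,
            gray_levels=config.gray_levels,
            displacement_mm=config.displacement_mm,
            entropy_bins=config.entropy_bins,
            corrections=curves,
        )
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            table.to_csv(cache_path, index=False)

    searches = {}
    for group in ("internal", "external", "combined"):
        searches[group] = classify.exhaustive_search(
            table, group, k=config.k, max_size=config.max_subset_size
        )
    comparison = classify.compare_groups(searches["internal"], searches["external"])

    summary = {
        "n_lesions": int(len(table)),
        "n_benign": int((table["label"] == "benign").sum()),
        "n_malignant": int((table["label"] == "malignant").sum()),
        "groups": {
            group: {
                "count": sr.count,
                "best_subset": list(sr.best.features),
                "best_auc": round(sr.best.auc, 6),
                "sensitivity": round(sr.best.sensitivity, 6),
                "specificity": round(sr.best.specificity, 6),
                "accuracy": round(sr.best.accuracy, 6),
                "p_value": round(sr.best.p_value, 9),
                "significance": sr.best.significance_class,
            }
            for group, sr in searches.items()
        },
        "delta_auc": {
            "n_internal_wins": comparison.n_internal_wins,
            "n_external_wins": comparison.n_external_wins,
            "n_ties": comparison.n_ties,
        },
        "config": config.to_dict(),
    }

    if outdir is not None:
        table.to_csv(outdir / "features.csv", index=False)
        for group, sr in searches.items():
            sr.reports.to_csv(outdir / f"reports_{group}.csv", index=False)
        comparison.table.to_csv(outdir / "delta_auc.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    return PipelineResult(
        features=table, searches=searches, comparison=comparison, summary=summary
    )
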