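"""End-to-end orchestration: manifest in, feature tables and models out.

Stages: segment each of the four views, mirror and register the left views
onto the right views, compute subtraction maps, build the 15-image stacks
per view, extract the 2,150-entry subject vectors, then run the modeling
stage (correlation filter, normalization, LASSO selection, blind
evaluation).  Subjects whose registration does not converge are excluded
and counted, and a machine-readable run report is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .features import BilateralViewStack, build_subject_vector, build_view_stack
from .filters import FilterConfig
from .grids import read_image
from .modeling import (
    FeatureTable,
    correlation_filter,
    evaluate_blind,
    lasso_train,
    prank_normalize,
    znormalize_int,
)
from .phantom import MammogramSet, VIEWS
from .registration import RegistrationConfig, mirror_horizontal, register_bspline
from .segmentation import NoTissueError, segment_breast

log = logging.getLogger("mammotriage")


@dataclass
class PipelineConfig:
    """One document holding every stage's knobs; round-trips through YAML."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    correlation_threshold: float = 0.96
    normalization: str = "znorm"  # prank | znorm
    n_train: int = 100
    modeling_seed: int = 0
    bit_depth: int = 12
    max_registration_failure_fraction: float = 0.2
    log_level: str = "INFO"
    output_dir: str = "runs"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["filters"] = FilterConfig(**raw.get("filters", {}))
        fl = raw["filters"]
        fl.lfd_scales = tuple(fl.lfd_scales)
        raw["registration"] = RegistrationConfig(**raw.get("registration", {}))
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def subject_view_stacks(
    subject: MammogramSet,
    reg_config: RegistrationConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> tuple[dict[str, BilateralViewStack], bool]:
    """Segment, register and stack one subject; False if registration failed."""
    reg_config = reg_config or RegistrationConfig()
    filter_config = filter_config or FilterConfig()
    stacks: dict[str, BilateralViewStack] = {}
    all_converged = True
    for view in VIEWS:
        right = segment_breast(subject.images[(view, "r")]).image
        left = segment_breast(subject.images[(view, "l")]).image
        mirrored = mirror_horizontal(left)
        reg = register_bspline(right, mirrored, reg_config)
        all_converged &= reg.converged
        stacks[view] = build_view_stack(view, right, left, reg.warped_moving, filter_config)
    return stacks, all_converged


def extract_cohort_features(
    subjects: list[MammogramSet],
    reg_config: RegistrationConfig | None = None,
    filter_config: FilterConfig | None = None,
    max_failure_fraction: float = 0.2,
) -> tuple[FeatureTable, list[str]]:
    """Per-subject vectors for a cohort; registration failures are excluded."""
    rows: dict[str, pd.Series] = {}
    labels: dict[str, str] = {}
    excluded: list[str] = []
    for subject in subjects:
        try:
            stacks, converged = subject_view_stacks(subject, reg_config, filter_config)
        except NoTissueError:
            log.warning("subject %s: segmentation found no tissue; excluded", subject.subject_id)
            excluded.append(subject.subject_id)
            continue
        if not converged:
            log.warning("subject %s: registration did not converge; excluded", subject.subject_id)
            excluded.append(subject.subject_id)
            continue
        rows[subject.subject_id] = build_subject_vector(stacks["CC"], stacks["MLO"])
        labels[subject.subject_id] = subject.label
    if subjects and len(excluded) / len(subjects) > max_failure_fraction:
        raise RuntimeError(
            f"{len(excluded)}/{len(subjects)} subjects failed registration/segmentation; "
            "aborting (check image quality or registration settings)"
        )
    data = pd.DataFrame(rows).T
    table = FeatureTable(data, pd.Series(labels), "raw")
    return table, excluded


def load_manifest_subjects(
    manifest_path: str | Path, bit_depth: int = 12
) -> tuple[list[MammogramSet], list[str]]:
    """Read a manifest CSV into mammogram sets; unreadable rows are skipped."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    base = manifest_path.parent
    subjects: list[MammogramSet] = []
    skipped: list[str] = []
    for _, row in df.iterrows():
        images = {}
        try:
            for view in VIEWS:
                for side in ("r", "l"):
                    rel = row[f"path_{view.lower()}_{side}"]
                    p = Path(rel)
                    images[(view, side)] = read_image(p if p.is_absolute() else base / p, bit_depth)
        except (FileNotFoundError, OSError) as exc:
            log.warning("subject %s: unreadable image (%s); row skipped", row["subject_id"], exc)
            skipped.append(str(row["subject_id"]))
            continue
        subjects.append(MammogramSet(str(row["subject_id"]), str(row["label"]), images))
    return subjects, skipped


def run_modeling_stage(
    table: FeatureTable,
    normalization: str = "znorm",
    n_train: int = 100,
    seed: int = 0,
    correlation_threshold: float = 0.96,
) -> dict:
    """Correlation filter, normalization, LASSO and blind evaluation.

    Runs each contrast (HS vs CS, HS vs MS) for which both classes have
    enough subjects; returns models and evaluation reports.
    """
    filtered = correlation_filter(table, correlation_threshold, seed)
    healthy = filtered.restrict("HS")
    if normalization == "prank":
        normalized = prank_normalize(filtered, filtered)
    elif normalization == "znorm":
        normalized = znormalize_int(filtered, healthy)
    else:
        raise ValueError("normalization must be 'prank' or 'znorm'")
    results: dict[str, dict] = {
        "n_features_after_filter": filtered.data.shape[1],
        "normalization": normalization,
        "contrasts": {},
    }
    counts = table.labels.value_counts()
    for positive in ("CS", "MS"):
        need = n_train // 2 + 1
        if counts.get("HS", 0) < need or counts.get(positive, 0) < need:
            continue
        contrast = f"HSvs{positive}"
        model = lasso_train(normalized, contrast, n_train=n_train, seed=seed)
        blind = normalized.contrast(positive)
        blind = FeatureTable(
            blind.data.loc[model.blind_ids], blind.labels.loc[model.blind_ids], normalized.normalization_state
        )
        report = evaluate_blind(model, blind, seed=seed)
        results["contrasts"][contrast] = {"model": model, "evaluation": report}
    return results


def run_pipeline(manifest_path: str | Path, config: PipelineConfig | None = None) -> dict:
    """File-based end-to-end run; writes features.csv, models and a run report."""
    config = config or PipelineConfig()
    logging.basicConfig(level=config.log_level)
    t_start = time.time()
    out_dir = Path(config.output_dir) / time.strftime("run-%Y%m%d-%H%M%S")
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.time()
    subjects, skipped = load_manifest_subjects(manifest_path, config.bit_depth)
    timings["load"] = time.time() - t0

    t0 = time.time()
    table, excluded = extract_cohort_features(
        subjects, config.registration, config.filters, config.max_registration_failure_fraction
    )
    timings["extract"] = time.time() - t0

    features_csv = out_dir / "features.csv"
    table.data.assign(label=table.labels).to_csv(features_csv)

    t0 = time.time()
    modeling: dict = {}
    try:
        stage = run_modeling_stage(
            table,
            normalization=config.normalization,
            n_train=config.n_train,
            seed=config.modeling_seed,
            correlation_threshold=config.correlation_threshold,
        )
        for contrast, res in stage["contrasts"].items():
            model_path = out_dir / f"model_{contrast}_{config.normalization}.json"
            model_path.write_text(json.dumps(res["model"].to_dict(), indent=1))
            ev = res["evaluation"]
            modeling[contrast] = {
                "accuracy": ev.accuracy,
                "accuracy_ci95": list(ev.accuracy_ci95),
                "auc": ev.auc,
                "n_test": ev.n_test,
                "n_selected": len(res["model"].selected_features),
                "model_file": model_path.name,
            }
        modeling["n_features_after_filter"] = stage["n_features_after_filter"]
    except ValueError as exc:
        log.warning("modeling stage skipped: %s", exc)
        modeling["skipped"] = str(exc)
    timings["modeling"] = time.time() - t0

    report = {
        "config_hash": config.config_hash(),
        "seeds": {
            "registration": config.registration.seed,
            "modeling": config.modeling_seed,
        },
        "n_subjects": len(subjects),
        "skipped_rows": skipped,
        "registration_excluded": excluded,
        "n_features": int(table.data.shape[1]),
        "modeling": modeling,
        "timings": timings,
        "total_seconds": time.time() - t_start,
        "features_csv": str(features_csv),
        "output_dir": str(out_dir),
    }
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
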