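"""The assembled pipeline: synthetic cohort -> detection/kinematics -> statistics.

A :class:`PipelineConfig` (usually loaded from YAML) names the stages to
run and their parameters. Three composite stages exist:

* ``histology`` — render sections, train the center detector on the
  training split, detect and evaluate on the held-out split, transfer the
  truth annotations onto matched detections, and score section metrics;
* ``casa`` — simulate labelled tracks, compute kinematics, train the
  motility SVM cascade, classify per-timepoint tracks and build the
  capacitation profile;
* ``stats`` — simulate (or read) a phenotype table and run summaries,
  heritability, correlations and the strain-by-age ANOVA.

One global seed drives everything; each stage derives its own sub-seed by
a fixed offset so stages are individually reproducible. Every run writes
a manifest with the config hash and a checksum per output file:
re-running an identical config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, casa, histology, io, pheno_stats, simulate

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "validate_inputs", "timepoint_mix"]

log = logging.getLogger("repro_pheno")

_STAGE_SEED_OFFSETS = {"histology": 11, "casa": 23, "stats": 37}
_KNOWN_STAGES = tuple(_STAGE_SEED_OFFSETS)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage label."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs.

    ``stages`` is an ordered subset of ``histology``, ``casa``,
    ``stats``. Stage parameter blocks are plain dicts mirroring the
    simulator / detector / statistics keyword arguments; absent blocks
    fall back to the package defaults.
    """

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("histology", "casa", "stats")
    histology_sim: Mapping[str, Any] = field(default_factory=dict)
    n_sections_train: int = 2
    n_sections_test: int = 2
    detector: Mapping[str, Any] = field(default_factory=dict)
    localize: Mapping[str, Any] = field(default_factory=dict)
    many_vacuole_threshold: int = 3
    track_sim: Mapping[str, Any] = field(default_factory=dict)
    timepoints_min: tuple[int, ...] = (10, 30, 60, 90, 120)
    phenotype_csv: Path | None = None
    pheno_traits: tuple[Mapping[str, Any], ...] = ()
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "out_dir" not in d:
            raise ValueError("config must name out_dir")
        d["out_dir"] = Path(d["out_dir"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "timepoints_min" in d:
            d["timepoints_min"] = tuple(int(t) for t in d["timepoints_min"])
        if d.get("phenotype_csv"):
            d["phenotype_csv"] = Path(d["phenotype_csv"])
        if "pheno_traits" in d:
            d["pheno_traits"] = tuple(dict(t) for t in d["pheno_traits"])
        return cls(**d)

    def validate(self) -> None:
        unknown = set(self.stages) - set(_KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages requested")
        if self.n_sections_train < 1 or self.n_sections_test < 1:
            raise ValueError("need at least one training and one test section")
        if "stats" in self.stages and self.phenotype_csv is not None:
            if not Path(self.phenotype_csv).exists():
                raise ValueError(f"phenotype_csv does not exist: {self.phenotype_csv}")

    def config_hash(self) -> str:
        def _default(o):
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    """What a run produced: config hash, stages, per-file checksums."""

    tool_version: str
    config_hash: str
    stages_completed: list[str]
    outputs: dict[str, str]  # relative path -> sha256
    started_utc: str
    finished_utc: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 100 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _run_histology(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    seed = _stage_seed(cfg.seed, "histology")
    base = io.histology_config_from_dict(cfg.histology_sim)
    n_total = cfg.n_sections_train + cfg.n_sections_test
    sections, truths = [], []
    for i in range(n_total):
        sec, tru = simulate.gen_histology(replace(base, seed=seed + i))
        sections.append(sec)
        truths.append(tru)
        sid = f"section_{i:02d}"
        io.write_section_image(out / f"{sid}.png", sec)
        io.write_truth_json(out / f"{sid}.truth.json", tru, sec.um_per_px)

    n_tr = cfg.n_sections_train
    clf = histology.train_center_classifier(
        sections[:n_tr], truths[:n_tr], seed=seed, **dict(cfg.detector)
    )
    loc = dict(cfg.localize)
    eval_rows = []
    all_metrics: dict[str, histology.SectionMetrics] = {}
    for i in range(n_tr, n_total):
        sid = f"section_{i:02d}"
        records = histology.detect_tubules(sections[i], clf, **loc)
        centers = [(r.center_row_px, r.center_col_px) for r in records]
        recall, fp = histology.evaluate_detection(
            truths[i], centers, um_per_px=sections[i].um_per_px
        )
        records = histology.transfer_annotations(records, truths[i], sections[i].um_per_px)
        io.write_records_json(out / f"{sid}.detections.json", records, sections[i].um_per_px)
        all_metrics[sid] = histology.compute_metrics(
            records, sections[i].um_per_px, cfg.many_vacuole_threshold
        )
        eval_rows.append({"section_id": sid, "recall": recall, "fp_per_image_pct": fp})
        log.info("histology: %s recall=%.3f fp=%.2f%%", sid, recall, fp)

    pd.DataFrame(eval_rows).to_csv(out / "detection_eval.csv", index=False)
    io.write_metrics_csv(out / "section_metrics.csv", all_metrics)
    return {}


def timepoint_mix(t_min: int, base: Mapping[str, int]) -> dict[str, int]:
    """Capacitation-like drift of the class mix over the incubation course.

    Progressive share decays while hyperactivated and nonvigorous shares
    rise, echoing the canonical time course of in-vitro capacitation.
    """
    total = sum(base.values())
    frac = min(1.0, t_min / 120.0)
    w = {
        "progressive": max(0.05, 0.50 - 0.32 * frac),
        "intermediate": 0.14,
        "hyperactivated": 0.05 + 0.18 * frac,
        "slow": 0.09 + 0.07 * frac,
        "weakly_motile": 0.09 + 0.06 * frac,
        "static": 0.13 + 0.05 * frac,
    }
    norm = sum(w.values())
    mix = {c: max(1, int(round(total * v / norm))) for c, v in w.items()}
    return mix


def _run_casa(cfg: PipelineConfig, out: Path) -> None:
    seed = _stage_seed(cfg.seed, "casa")
    base = io.track_config_from_dict(cfg.track_sim)

    # training batch with the default balanced mix
    train_cfg = replace(base, seed=seed)
    labeled = simulate.gen_tracks(train_cfg)
    train_params = [casa.compute_kinematics(t) for t, _ in labeled]
    model = casa.train_motility_svm(
        [(p, lab) for p, (_, lab) in zip(train_params, labeled)], seed=seed
    )

    all_tracks: list[casa.SpermTrack] = []
    all_params: list[casa.KinematicParams] = []
    all_motile: list[bool] = []
    all_classes: list[str | None] = []
    per_timepoint: dict[int, list[str]] = {}
    for j, t_min in enumerate(cfg.timepoints_min):
        mix = timepoint_mix(t_min, base.n_per_class)
        tp_cfg = replace(base, n_per_class=mix, seed=seed + 1000 + j)
        pairs = simulate.gen_tracks(tp_cfg)
        tracks = [
            casa.SpermTrack(
                sample_id=f"t{t_min:03d}", track_id=t.track_id,
                positions=t.positions, frame_rate_hz=t.frame_rate_hz,
            )
            for t, _ in pairs
        ]
        params = [casa.compute_kinematics(t) for t in tracks]
        motile = [casa.is_motile(p) for p in params]
        motile_params = [p for p, m in zip(params, motile) if m]
        classes_motile = casa.classify_tracks(model, motile_params)
        it = iter(classes_motile)
        classes = [next(it) if m else None for m in motile]
        per_timepoint[t_min] = [c if c is not None else "static" for c in classes]
        all_tracks.extend(tracks)
        all_params.extend(params)
        all_motile.extend(motile)
        all_classes.extend(classes)
        log.info("casa: t=%d min, %d tracks, %.0f%% motile",
                 t_min, len(tracks), 100.0 * np.mean(motile))

    io.write_tracks_csv(out / "tracks.csv", all_tracks)
    io.write_kinematics_csv(out / "kinematics.csv", all_tracks, all_params, all_motile, all_classes)
    profile = casa.timecourse_profile(per_timepoint)
    io.write_profiles_csv(out / "motility_profiles.csv", {"sim": profile})


def _run_stats(cfg: PipelineConfig, out: Path) -> None:
    seed = _stage_seed(cfg.seed, "stats")
    if cfg.phenotype_csv is not None:
        table = io.read_phenotypes_csv(cfg.phenotype_csv)
    else:
        trait_cfgs = [io.pheno_config_from_dict(d) for d in cfg.pheno_traits] or [
            simulate.PhenoSimConfig(trait_name="trait_a", va=0.7, ve=0.3),
            simulate.PhenoSimConfig(trait_name="trait_b", va=0.3, ve=0.7),
            simulate.PhenoSimConfig(trait_name="trait_c", va=0.1, ve=0.9, age_slope=0.002),
        ]
        table = simulate.gen_phenotype_panel(trait_cfgs, seed=seed)
        io.write_phenotypes_csv(out / "phenotypes.csv", table)

    problems = pheno_stats.validate_phenotype_table(table)
    if problems:
        raise PipelineError(f"phenotype table invalid: {problems}")
    traits = pheno_stats.trait_columns(table)
    io.write_summaries_csv(
        out / "strain_summaries.csv",
        {t: pheno_stats.strain_summaries(table, t) for t in traits},
    )
    io.write_heritability_csv(
        out / "heritability.csv", [pheno_stats.heritability(table, t) for t in traits]
    )
    io.write_correlations_csv(out / "correlations.csv", pheno_stats.pairwise_pearson(table, traits))
    io.write_anova_csv(out / "anova.csv", [pheno_stats.two_way_anova(table, t) for t in traits])
    log.info("stats: %d traits summarized", len(traits))


_STAGE_FUNCS = {"histology": _run_histology, "casa": _run_casa, "stats": _run_stats}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the requested stages in order and write a manifest.

    Fails fast with a stage-labelled :class:`PipelineError`; a manifest of
    the stages that did complete is still written.
    """
    config.validate()
    logging.basicConfig(level=config.log_level, format="[%(name)s] %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config.config_hash(),
        stages_completed=[],
        outputs={},
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    try:
        for stage in config.stages:
            log.info("stage %s: start", stage)
            try:
                _STAGE_FUNCS[stage](config, out)
            except Exception as exc:  # noqa: BLE001 - relabelled with the stage
                raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
            manifest.stages_completed.append(stage)
    finally:
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                manifest.outputs[str(p.relative_to(out))] = _sha256(p)
        manifest.finished_utc = datetime.now(timezone.utc).isoformat()
        manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


def validate_inputs(path: str | Path, format_tag: str) -> list[str]:
    """Schema-check an input file; returns line-numbered error strings.

    ``format_tag`` is one of ``tracks``, ``phenotypes`` or ``truth_json``.
    An empty list means the file is acceptable.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format_tag == "tracks":
        return _validate_tracks(path)
    if format_tag == "phenotypes":
        return _validate_phenotypes(path)
    if format_tag == "truth_json":
        return _validate_truth_json(path)
    raise ValueError(f"unknown format tag {format_tag!r}")


def _validate_tracks(path: Path) -> list[str]:
    errors: list[str] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - unreadable file
        raise IOError(f"cannot read {path}: {exc}") from exc
    missing = set(io.TRACK_COLUMNS) - set(df.columns)
    if missing:
        return [f"header: missing columns {sorted(missing)}"]
    for col in ("x_um", "y_um", "frame"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        for i in df.index[bad]:
            errors.append(f"row {i + 2}: non-numeric {col} value {df.loc[i, col]!r}")
    if errors:
        return errors
    for (sid, tid), grp in df.groupby(["sample_id", "track_id"], sort=False):
        frames = grp["frame"].to_numpy()
        if len(frames) and frames[0] != 0:
            errors.append(
                f"row {grp.index[0] + 2}: track ({sid}, {tid}) does not start at frame 0"
            )
        steps = np.diff(frames)
        for off in np.flatnonzero(steps <= 0):
            errors.append(
                f"row {grp.index[off + 1] + 2}: non-monotone frame column in track ({sid}, {tid})"
            )
    return errors


def _validate_phenotypes(path: Path) -> list[str]:
    df = pd.read_csv(path)
    errors = [f"header: {p}" for p in pheno_stats.validate_phenotype_table(df)]
    if any("missing required" in e or "no trait columns" in e for e in errors):
        return errors
    ages = pd.to_numeric(df["age_days"], errors="coerce")
    for i in df.index[ages.isna() | (ages <= 0)]:
        errors.append(f"row {i + 2}: invalid age_days {df.loc[i, 'age_days']!r}")
    return [e for e in errors if not e.startswith("header: age_days")]


def _validate_truth_json(path: Path) -> list[str]:
    errors = []
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        return [f"not valid JSON: {exc}"]
    if "um_per_px" not in payload or not isinstance(payload["um_per_px"], (int, float)):
        errors.append("missing or non-numeric um_per_px")
    elif payload["um_per_px"] <= 0:
        errors.append("um_per_px must be positive")
    for i, d in enumerate(payload.get("tubules", [])):
        for key in ("row", "col", "radius_um"):
            if key not in d:
                errors.append(f"tubule {i}: missing {key}")
        if d.get("radius_um", 1) <= 0:
            errors.append(f"tubule {i}: nonpositive radius_um")
        if d.get("kind", "tubule") not in ("tubule", "rete"):
            errors.append(f"tubule {i}: unknown kind {d.get('kind')!r}")
    return errors
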