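"""File formats for the pipeline.

Conventions: CSV is comma-separated UTF-8 with a mandatory header row and
an empty string for a missing cell; floats are serialized with Python's
shortest round-tripping repr (full precision). Geometric and annotation
data travel as JSON with 0-based (row, col) pixel coordinates and radii
in micrometers. Section images are PNG or TIFF with a JSON truth/detection
sidecar. Simulation configs load from YAML blocks that mirror the config
dataclasses field for field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import simulate
from .casa import KinematicParams, MotilityProfile, SpermTrack
from .histology import CorrectionSet, SectionImage, SectionMetrics, TubuleRecord, TubuleTruth

__all__ = [
    "write_section_image", "read_section_image",
    "write_truth_json", "read_truth_json",
    "write_records_json", "read_records_json",
    "write_correction_json", "read_correction_json",
    "write_metrics_csv",
    "write_tracks_csv", "read_tracks_csv",
    "write_kinematics_csv", "read_kinematics_csv",
    "write_phenotypes_csv", "read_phenotypes_csv",
    "write_summaries_csv", "write_heritability_csv",
    "write_correlations_csv", "write_anova_csv",
    "write_profiles_csv",
    "histology_config_from_dict", "track_config_from_dict", "pheno_config_from_dict",
    "load_yaml_config",
]


# ---------------------------------------------------------------------------
# sections, truth, detections
# ---------------------------------------------------------------------------


def write_section_image(path: str | Path, section: SectionImage) -> None:
    """PNG or TIFF by extension; the µm/px scale lives in the JSON sidecar."""
    Image.fromarray(section.pixels).save(Path(path))


def read_section_image(path: str | Path, um_per_px: float) -> SectionImage:
    pixels = np.asarray(Image.open(Path(path)).convert("RGB"), dtype=np.uint8)
    return SectionImage(pixels=pixels, um_per_px=um_per_px)


def _truth_to_dict(t: TubuleTruth) -> dict:
    return {
        "row": t.center_row_px,
        "col": t.center_col_px,
        "radius_um": t.radius_um,
        "kind": t.kind,
        "n_vacuoles": t.n_vacuoles,
        "flags": {
            "germ_cell_loss": t.germ_cell_loss,
            "abnormal_germ_cells": t.abnormal_germ_cells,
            "sloughing": t.sloughing,
        },
    }


def write_truth_json(path: str | Path, truths: Sequence[TubuleTruth], um_per_px: float) -> None:
    payload = {"um_per_px": um_per_px, "tubules": [_truth_to_dict(t) for t in truths]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> tuple[list[TubuleTruth], float]:
    payload = json.loads(Path(path).read_text())
    truths = []
    for d in payload["tubules"]:
        flags = d.get("flags", {})
        truths.append(
            TubuleTruth(
                center_row_px=d["row"], center_col_px=d["col"], radius_um=d["radius_um"],
                kind=d.get("kind", "tubule"), n_vacuoles=d.get("n_vacuoles", 0),
                germ_cell_loss=flags.get("germ_cell_loss", False),
                abnormal_germ_cells=flags.get("abnormal_germ_cells", False),
                sloughing=flags.get("sloughing", False),
            )
        )
    return truths, float(payload["um_per_px"])


def write_records_json(path: str | Path, records: Sequence[TubuleRecord], um_per_px: float) -> None:
    payload = {
        "um_per_px": um_per_px,
        "tubules": [dataclasses.asdict(r) for r in records],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_records_json(path: str | Path) -> tuple[list[TubuleRecord], float]:
    payload = json.loads(Path(path).read_text())
    records = [TubuleRecord(**d) for d in payload["tubules"]]
    return records, float(payload["um_per_px"])


def write_correction_json(path: str | Path, corr: CorrectionSet) -> None:
    payload = {
        "additions": [list(a) for a in corr.additions],
        "deletions": [list(d) for d in corr.deletions],
        "relabels": [[list(ref), flags] for ref, flags in corr.relabels],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_correction_json(path: str | Path) -> CorrectionSet:
    payload = json.loads(Path(path).read_text())
    return CorrectionSet(
        additions=tuple((int(r), int(c), str(k)) for r, c, k in payload.get("additions", [])),
        deletions=tuple((int(r), int(c)) for r, c in payload.get("deletions", [])),
        relabels=tuple(((int(ref[0]), int(ref[1])), dict(flags))
                       for ref, flags in payload.get("relabels", [])),
    )


def write_metrics_csv(path: str | Path, metrics: Mapping[str, SectionMetrics]) -> None:
    """One row per section, keyed by a section identifier."""
    rows = [{"section_id": sid, **dataclasses.asdict(m)} for sid, m in metrics.items()]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# tracks and kinematics
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["sample_id", "track_id", "frame", "x_um", "y_um"]


def write_tracks_csv(path: str | Path, tracks: Sequence[SpermTrack]) -> None:
    frames = []
    for t in tracks:
        n = len(t.positions)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": t.sample_id,
                    "track_id": t.track_id,
                    "frame": np.arange(n),
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_tracks_csv(path: str | Path, frame_rate_hz: float = 60.0) -> list[SpermTrack]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for (sid, tid), grp in df.groupby(["sample_id", "track_id"], sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            SpermTrack(
                sample_id=str(sid),
                track_id=str(tid),
                positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                frame_rate_hz=frame_rate_hz,
            )
        )
    return tracks


def write_kinematics_csv(
    path: str | Path,
    tracks: Sequence[SpermTrack],
    params: Sequence[KinematicParams],
    motile: Sequence[bool],
    classes: Sequence[str | None] | None = None,
) -> None:
    """One row per track: seven CASA parameters, the motile flag, the class."""
    rows = []
    for i, (t, p, m) in enumerate(zip(tracks, params, motile)):
        rows.append(
            {
                "sample_id": t.sample_id,
                "track_id": t.track_id,
                "vap_um_s": p.vap_um_s, "vsl_um_s": p.vsl_um_s, "vcl_um_s": p.vcl_um_s,
                "alh_um": p.alh_um, "bcf_hz": p.bcf_hz,
                "str_frac": p.str_frac, "lin_frac": p.lin_frac,
                "duration_s": p.duration_s,
                "motile": bool(m),
                "motility_class": (classes[i] if classes is not None else None) or "",
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_kinematics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), keep_default_na=False, na_values=[""], float_precision="round_trip")
    return df


def write_profiles_csv(path: str | Path, profiles: Mapping[str, MotilityProfile]) -> None:
    """One row per sample x time point, percentages for the five patterns."""
    rows = []
    for sid, prof in profiles.items():
        for i, t in enumerate(prof.time_points_min):
            row = {"sample_id": sid, "time_min": t}
            row.update({f"pct_{c}": prof.class_pct[i][c] for c in prof.class_pct[i]})
            row["percent_motile"] = prof.percent_motile[i]
            row["percent_vigorous"] = prof.percent_vigorous[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# phenotypes and statistics outputs
# ---------------------------------------------------------------------------


def write_phenotypes_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False, na_rep="")


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    for col in df.columns:
        if col not in ("animal_id", "strain"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_summaries_csv(path: str | Path, summaries: Mapping[str, Sequence]) -> None:
    """``summaries`` maps trait name -> list of StrainTraitSummary."""
    rows = []
    for trait, per_strain in summaries.items():
        for s in per_strain:
            rows.append({"trait": trait, **dataclasses.asdict(s)})
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_heritability_csv(path: str | Path, results: Sequence) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(Path(path), index=False)


def write_correlations_csv(path: str | Path, corr) -> None:
    corr.to_long().to_csv(Path(path), index=False)


def write_anova_csv(path: str | Path, results: Sequence) -> None:
    frames = []
    for r in results:
        t = r.table.reset_index()
        t.insert(0, "trait", r.trait)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------


def histology_config_from_dict(d: Mapping[str, Any]) -> simulate.HistologySimConfig:
    d = dict(d)
    if "palette" in d and not isinstance(d["palette"], simulate.Palette):
        d["palette"] = simulate.Palette(**{k: tuple(v) for k, v in d["palette"].items()})
    if "vacuole_count_law" in d:
        d["vacuole_count_law"] = {int(k): float(v) for k, v in d["vacuole_count_law"].items()}
    return simulate.HistologySimConfig(**d)


def track_config_from_dict(d: Mapping[str, Any]) -> simulate.TrackSimConfig:
    d = dict(d)
    if "class_params" in d:
        d["class_params"] = {
            cls: (
                ck if isinstance(ck, simulate.ClassKinematics)
                else simulate.ClassKinematics(
                    speed_um_s=tuple(ck["speed_um_s"]),
                    amp_um=tuple(ck["amp_um"]),
                    freq_hz=tuple(ck["freq_hz"]),
                    heading_diffusion=tuple(ck["heading_diffusion"]),
                    jitter_sd_um=float(ck["jitter_sd_um"]),
                )
            )
            for cls, ck in d["class_params"].items()
        }
    if "n_per_class" in d:
        d["n_per_class"] = {str(k): int(v) for k, v in d["n_per_class"].items()}
    return simulate.TrackSimConfig(**d)


def pheno_config_from_dict(d: Mapping[str, Any]) -> simulate.PhenoSimConfig:
    d = dict(d)
    if "age_range_days" in d:
        d["age_range_days"] = tuple(d["age_range_days"])
    return simulate.PhenoSimConfig(**d)


def load_yaml_config(path: str | Path) -> dict:
    with open(Path(path), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
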