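"""Synthetic cohorts with known ground truth.

Three generators stand in for the raw material of a strain survey of male
reproduction:

``gen_histology``
    renders a PAS/hematoxylin-like transverse testis section — purple
    seminiferous epithelium rings around pale lumens on a pale-pink
    interstitial background — with exactly known tubule centers, radii and
    abnormality labels (vacuoles, germ-cell loss, abnormal germ cells,
    sloughing).
``gen_tracks``
    produces 90-frame sperm head trajectories at 60 Hz for five motility
    classes (progressive, intermediate, hyperactivated, slow, weakly
    motile) whose kinematic ranges are separable by construction.
``gen_phenotypes``
    draws a strain-structured phenotype table from the variance-component
    model ``y_ij = mu + s_i + beta_age * age_ij + e_ij`` with known
    between-strain variance ``va`` and within-strain variance ``ve``.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk_coords
from skimage.draw import ellipse as _ellipse_coords

from .casa import SpermTrack
from .histology import SectionImage, TubuleTruth

__all__ = [
    "HistologySimConfig",
    "Palette",
    "TrackSimConfig",
    "ClassKinematics",
    "PhenoSimConfig",
    "InfeasibleConfigError",
    "MOTILITY_CLASSES",
    "gen_histology",
    "gen_tracks",
    "gen_phenotypes",
    "gen_phenotype_panel",
]


class InfeasibleConfigError(RuntimeError):
    """Raised when tubule placement cannot satisfy the packing constraints."""


# ---------------------------------------------------------------------------
# histology sections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Palette:
    """Four-color stain model: RGB triples on the 0-255 scale.

    The defaults imitate periodic acid-Schiff + hematoxylin: purple
    epithelium, near-white lumen, pale-pink interstitium, white vacuoles.
    """

    epithelium: tuple[int, int, int] = (150, 90, 160)
    lumen: tuple[int, int, int] = (245, 240, 245)
    interstitium: tuple[int, int, int] = (235, 200, 210)
    vacuole: tuple[int, int, int] = (252, 252, 252)
    background: tuple[int, int, int] = (255, 255, 255)


def _default_vacuole_law() -> dict[int, float]:
    # geometric-ish tail over 1..10 vacuoles per affected tubule
    raw = {k: 0.55**k for k in range(1, 11)}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass(frozen=True)
class HistologySimConfig:
    """Geometry, abnormality rates and color model for one synthetic section.

    Radii follow a lognormal law with the given mean/sd in micrometers.
    ``min_gap_um`` is the minimum interstitial gap between tubule circles.
    """

    canvas_height_px: int = 640
    canvas_width_px: int = 640
    um_per_px: float = 1.0
    n_tubules: int = 40
    radius_mean_um: float = 28.0
    radius_sd_um: float = 4.0
    min_gap_um: float = 6.0
    p_vacuole_tubule: float = 0.15
    vacuole_count_law: Mapping[int, float] = field(default_factory=_default_vacuole_law)
    many_vacuole_threshold: int = 3
    p_germ_cell_loss: float = 0.05
    p_abnormal_germ_cells: float = 0.05
    p_sloughing: float = 0.03
    include_rete: bool = False
    rete_radius_factor: float = 1.6
    palette: Palette = field(default_factory=Palette)
    noise_sd: float = 6.0
    max_placement_attempts: int = 20000
    seed: int = 0

    def validate(self) -> None:
        if self.canvas_height_px <= 0 or self.canvas_width_px <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.n_tubules <= 0:
            raise ValueError("n_tubules must be positive")
        if self.radius_mean_um <= 0 or self.radius_sd_um <= 0:
            raise ValueError("radius law parameters must be positive")
        if self.min_gap_um < 0:
            raise ValueError("min_gap_um must be nonnegative")
        for name in ("p_vacuole_tubule", "p_germ_cell_loss", "p_abnormal_germ_cells", "p_sloughing"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        law_total = sum(self.vacuole_count_law.values())
        if not math.isclose(law_total, 1.0, abs_tol=1e-8):
            raise ValueError("vacuole_count_law probabilities must sum to 1")
        if any(k < 1 for k in self.vacuole_count_law):
            raise ValueError("vacuole counts start at 1")
        if self.many_vacuole_threshold < 1:
            raise ValueError("many_vacuole_threshold must be positive")
        min_side_um = min(self.canvas_height_px, self.canvas_width_px) * self.um_per_px
        if 2.0 * self.radius_mean_um + self.min_gap_um >= min_side_um:
            raise ValueError("mean tubule diameter plus gap does not fit in the canvas")


def _lognormal_radii(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _place_circles(
    rng: np.random.Generator, cfg: HistologySimConfig, radii_px: np.ndarray
) -> list[tuple[float, float]]:
    """Dart-throwing placement inside an elliptical section mask.

    Circles (plus the interstitial gap) never overlap; placement failure
    after the attempt budget raises :class:`InfeasibleConfigError`.
    """
    h, w = cfg.canvas_height_px, cfg.canvas_width_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    semi_b, semi_a = 0.47 * h, 0.47 * w
    gap_px = cfg.min_gap_um / cfg.um_per_px

    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    attempts = 0
    # place large circles first: easier packing
    order = np.argsort(radii_px)[::-1]
    for idx in order:
        r = float(radii_px[idx])
        while True:
            attempts += 1
            if attempts > cfg.max_placement_attempts:
                raise InfeasibleConfigError(
                    f"could not place {cfg.n_tubules} tubules after "
                    f"{cfg.max_placement_attempts} attempts; reduce n_tubules or radii"
                )
            row = rng.uniform(0, h - 1)
            col = rng.uniform(0, w - 1)
            eb, ea = semi_b - r - 1, semi_a - r - 1
            if eb <= 0 or ea <= 0:
                raise InfeasibleConfigError("tubule radius exceeds the section mask")
            if ((row - cy) / eb) ** 2 + ((col - cx) / ea) ** 2 > 1.0:
                continue
            ok = True
            for (pr, pc), pr_r in zip(centers, placed_r):
                if math.hypot(row - pr, col - pc) < r + pr_r + gap_px:
                    ok = False
                    break
            if ok:
                centers.append((row, col))
                placed_r.append(r)
                break
    # undo the size ordering so center i corresponds to radius i
    out: list[tuple[float, float]] = [(0.0, 0.0)] * len(radii_px)
    for slot, idx in enumerate(order):
        out[idx] = centers[slot]
    return out


def _paint_disk(img: np.ndarray, row: float, col: float, radius: float, color: Sequence[int]) -> None:
    rr, cc = _disk_coords((row, col), radius, shape=img.shape[:2])
    img[rr, cc] = color


def _render_tubule(
    img: np.ndarray,
    rng: np.random.Generator,
    truth: TubuleTruth,
    radius_px: float,
    pal: Palette,
) -> None:
    row, col = truth.center_row_px, truth.center_col_px
    lumen_frac = 0.85 if truth.germ_cell_loss else 0.55
    _paint_disk(img, row, col, radius_px, pal.epithelium)
    _paint_disk(img, row, col, lumen_frac * radius_px, pal.lumen)

    if truth.sloughing:
        # shed earlier-stage germ cells sitting inside the lumen
        ang = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(0.0, 0.3) * radius_px
        _paint_disk(img, row + d * math.sin(ang), col + d * math.cos(ang),
                    0.18 * radius_px, pal.epithelium)

    if truth.abnormal_germ_cells:
        # condensed dark nuclei within the epithelium ring
        dark = tuple(max(0, c - 70) for c in pal.epithelium)
        for _ in range(rng.integers(2, 5)):
            ang = rng.uniform(0, 2 * math.pi)
            d = rng.uniform(min(lumen_frac + 0.05, 0.88), 0.94) * radius_px
            _paint_disk(img, row + d * math.sin(ang), col + d * math.cos(ang),
                        max(1.5, 0.04 * radius_px), dark)

    vac_lo = min(lumen_frac + 0.05, 0.86)
    for _ in range(truth.n_vacuoles):
        ang = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(vac_lo, 0.9) * radius_px
        vr = rng.uniform(0.05, 0.11) * radius_px
        rr, cc = _ellipse_coords(
            row + d * math.sin(ang), col + d * math.cos(ang),
            max(1.2, vr), max(1.2, vr * rng.uniform(0.6, 1.0)),
            shape=img.shape[:2], rotation=rng.uniform(0, math.pi),
        )
        img[rr, cc] = pal.vacuole


def _render_rete(img: np.ndarray, rng: np.random.Generator, row: float, col: float,
                 radius_px: float, pal: Palette) -> None:
    # anastomosing channel network: pale region criss-crossed by epithelial strands
    _paint_disk(img, row, col, radius_px, pal.epithelium)
    _paint_disk(img, row, col, 0.92 * radius_px, pal.lumen)
    for _ in range(8):
        ang = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(0.0, 0.75) * radius_px
        rr, cc = _ellipse_coords(
            row + d * math.sin(ang), col + d * math.cos(ang),
            0.30 * radius_px, 0.06 * radius_px,
            shape=img.shape[:2], rotation=rng.uniform(0, math.pi),
        )
        img[rr, cc] = pal.epithelium


def gen_histology(cfg: HistologySimConfig) -> tuple[SectionImage, list[TubuleTruth]]:
    """Render one synthetic transverse section and its ground-truth labels.

    Returns the RGB section and one :class:`TubuleTruth` per object
    (tubules, plus one rete region when ``cfg.include_rete``), with exact
    0-based pixel centers and radii in micrometers.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.canvas_height_px, cfg.canvas_width_px
    pal = cfg.palette

    radii_um = _lognormal_radii(rng, cfg.radius_mean_um, cfg.radius_sd_um, cfg.n_tubules)
    radii_px = radii_um / cfg.um_per_px
    if cfg.include_rete:
        rete_um = cfg.rete_radius_factor * cfg.radius_mean_um
        radii_um = np.concatenate([[rete_um], radii_um])
        radii_px = np.concatenate([[rete_um / cfg.um_per_px], radii_px])
    centers = _place_circles(rng, cfg, radii_px)

    vac_counts = np.array(sorted(cfg.vacuole_count_law))
    vac_probs = np.array([cfg.vacuole_count_law[k] for k in vac_counts], dtype=float)

    truths: list[TubuleTruth] = []
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = pal.background
    # elliptical interstitial section mask
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = ((yy - cy) / (0.47 * h)) ** 2 + ((xx - cx) / (0.47 * w)) ** 2 <= 1.0
    img[mask] = pal.interstitium

    for i, ((row, col), r_px, r_um) in enumerate(zip(centers, radii_px, radii_um)):
        if cfg.include_rete and i == 0:
            truth = TubuleTruth(center_row_px=row, center_col_px=col,
                                radius_um=float(r_um), kind="rete")
            _render_rete(img, rng, row, col, float(r_px), pal)
        else:
            has_vac = rng.random() < cfg.p_vacuole_tubule
            n_vac = int(rng.choice(vac_counts, p=vac_probs)) if has_vac else 0
            truth = TubuleTruth(
                center_row_px=row,
                center_col_px=col,
                radius_um=float(r_um),
                kind="tubule",
                n_vacuoles=n_vac,
                germ_cell_loss=bool(rng.random() < cfg.p_germ_cell_loss),
                abnormal_germ_cells=bool(rng.random() < cfg.p_abnormal_germ_cells),
                sloughing=bool(rng.random() < cfg.p_sloughing),
            )
            _render_tubule(img, rng, truth, float(r_px), pal)
        truths.append(truth)

    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SectionImage(pixels=pixels, um_per_px=cfg.um_per_px), truths


# ---------------------------------------------------------------------------
# sperm tracks
# ---------------------------------------------------------------------------

MOTILITY_CLASSES = ("progressive", "intermediate", "hyperactivated", "slow", "weakly_motile")


@dataclass(frozen=True)
class ClassKinematics:
    """Per-class generator ranges: uniform draws within each interval.

    speed is forward drift along the heading (µm/s); lateral oscillation is
    ``amp * sin(2*pi*freq*t)`` perpendicular to the heading; the heading
    itself diffuses with standard deviation ``heading_diffusion*sqrt(dt)``
    per step (rad); jitter is iid positional noise per frame (µm).
    """

    speed_um_s: tuple[float, float]
    amp_um: tuple[float, float]
    freq_hz: tuple[float, float]
    heading_diffusion: tuple[float, float]
    jitter_sd_um: float


def _default_class_params() -> dict[str, ClassKinematics]:
    return {
        "progressive": ClassKinematics((110.0, 180.0), (1.0, 3.0), (3.0, 7.0), (0.0, 0.3), 0.15),
        "intermediate": ClassKinematics((50.0, 90.0), (3.0, 6.0), (4.0, 7.0), (0.2, 0.8), 0.15),
        "hyperactivated": ClassKinematics((20.0, 50.0), (10.0, 18.0), (3.0, 6.0), (0.8, 2.5), 0.2),
        "slow": ClassKinematics((8.0, 18.0), (0.4, 1.5), (2.0, 4.0), (0.2, 0.8), 0.1),
        "weakly_motile": ClassKinematics((0.8, 2.5), (0.8, 2.0), (5.0, 9.0), (1.5, 4.0), 0.15),
        # immotile sperm: centroid jitter only; gated out before classification
        "static": ClassKinematics((0.0, 0.2), (0.0, 0.05), (1.0, 2.0), (0.5, 2.0), 0.08),
    }


@dataclass(frozen=True)
class TrackSimConfig:
    """Sampling scheme and class mix for synthetic sperm head tracks."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c: 40 for c in MOTILITY_CLASSES}
    )
    frame_rate_hz: float = 60.0
    n_frames: int = 90
    class_params: Mapping[str, ClassKinematics] = field(default_factory=_default_class_params)
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if not self.n_per_class or all(n == 0 for n in self.n_per_class.values()):
            raise ValueError("empty class mix")
        for cls, n in self.n_per_class.items():
            if n < 0:
                raise ValueError("class counts must be nonnegative")
            if n > 0 and cls not in self.class_params:
                raise ValueError(f"no kinematic ranges configured for class {cls!r}")


def _simulate_track(rng: np.random.Generator, cfg: TrackSimConfig, ck: ClassKinematics) -> np.ndarray:
    dt = 1.0 / cfg.frame_rate_hz
    n = cfg.n_frames
    speed = rng.uniform(*ck.speed_um_s)
    amp = rng.uniform(*ck.amp_um)
    freq = rng.uniform(*ck.freq_hz)
    hdiff = rng.uniform(*ck.heading_diffusion)
    phase = rng.uniform(0, 2 * math.pi)
    theta0 = rng.uniform(0, 2 * math.pi)

    t = np.arange(n) * dt
    theta = theta0 + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, hdiff * math.sqrt(dt), n - 1))])
    # base point advances along the (diffusing) heading
    step = speed * dt
    base = np.zeros((n, 2))
    base[1:, 0] = np.cumsum(step * np.cos(theta[:-1]))
    base[1:, 1] = np.cumsum(step * np.sin(theta[:-1]))
    lateral = amp * np.sin(2 * math.pi * freq * t + phase)
    normal = np.stack([-np.sin(theta), np.cos(theta)], axis=1)
    pos = base + lateral[:, None] * normal
    pos += rng.normal(0.0, ck.jitter_sd_um, size=pos.shape)
    return pos


def gen_tracks(cfg: TrackSimConfig) -> list[tuple[SpermTrack, str]]:
    """Simulate labelled sperm head tracks, one (track, class) pair per sperm."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out: list[tuple[SpermTrack, str]] = []
    tid = 0
    ordered = [c for c in MOTILITY_CLASSES if c in cfg.n_per_class]
    ordered += sorted(c for c in cfg.n_per_class if c not in MOTILITY_CLASSES)
    for cls in ordered:
        n = int(cfg.n_per_class.get(cls, 0))
        for _ in range(n):
            pos = _simulate_track(rng, cfg, cfg.class_params[cls])
            track = SpermTrack(
                sample_id="sim",
                track_id=f"t{tid:04d}",
                positions=pos,
                frame_rate_hz=cfg.frame_rate_hz,
            )
            out.append((track, cls))
            tid += 1
    return out


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenoSimConfig:
    """Variance-component model for one trait across an inbred strain panel.

    ``va`` is the between-strain (genetic) variance, ``ve`` the
    within-strain (residual) variance; broad-sense heritability of the
    simulated trait is ``va / (va + ve)`` before the age covariate. Ages
    are uniform integers on ``age_range_days`` (default spans the adult
    survey window, 70-461 days).
    """

    n_strains: int = 8
    n_per_strain: int = 25
    grand_mean: float = 0.0
    va: float = 0.7
    ve: float = 0.3
    age_slope: float = 0.0
    age_range_days: tuple[int, int] = (70, 461)
    missing_rate: float = 0.0
    trait_name: str = "trait"
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains (heritability undefined otherwise)")
        if self.n_per_strain < 1:
            raise ValueError("n_per_strain must be positive")
        if self.va < 0 or self.ve < 0 or self.va + self.ve <= 0:
            raise ValueError("need va, ve >= 0 with va + ve > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.age_range_days
        if lo <= 0 or hi < lo:
            raise ValueError("age_range_days must be a positive interval")


def _pheno_design(rng: np.random.Generator, cfg: PhenoSimConfig) -> pd.DataFrame:
    strains = [f"S{i + 1:02d}" for i in range(cfg.n_strains)]
    rows = []
    for s in strains:
        for j in range(cfg.n_per_strain):
            rows.append((f"{s}_a{j + 1:03d}", s))
    df = pd.DataFrame(rows, columns=["animal_id", "strain"])
    lo, hi = cfg.age_range_days
    df["age_days"] = rng.integers(lo, hi + 1, size=len(df))
    return df


def _pheno_values(rng: np.random.Generator, cfg: PhenoSimConfig, design: pd.DataFrame) -> pd.Series:
    strains = design["strain"].unique()
    effects = dict(zip(strains, rng.normal(0.0, math.sqrt(cfg.va), len(strains))))
    resid = rng.normal(0.0, math.sqrt(cfg.ve), len(design))
    y = (
        cfg.grand_mean
        + design["strain"].map(effects).to_numpy()
        + cfg.age_slope * design["age_days"].to_numpy()
        + resid
    )
    vals = pd.Series(y, index=design.index, name=cfg.trait_name)
    if cfg.missing_rate > 0:
        vals[rng.random(len(vals)) < cfg.missing_rate] = np.nan
    return vals


def gen_phenotypes(cfg: PhenoSimConfig) -> pd.DataFrame:
    """Simulate a one-trait phenotype table (animal_id, strain, age_days, trait)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    design = _pheno_design(rng, cfg)
    design[cfg.trait_name] = _pheno_values(rng, cfg, design)
    return design


def gen_phenotype_panel(cfgs: Sequence[PhenoSimConfig], seed: int | None = None) -> pd.DataFrame:
    """Simulate several traits on one shared animal panel.

    The first config fixes the panel design (strains, counts, ages); each
    trait draws its own strain effects and residuals. Trait names must be
    unique. ``seed`` overrides the first config's seed for the design.
    """
    if not cfgs:
        raise ValueError("need at least one trait config")
    names = [c.trait_name for c in cfgs]
    if len(set(names)) != len(names):
        raise ValueError("trait names must be unique")
    base = cfgs[0] if seed is None else replace(cfgs[0], seed=seed)
    base.validate()
    rng = np.random.default_rng(base.seed)
    design = _pheno_design(rng, base)
    for i, cfg in enumerate(cfgs):
        cfg.validate()
        trait_rng = np.random.default_rng(np.random.SeedSequence([base.seed, 1000 + i]))
        design[cfg.trait_name] = _pheno_values(trait_rng, cfg, design)
    return design
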