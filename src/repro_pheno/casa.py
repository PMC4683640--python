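"""Computer-assisted sperm analysis (CASA) on head-position tracks.

Tracks are short head trajectories (by convention 90 frames at 60 Hz,
1.5 s). Each track is summarized by seven kinematic parameters:

* VCL — curvilinear velocity, point-to-point path length over time, on
  the raw track (µm/s);
* VSL — straight-line velocity, net displacement over time (µm/s);
* VAP — average-path velocity, the path length of a smoothed ("average")
  path over time (µm/s);
* ALH — amplitude of lateral head displacement, here twice the mean
  unsigned deviation of the raw track from the average path (µm);
* BCF — beat-cross frequency, the rate at which the raw track crosses
  the average path (Hz);
* STR — straightness, VSL/VAP; LIN — linearity, VSL/VCL (fractions).

A configurable gate separates motile from static tracks (deliberately
permissive: slow sperm count as motile). Motile tracks are classified
into five patterns — progressive, intermediate, hyperactivated, slow,
weakly motile — by a cascade of binary RBF-SVMs on the standardized
seven-parameter vector, and per-timepoint classifications are folded into
capacitation time-course profiles. "Vigorous" motility is the sum of the
progressive, intermediate and hyperactivated percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SpermTrack",
    "KinematicParams",
    "MotileGateConfig",
    "MotilityModel",
    "MotilityProfile",
    "MOTILE_CLASSES",
    "VIGOROUS_CLASSES",
    "average_path",
    "compute_kinematics",
    "is_motile",
    "train_motility_svm",
    "classify_tracks",
    "timecourse_profile",
]

MOTILE_CLASSES = ("progressive", "intermediate", "hyperactivated", "slow", "weakly_motile")
VIGOROUS_CLASSES = ("progressive", "intermediate", "hyperactivated")


@dataclass(frozen=True)
class SpermTrack:
    """One sperm head trajectory in micrometers."""

    sample_id: str
    track_id: str
    positions: np.ndarray  # n_frames x 2, (x, y) in µm
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ValueError("positions must be an (n>=2) x 2 array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return (len(self.positions) - 1) / self.frame_rate_hz


@dataclass(frozen=True)
class KinematicParams:
    """The seven CASA summary statistics of one track.

    Ratios are stored as fractions in [0, 1]; ``duration_s`` is carried
    along so net displacement (VSL x duration) can be recovered.
    """

    vap_um_s: float
    vsl_um_s: float
    vcl_um_s: float
    alh_um: float
    bcf_hz: float
    str_frac: float
    lin_frac: float
    duration_s: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.vap_um_s, self.vsl_um_s, self.vcl_um_s, self.alh_um,
             self.bcf_hz, self.str_frac, self.lin_frac],
            dtype=np.float64,
        )


FEATURE_NAMES = ("vap_um_s", "vsl_um_s", "vcl_um_s", "alh_um", "bcf_hz", "str_frac", "lin_frac")


def average_path(track: SpermTrack, window: int = 5) -> np.ndarray:
    """Centered moving average of the positions; the CASA "average path".

    Windows shrink symmetrically near the ends so the smoothed path has
    the same length as the raw one; ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    pos = track.positions
    n = len(pos)
    half = window // 2
    out = np.empty_like(pos)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = pos[i - k: i + k + 1].mean(axis=0)
    return out


def _path_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _signed_deviation(pos: np.ndarray, avg: np.ndarray) -> np.ndarray:
    """Signed perpendicular deviation of raw points from the average path.

    The sign is taken against the local tangent of the average path (z
    component of the tangent x offset cross product).
    """
    tangent = np.gradient(avg, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    norms[norms == 0] = 1.0
    tangent = tangent / norms[:, None]
    offset = pos - avg
    return tangent[:, 0] * offset[:, 1] - tangent[:, 1] * offset[:, 0]


def compute_kinematics(track: SpermTrack, window: int = 5) -> KinematicParams:
    """All seven CASA parameters of one track.

    Velocities use the track duration ``(n_frames - 1) / frame_rate``; ALH
    is twice the mean unsigned deviation from the average path; BCF counts
    sign changes of the signed deviation per second. Ratios with a zero
    denominator are reported as 0.
    """
    pos = track.positions
    duration = track.duration_s
    avg = average_path(track, window)

    vcl = _path_length(pos) / duration
    vsl = float(np.linalg.norm(pos[-1] - pos[0])) / duration
    vap = _path_length(avg) / duration

    dev = _signed_deviation(pos, avg)
    alh = 2.0 * float(np.mean(np.abs(dev)))
    signs = np.sign(dev)
    signs = signs[signs != 0]
    bcf = float(np.count_nonzero(np.diff(signs))) / duration

    return KinematicParams(
        vap_um_s=vap,
        vsl_um_s=vsl,
        vcl_um_s=vcl,
        alh_um=alh,
        bcf_hz=bcf,
        str_frac=vsl / vap if vap > 0 else 0.0,
        lin_frac=vsl / vcl if vcl > 0 else 0.0,
        duration_s=duration,
    )


@dataclass(frozen=True)
class MotileGateConfig:
    """Motile/static gate: motile iff VCL or net displacement clears a bound.

    Kept permissive on purpose — slow sperm are treated as motile; static
    means essentially no movement.
    """

    vcl_min_um_s: float = 25.0
    disp_min_um: float = 4.0


def is_motile(params: KinematicParams, gate_cfg: MotileGateConfig | None = None) -> bool:
    """Gate a track as motile (True) or static (False)."""
    gate = gate_cfg or MotileGateConfig()
    net_disp = params.vsl_um_s * params.duration_s
    return params.vcl_um_s >= gate.vcl_min_um_s or net_disp >= gate.disp_min_um


# ---------------------------------------------------------------------------
# the SVM cascade
# ---------------------------------------------------------------------------


def _binary_svm(seed: int):
    return make_pipeline(
        StandardScaler(), SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed)
    )


@dataclass(frozen=True)
class MotilityModel:
    """A cascade of binary SVMs over the five motile patterns.

    Stage 1 splits vigorous (progressive / intermediate / hyperactivated)
    from nonvigorous (slow / weakly motile); stage 2 resolves
    hyperactivated then progressive-vs-intermediate within the vigorous
    branch; stage 3 resolves slow vs weakly motile. Static tracks must be
    gated out before classification.
    """

    vigorous_svm: object
    hyper_svm: object
    prog_svm: object
    slow_svm: object
    seed: int

    def classify(self, params: Sequence[KinematicParams]) -> list[str]:
        if not params:
            return []
        x = np.stack([p.as_vector() for p in params])
        out = np.empty(len(x), dtype=object)
        vig = self.vigorous_svm.predict(x).astype(bool)
        if vig.any():
            xv = x[vig]
            hyper = self.hyper_svm.predict(xv).astype(bool)
            labels_v = np.empty(len(xv), dtype=object)
            labels_v[hyper] = "hyperactivated"
            if (~hyper).any():
                prog = self.prog_svm.predict(xv[~hyper]).astype(bool)
                labels_v[~hyper] = np.where(prog, "progressive", "intermediate")
            out[vig] = labels_v
        if (~vig).any():
            slow = self.slow_svm.predict(x[~vig]).astype(bool)
            out[~vig] = np.where(slow, "slow", "weakly_motile")
        return list(out)


def train_motility_svm(
    labeled: Sequence[tuple[KinematicParams, str]], seed: int = 0
) -> MotilityModel:
    """Fit the five-class cascade from labelled kinematic vectors.

    Every one of the five motile classes must be represented in the
    training set.
    """
    if not labeled:
        raise ValueError("empty training set")
    classes = {lab for _, lab in labeled}
    missing = set(MOTILE_CLASSES) - classes
    if missing:
        raise ValueError(f"training set missing classes: {sorted(missing)}")
    unknown = classes - set(MOTILE_CLASSES)
    if unknown:
        raise ValueError(f"unknown motility classes: {sorted(unknown)}")

    x = np.stack([p.as_vector() for p, _ in labeled])
    y = np.array([lab for _, lab in labeled])

    vig_mask = np.isin(y, VIGOROUS_CLASSES)
    vigorous_svm = _binary_svm(seed).fit(x, vig_mask.astype(int))

    xv, yv = x[vig_mask], y[vig_mask]
    hyper_svm = _binary_svm(seed).fit(xv, (yv == "hyperactivated").astype(int))
    not_h = yv != "hyperactivated"
    prog_svm = _binary_svm(seed).fit(xv[not_h], (yv[not_h] == "progressive").astype(int))

    xn, yn = x[~vig_mask], y[~vig_mask]
    slow_svm = _binary_svm(seed).fit(xn, (yn == "slow").astype(int))

    return MotilityModel(
        vigorous_svm=vigorous_svm, hyper_svm=hyper_svm,
        prog_svm=prog_svm, slow_svm=slow_svm, seed=seed,
    )


def classify_tracks(model: MotilityModel, params: Sequence[KinematicParams]) -> list[str]:
    """One of the five motile classes per track (static gated out upstream)."""
    if model is None:
        raise ValueError("untrained model")
    return model.classify(params)


# ---------------------------------------------------------------------------
# time-course profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotilityProfile:
    """Percentages of the five motility patterns over a capacitation course.

    ``class_pct[t][c]`` is the share of *motile* sperm in class ``c`` at
    time point ``t`` (percent; the five sum to 100); ``percent_motile`` is
    over all tracks including static; ``percent_vigorous`` sums the
    progressive, intermediate and hyperactivated shares.
    """

    time_points_min: tuple[int, ...]
    class_pct: tuple[Mapping[str, float], ...]
    percent_motile: tuple[float, ...]
    percent_vigorous: tuple[float, ...]


def timecourse_profile(
    classified: Mapping[int, Sequence[str]] | Sequence[tuple[int, Sequence[str]]],
) -> MotilityProfile:
    """Fold per-timepoint track classes into a motility profile.

    ``classified`` maps incubation time (minutes) to the per-track labels
    at that time point — the five motile classes plus ``"static"`` for
    gated-out tracks. Class percentages are taken over motile tracks only;
    a time point with no tracks, or none motile, is an error.
    """
    items = sorted(classified.items()) if isinstance(classified, Mapping) else sorted(classified)
    if not items:
        raise ValueError("no time points")
    times: list[int] = []
    pcts: list[dict[str, float]] = []
    motile_pct: list[float] = []
    vigorous_pct: list[float] = []
    for t, labels in items:
        labels = list(labels)
        if not labels:
            raise ValueError(f"time point {t} has no tracks")
        unknown = set(labels) - set(MOTILE_CLASSES) - {"static"}
        if unknown:
            raise ValueError(f"unknown labels at t={t}: {sorted(unknown)}")
        motile = [lab for lab in labels if lab != "static"]
        if not motile:
            raise ValueError(f"time point {t} has no motile tracks")
        n_mot = len(motile)
        pct = {c: 100.0 * motile.count(c) / n_mot for c in MOTILE_CLASSES}
        times.append(int(t))
        pcts.append(pct)
        motile_pct.append(100.0 * n_mot / len(labels))
        vigorous_pct.append(sum(pct[c] for c in VIGOROUS_CLASSES))
    return MotilityProfile(
        time_points_min=tuple(times),
        class_pct=tuple(pcts),
        percent_motile=tuple(motile_pct),
        percent_vigorous=tuple(vigorous_pct),
    )
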