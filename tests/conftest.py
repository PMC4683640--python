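from dataclasses import replace

import pytest

from repro_pheno import casa, histology, simulate


@pytest.fixture(scope="session")
def default_track_pairs():
    """Labelled tracks at the default generator settings."""
    return simulate.gen_tracks(simulate.TrackSimConfig(seed=7))


@pytest.fixture(scope="session")
def kin_by_class(default_track_pairs):
    out: dict[str, list] = {}
    for track, label in default_track_pairs:
        out.setdefault(label, []).append(casa.compute_kinematics(track))
    return out


@pytest.fixture(scope="session")
def small_section():
    """A compact section for feature/metric unit tests."""
    cfg = simulate.HistologySimConfig(
        canvas_height_px=320, canvas_width_px=320, n_tubules=8, seed=42
    )
    return simulate.gen_histology(cfg)


@pytest.fixture(scope="session")
def trained_detector_setup():
    """Two training sections, one held-out section, and a fitted classifier."""
    cfg = simulate.HistologySimConfig(canvas_height_px=384, canvas_width_px=384, n_tubules=12)
    sections, truths = [], []
    for i in range(3):
        s, t = simulate.gen_histology(replace(cfg, seed=200 + i))
        sections.append(s)
        truths.append(t)
    clf = histology.train_center_classifier(
        sections[:2], truths[:2], seed=0, n_estimators=100
    )
    return sections, truths, clf
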