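"""The generators are deterministic, geometrically valid, and land in the
configured statistical regimes."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import binom

from repro_pheno import casa, simulate


class TestHistologyGenerator:
    def test_single_tubule_no_vacuoles(self):
        cfg = simulate.HistologySimConfig(n_tubules=1, p_vacuole_tubule=0.0, seed=3)
        section, truth = simulate.gen_histology(cfg)
        assert len(truth) == 1
        assert truth[0].n_vacuoles == 0
        assert truth[0].kind == "tubule"
        assert section.pixels.shape == (640, 640, 3)

    def test_same_seed_bit_identical(self):
        cfg = simulate.HistologySimConfig(n_tubules=15, seed=11)
        img1, truth1 = simulate.gen_histology(cfg)
        img2, truth2 = simulate.gen_histology(cfg)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert truth1 == truth2

    def test_vacuole_prevalence_within_binomial_bounds(self):
        """With p=0.25 per tubule, the number of vacuolated tubules must sit
        inside the exact central 95% binomial interval."""
        cfg = simulate.HistologySimConfig(n_tubules=40, p_vacuole_tubule=0.25, seed=5)
        _, truth = simulate.gen_histology(cfg)
        n_vac = sum(t.n_vacuoles > 0 for t in truth)
        lo, hi = binom.ppf([0.025, 0.975], 40, 0.25)
        assert lo <= n_vac <= hi

    def test_min_gap_respected_between_all_circle_pairs(self):
        cfg = simulate.HistologySimConfig(n_tubules=30, min_gap_um=8.0, seed=9)
        _, truth = simulate.gen_histology(cfg)
        for i, a in enumerate(truth):
            for b in truth[i + 1:]:
                d = math.hypot(a.center_row_px - b.center_row_px,
                               a.center_col_px - b.center_col_px)
                required = (a.radius_um + b.radius_um + cfg.min_gap_um) / cfg.um_per_px
                assert d >= required - 1e-9

    def test_overcrowded_config_raises(self):
        cfg = simulate.HistologySimConfig(
            canvas_height_px=200, canvas_width_px=200, n_tubules=60,
            max_placement_attempts=2000, seed=0,
        )
        with pytest.raises(simulate.InfeasibleConfigError):
            simulate.gen_histology(cfg)

    def test_rete_region_labelled_and_unflagged(self):
        cfg = simulate.HistologySimConfig(n_tubules=10, include_rete=True, seed=2)
        _, truth = simulate.gen_histology(cfg)
        retes = [t for t in truth if t.kind == "rete"]
        assert len(retes) == 1
        assert retes[0].n_vacuoles == 0 and not retes[0].germ_cell_loss

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_histology(simulate.HistologySimConfig(p_vacuole_tubule=1.5))


class TestTrackGenerator:
    def test_noise_free_progressive_is_straight(self):
        ck = simulate.ClassKinematics(
            speed_um_s=(100.0, 100.0), amp_um=(0.0, 0.0), freq_hz=(5.0, 5.0),
            heading_diffusion=(0.0, 0.0), jitter_sd_um=0.0,
        )
        cfg = simulate.TrackSimConfig(
            n_per_class={"progressive": 1}, class_params={"progressive": ck}, seed=1
        )
        (track, label), = simulate.gen_tracks(cfg)
        assert label == "progressive"
        # collinearity: every point on the segment through first and last
        v = track.positions[-1] - track.positions[0]
        v = v / np.linalg.norm(v)
        rel = track.positions - track.positions[0]
        cross = rel[:, 0] * v[1] - rel[:, 1] * v[0]
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_weakly_motile_net_displacement_small(self, default_track_pairs):
        weak = [t for t, lab in default_track_pairs if lab == "weakly_motile"]
        assert weak
        for track in weak:
            net = np.linalg.norm(track.positions[-1] - track.positions[0])
            assert net < 5.0

    def test_hyperactivated_vcl_dwarfs_vsl(self, kin_by_class):
        for p in kin_by_class["hyperactivated"]:
            assert p.vcl_um_s >= 2.0 * p.vsl_um_s

    def test_determinism_and_frame_count(self):
        cfg = simulate.TrackSimConfig(seed=13)
        a = simulate.gen_tracks(cfg)
        b = simulate.gen_tracks(cfg)
        assert all(np.array_equal(x.positions, y.positions) for (x, _), (y, _) in zip(a, b))
        assert all(len(t.positions) == cfg.n_frames for t, _ in a)

    def test_empty_class_mix_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_tracks(simulate.TrackSimConfig(n_per_class={}))

    def test_classes_separable_in_kinematic_space(self, default_track_pairs):
        """A nearest-centroid rule on (log VCL, LIN, ALH) should make almost
        no mistakes when the five classes are separable by construction."""
        feats, labels = [], []
        for track, lab in default_track_pairs:
            p = casa.compute_kinematics(track)
            feats.append([math.log1p(p.vcl_um_s), p.lin_frac, p.alh_um])
            labels.append(lab)
        x = np.array(feats)
        y = np.array(labels)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        xz = (x - mu) / sd
        cents = {lab: xz[y == lab].mean(axis=0) for lab in np.unique(y)}
        pred = [
            min(cents, key=lambda lab: np.linalg.norm(row - cents[lab])) for row in xz
        ]
        err = np.mean([p != t for p, t in zip(pred, y)])
        assert err < 0.05


class TestPhenotypeGenerator:
    def test_null_model_strain_spread(self):
        """With va=0 the spread of strain means is pure sampling noise ve/n."""
        reps = []
        for seed in range(40):
            cfg = simulate.PhenoSimConfig(va=0.0, ve=1.0, age_slope=0.0, seed=seed)
            table = simulate.gen_phenotypes(cfg)
            reps.append(table.groupby("strain")["trait"].mean().var(ddof=1))
        # E[var of strain means] = ve / n_per_strain = 0.04
        assert np.mean(reps) == pytest.approx(1.0 / 25, rel=0.35)

    def test_no_missing_when_rate_zero(self):
        table = simulate.gen_phenotypes(simulate.PhenoSimConfig(missing_rate=0.0, seed=1))
        assert table["trait"].notna().all()

    def test_missing_rate_realized(self):
        table = simulate.gen_phenotypes(
            simulate.PhenoSimConfig(missing_rate=0.2, n_per_strain=100, seed=1)
        )
        assert table["trait"].isna().mean() == pytest.approx(0.2, abs=0.05)

    def test_age_slope_enters_linearly(self):
        cfg = simulate.PhenoSimConfig(va=0.0, ve=1e-12, age_slope=0.5, seed=2)
        table = simulate.gen_phenotypes(cfg)
        fit = np.polyfit(table["age_days"], table["trait"], 1)
        assert fit[0] == pytest.approx(0.5, abs=1e-3)

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_phenotypes(simulate.PhenoSimConfig(n_strains=1))

    def test_panel_shares_design_across_traits(self):
        cfgs = [
            simulate.PhenoSimConfig(trait_name="a", seed=4),
            simulate.PhenoSimConfig(trait_name="b"),
        ]
        panel = simulate.gen_phenotype_panel(cfgs)
        assert list(panel.columns) == ["animal_id", "strain", "age_days", "a", "b"]
        # traits are drawn independently given the design
        assert abs(np.corrcoef(panel["a"], panel["b"])[0, 1]) < 0.5

    def test_determinism(self):
        cfg = simulate.PhenoSimConfig(seed=8, missing_rate=0.1)
        assert simulate.gen_phenotypes(cfg).equals(simulate.gen_phenotypes(cfg))
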