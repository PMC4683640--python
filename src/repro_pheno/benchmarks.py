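"""Standard evaluation protocols run on freshly generated synthetic cohorts.

These functions wire the generators to the estimators under fixed study
conditions so that detector quality, classifier accuracy and heritability
recovery can be recomputed from scratch with a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import casa, histology, pheno_stats, simulate

__all__ = [
    "DetectionBenchmark",
    "detection_benchmark",
    "motility_benchmark",
    "heritability_recovery",
    "reproduce_study_table1",
]


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


@dataclass(frozen=True)
class DetectionBenchmark:
    """Held-out detector quality: recall and false positives, in percent."""

    recall_pct: float
    fp_per_image_pct: float
    n_truth: int
    per_section: pd.DataFrame


def detection_benchmark(
    seed: int,
    n_train: int = 6,
    n_test: int = 6,
    sim_cfg: simulate.HistologySimConfig | None = None,
    training_fraction: float = 0.001,
) -> DetectionBenchmark:
    """Train-on-disjoint-sections detection protocol.

    Renders ``n_train + n_test`` sections (defaults: ~40 tubules each),
    trains the random-forest center detector on at most
    ``training_fraction`` of the training sections' pixels, localizes
    centers on the held-out sections, and scores greedy one-to-one
    matching within half of each truth radius. Recall and the
    false-positive rate are averaged over held-out sections and reported
    in percent.
    """
    base = sim_cfg or simulate.HistologySimConfig()
    sections, truths = [], []
    for i in range(n_train + n_test):
        s, t = simulate.gen_histology(replace(base, seed=_sub_seed(seed, i)))
        sections.append(s)
        truths.append(t)

    clf = histology.train_center_classifier(
        sections[:n_train], truths[:n_train],
        training_fraction=training_fraction, seed=_sub_seed(seed, 900),
    )

    rows = []
    for i in range(n_train, n_train + n_test):
        records = histology.detect_tubules(sections[i], clf)
        centers = [(r.center_row_px, r.center_col_px) for r in records]
        recall, fp = histology.evaluate_detection(
            truths[i], centers, um_per_px=sections[i].um_per_px
        )
        rows.append(
            {"section": i, "n_truth": len(truths[i]), "n_detected": len(centers),
             "recall": recall, "fp_per_image_pct": fp}
        )
    per_section = pd.DataFrame(rows)
    return DetectionBenchmark(
        recall_pct=100.0 * float(per_section["recall"].mean()),
        fp_per_image_pct=float(per_section["fp_per_image_pct"].mean()),
        n_truth=int(per_section["n_truth"].sum()),
        per_section=per_section,
    )


def motility_benchmark(seed: int, cfg: simulate.TrackSimConfig | None = None) -> float:
    """Held-out five-class accuracy of the motility SVM cascade.

    Trains on one synthetic batch and classifies an independent batch
    drawn from the same class-conditional generator.
    """
    base = cfg or simulate.TrackSimConfig()
    train = simulate.gen_tracks(replace(base, seed=_sub_seed(seed, 1)))
    test = simulate.gen_tracks(replace(base, seed=_sub_seed(seed, 2)))
    model = casa.train_motility_svm(
        [(casa.compute_kinematics(t), lab) for t, lab in train], seed=_sub_seed(seed, 3)
    )
    pred = casa.classify_tracks(model, [casa.compute_kinematics(t) for t, _ in test])
    return float(np.mean([p == lab for p, (_, lab) in zip(pred, test)]))


def heritability_recovery(
    seed: int,
    h2_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    n_reps: int = 200,
    n_strains: int = 8,
    n_per_strain: int = 25,
    estimator_tag: str = "strain_mean_variance",
) -> dict[float, float]:
    """Mean estimated h2 per true h2 over replicate synthetic panels."""
    out = {}
    for g, h2_true in enumerate(h2_grid):
        ests = []
        for rep in range(n_reps):
            cfg = simulate.PhenoSimConfig(
                va=h2_true, ve=1.0 - h2_true, n_strains=n_strains,
                n_per_strain=n_per_strain, seed=_sub_seed(seed, 10_000 * (g + 1) + rep),
            )
            table = simulate.gen_phenotypes(cfg)
            ests.append(pheno_stats.heritability(table, "trait", estimator_tag).h2)
        out[h2_true] = float(np.mean(ests))
    return out


# ---------------------------------------------------------------------------
# reproduction of the published strain-survey values
# ---------------------------------------------------------------------------


def reproduce_study_table1(table_s1_csv, table_s2_csv) -> dict[str, float]:
    """Recompute headline strain-survey statistics from the per-animal tables.

    Needs the survey's per-animal supplementary tables (primary phenotypes
    and the motility time course), which are not redistributed with this
    package; point the arguments at local copies. Returns broad-sense
    heritabilities for body weight, mean testis weight and percent motile
    at 90 min (both VA estimators, the larger reported), the strain means
    of tubules with abnormal germ cells (A/J) and with sloughing
    (NZO/H1LtJ), and the WSB/EiJ vacuole-tubule prevalence in percent.
    """
    from pathlib import Path

    for p in (table_s1_csv, table_s2_csv):
        if not Path(p).exists():
            raise FileNotFoundError(
                f"supplementary per-animal table not found: {p}; the published "
                "survey data must be supplied locally to reproduce its values"
            )
    s1 = pd.read_csv(table_s1_csv)
    s2 = pd.read_csv(table_s2_csv)

    def h2_best(table, trait):
        return max(
            pheno_stats.heritability(table, trait, tag).h2
            for tag in ("strain_mean_variance", "anova_mom")
        )

    aj = s1[s1["strain"] == "A/J"]
    nzo = s1[s1["strain"] == "NZO/H1LtJ"]
    wsb = s1[s1["strain"] == "WSB/EiJ"]
    return {
        "h2_body_weight": h2_best(s1, "body_weight_g"),
        "h2_mean_testis_weight": h2_best(s1, "mean_testis_weight_g"),
        "h2_percent_motile_90min": h2_best(s2[s2["time_min"] == 90], "percent_motile"),
        "mean_abnormal_germ_cell_tubules_aj": float(aj["n_tubules_abnormal_germ_cells"].mean()),
        "mean_sloughing_tubules_nzo": float(nzo["n_tubules_sloughing"].mean()),
        "wsb_vacuole_tubule_prevalence_pct": float(
            (100.0 * wsb["n_tubules_vacuoles"] / wsb["n_tubules"]).mean()
        ),
    }
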