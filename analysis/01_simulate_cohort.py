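#!/usr/bin/env python
"""Generate the synthetic survey cohort: sections, sperm tracks, phenotypes.

Writes a small demonstration cohort under results/cohort/: two PAS-like
testis sections with ground-truth tubule annotations, one labelled batch
of 90-frame sperm tracks, and an eight-strain phenotype panel with three
traits of differing heritability.
"""

import argparse
from dataclasses import replace
from pathlib import Path

from repro_pheno import io, simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    hcfg = simulate.HistologySimConfig(seed=args.seed)
    for i in range(2):
        section, truth = simulate.gen_histology(replace(hcfg, seed=args.seed + i))
        io.write_section_image(args.out / f"section_{i}.png", section)
        io.write_truth_json(args.out / f"section_{i}.truth.json", truth, section.um_per_px)
        n_vac = sum(t.n_vacuoles > 0 for t in truth)
        print(f"section_{i}: {len(truth)} tubules, {n_vac} with vacuoles")

    pairs = simulate.gen_tracks(simulate.TrackSimConfig(seed=args.seed))
    io.write_tracks_csv(args.out / "tracks.csv", [t for t, _ in pairs])
    (args.out / "track_labels.csv").write_text(
        "track_id,label\n" + "\n".join(f"{t.track_id},{lab}" for t, lab in pairs) + "\n"
    )
    print(f"tracks.csv: {len(pairs)} tracks across five motility classes")

    panel = simulate.gen_phenotype_panel(
        [
            simulate.PhenoSimConfig(trait_name="testis_weight", va=0.7, ve=0.3),
            simulate.PhenoSimConfig(trait_name="body_weight", va=0.84, ve=0.16, age_slope=0.002),
            simulate.PhenoSimConfig(trait_name="sloughing_count", va=0.1, ve=0.9),
        ],
        seed=args.seed,
    )
    io.write_phenotypes_csv(args.out / "phenotypes.csv", panel)
    print(f"phenotypes.csv: {len(panel)} animals x {panel.shape[1] - 3} traits")


if __name__ == "__main__":
    main()
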