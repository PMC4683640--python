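#!/usr/bin/env python
"""Recompute the published survey's headline values from its primary data.

The strain survey distributed its per-animal phenotypes as supplementary
tables without a public accession; they are not redistributed here.
Supply local copies (CSV) to recompute the broad-sense heritabilities of
body weight, mean testis weight and percent motile at 90 min, the strain
means of abnormal-germ-cell and sloughing tubule counts, and the
WSB/EiJ vacuole-tubule prevalence with this package's estimators.
"""

import argparse
import sys
from pathlib import Path

from repro_pheno import benchmarks


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table-s1", type=Path, default=Path("data/study/table_s1.csv"),
                        help="per-animal primary phenotype table")
    parser.add_argument("--table-s2", type=Path, default=Path("data/study/table_s2.csv"),
                        help="per-animal motility time-course table")
    args = parser.parse_args()

    try:
        values = benchmarks.reproduce_study_table1(args.table_s1, args.table_s2)
    except FileNotFoundError as exc:
        print(exc, file=sys.stderr)
        print("place the survey's per-animal tables at the paths above to run "
              "this reproduction", file=sys.stderr)
        sys.exit(1)
    for key, value in values.items():
        print(f"{key}: {value:.3f}")


if __name__ == "__main__":
    main()
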