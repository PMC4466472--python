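#!/usr/bin/env python
"""Pairwise-tissue differential expression of the annotated sRNAs.

Kal's pooled two-proportion Z-test per library pair with BH-FDR, the
significant/likely/ns categorisation, and Z-score clustering of the
significant sequences into expression groups; outputs under results/run/de
and the overall run report under results/run/report.
"""

from pathlib import Path

import pandas as pd

from phasiforge.pipeline import RunConfig, run_all

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = RunConfig(seed=17)
    run_all(cfg, RUN_DIR, until="report")
    cats = pd.read_csv(RUN_DIR / "de" / "categories.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(RUN_DIR / "de" / "clusters.tsv", sep="\t", index_col=0)
    print("differential-expression categories:")
    print(cats.category.value_counts().to_string())
    print("expression-group sizes (significant sequences):")
    print(clusters.cluster_group.value_counts().sort_index().to_string())
    print(f"\nfull run report: {RUN_DIR / 'report' / 'report.txt'}")


if __name__ == "__main__":
    main()
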