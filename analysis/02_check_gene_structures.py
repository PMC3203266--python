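#!/usr/bin/env python
"""Validate gene structures: splice sites, intron projection, exon-border
support, mutually exclusive exons, completeness and pseudogene calls.

Reads nothing from disk: the family is regenerated deterministically (same
seed as 01) so every stage is reproducible in isolation.  Writes per-gene
tables under results/.
"""

from pathlib import Path

import pandas as pd

from coronin import pipeline as P
from coronin.simulate import SimParams, simulate_family

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    fam = simulate_family(SimParams(seed=SEED))
    OUT.mkdir(exist_ok=True)

    checks = P.splice_analysis(fam)
    pd.DataFrame([c.__dict__ for c in checks]).to_csv(
        OUT / "splice_checks.tsv", sep="\t", index=False
    )
    n_noncanon = sum(1 for c in checks if c.status != "canonical")
    print(f"{len(checks)} introns checked; {n_noncanon} non-canonical/violations")

    flags = P.border_analysis(fam)
    pd.DataFrame([f.__dict__ for f in flags]).to_csv(
        OUT / "border_flags.tsv", sep="\t", index=False
    )
    susp = [f for f in flags if f.verdict == "suspicious"]
    print(f"{len(flags)} projected exon borders; {len(susp)} suspicious:")
    for f in susp:
        print(f"  {f.gene_id} intron {f.intron_index} (column {f.column})")

    clusters = P.mxe_analysis(fam)
    pd.DataFrame([c.__dict__ for c in clusters]).to_csv(
        OUT / "mxe_clusters.tsv", sep="\t", index=False
    )
    print(f"{len(clusters)} mutually-exclusive-exon clusters "
          f"(truth: {len(fam.truth.mxe)})")

    completeness, pseudogene = P.curation_calls(fam)
    pd.DataFrame([c.__dict__ for c in completeness.values()]).to_csv(
        OUT / "completeness.tsv", sep="\t", index=False
    )
    pd.DataFrame([c.__dict__ for c in pseudogene.values()]).to_csv(
        OUT / "pseudogene_calls.tsv", sep="\t", index=False
    )
    n_pseudo = sum(c.verdict for c in pseudogene.values())
    print(f"{n_pseudo} pseudogenes called "
          f"(truth: {sum(fam.truth.pseudogene.values())})")


if __name__ == "__main__":
    main()
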