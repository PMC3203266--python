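"""Dataset bookkeeping: curation statistics and repertoire tables.

Mirrors the summary reporting of a gene-family survey: total sequences and
species, completeness categories, pseudogene counts (kept separate from
the completeness totals), a species x class repertoire table, and the
number of coronin domains entering a phylogeny (complete and partial
sequences only, with both domains of each tandem coronin counted
separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from coronin.seqio import SequenceRecord

CLASS_COLUMNS = ["class-1", "class-2", "class-3", "class-4", "unclassified"]


def _base_class(label: str | None) -> str:
    if label is None:
        return "unclassified"
    for base in ("class-1", "class-2", "class-3", "class-4"):
        if label.startswith(base):
            return base
    return "unclassified"


@dataclass
class DatasetSummary:
    n_sequences: int
    n_from_wgs: int
    n_species: int
    n_complete: int
    n_partial: int
    n_fragment: int
    n_pseudogenes: int
    n_pseudogenes_without_sequence: int
    per_species_class_counts: pd.DataFrame  # species x class table

    def to_markdown(self) -> str:
        """A markdown report mirroring the survey's data-statistics table."""
        rows = [
            ("Total", self.n_sequences),
            ("From WGS", self.n_from_wgs),
            ("Total pseudogenes", self.n_pseudogenes),
            ("Pseudogenes without sequence", self.n_pseudogenes_without_sequence),
            ("Complete", self.n_complete),
            ("Partials", self.n_partial),
            ("Fragments", self.n_fragment),
            ("Species", self.n_species),
        ]
        lines = ["| statistic | coronin |", "| --- | --- |"]
        lines += [f"| {k} | {v} |" for k, v in rows]
        return "\n".join(lines) + "\n"


def summarize(records: Sequence[SequenceRecord]) -> DatasetSummary:
    """Deterministic dataset counts.

    Pseudogenes are counted separately and excluded from the completeness
    totals; species identity is the exact species string.
    """
    pseudo = [r for r in records if r.pseudogene]
    regular = [r for r in records if not r.pseudogene]
    species = sorted({r.species for r in records if r.species})
    counts = {sp: {c: 0 for c in CLASS_COLUMNS} for sp in species}
    for r in records:
        if r.species:
            counts[r.species][_base_class(r.class_label)] += 1
    table = pd.DataFrame.from_dict(counts, orient="index", columns=CLASS_COLUMNS)
    table.index.name = "species"
    return DatasetSummary(
        n_sequences=len(records),
        n_from_wgs=sum(1 for r in records if r.from_wgs),
        n_species=len(species),
        n_complete=sum(1 for r in regular if r.completeness == "Complete"),
        n_partial=sum(1 for r in regular if r.completeness == "Partial"),
        n_fragment=sum(1 for r in regular if r.completeness == "Fragment"),
        n_pseudogenes=len(pseudo),
        n_pseudogenes_without_sequence=sum(1 for r in pseudo if not r.has_sequence),
        per_species_class_counts=table,
    )


def phylogeny_domain_count(records: Iterable[SequenceRecord]) -> int:
    """Number of coronin-domain rows entering the phylogeny.

    Only complete and partial non-pseudogene sequences are included
    (pseudogenes are excluded before counting); each tandem (class-3)
    sequence contributes its two coronin domains separately.
    """
    count = 0
    for r in records:
        if r.pseudogene:
            continue
        if r.completeness not in ("Complete", "Partial"):
            continue
        count += 2 if _base_class(r.class_label) == "class-3" else 1
    return count
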