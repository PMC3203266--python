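"""End-to-end drivers over a (simulated or curated) coronin family.

Each function runs one stage of the survey on a :class:`SimulatedFamily`
— the same calls apply to curated data loaded through :mod:`coronin.seqio`
— and returns plain dictionaries keyed by gene id, ready for tabulation.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from coronin import gene_structure as gst
from coronin import motif_domain as md
from coronin.classification import ClassCall, classify_pipeline
from coronin.seqio import read_tree
from coronin.simulate import SimulatedFamily


def build_reference_map(fam: SimulatedFamily, every: int = 2) -> dict[str, str]:
    """Pick every ``every``-th member of each class (by id order) as a
    labelled reference leaf; tandem coronins contribute both domain rows."""
    truth = fam.truth
    included = set(truth.domain_rows)
    refs: dict[str, str] = {}
    for cls in ("class-1", "class-2", "class-3", "class-4"):
        members = sorted(g for g, k in truth.classes.items() if k == cls)
        for i, g in enumerate(members):
            if i % every:
                continue
            if cls == "class-3":
                for leaf in (g + "_Nd", g + "_Cd"):
                    if leaf in included:
                        refs[leaf] = cls
            elif g in included:
                refs[g] = cls
    return refs


def curation_calls(fam: SimulatedFamily):
    """Completeness and pseudogene calls for every gene.

    Expected lengths and conserved intron phases come from the family's
    ground truth (for curated data: the family median of complete
    homologs and the consensus phases)."""
    completeness: dict[str, gst.CompletenessCall] = {}
    pseudogene: dict[str, gst.PseudogeneCall] = {}
    records = {r.id: r for r in fam.records}
    for gid, gs in fam.structures.items():
        comp = gst.call_completeness(records[gid], fam.truth.expected_length[gid])
        completeness[gid] = comp
        pseudogene[gid] = gst.call_pseudogene(
            gs,
            expected_phases=fam.truth.expected_phases[gid],
            missing_fraction=comp.missing_fraction,
        )
    return completeness, pseudogene


def border_analysis(fam: SimulatedFamily, min_support: int = 2, window: int = 5):
    """Project the introns of every aligned short coronin and flag exon
    borders without homolog support."""
    marks = []
    for row_id, _ in fam.alignment.rows:
        marks.extend(gst.intron_marks(fam.structures[row_id]))
    projected = gst.project_introns(fam.alignment, marks)
    return gst.flag_borders(projected, min_support=min_support, window=window)


def splice_analysis(fam: SimulatedFamily):
    checks = []
    for gs in fam.structures.values():
        checks.extend(gst.validate_splice_sites(gs))
    return checks


def mxe_analysis(fam: SimulatedFamily):
    clusters = []
    for gs in fam.structures.values():
        clusters.extend(gst.detect_mxe(gs))
    return clusters


def oligomer_analysis(fam: SimulatedFamily) -> dict[str, md.OligomerCall]:
    """Motif scan + oligomer prediction for every non-pseudogene record,
    using the coiled-coil annotations to delimit the scan."""
    cc_regions = {
        row.seq_id: (int(row.start), int(row.end))
        for _, row in fam.annotations.iterrows()
        if row.domain_name == "CC"
    }
    calls: dict[str, md.OligomerCall] = {}
    for rec in fam.records:
        if fam.truth.pseudogene[rec.id]:
            continue
        region = cc_regions.get(rec.id)
        if region is None:
            calls[rec.id] = md.OligomerCall(rec.id, "no_coiled_coil", "no_coiled_coil", None)
            continue
        hit = md.find_trimerization_motif(rec.protein, cc_region=region, seq_id=rec.id)
        calls[rec.id] = md.predict_oligomer(hit, has_cc=True)
    return calls


def architecture_analysis(fam: SimulatedFamily) -> dict[str, md.DomainArchitecture]:
    """Profile-based coronin-domain detection plus external annotations,
    assembled into per-gene architectures.

    The CA-domain search is only attempted on tandem candidates (two
    coronin-domain hits), where the class-3 C-terminal CA is expected."""
    pssm = md.build_pssm(fam.domain_alignment)
    c_prof = (
        md.build_pssm(fam.ca_c_alignment) if fam.ca_c_alignment is not None else None
    )
    a_prof = (
        md.build_pssm(fam.ca_a_alignment) if fam.ca_a_alignment is not None else None
    )
    out: dict[str, md.DomainArchitecture] = {}
    for rec in fam.records:
        if fam.truth.pseudogene[rec.id]:
            continue
        hits = md.scan_domain(rec.protein, pssm, seq_id=rec.id)
        hits += md.hits_from_annotations(fam.annotations, rec.id)
        n_coro = sum(1 for h in hits if h.domain_name == "CORO")
        if n_coro >= 2 and c_prof is not None and a_prof is not None:
            ca = md.find_ca_domain(rec.protein, c_prof, a_prof, seq_id=rec.id)
            if ca is not None:
                hits.append(ca)
        out[rec.id] = md.assemble_architecture(rec.id, hits)
    return out


def classify_family(
    fam: SimulatedFamily,
    architectures: Optional[dict[str, md.DomainArchitecture]] = None,
    references: Optional[dict[str, str]] = None,
) -> dict[str, ClassCall]:
    """Classify every non-pseudogene, non-fragment gene by architecture
    plus tree grouping; reference leaves keep their given label."""
    if architectures is None:
        architectures = architecture_analysis(fam)
    if references is None:
        references = build_reference_map(fam)
    tree = read_tree(fam.gene_tree_newick)
    calls: dict[str, ClassCall] = {}
    for rec in fam.records:
        gid = rec.id
        if fam.truth.pseudogene[gid] or fam.truth.completeness[gid] == "Fragment":
            continue
        if gid in references:
            calls[gid] = ClassCall(gid, references[gid], "tree")
            continue
        if gid + "_Nd" in references:  # tandem reference
            calls[gid] = ClassCall(gid, references[gid + "_Nd"], "tree")
            continue
        calls[gid] = classify_pipeline(
            rec,
            architectures[gid],
            tree=tree,
            references=references,
            outgroup=fam.truth.outgroup,
        )
    return calls


def class_calls_to_frame(calls: dict[str, ClassCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"seq_id": c.seq_id, "class": c.class_label, "basis": c.basis}
            for c in calls.values()
        ]
    ).set_index("seq_id")
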