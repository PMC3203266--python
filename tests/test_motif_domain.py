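"""Profiles, domain scanning, trimerization-motif rules, CA domains and
architecture strings."""

import math
import re

import numpy as np
import pytest

from coronin.motif_domain import (
    DomainHit,
    Pssm,
    assemble_architecture,
    build_pssm,
    classify_motif_window,
    find_ca_domain,
    find_trimerization_motif,
    hits_from_annotations,
    predict_oligomer,
    scan_domain,
)
from coronin.seqio import AA20, AlignmentBlock


class TestPssm:
    def test_invariant_column_closed_form(self):
        aln = AlignmentBlock([(f"r{i}", "R") for i in range(10)])
        pssm = build_pssm(aln, pseudocount=0.0)
        r = AA20.index("R")
        assert pssm.scores[0, r] == pytest.approx(math.log2(20))
        others = np.delete(pssm.scores[0], r)
        assert (others == -20.0).all()  # -inf capped

    def test_uniform_column_scores_zero(self):
        aln = AlignmentBlock([(f"r{i}", aa) for i, aa in enumerate(AA20)])
        pssm = build_pssm(aln, pseudocount=0.0)
        assert np.allclose(pssm.scores, 0.0)

    def test_half_half_column(self):
        aln = AlignmentBlock(
            [(f"r{i}", "R") for i in range(5)] + [(f"k{i}", "K") for i in range(5)]
        )
        pssm = build_pssm(aln, pseudocount=0.0)
        assert pssm.scores[0, AA20.index("R")] == pytest.approx(math.log2(10))
        assert pssm.scores[0, AA20.index("K")] == pytest.approx(math.log2(10))

    def test_gap_cells_excluded_and_all_gap_column_errors(self):
        aln = AlignmentBlock([("a", "R-"), ("b", "R-")])
        pssm = build_pssm(aln, columns=[1], pseudocount=0.0)
        assert pssm.width == 1
        with pytest.raises(ValueError, match="only gaps"):
            build_pssm(aln, columns=[2])

    def test_json_round_trip(self):
        aln = AlignmentBlock([("a", "RKDE"), ("b", "RKDD")])
        pssm = build_pssm(aln)
        back = Pssm.from_json(pssm.to_json())
        assert back.width == pssm.width
        assert np.allclose(back.scores, pssm.scores)


@pytest.fixture(scope="module")
def profile():
    rng = np.random.default_rng(0)
    base = "".join(AA20[i] for i in rng.integers(0, 20, size=60))
    rows = []
    for r in range(8):
        chars = list(base)
        for pos in rng.choice(60, size=6, replace=False):
            chars[pos] = AA20[int(rng.integers(0, 20))]
        rows.append((f"r{r}", "".join(chars)))
    return build_pssm(AlignmentBlock(rows))


class TestScanDomain:

    def test_consensus_attains_column_max_sum(self, profile):
        hits = scan_domain(profile.consensus(), profile)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(profile.consensus_score())

    def test_planted_consensus_found_at_offset(self, profile):
        rng = np.random.default_rng(1)
        flank = "".join(AA20[i] for i in rng.integers(0, 20, size=50))
        seq = flank + profile.consensus() + flank
        (hit,) = scan_domain(seq, profile)
        assert (hit.start, hit.end) == (51, 110)

    def test_random_sequences_yield_no_hits(self, profile):
        rng = np.random.default_rng(2)
        for _ in range(200):
            seq = "".join(AA20[i] for i in rng.integers(0, 20, size=150))
            assert scan_domain(seq, profile) == []

    def test_tandem_consensus_yields_two_hits(self, profile):
        rng = np.random.default_rng(3)
        linker = "".join(AA20[i] for i in rng.integers(0, 20, size=30))
        seq = profile.consensus() + linker + profile.consensus()
        hits = scan_domain(seq, profile)
        assert [(h.start, h.end) for h in hits] == [(1, 60), (91, 150)]


class TestTrimerizationMotif:
    def test_classical(self):
        hit = find_trimerization_motif("AAAAAA" + "RLASLE" + "AAAA")
        assert hit.variant == "classical" and hit.start == 7

    def test_arginine_to_glutamine(self):
        hit = find_trimerization_motif("AAAAAA" + "QLASLE" + "AAAA")
        assert hit.variant == "p1_sub(Q)"

    def test_salt_bridge_swap(self):
        hit = find_trimerization_motif("AAAAAA" + "ELASLR" + "AAAA")
        assert hit.variant == "swapped"

    def test_classical_preferred_over_variant(self):
        seq = "QLASLE" + "AAAA" + "RLASLE"
        hit = find_trimerization_motif(seq, cc_region=(1, len(seq)))
        assert (hit.start, hit.variant) == (11, "classical")

    def test_leftmost_wins_ties(self):
        seq = "RLASLE" + "AAAA" + "RIKSVE"
        hit = find_trimerization_motif(seq, cc_region=(1, len(seq)))
        assert hit.start == 1

    def test_no_motif(self):
        assert find_trimerization_motif("G" * 40) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_regex_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(400):
            seq = "".join(AA20[i] for i in rng.integers(0, 20, size=80))
            hit = find_trimerization_motif(seq, cc_region=(1, 80))
            want = regex_oracle(seq)
            got = None if hit is None else (hit.start, hit.variant)
            assert got == want, seq


def regex_oracle(seq):
    """Independent motif finder: one regex per variant class, scanned in
    rank order, leftmost match wins."""
    patterns = [
        ("classical", re.compile(r"(?=(R[ILVM]..[ILV]E))")),
        ("swapped", re.compile(r"(?=(E[ILVM]..[ILV]R))")),
        ("p1_sub", re.compile(r"(?=([^R][ILVM]..[ILV]E))")),
        ("p6_sub", re.compile(r"(?=(R[ILVM]..[ILV][^E]))")),
    ]
    for name, pat in patterns:
        m = pat.search(seq)
        if not m:
            continue
        w = m.group(1)
        if name == "p1_sub":
            sub = w[0] if w[0] in "KQA" else "other"
            return m.start() + 1, f"p1_sub({sub})"
        if name == "p6_sub":
            sub = w[5] if w[5] == "Q" else "other"
            return m.start() + 1, f"p6_sub({sub})"
        return m.start() + 1, name
    for m in re.finditer(r"(?=(R....E))", seq):
        w = m.group(1)
        if not (w[1] in "ILVM" and w[4] in "ILV"):
            return m.start() + 1, "p2/p5_sub"
    return None


class TestOligomerRules:
    @pytest.mark.parametrize(
        "window,state",
        [
            ("RIKSVE", "trimer"),
            ("EIKSVR", "trimer"),
            ("KIKSVE", "trimer_tetramer_equilibrium"),
            ("AIKSVE", "tetramer"),
            ("QIKSVE", "tetramer"),
            ("HIKSVE", "unknown"),
            ("RIKSVQ", "unknown"),
            ("RIKSVD", "unknown"),
            ("RGKSVE", "unknown"),
        ],
    )
    def test_substitution_effects(self, window, state):
        hit = find_trimerization_motif("A" * 10 + window + "A" * 10)
        assert predict_oligomer(hit).state == state

    def test_absent_coiled_coil(self):
        call = predict_oligomer(None, has_cc=False)
        assert call.state == "no_coiled_coil"

    def test_no_motif_is_unknown(self):
        call = predict_oligomer(None, has_cc=True)
        assert (call.state, call.rule_id) == ("unknown", "no_motif")

    def test_total_over_variant_space(self):
        # every classifiable 6-mer maps to exactly one state
        for p1 in AA20:
            for p6 in AA20:
                for p2, p5 in (("I", "V"), ("G", "V"), ("I", "G")):
                    w = p1 + p2 + "KS" + p5 + p6
                    v = classify_motif_window(w)
                    if v is None:
                        continue
                    hit = find_trimerization_motif("A" * 8 + w + "A" * 8)
                    call = predict_oligomer(hit)
                    assert call.state in (
                        "trimer",
                        "tetramer",
                        "trimer_tetramer_equilibrium",
                        "unknown",
                    )


@pytest.fixture(scope="module")
def profiles():
    c_rows = [("a", "LIVLFAKLIVLFAK"[:12] + "RK"), ("b", "LIVLFAKLIVLFAM"[:12] + "KK")]
    a_rows = [("a", "DEDEDDEEDEDD"), ("b", "DEDEEDEEDEDD")]
    return build_pssm(AlignmentBlock(c_rows)), build_pssm(AlignmentBlock(a_rows))


class TestCaDomain:

    def test_planted_c_plus_a_found(self, profiles):
        c_prof, a_prof = profiles
        seq = "G" * 40 + c_prof.consensus() + "KSTN" * 3 + a_prof.consensus()
        hit = find_ca_domain(seq, c_prof, a_prof, max_linker=20)
        assert hit is not None and hit.domain_name == "CA"
        assert hit.start == 41 and hit.end == len(seq)

    def test_acidic_without_c_region_is_none(self, profiles):
        c_prof, a_prof = profiles
        seq = "G" * 40 + a_prof.consensus() + "G" * 10
        assert find_ca_domain(seq, c_prof, a_prof) is None

    def test_linker_beyond_bound_is_none(self, profiles):
        c_prof, a_prof = profiles
        seq = "G" * 10 + c_prof.consensus() + "KSTN" * 20 + a_prof.consensus()
        assert find_ca_domain(seq, c_prof, a_prof, max_linker=20) is None

    def test_family_class3_ca_detected(self, noise_free_family):
        fam = noise_free_family
        from coronin.motif_domain import build_pssm as bp

        c_prof = bp(fam.ca_c_alignment)
        a_prof = bp(fam.ca_a_alignment)
        for rec in fam.records:
            if fam.truth.classes[rec.id] == "class-3":
                hit = find_ca_domain(rec.protein, c_prof, a_prof)
                assert hit is not None
                assert hit.end == len(rec.protein)


class TestArchitecture:
    def test_short_coronin_string(self):
        hits = [
            DomainHit("s", "CORO", 1, 390, 100.0, "pssm"),
            DomainHit("s", "CC", 420, 455, 10.0, "annotation"),
        ]
        assert assemble_architecture("s", hits).architecture_string == "CORO–U–CC"

    def test_tandem_string(self):
        hits = [
            DomainHit("s", "CORO", 1, 390, 100.0, "pssm"),
            DomainHit("s", "CORO", 431, 820, 90.0, "pssm"),
            DomainHit("s", "CA", 840, 875, 12.0, "pssm"),
        ]
        assert (
            assemble_architecture("s", hits).architecture_string
            == "CORO–X–CORO–CA"
        )

    def test_class4_string_with_multiplicities(self):
        hits = [DomainHit("s", "CORO", 1, 390, 100.0, "pssm")]
        pos = 400
        for name, n, ln in (("PH", 3, 100), ("GEL", 5, 110), ("VHP", 1, 35)):
            for _ in range(n):
                hits.append(DomainHit("s", name, pos, pos + ln - 1, 5.0, "annotation"))
                pos += ln + 5
        assert (
            assemble_architecture("s", hits).architecture_string
            == "CORO–PH×3–GEL×5–VHP"
        )

    def test_overlap_resolved_by_score_then_source(self):
        hits = [
            DomainHit("s", "CORO", 1, 390, 50.0, "pssm"),
            DomainHit("s", "other", 100, 200, 20.0, "pattern"),
        ]
        arch = assemble_architecture("s", hits)
        assert [h.domain_name for h in arch.hits] == ["CORO"]

    def test_annotation_conversion(self, noise_free_family):
        fam = noise_free_family
        gid = next(g for g, k in fam.truth.classes.items() if k == "class-4")
        hits = hits_from_annotations(fam.annotations, gid)
        names = {h.domain_name for h in hits}
        assert names == {"PH", "GEL", "VHP"}
        assert all(h.source == "annotation" for h in hits)
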