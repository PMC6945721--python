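"""Germline annotation: RS detection, numbering, scanners, classification,
identity, subgroups and the locus map."""

import numpy as np
import pytest

from trkit._seq import revcomp, translate
from trkit.germline import (
    DEGENERATE,
    FRAMESHIFT,
    MISSING_ANCHOR,
    NONCANONICAL_RS,
    STOP_CODON,
    GermlineGene,
    VGeneProfile,
    annotate_locus,
    assign_subgroups,
    build_locus_map,
    classify_functionality,
    detect_rs,
    number_v_region,
    pairwise_identity,
    scan_c_genes,
    scan_d_genes,
    scan_j_genes,
    scan_v_genes,
)
from trkit.io_formats import ConfigError, TRKitError
from trkit.rs_profile import default_rs_pwms
from tests.conftest import reference_from_truth


def _rand_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestDetectRs:
    def test_consensus_planted_top_hit(self):
        rng = np.random.default_rng(0)
        bg = _rand_nt(rng, 300)
        rs = "CACAGTG" + _rand_nt(rng, 23) + "ACAAAAACC"
        dna = bg[:50] + rs + bg[50:]
        hits = detect_rs(dna, "3p", 23)
        assert hits[0].offset == 50 and hits[0].canonical

    def test_noncanonical_heptamer_still_reported(self):
        rng = np.random.default_rng(1)
        bg = _rand_nt(rng, 300)
        rs = "TACAGTG" + _rand_nt(rng, 23) + "ACAAAAACC"
        dna = bg[:50] + rs + bg[50:]
        hits = detect_rs(dna, "3p", 23)
        assert hits and hits[0].offset == 50 and not hits[0].canonical

    def test_invalid_spacer_rejected(self):
        with pytest.raises(ConfigError):
            detect_rs("ACGT" * 20, "3p", 15)

    def test_exhaustive_scan_equals_brute_force(self):
        """Independent oracle: per-window python scoring of every offset."""
        rng = np.random.default_rng(2)
        dna = _rand_nt(rng, 280) + "CACAGTG" + _rand_nt(rng, 12) + "ACAAAAACC" + _rand_nt(rng, 20)
        hept, non = default_rs_pwms()

        def naive(side, spacer):
            w = 16 + spacer
            out = {}
            for i in range(len(dna) - w + 1):
                win = dna[i : i + w]
                if side == "5p":
                    win = revcomp(win)
                out[i] = hept.score(win[:7]) + non.score(win[7 + spacer :])
            return out

        for side, spacer in (("3p", 12), ("5p", 23)):
            expected = naive(side, spacer)
            hits = detect_rs(dna, side, spacer, min_score=-1e9)
            assert len(hits) == len(expected)
            for h in hits:
                assert h.score == pytest.approx(expected[h.offset], abs=1e-9)


class TestNumberVRegion:
    def test_planted_gap_pattern_recovered(self, trg_locus):
        for g in trg_locus.genes:
            if g.gene_type != "V" or g.numbering is None:
                continue
            n = number_v_region(translate(g.nt_sequence))
            assert n.ok
            assert (n.cdr1_len, n.cdr2_len) == (g.numbering.cdr1_len, g.numbering.cdr2_len)

    def test_functional_trgv_reads_ihwy_at_39_to_42(self, trg_locus):
        g = next(x for x in trg_locus.genes if x.gene_type == "V" and x.functionality == "F")
        aa = translate(g.nt_sequence)
        n = number_v_region(aa)
        inv = {pos: idx for idx, pos in n.positions.items()}
        assert "".join(aa[inv[p]] for p in (39, 40, 41, 42)) == "IHWY"

    def test_no_cysteines_flags_anchors_absent(self):
        n = number_v_region("A" * 90)
        assert n.ok and not n.anchors[23] and not n.anchors[104]

    def test_short_sequence_is_numbering_failure(self):
        assert not number_v_region("ACD" * 10).ok

    def test_mapping_strictly_increasing(self, trg_locus):
        g = next(x for x in trg_locus.genes if x.gene_type == "V")
        n = number_v_region(translate(g.nt_sequence))
        imgt = [n.positions[i] for i in sorted(n.positions)]
        assert all(a < b for a, b in zip(imgt, imgt[1:]))


class TestScanners:
    def test_all_planted_v_found_at_exact_coordinates(self, trg_locus, trg_reference):
        prof = VGeneProfile.train(trg_reference.v_sequences)
        found = {(g.start, g.end) for g in scan_v_genes(trg_locus.sequence, prof)}
        truth = {(g.start, g.end) for g in trg_locus.genes if g.gene_type == "V"}
        assert found == truth

    def test_stop_codon_pseudogene_still_reported(self, trg_locus, trg_reference):
        prof = VGeneProfile.train(trg_reference.v_sequences)
        genes = {(g.start, g.end): g for g in scan_v_genes(trg_locus.sequence, prof)}
        for t in trg_locus.genes:
            if t.gene_type == "V" and STOP_CODON in t.defects:
                g = genes[(t.start, t.end)]
                assert STOP_CODON in g.defects and g.functionality == "P"

    def test_reverse_strand_v_reported_with_minus(self, trg_locus, trg_reference):
        rc = revcomp(trg_locus.sequence)
        prof = VGeneProfile.train(trg_reference.v_sequences)
        genes = scan_v_genes(rc, prof)
        n = len(trg_locus.sequence)
        mirrored = {(n - g.end, n - g.start): g.strand for g in genes}
        for t in trg_locus.genes:
            if t.gene_type == "V":
                assert mirrored[(t.start, t.end)] == "-"

    def test_j_functionality_classes(self, trg_locus, trg_reference):
        genes = {
            (g.start, g.end): g
            for g in scan_j_genes(trg_locus.sequence, trg_reference.j_sequences)
        }
        for t in trg_locus.genes:
            if t.gene_type != "J":
                continue
            g = genes[(t.start, t.end)]
            assert g.functionality == t.functionality, t.name
            if t.functionality == "ORF":
                assert NONCANONICAL_RS in g.defects

    def test_d_found_with_both_motifs_and_cluster_order(self, trb_locus):
        ds = scan_d_genes(trb_locus.sequence)
        truth = sorted((g for g in trb_locus.genes if g.gene_type == "D"), key=lambda g: g.start)
        assert [(d.start, d.end) for d in ds] == [(t.start, t.end) for t in truth]
        assert all(d.rs_5p is not None and d.rs_3p is not None for d in ds)
        assert all(d.rs_5p.spacer_len == 12 and d.rs_3p.spacer_len == 23 for d in ds)

    def test_segment_with_single_rs_is_not_a_d(self):
        rng = np.random.default_rng(3)
        bg = _rand_nt(rng, 400)
        # 5' RS only
        dna = bg[:100] + revcomp("CACAGTG" + _rand_nt(rng, 12) + "ACAAAAACC") + _rand_nt(rng, 14) + bg[100:]
        assert scan_d_genes(dna) == []

    def test_c_exon_structure_and_frameshift(self, trg_locus, trg_reference):
        cs = {(g.start, g.end): g for g in scan_c_genes(trg_locus.sequence, trg_reference.c_exons)}
        for t in trg_locus.genes:
            if t.gene_type != "C":
                continue
            g = cs[(min(s for s, _ in t.exons), max(e for _, e in t.exons))]
            assert len(g.exons) == 3
            assert g.functionality == t.functionality
            if t.functionality == "P":
                assert FRAMESHIFT in g.defects

    def test_four_exon_c_genes(self, trb_locus):
        c_gene = next(g for g in trb_locus.genes if g.gene_type == "C" and g.functionality == "F")
        refs = [trb_locus.sequence[s:e] for s, e in c_gene.exons]
        cs = scan_c_genes(trb_locus.sequence, refs)
        assert cs and all(len(g.exons) == 4 for g in cs)


class TestClassifyFunctionality:
    @pytest.mark.parametrize(
        "defects,expected",
        [
            ([], "F"),
            ([NONCANONICAL_RS], "ORF"),
            ([MISSING_ANCHOR], "ORF"),
            ([STOP_CODON], "P"),
            ([STOP_CODON, STOP_CODON], "P"),
            ([FRAMESHIFT, NONCANONICAL_RS], "P"),
            ([DEGENERATE], "P"),
        ],
    )
    def test_pure_function_of_defects(self, defects, expected):
        g = GermlineGene(name="x", locus="TRG", gene_type="V", start=0, end=3, defects=defects)
        assert classify_functionality(g) == expected
        assert classify_functionality(g) == expected  # idempotent

    def test_strand_invariance_of_defects(self, trg_locus, trg_reference):
        """Reverse-complementing the locus mirrors coordinates but leaves
        the defect-derived functionality of every gene unchanged."""
        fwd = annotate_locus(trg_locus.sequence, trg_reference, "TRG")
        rev = annotate_locus(revcomp(trg_locus.sequence), trg_reference, "TRG")
        n = len(trg_locus.sequence)
        fwd_map = {(g.start, g.end): g.functionality for g in fwd.genes}
        rev_map = {(n - g.end, n - g.start): g.functionality for g in rev.genes}
        assert fwd_map == rev_map


class TestPairwiseIdentity:
    def test_identical_is_100(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_one_mismatch_in_ten(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAT") == 90.0

    def test_terminal_gaps_excluded(self):
        # 10 aligned columns after the unmatched prefix is discounted
        assert pairwise_identity("AAAACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(TRKitError):
            pairwise_identity("", "ACGT")


class TestAssignSubgroups:
    @staticmethod
    def _vgene(name, seq, start):
        return GermlineGene(name=name, locus="TRG", gene_type="V", start=start, end=start + len(seq), nt_sequence=seq)

    def test_identity_above_threshold_joins(self):
        rng = np.random.default_rng(4)
        base = _rand_nt(rng, 100)
        close = base[:20] + _rand_nt(rng, 10) + base[30:]  # ~90% identity... mutate 10 of 100
        far = _rand_nt(rng, 100)
        genes = [self._vgene("", base, 0), self._vgene("", close, 200), self._vgene("", far, 400)]
        groups = assign_subgroups(genes, 75.0)
        assert len(groups) == 2
        assert genes[0].subgroup == genes[1].subgroup != genes[2].subgroup

    def test_trg_locus_has_six_subgroups(self, trg_locus):
        vs = [g for g in trg_locus.genes if g.gene_type == "V"]
        groups = assign_subgroups([GermlineGene(name="", locus="TRG", gene_type="V", start=g.start, end=g.end, nt_sequence=g.nt_sequence) for g in vs], 75.0)
        assert len(groups) == 6
        assert sorted(len(g) for g in groups) == [1, 1, 1, 1, 4, 4]

    def test_partition_invariant_under_permutation(self, trg_locus):
        vs = [g for g in trg_locus.genes if g.gene_type == "V"]
        def build():
            return [GermlineGene(name="", locus="TRG", gene_type="V", start=g.start, end=g.end, nt_sequence=g.nt_sequence) for g in vs]
        a = assign_subgroups(build(), 75.0)
        shuffled = build()
        rng = np.random.default_rng(0)
        rng.shuffle(shuffled)
        b = assign_subgroups(shuffled, 75.0)
        key = lambda groups: sorted(sorted(g.start for g in grp) for grp in groups)
        assert key(a) == key(b)

    def test_threshold_extremes(self):
        rng = np.random.default_rng(5)
        genes = [self._vgene("", _rand_nt(rng, 60), i * 100) for i in range(4)]
        assert len(assign_subgroups(genes, 0.0)) == 1
        assert len(assign_subgroups(genes, 100.0)) == 4
        # exact duplicates still merge at threshold 100
        dup = [self._vgene("", genes[0].nt_sequence, 0), self._vgene("", genes[0].nt_sequence, 500)]
        assert len(assign_subgroups(dup, 100.0)) == 1


class TestLocusMap:
    def test_five_cassettes_and_j_names(self, trg_locus):
        lm = trg_locus.locus_map
        units = {g.unit for g in lm.genes}
        assert units == {1, 2, 3, 4, 5}
        for u in range(1, 6):
            js = [g.name for g in lm.genes if g.gene_type == "J" and g.unit == u]
            assert js == [f"TRGJ{u}-1", f"TRGJ{u}-2"]

    def test_trb_cluster_composition(self, trb_locus):
        lm = trb_locus.locus_map
        for u in (1, 2):
            sizes = {
                t: sum(1 for g in lm.genes if g.unit == u and g.gene_type == t)
                for t in ("D", "J", "C")
            }
            assert sizes == {"D": 1, "J": 6, "C": 1}
        tail = [g for g in lm.genes if g.gene_type == "V" and g.strand == "-"]
        assert len(tail) == 1 and tail[0].unit is None

    def test_empty_gene_list(self):
        lm = build_locus_map([], "TRG")
        assert lm.genes == [] and lm.units == {}

    def test_summary_tallies_match_blueprint(self, trg_locus):
        df = trg_locus.locus_map.summary()
        tally = {(r.gene_type, r.functionality): r["count"] for _, r in df.iterrows()}
        assert tally[("V", "F")] == 6 and tally[("V", "P")] == 6
        assert tally[("J", "F")] == 4 and tally[("J", "ORF")] == 2 and tally[("J", "P")] == 4
        assert tally[("C", "F")] == 4 and tally[("C", "P")] == 1
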