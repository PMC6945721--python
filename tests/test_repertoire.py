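"""Repertoire pipeline: trimming, merging, assignment, junctions, usage and
pairing statistics."""

import numpy as np
import pytest

from trkit._seq import revcomp
from trkit.germline import GermlineEntry, GermlineGene, GermlineSet, LocusMap
from trkit.io_formats import FastqRead
from trkit.repertoire import (
    Rearrangement,
    assign_genes,
    extract_junction,
    merge_pairs,
    pairing_matrix,
    process_sample,
    sliding_window_trim,
    usage_stats,
)
from trkit.simulate import SimConfig, emit_reads, simulate_repertoire


class TestSlidingWindowTrim:
    def test_high_quality_read_unchanged(self):
        r = FastqRead("r", "ACGT" * 25, [40] * 100)
        assert sliding_window_trim(r) == r

    def test_all_low_quality_read_dropped(self):
        r = FastqRead("r", "ACGT" * 25, [2] * 100)
        assert sliding_window_trim(r) is None

    def test_cut_matches_brute_force_window_scan(self):
        """Oracle: first window (any start) whose mean quality < qmin."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 120))
            quals = [int(q) for q in rng.integers(2, 41, n)]
            read = FastqRead("r", "A" * n, quals)
            window, qmin = 4, 30
            cut = n
            for i in range(n - window + 1):
                if sum(quals[i : i + window]) / window < qmin:
                    cut = i
                    break
            expected = None if cut < 50 else FastqRead("r", "A" * cut, quals[:cut])
            assert sliding_window_trim(read, window, qmin, min_len=50) == expected


class TestMergePairs:
    def test_exact_overlap_merges_to_full_length(self):
        rng = np.random.default_rng(7)
        amp = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        r1 = FastqRead("r", amp[:55], [40] * 55)
        r2 = FastqRead("r", revcomp(amp[25:]), [40] * 55)  # 30-nt overlap
        m = merge_pairs(r1, r2, min_overlap=20)
        assert m is not None and m.seq == amp and m.overlap == 30

    def test_disagreement_resolved_to_higher_quality(self):
        rng = np.random.default_rng(8)
        amp = "".join("ACGT"[i] for i in rng.integers(0, 4, 32))
        r1_seq = amp[:24]
        r2_region = list(amp[8:])
        orig = r2_region[4]  # amplicon position 12
        flip = "ACGT"[("ACGT".index(orig) + 1) % 4]
        r2_region[4] = flip
        r2 = FastqRead("r", revcomp("".join(r2_region)), [40] * 24)
        r1 = FastqRead("r", r1_seq, [10] * 24)
        m = merge_pairs(r1, r2, min_overlap=10)
        assert m.seq[12] == flip  # Q40 base wins over Q10
        r1_hi = FastqRead("r", r1_seq, [40] * 24)
        r2_lo = FastqRead("r", r2.seq, [10] * 24)
        assert merge_pairs(r1_hi, r2_lo, min_overlap=10).seq[12] == orig

    def test_unrelated_reads_fail_to_merge(self):
        rng = np.random.default_rng(1)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        assert merge_pairs(FastqRead("r", a, [40] * 80), FastqRead("r", b, [40] * 80)) is None


@pytest.fixture(scope="module")
def trg_pipeline(trg_locus):
    """One simulated error-free library pushed through the full pipeline."""
    gs = trg_locus.germline_set
    cfg = SimConfig(locus_id="TRG", n_reads=400, error_rate=0.0, rng_seed=17)
    amps, truths = simulate_repertoire(gs, cfg, "s1")
    r1s, r2s = emit_reads(amps, 300, 0.0, seed=18)
    rearrs, stats = process_sample(r1s, r2s, gs, "TRG", "s1")
    return gs, truths, rearrs, stats


class TestAssignGenes:
    def test_error_free_reads_recover_generating_genes(self, trg_pipeline):
        gs, truths, rearrs, stats = trg_pipeline
        # reads whose J was trimmed beyond the identity floor are legitimately
        # unassignable; everything assigned must name the generating genes
        assert stats["assigned"] >= 0.99 * stats["pairs"]
        by_id = {t.read_id: t for t in truths}
        for r in rearrs:
            t = by_id[r.sequence_id]
            assert t.v_name in r.v_call
            assert t.j_name in r.j_call

    def test_single_nucleotide_j_pair_ambiguity(self, trg_locus):
        """Two J genes differing only in their first nucleotide: a read with
        that nucleotide trimmed must report both."""
        gs = trg_locus.germline_set
        j1 = next(e for e in gs.entries if e.gene_type == "J" and e.functionality == "F")
        v1 = next(e for e in gs.entries if e.gene_type == "V" and e.functionality == "F")
        twin_seq = ("G" if j1.nt_sequence[0] != "G" else "A") + j1.nt_sequence[1:]
        entries = [e for e in gs.entries] + [
            GermlineEntry("TRGJX", "J", "TRG", "F", twin_seq, j1.unit, j1.anchor_offset)
        ]
        gs2 = GermlineSet(entries)
        read = "AAGCAGTGGTATCAACGCAG" + v1.nt_sequence + j1.nt_sequence[1:] + "GGTTGGAGTCTGCAAGAGGG"
        res = assign_genes(read, gs2, "TRG")
        assert j1.name in res.j_call and "TRGJX" in res.j_call

    def test_foreign_locus_read_unassigned(self, trg_locus, trb_locus):
        gs = trg_locus.germline_set
        trb_v = next(g for g in trb_locus.genes if g.gene_type == "V").nt_sequence
        trb_j = next(g for g in trb_locus.genes if g.gene_type == "J").nt_sequence
        assert assign_genes(trb_v + trb_j, gs, "TRG") is None


class TestExtractJunction:
    def test_error_free_junctions_match_truth_exactly(self, trg_pipeline):
        gs, truths, rearrs, _ = trg_pipeline
        by_id = {t.read_id: t for t in truths}
        comparable = [(r, by_id[r.sequence_id]) for r in rearrs if by_id[r.sequence_id].junction]
        assert comparable
        assert all(r.junction == t.junction for r, t in comparable)

    def test_untrimmed_junction_is_germline_concatenation(self, trg_locus):
        gs = trg_locus.germline_set
        cfg = SimConfig(
            locus_id="TRG", n_reads=20, p_trim_v=1.0, p_trim_j=1.0, lambda_n=0.0, rng_seed=19
        )
        amps, truths = simulate_repertoire(gs, cfg, "s1")
        for t in truths:
            v = gs.by_name[t.v_name]
            j = gs.by_name[t.j_name]
            expected = (
                v.nt_sequence[v.anchor_offset :] + j.nt_sequence[: j.anchor_offset + 3]
            )
            assert t.junction == expected

    def test_out_of_frame_junction_unproductive(self, trg_pipeline):
        gs, truths, rearrs, _ = trg_pipeline
        for r in rearrs:
            if r.junction is not None and len(r.junction) % 3 != 0:
                assert not r.productive
            if r.productive:
                assert len(r.junction) % 3 == 0
                assert r.junction_aa[0] == "C" and r.junction_aa[-1] in "FW"
                assert r.cdr3 == r.junction[3:-3]


def _rearr(i, v_call, j_call, sample="s1", vu=None, ju=None):
    return Rearrangement(
        sequence_id=f"q{i}", locus="TRG", v_call=v_call, j_call=j_call,
        sample_id=sample, v_cassette=vu, j_cassette=ju,
    )


class TestUsageStats:
    def test_single_gene_is_100_percent(self):
        table = usage_stats([_rearr(i, ["TRGV1"], ["TRGJ1-1"]) for i in range(5)])
        assert table.summary.loc["TRGV1", "median_pct"] == 100.0

    def test_median_across_samples(self):
        rearrs = []
        i = 0
        for sample, pct in (("s1", 10), ("s2", 20), ("s3", 30)):
            for _ in range(pct):
                rearrs.append(_rearr(i, ["g"], ["j"], sample)); i += 1
            for _ in range(100 - pct):
                rearrs.append(_rearr(i, ["h"], ["j"], sample)); i += 1
        table = usage_stats(rearrs)
        assert table.summary.loc["g", "median_pct"] == pytest.approx(20.0)
        assert table.summary.loc["g", "q1_pct"] == pytest.approx(15.0)

    def test_fractional_split_conserves_totals(self):
        rearrs = [_rearr(0, ["a", "b"], ["j"]), _rearr(1, ["a"], ["j"])]
        table = usage_stats(rearrs)
        col = table.frequencies["s1"]
        assert col.sum() == pytest.approx(1.0)
        assert col["a"] == pytest.approx(0.75) and col["b"] == pytest.approx(0.25)

    def test_merged_category_mode(self):
        rearrs = [_rearr(0, ["x"], ["TRGJ2-2", "TRGJ3-2"])]
        table = usage_stats(rearrs, level="j", by="merged")
        assert "TRGJ2-2/TRGJ3-2" in table.frequencies.index

    def test_pipeline_usage_sums_to_one(self, trg_pipeline):
        _, _, rearrs, _ = trg_pipeline
        table = usage_stats(rearrs, level="v")
        assert np.allclose(table.frequencies.sum(axis=0), 1.0)


def _map_for(entries):
    genes = [
        GermlineGene(name=e.name, locus=e.locus, gene_type=e.gene_type, start=i, end=i + 1,
                     functionality=e.functionality, unit=e.unit)
        for i, e in enumerate(entries)
    ]
    return LocusMap(locus_id="TRG", genes=genes)


class TestPairingMatrix:
    def test_all_intra_cassette_fraction_is_one(self, trg_locus):
        gs = trg_locus.germline_set
        lmap = trg_locus.locus_map
        v = next(e for e in gs.entries if e.gene_type == "V" and e.unit == 2)
        j = next(e for e in gs.entries if e.gene_type == "J" and e.unit == 2)
        rearrs = [_rearr(i, [v.name], [j.name], vu=2, ju=2) for i in range(10)]
        res = pairing_matrix(rearrs, lmap)
        assert res.intra_fraction == 1.0
        assert res.matrix.loc[v.name, j.name] == 10

    def test_intra_preference_recovered_within_three_se(self, trg_locus):
        gs = trg_locus.germline_set
        n = 4000
        cfg = SimConfig(locus_id="TRG", n_reads=n, intra_unit_preference=0.8, rng_seed=23)
        _, truths = simulate_repertoire(gs, cfg, "s1")
        unit = {e.name: e.unit for e in gs.entries}
        rearrs = [
            _rearr(i, [t.v_name], [t.j_name], vu=unit[t.v_name], ju=unit[t.j_name])
            for i, t in enumerate(truths)
        ]
        res = pairing_matrix(rearrs, trg_locus.locus_map)
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(res.intra_fraction - 0.8) <= 3 * se

    def test_cross_locus_join_is_representable(self):
        entries = [
            GermlineEntry("TRDV1", "V", "TRD", "F", "ACGT" * 30, 1, 0),
            GermlineEntry("TRDJ1", "J", "TRD", "F", "ACGT" * 7, 1, 6),
            GermlineEntry("TRAJ1", "J", "TRA", "F", "TGCA" * 7, None, 6),
        ]
        lmap = _map_for(entries)
        rearrs = [_rearr(0, ["TRDV1"], ["TRDJ1"]), _rearr(1, ["TRDV1"], ["TRAJ1"])]
        res = pairing_matrix(rearrs, lmap)
        assert res.matrix.loc["TRDV1", "TRAJ1"] == 1
        assert res.by_j_locus == {"TRD": 1.0, "TRA": 1.0}

    def test_unmapped_gene_pooled(self):
        lmap = _map_for([GermlineEntry("TRGV1", "V", "TRG", "F", "A" * 60, 1, 0)])
        res = pairing_matrix([_rearr(0, ["TRGV1"], ["TRGJ9"])], lmap)
        assert res.matrix.loc["TRGV1", "unmapped"] == 1
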