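"""Expressed-repertoire pipeline: paired FASTQ -> AIRR rearrangement table.

Stages: sliding-window quality trimming, overlap merging of read pairs,
V/J (and best-effort D) gene assignment against a germline directory,
junction extraction between the conserved anchors (cys-104 codon through
the J-PHE/J-TRP-118 codon, both inclusive), and the per-sample usage and
V-J pairing statistics.

Gene calls are ambiguity sets: every germline gene whose alignment score is
within one match-equivalent of the best is reported, in locus order. Usage
statistics split ambiguous calls fractionally (1/k to each member), which
conserves total counts; a merged-category mode is available as well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp, translate
from .germline import GermlineEntry, GermlineSet, LocusMap
from .io_formats import FastqRead, TRKitError

# alignment floors: a V call needs >= 60% identity over a >= 50 nt gene,
# a J call >= 60% identity over a >= 14 nt gene
V_MIN_IDENTITY, V_MIN_LEN = 0.6, 50
J_MIN_IDENTITY, J_MIN_LEN = 0.6, 14
TIE_MARGIN = 1          # score window for the ambiguity set, in edits
D_MIN_EXACT = 5         # minimum exact D match inside the junction


@dataclass
class Rearrangement:
    sequence_id: str
    locus: str
    v_call: list
    j_call: list
    d_call: list | None = None
    junction: str | None = None
    junction_aa: str | None = None
    cdr3: str | None = None
    productive: bool = False
    v_cassette: int | None = None
    j_cassette: int | None = None
    sample_id: str = ""
    sequence: str = ""

    def to_airr_dict(self) -> dict:
        return {
            "sequence_id": self.sequence_id,
            "sequence": self.sequence,
            "locus": self.locus,
            "v_call": self.v_call,
            "d_call": self.d_call,
            "j_call": self.j_call,
            "junction": self.junction,
            "junction_aa": self.junction_aa,
            "cdr3": self.cdr3,
            "productive": self.productive,
            "v_cassette": self.v_cassette,
            "j_cassette": self.j_cassette,
            "sample_id": self.sample_id,
        }


# ---------------------------------------------------------------------------
# read preprocessing
# ---------------------------------------------------------------------------

def sliding_window_trim(read: FastqRead, window: int = 4, qmin: int = 30, min_len: int = 50) -> FastqRead | None:
    """Trimmomatic-style sliding-window trim.

    Scans 5'->3' and cuts the read at the start of the first window whose
    mean quality falls below ``qmin``; reads shorter than ``min_len`` after
    trimming are dropped (None).
    """
    if len(read.seq) != len(read.qual):
        raise TRKitError(f"read {read.read_id!r}: sequence/quality length mismatch")
    q = np.asarray(read.qual, dtype=float)
    n = len(q)
    cut = n
    if n >= window:
        means = np.convolve(q, np.ones(window) / window, mode="valid")
        bad = np.nonzero(means < qmin)[0]
        if bad.size:
            cut = int(bad[0])
    elif q.mean() < qmin:
        cut = 0
    if cut < min_len:
        return None
    return FastqRead(read.read_id, read.seq[:cut], read.qual[:cut])


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: list[int]
    overlap: int
    mismatches: int


def merge_pairs(r1: FastqRead, r2: FastqRead, min_overlap: int = 20, max_mm: int = 8) -> MergedRead | None:
    """Merge a forward read with its reverse mate by best overlap.

    The admissible overlap maximizing agreement (fewest mismatches, ties to
    the longer overlap) is chosen among those with <= ``max_mm`` mismatches;
    base disagreements resolve toward the higher-quality base (ties to R1).
    Returns None when no admissible overlap exists.
    """
    rc2 = revcomp(r2.seq)
    q2 = r2.qual[::-1]
    a = np.frombuffer(r1.seq.encode(), dtype=np.uint8)
    b = np.frombuffer(rc2.encode(), dtype=np.uint8)
    n1, n2 = len(a), len(b)
    max_ov = min(n1, n2)

    candidates: list[tuple[int, int]] = []  # (mismatches, overlap)
    # fast path: anchor the R2 prefix exactly inside R1
    probe = rc2[: min(20, n2)]
    p = r1.seq.find(probe)
    while p != -1:
        ov = n1 - p
        if min_overlap <= ov <= max_ov:
            mm = int(np.count_nonzero(a[n1 - ov :] != b[:ov]))
            if mm <= max_mm:
                candidates.append((mm, ov))
        p = r1.seq.find(probe, p + 1)
    if not candidates:
        for ov in range(max_ov, min_overlap - 1, -1):
            mm = int(np.count_nonzero(a[n1 - ov :] != b[:ov]))
            if mm <= max_mm:
                candidates.append((mm, ov))
    if not candidates:
        return None
    mm, ov = min(candidates, key=lambda c: (c[0], -c[1]))

    seq = list(r1.seq[: n1 - ov])
    qual = list(r1.qual[: n1 - ov])
    for i in range(ov):
        c1, c2 = r1.seq[n1 - ov + i], rc2[i]
        q1v, q2v = r1.qual[n1 - ov + i], q2[i]
        if c1 == c2 or q1v >= q2v:
            seq.append(c1)
        else:
            seq.append(c2)
        qual.append(max(q1v, q2v))
    seq.extend(rc2[ov:])
    qual.extend(q2[ov:])
    return MergedRead(r1.read_id, "".join(seq), qual, ov, mm)


# ---------------------------------------------------------------------------
# gene assignment
# ---------------------------------------------------------------------------

@dataclass
class GeneAlignment:
    entry: GermlineEntry
    edit_distance: int
    target_start: int
    target_end: int  # half-open, in read coordinates


@dataclass
class AssignResult:
    v_call: list[str]
    j_call: list[str]
    d_call: list[str] | None
    v_best: GeneAlignment
    j_best: GeneAlignment


def _hw_align(query: str, target: str, max_k: int) -> dict:
    return edlib.align(query, target, mode="HW", task="locations", k=max_k)


def assign_genes(seq: str, germline: GermlineSet, locus: str, tie_margin: int = TIE_MARGIN) -> AssignResult | None:
    """Best V from the 5' part and best J from the 3' part of a merged read.

    All germline genes within ``tie_margin`` edits of the best score form
    the ambiguity call set (locus order). Reads failing the identity floors
    for either V or J are unassignable (None).
    """
    want_locus = None if locus == "TRA" else locus
    vs = [e for e in germline.of_type("V", want_locus) if len(e.nt_sequence) >= V_MIN_LEN]
    js = germline.of_type("J", want_locus)
    v_hits: list[GeneAlignment] = []
    for e in vs:
        k = int(len(e.nt_sequence) * (1 - V_MIN_IDENTITY)) + 1
        a = _hw_align(e.nt_sequence, seq, k)
        ed = a["editDistance"]
        if ed < 0 or (len(e.nt_sequence) - ed) / len(e.nt_sequence) < V_MIN_IDENTITY:
            continue
        st, en = a["locations"][0]
        v_hits.append(GeneAlignment(e, ed, st, en + 1))
    if not v_hits:
        return None
    best_v = min(v_hits, key=lambda h: h.edit_distance)
    v_set = [h for h in v_hits if h.edit_distance <= best_v.edit_distance + tie_margin]

    # J lives downstream of the V match; allow a little slack for overlap
    j_from = max(0, best_v.target_end - 6)
    region = seq[j_from:]
    j_hits: list[GeneAlignment] = []
    for e in js:
        if len(e.nt_sequence) < J_MIN_LEN:
            continue
        k = int(len(e.nt_sequence) * (1 - J_MIN_IDENTITY)) + 1
        a = _hw_align(e.nt_sequence, region, k)
        ed = a["editDistance"]
        if ed < 0 or (len(e.nt_sequence) - ed) / len(e.nt_sequence) < J_MIN_IDENTITY:
            continue
        st, en = a["locations"][0]
        j_hits.append(GeneAlignment(e, ed, j_from + st, j_from + en + 1))
    if not j_hits:
        return None
    best_j = min(j_hits, key=lambda h: h.edit_distance)
    j_set = [h for h in j_hits if h.edit_distance <= best_j.edit_distance + tie_margin]

    order = {e.name: i for i, e in enumerate(germline.entries)}
    v_call = sorted((h.entry.name for h in v_set), key=order.get)
    j_call = sorted((h.entry.name for h in j_set), key=order.get)
    return AssignResult(v_call=v_call, j_call=j_call, d_call=None, v_best=best_v, j_best=best_j)


def label_d(junction: str, germline: GermlineSet, locus: str, min_exact: int = D_MIN_EXACT) -> list[str] | None:
    """Best-effort D label: longest exact contiguous match (>= ``min_exact``)
    between the junction interior and any D gene; ties all reported."""
    if not junction or len(junction) <= 6:
        return None
    interior = junction[3:-3]
    best_len, best = 0, []
    for e in germline.of_type("D", None if locus == "TRA" else locus):
        d = e.nt_sequence
        longest = 0
        for i in range(len(interior)):
            for j in range(i + max(min_exact, longest + 1), len(interior) + 1):
                if interior[i:j] in d:
                    longest = j - i
                else:
                    break
        if longest >= min_exact:
            if longest > best_len:
                best_len, best = longest, [e.name]
            elif longest == best_len:
                best.append(e.name)
    return best or None


# ---------------------------------------------------------------------------
# junction extraction
# ---------------------------------------------------------------------------

def _map_query_positions(cigar: str, tstart: int, wanted: set[int]) -> dict[int, int]:
    """Map query positions to target positions through an edlib CIGAR
    ('=' 'X' consume both, 'I' query only, 'D' target only)."""
    out: dict[int, int] = {}
    qpos, tpos = 0, tstart
    for count, op in re.findall(r"(\d+)([=XIDM])", cigar):
        count = int(count)
        if op in ("=", "X", "M"):
            for w in wanted:
                if qpos <= w < qpos + count:
                    out[w] = tpos + (w - qpos)
            qpos += count
            tpos += count
        elif op == "I":
            qpos += count
        else:
            tpos += count
    return out


@dataclass
class JunctionResult:
    junction: str | None
    junction_aa: str | None
    cdr3: str | None
    productive: bool


def extract_junction(seq: str, v_best: GeneAlignment, j_best: GeneAlignment) -> JunctionResult:
    """Junction = cys-104 codon through the J-PHE/J-TRP-118 codon inclusive.

    Anchor codon positions are carried by the germline entries and mapped
    into read coordinates through the alignments. Productive requires an
    in-frame (length % 3 == 0), stop-free junction with both anchor
    residues (C ... F/W) present. CDR3 is the junction minus both anchors.
    """
    va, ja = v_best.entry.anchor_offset, j_best.entry.anchor_offset
    if va is None or ja is None:
        return JunctionResult(None, None, None, False)
    # V side: the 5' end of the V is never trimmed, so the cys-104 codon is
    # mapped through the alignment path from the start.
    av = edlib.align(v_best.entry.nt_sequence, seq, mode="HW", task="path")
    vmap = _map_query_positions(av["cigar"], av["locations"][0][0], {va})
    if va not in vmap:
        return JunctionResult(None, None, None, False)
    js = vmap[va]
    # J side: the 5' end IS trimmed (and an optimal alignment may absorb the
    # missing prefix into the N region), but the 3' end is intact, so the
    # J-PHE/TRP-118 codon end is fixed relative to the alignment end.
    j_len = len(j_best.entry.nt_sequence)
    je = j_best.target_end - (j_len - (ja + 3))
    if je <= js or je > len(seq):
        return JunctionResult(None, None, None, False)
    junction = seq[js:je]
    in_frame = len(junction) % 3 == 0
    aa = translate(junction) if in_frame else None
    productive = bool(
        in_frame and aa and "*" not in aa and aa[0] == "C" and aa[-1] in "FW"
    )
    cdr3 = junction[3:-3] if len(junction) > 6 else None
    return JunctionResult(junction, aa, cdr3, productive)


# ---------------------------------------------------------------------------
# sample-level pipeline
# ---------------------------------------------------------------------------

def process_sample(
    r1_reads: list[FastqRead],
    r2_reads: list[FastqRead],
    germline: GermlineSet,
    locus: str,
    sample_id: str = "s1",
    trim_window: int = 4,
    trim_quality: int = 30,
    min_len: int = 50,
    min_overlap: int = 20,
) -> tuple[list[Rearrangement], dict]:
    """Trim, merge, assign and extract for one paired-end library.

    Returns the assigned rearrangements plus counters for every attrition
    step. Deterministic given input order.
    """
    stats = {"pairs": len(r1_reads), "trimmed_out": 0, "unmerged": 0, "unassigned": 0, "assigned": 0}
    rearrangements: list[Rearrangement] = []
    for r1, r2 in zip(r1_reads, r2_reads):
        t1 = sliding_window_trim(r1, trim_window, trim_quality, min_len)
        t2 = sliding_window_trim(r2, trim_window, trim_quality, min_len)
        if t1 is None or t2 is None:
            stats["trimmed_out"] += 1
            continue
        merged = merge_pairs(t1, t2, min_overlap=min_overlap)
        if merged is None:
            stats["unmerged"] += 1
            continue
        assigned = assign_genes(merged.seq, germline, locus)
        if assigned is None:
            stats["unassigned"] += 1
            continue
        jr = extract_junction(merged.seq, assigned.v_best, assigned.j_best)
        d_call = label_d(jr.junction, germline, locus) if jr.junction else None
        v_entry, j_entry = assigned.v_best.entry, assigned.j_best.entry
        rearrangements.append(
            Rearrangement(
                sequence_id=r1.read_id,
                locus=j_entry.locus if locus == "TRA" else locus,
                v_call=assigned.v_call,
                j_call=assigned.j_call,
                d_call=d_call,
                junction=jr.junction,
                junction_aa=jr.junction_aa,
                cdr3=jr.cdr3,
                productive=jr.productive,
                v_cassette=v_entry.unit,
                j_cassette=j_entry.unit,
                sample_id=sample_id,
                sequence=merged.seq,
            )
        )
        stats["assigned"] += 1
    return rearrangements, stats


# ---------------------------------------------------------------------------
# usage statistics
# ---------------------------------------------------------------------------

@dataclass
class UsageTable:
    """Per-sample gene (or subgroup) usage with cross-sample quartiles."""

    frequencies: pd.DataFrame  # genes x samples, per-sample columns sum to 1
    summary: pd.DataFrame      # median/q1/q3 per gene, percent scale
    outliers: list = field(default_factory=list)  # (gene, sample, percent)


def _subgroup_of(name: str) -> str:
    base, _, tail = name.rpartition("-")
    return base if base and tail.isdigit() else name


def usage_stats(rearrangements: list[Rearrangement], level: str = "v", by: str = "gene") -> UsageTable:
    """Gene usage per sample with fractional splitting of ambiguous calls.

    ``level`` selects V or J calls; ``by`` aggregates per gene, per subgroup,
    or treats each ambiguity set as one merged category ("TRGJ2-2/TRGJ3-2"
    style). Per-sample frequencies sum to 1; cross-sample median and
    quartiles use linear interpolation, outliers lie beyond 1.5 IQR.
    """
    counts: dict[str, dict[str, float]] = {}
    for r in rearrangements:
        calls = r.v_call if level == "v" else r.j_call
        if not calls:
            continue
        sample = counts.setdefault(r.sample_id, {})
        if by == "merged":
            key = "/".join(calls)
            sample[key] = sample.get(key, 0.0) + 1.0
        else:
            for name in calls:
                key = _subgroup_of(name) if by == "subgroup" else name
                sample[key] = sample.get(key, 0.0) + 1.0 / len(calls)
    freq = pd.DataFrame(counts).fillna(0.0).sort_index()
    freq = freq / freq.sum(axis=0)
    med = freq.median(axis=1) * 100
    q1 = freq.quantile(0.25, axis=1) * 100
    q3 = freq.quantile(0.75, axis=1) * 100
    summary = pd.DataFrame({"median_pct": med, "q1_pct": q1, "q3_pct": q3})
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [
        (gene, sample, float(freq.loc[gene, sample] * 100))
        for gene in freq.index
        for sample in freq.columns
        if not lo[gene] <= freq.loc[gene, sample] * 100 <= hi[gene]
    ]
    return UsageTable(frequencies=freq, summary=summary, outliers=outliers)


# ---------------------------------------------------------------------------
# V-J pairing
# ---------------------------------------------------------------------------

@dataclass
class PairingResult:
    matrix: pd.DataFrame       # V (rows) x J (columns), chromosomal order
    intra_unit: float          # fractional counts with matching cassette
    inter_unit: float
    by_j_locus: dict           # fractional counts per J-gene locus (TRA/TRD)

    @property
    def intra_fraction(self) -> float:
        total = self.intra_unit + self.inter_unit
        return self.intra_unit / total if total else float("nan")


def pairing_matrix(rearrangements: list[Rearrangement], locus_map: LocusMap) -> PairingResult:
    """V x J pairing counts ordered by chromosomal gene order.

    Ambiguous calls contribute fractionally over the v x j cross product.
    Intra- vs inter-cassette classification uses the map's unit indices
    (never gene names); genes absent from the map are pooled under
    "unmapped". For nested TRA/TRD data the per-J-locus totals record how
    often V genes reached into each locus's J genes.
    """
    unit = {g.name: g.unit for g in locus_map.genes}
    locus_of = {g.name: g.locus for g in locus_map.genes}
    v_order = [g.name for g in locus_map.genes if g.gene_type == "V"]
    j_order = [g.name for g in locus_map.genes if g.gene_type == "J"]
    mat = pd.DataFrame(0.0, index=v_order + ["unmapped"], columns=j_order + ["unmapped"])
    intra = inter = 0.0
    by_j_locus: dict[str, float] = {}
    for r in rearrangements:
        if not r.v_call or not r.j_call:
            continue
        w = 1.0 / (len(r.v_call) * len(r.j_call))
        for v in r.v_call:
            vrow = v if v in mat.index else "unmapped"
            for j in r.j_call:
                jcol = j if j in mat.columns else "unmapped"
                mat.loc[vrow, jcol] += w
                vu, ju = unit.get(v), unit.get(j)
                if vu is not None and ju is not None:
                    if vu == ju:
                        intra += w
                    else:
                        inter += w
                jl = locus_of.get(j)
                if jl:
                    by_j_locus[jl] = by_j_locus.get(jl, 0.0) + w
    return PairingResult(matrix=mat, intra_unit=intra, inter_unit=inter, by_j_locus=by_j_locus)
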