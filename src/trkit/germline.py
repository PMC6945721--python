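"""Germline V/D/J/C gene discovery and IMGT-style classification.

Given a genomic locus sequence, this module locates candidate genes by
combining two signals: a position-specific log-odds profile over the coding
region (trained from any germline gene set) and a recombination-signal (RS)
hit with the configured heptamer/spacer/nonamer geometry. Candidates are
classified into the IMGT functionality classes

* ``F``   functional: intact coding region, anchors present, canonical RS;
* ``ORF`` open reading frame: coding frame intact but a non-canonical RS,
  a missing anchor or a missing splice site;
* ``P``   pseudogene: stop codon, frameshift, or a degenerate relic.

All coordinates are 0-based half-open on the forward strand; reverse-strand
genes carry forward-strand coordinates and a strand flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align

from ._seq import HYDROPHOBIC, revcomp, translate
from .io_formats import ConfigError, TRKitError, VALID_SPACERS
from .rs_profile import PWM, default_rs_pwms

# defect vocabulary
STOP_CODON = "STOP_CODON"
FRAMESHIFT = "FRAMESHIFT"
NONCANONICAL_RS = "NONCANONICAL_RS"
MISSING_ANCHOR = "MISSING_ANCHOR"
MISSING_SPLICE = "MISSING_SPLICE"
DEGENERATE = "DEGENERATE"

_PSEUDO_DEFECTS = {STOP_CODON, FRAMESHIFT, DEGENERATE}
_ORF_DEFECTS = {NONCANONICAL_RS, MISSING_ANCHOR, MISSING_SPLICE}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RSMotif:
    """One heptamer/spacer/nonamer triplet, stored gene-facing.

    The heptamer is always given in the orientation in which the canonical
    consensus reads CACAGTG, i.e. pointing away from the coding region; for a
    5' RS the scanned window on the forward strand is the reverse complement
    of nonamer+spacer+heptamer.
    """

    heptamer: str
    spacer: str
    nonamer: str
    side: str            # {"5p", "3p"}
    score: float
    canonical: bool
    offset: int = 0      # window start in the scanned sequence
    start: int = 0       # forward-strand genomic interval of the full RS
    end: int = 0

    @property
    def spacer_len(self) -> int:
        return len(self.spacer)


@dataclass
class VNumbering:
    """Map from V-REGION residue index to IMGT unique-numbering position.

    Framework regions have fixed spans (FR1 1-26, FR2 39-55, FR3 66-104);
    length variation is absorbed by gaps inside CDR1 (27-38) and CDR2
    (56-65), inserted at the top of each loop as IMGT prescribes. Anchors:
    1st-CYS 23, CONSERVED-TRP 41, hydrophobic 89, 2nd-CYS 104.
    """

    ok: bool
    cdr1_len: int = 0
    cdr2_len: int = 0
    positions: dict = field(default_factory=dict)  # seq index -> IMGT position
    anchors: dict = field(default_factory=dict)    # IMGT position -> present?
    n_trailing: int = 0

    REGIONS = {"FR1": (1, 26), "CDR1": (27, 38), "FR2": (39, 55), "CDR2": (56, 65), "FR3": (66, 104)}

    def imgt_of(self, seq_index: int):
        return self.positions.get(seq_index)


@dataclass
class GermlineGene:
    name: str
    locus: str
    gene_type: str                      # {"V", "D", "J", "C"}
    start: int
    end: int
    strand: str = "+"
    subgroup: str | None = None
    functionality: str = "F"
    defects: list = field(default_factory=list)
    rs_5p: RSMotif | None = None
    rs_3p: RSMotif | None = None
    exons: list = field(default_factory=list)   # forward-strand intervals, C genes
    nt_sequence: str = ""
    numbering: VNumbering | None = None
    score: float = 0.0
    unit: int | None = None             # cassette / D-J-C-cluster index (1-based)
    anchor_offset: int | None = None    # V: cys-104 codon start; J: F/W-118 codon start

    @property
    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# RS detection
# ---------------------------------------------------------------------------

def _encode(dna: str) -> np.ndarray:
    return np.frombuffer(dna.encode(), dtype=np.uint8)


def _code_array(dna: str) -> np.ndarray:
    arr = np.full(len(dna), 4, dtype=np.int8)
    raw = _encode(dna)
    for base, code in _BASE_CODE.items():
        arr[raw == ord(base)] = code
    return arr


def is_canonical_rs(heptamer: str, nonamer: str) -> bool:
    """Canonical flag: heptamer starts CAC and the nonamer keeps its poly-A
    tract (>= 5 adenines). Only the heptamer condition gates F vs ORF."""
    return heptamer.startswith("CAC") and nonamer.count("A") >= 5


def detect_rs(
    dna: str,
    side: str,
    spacer_len: int,
    pwm_pair: tuple[PWM, PWM] | None = None,
    min_score: float | None = None,
) -> list[RSMotif]:
    """Exhaustive scan for RS windows on the given (single-stranded) sequence.

    Every window is scored by the summed heptamer+nonamer PWM log-odds; hits
    at or above ``min_score`` (default: half the maximum attainable score)
    are returned sorted by descending score. ``side`` is the side of the RS
    relative to the gene it flanks: a 3' RS reads heptamer-spacer-nonamer on
    this strand, a 5' RS reads the reverse complement of that.
    """
    if spacer_len not in VALID_SPACERS:
        raise ConfigError(f"spacer length must be 12 or 23, got {spacer_len}")
    if side not in ("5p", "3p"):
        raise ConfigError(f"side must be '5p' or '3p', got {side!r}")
    hept_pwm, non_pwm = pwm_pair if pwm_pair is not None else default_rs_pwms()
    window = 16 + spacer_len
    if len(dna) < window:
        return []
    if min_score is None:
        min_score = 0.5 * (hept_pwm.max_score() + non_pwm.max_score())

    # vectorized sliding-window scoring; N and other ambiguity codes score 0
    codes = _code_array(dna)
    lo_h = np.hstack([hept_pwm.log_odds(), np.zeros((7, 1))])
    lo_n = np.hstack([non_pwm.log_odds(), np.zeros((9, 1))])
    n_win = len(dna) - window + 1
    scores = np.zeros(n_win)
    if side == "3p":
        h_off, n_off = 0, 7 + spacer_len
        for k in range(7):
            scores += lo_h[k, codes[h_off + k : h_off + k + n_win]]
        for k in range(9):
            scores += lo_n[k, codes[n_off + k : n_off + k + n_win]]
    else:
        # forward strand holds rc(nonamer)+rc(spacer)+rc(heptamer):
        # heptamer position j (gene-facing) sits at window offset
        # (window-1) - j complemented
        comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
        rc_codes = comp[codes]
        for k in range(7):
            scores += lo_h[k, rc_codes[window - 1 - k : window - 1 - k + n_win]]
        for k in range(9):
            scores += lo_n[k, rc_codes[8 - k : 8 - k + n_win]]

    hits = []
    for i in np.nonzero(scores >= min_score)[0]:
        w = dna[i : i + window]
        if side == "3p":
            hept, spacer, non = w[:7], w[7 : 7 + spacer_len], w[7 + spacer_len :]
        else:
            rc = revcomp(w)
            hept, spacer, non = rc[:7], rc[7 : 7 + spacer_len], rc[7 + spacer_len :]
        hits.append(
            RSMotif(
                heptamer=hept,
                spacer=spacer,
                nonamer=non,
                side=side,
                score=float(scores[i]),
                canonical=is_canonical_rs(hept, non),
                offset=int(i),
                start=int(i),
                end=int(i) + window,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.offset))
    return hits


# ---------------------------------------------------------------------------
# IMGT unique numbering of V-REGIONs
# ---------------------------------------------------------------------------

_MAX_CDR1, _MAX_CDR2 = 12, 10
_MAX_TRAILING = 8  # residues past position 104 (germline CDR3 contribution)


def _imgt_cdr_positions(first: int, last: int, n: int) -> list[int]:
    """Occupied IMGT positions of a CDR of length ``n`` inside [first, last]:
    filled from both ends, gaps at the top of the loop."""
    head = (n + 1) // 2
    tail = n // 2
    return list(range(first, first + head)) + list(range(last - tail + 1, last + 1))


def number_v_region(aa_seq: str) -> VNumbering:
    """Anchor-constrained IMGT numbering of a translated V-REGION.

    Enumerates CDR1/CDR2 lengths, scores each placement by the number of
    anchor residues it recovers (C23, W41, hydrophobic 89, C104), and keeps
    the best; ties prefer longer CDRs then shorter CDR1. Sequences whose
    length admits no monotone placement yield ``VNumbering(ok=False)``.
    """
    n = len(aa_seq)
    best = None
    for c1 in range(_MAX_CDR1 + 1):
        for c2 in range(_MAX_CDR2 + 1):
            total = 82 + c1 + c2
            if total > n or n - total > _MAX_TRAILING:
                continue
            anchors = {
                23: aa_seq[22] == "C",
                41: aa_seq[28 + c1] == "W",
                89: aa_seq[66 + c1 + c2] in HYDROPHOBIC,
                104: aa_seq[81 + c1 + c2] == "C",
            }
            key = (sum(anchors.values()), c1 + c2, -c1)
            if best is None or key > best[0]:
                best = (key, c1, c2, anchors)
    if best is None:
        return VNumbering(ok=False)
    _, c1, c2, anchors = best
    imgt = (
        list(range(1, 27))
        + _imgt_cdr_positions(27, 38, c1)
        + list(range(39, 56))
        + _imgt_cdr_positions(56, 65, c2)
        + list(range(66, 105))
    )
    positions = {i: p for i, p in enumerate(imgt)}
    return VNumbering(
        ok=True,
        cdr1_len=c1,
        cdr2_len=c2,
        positions=positions,
        anchors=anchors,
        n_trailing=n - (82 + c1 + c2),
    )


# ---------------------------------------------------------------------------
# position-specific gene-finding profiles
# ---------------------------------------------------------------------------

class VGeneProfile:
    """Per-length position-specific nucleotide log-odds profiles.

    Trained from a germline V set (functional and ORF genes); the acceptance
    threshold per length is mean(training self-scores) - 3 SD, falling back
    to 60% of the mean when fewer than three training sequences of that
    length exist. A lower "relic" threshold admits heavily degenerate
    pseudogenes when relic reporting is requested.
    """

    def __init__(self, pseudocount: float = 0.5, relic_fraction: float = 0.25):
        self.pseudocount = pseudocount
        self.relic_fraction = relic_fraction
        self.matrices: dict[int, np.ndarray] = {}
        self.thresholds: dict[int, float] = {}
        self.relic_thresholds: dict[int, float] = {}

    @property
    def lengths(self) -> list[int]:
        return sorted(self.matrices)

    @classmethod
    def train(cls, sequences: list[str], pseudocount: float = 0.5) -> "VGeneProfile":
        if not sequences:
            raise TRKitError("cannot train a profile from an empty sequence set")
        prof = cls(pseudocount=pseudocount)
        by_len: dict[int, list[str]] = {}
        for s in sequences:
            by_len.setdefault(len(s), []).append(s.upper())
        for length, seqs in by_len.items():
            counts = np.zeros((length, 4))
            for s in seqs:
                for i, c in enumerate(s):
                    j = _BASE_CODE.get(c)
                    if j is not None:
                        counts[i, j] += 1
            freqs = (counts + pseudocount) / (len(seqs) + 4 * pseudocount)
            prof.matrices[length] = np.log2(freqs / 0.25)
            self_scores = [prof.score(s) for s in seqs]
            mean = float(np.mean(self_scores))
            if len(seqs) >= 3:
                thr = mean - 3 * float(np.std(self_scores))
                thr = min(thr, 0.9 * mean)  # guard against zero-variance sets
            else:
                thr = 0.6 * mean
            prof.thresholds[length] = thr
            prof.relic_thresholds[length] = prof.relic_fraction * mean
        return prof

    def score(self, seq: str) -> float:
        lo = self.matrices.get(len(seq))
        if lo is None:
            raise TRKitError(f"no profile matrix for length {len(seq)}")
        lo_ext = np.hstack([lo, np.zeros((lo.shape[0], 1))])
        codes = _code_array(seq)
        return float(lo_ext[np.arange(len(seq)), codes].sum())


# ---------------------------------------------------------------------------
# scanners
# ---------------------------------------------------------------------------

def _forward_coords(start: int, end: int, strand: str, seq_len: int) -> tuple[int, int]:
    if strand == "+":
        return start, end
    return seq_len - end, seq_len - start


def _rs_forward(rs: RSMotif, strand: str, seq_len: int) -> RSMotif:
    import dataclasses as _dc

    out = _dc.replace(rs)
    if strand == "-":
        out.start, out.end = seq_len - rs.end, seq_len - rs.start
    return out


def scan_v_genes(
    locus_seq: str,
    v_profile: VGeneProfile,
    pwm_pair: tuple[PWM, PWM] | None = None,
    spacer_len: int = 23,
    locus_id: str = "TRG",
    report_relics: bool = False,
) -> list[GermlineGene]:
    """Find V genes: a profile-scoring coding segment immediately followed
    (3', coding strand) by an RS with the configured V spacer."""
    genes: list[GermlineGene] = []
    n = len(locus_seq)
    for strand in ("+", "-"):
        seq = locus_seq if strand == "+" else revcomp(locus_seq)
        for hit in detect_rs(seq, "3p", spacer_len, pwm_pair):
            best = None
            for length in v_profile.lengths:
                start = hit.offset - length
                if start < 0:
                    continue
                window = seq[start : hit.offset]
                score = v_profile.score(window)
                margin = score - v_profile.thresholds[length]
                relic_margin = score - v_profile.relic_thresholds[length]
                if margin >= 0:
                    cand = (margin, score, start, length, False)
                elif report_relics and relic_margin >= 0:
                    cand = (relic_margin, score, start, length, True)
                else:
                    continue
                if best is None or cand[0] > best[0]:
                    best = cand
            if best is None:
                continue
            _, score, start, length, is_relic = best
            window = seq[start : hit.offset]
            aa = translate(window)
            defects = []
            if is_relic:
                defects.append(DEGENERATE)
            if "*" in aa:
                defects.append(STOP_CODON)
            numbering = number_v_region(aa)
            if numbering.ok:
                if not all(numbering.anchors.values()):
                    defects.append(MISSING_ANCHOR)
            else:
                defects.append(MISSING_ANCHOR)
            if not hit.heptamer.startswith("CAC"):
                defects.append(NONCANONICAL_RS)
            fstart, fend = _forward_coords(start, hit.offset, strand, n)
            rs = _rs_forward(hit, strand, n)
            gene = GermlineGene(
                name="",
                locus=locus_id,
                gene_type="V",
                start=fstart,
                end=fend,
                strand=strand,
                defects=defects,
                rs_3p=rs,
                nt_sequence=window,
                numbering=numbering if numbering.ok else None,
                score=score,
            )
            if numbering.ok:
                cys_idx = 81 + numbering.cdr1_len + numbering.cdr2_len
                gene.anchor_offset = 3 * cys_idx
            classify_functionality(gene)
            genes.append(gene)
    return _dedup_overlaps(genes)


_FGXG = re.compile(r"[FW]G.G")

def _net_indel(cigar: str) -> int:
    """Net query-vs-target length change along an edlib CIGAR; a frameshift
    is a net indel not divisible by 3 (balanced I/D pairs are just paired
    substitutions in an optimal edit path)."""
    net = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", cigar):
        if op == "I":
            net += int(count)
        elif op == "D":
            net -= int(count)
    return net



def scan_j_genes(
    locus_seq: str,
    j_references: list[str],
    pwm_pair: tuple[PWM, PWM] | None = None,
    spacer_len: int = 12,
    locus_id: str = "TRG",
    max_identity_dist: float = 0.3,
) -> list[GermlineGene]:
    """Find J genes: a segment preceded (5') by an RS with the configured J
    spacer, carrying an FGXG-compatible frame anchored at the 3' end and
    terminating at a GT splice donor."""
    if not j_references:
        raise TRKitError("scan_j_genes requires at least one reference J sequence")
    refs = [r.upper() for r in j_references]
    lens = sorted({len(r) for r in refs})
    lmin, lmax = min(lens) - 1, max(lens) + 1
    genes: list[GermlineGene] = []
    n = len(locus_seq)
    for strand in ("+", "-"):
        seq = locus_seq if strand == "+" else revcomp(locus_seq)
        for hit in detect_rs(seq, "5p", spacer_len, pwm_pair):
            gstart = hit.offset + 16 + spacer_len
            candidates = []
            for require_donor in (True, False):
                for length in range(lmin, lmax + 1):
                    if gstart + length + 2 > len(seq):
                        continue
                    if require_donor and seq[gstart + length : gstart + length + 2] != "GT":
                        continue
                    window = seq[gstart : gstart + length]
                    aln = min(
                        (edlib.align(window, r, mode="NW", task="path") | {"_ref": r} for r in refs),
                        key=lambda a: a["editDistance"],
                    )
                    dist = aln["editDistance"] / max(length, len(aln["_ref"]))
                    if dist <= max_identity_dist:
                        candidates.append((aln["editDistance"], length, window, aln, require_donor))
                if candidates:
                    break
            if not candidates:
                continue
            ed, length, window, aln, has_donor = min(candidates, key=lambda c: (c[0], -c[1]))
            defects = []
            if not has_donor:
                defects.append(MISSING_SPLICE)
            has_indel = _net_indel(aln["cigar"]) % 3 != 0
            # frame anchored at the 3' end: codons must close at the gene end
            frame_start = length % 3
            aa3 = translate(window[frame_start:])
            m = _FGXG.search(aa3)
            if "*" in aa3:
                defects.append(STOP_CODON)
            if m is None:
                found_other = any(_FGXG.search(translate(window[f:])) for f in range(3) if f != frame_start)
                defects.append(FRAMESHIFT if (found_other or has_indel) else MISSING_ANCHOR)
            elif has_indel:
                defects.append(FRAMESHIFT)
            if not hit.heptamer.startswith("CAC"):
                defects.append(NONCANONICAL_RS)
            fstart, fend = _forward_coords(gstart, gstart + length, strand, n)
            rs = _rs_forward(hit, strand, n)
            gene = GermlineGene(
                name="",
                locus=locus_id,
                gene_type="J",
                start=fstart,
                end=fend,
                strand=strand,
                defects=defects,
                rs_5p=rs,
                nt_sequence=window,
                score=-float(ed),
            )
            if m is not None:
                gene.anchor_offset = frame_start + 3 * m.start()
            classify_functionality(gene)
            genes.append(gene)
    return _dedup_overlaps(genes)


def scan_d_genes(
    locus_seq: str,
    pwm_pair: tuple[PWM, PWM] | None = None,
    spacer_5p: int = 12,
    spacer_3p: int = 23,
    locus_id: str = "TRB",
    min_len: int = 8,
    max_len: int = 25,
) -> list[GermlineGene]:
    """Find D genes: a short segment flanked by a 5' RS and a 3' RS whose
    spacer lengths satisfy the configured 12/23 pairing."""
    genes: list[GermlineGene] = []
    n = len(locus_seq)
    for strand in ("+", "-"):
        seq = locus_seq if strand == "+" else revcomp(locus_seq)
        hits5 = detect_rs(seq, "5p", spacer_5p, pwm_pair)
        hits3 = detect_rs(seq, "3p", spacer_3p, pwm_pair)
        starts3 = sorted((h.offset, h) for h in hits3)
        for h5 in hits5:
            gstart = h5.offset + 16 + spacer_5p
            for off3, h3 in starts3:
                length = off3 - gstart
                if length < min_len:
                    continue
                if length > max_len:
                    break
                defects = []
                if not (h5.heptamer.startswith("CAC") and h3.heptamer.startswith("CAC")):
                    defects.append(NONCANONICAL_RS)
                fstart, fend = _forward_coords(gstart, off3, strand, n)
                gene = GermlineGene(
                    name="",
                    locus=locus_id,
                    gene_type="D",
                    start=fstart,
                    end=fend,
                    strand=strand,
                    defects=defects,
                    rs_5p=_rs_forward(h5, strand, n),
                    rs_3p=_rs_forward(h3, strand, n),
                    nt_sequence=seq[gstart:off3],
                    score=h5.score + h3.score,
                )
                classify_functionality(gene)
                genes.append(gene)
    return _dedup_overlaps(genes)


def scan_c_genes(
    locus_seq: str,
    c_reference_exons: list[str],
    locus_id: str = "TRG",
    max_dist: float = 0.3,
    intron_window: int = 3000,
    max_copies: int = 50,
) -> list[GermlineGene]:
    """Locate constant genes by local similarity to a reference exon set.

    All copies of the first exon are found by iterated masked search; each
    anchor is extended exon by exon, requiring canonical GT/AG intron
    boundaries. An indel within any exon is a frameshift, a stop codon in
    the spliced frame marks a pseudogene.
    """
    if not c_reference_exons:
        raise TRKitError("scan_c_genes requires reference exon sequences")
    refs = [r.upper() for r in c_reference_exons]
    genes: list[GermlineGene] = []
    n = len(locus_seq)
    for strand in ("+", "-"):
        seq = locus_seq if strand == "+" else revcomp(locus_seq)
        masked = list(seq)
        for _ in range(max_copies):
            aln = edlib.align(refs[0], "".join(masked), mode="HW", task="locations")
            if aln["editDistance"] < 0 or aln["editDistance"] / len(refs[0]) > max_dist:
                break
            st, en = aln["locations"][0]
            en += 1
            for i in range(st, en):
                masked[i] = "N"
            exons = [(st, en)]
            defects: list[str] = []
            ok = True
            prev_end = en
            for ref in refs[1:]:
                # nearest acceptable match, not best-in-window: the next copy
                # of this C gene may lie within the search window
                a = None
                hit_off = prev_end
                step = 400
                for off in range(prev_end, min(len(seq), prev_end + intron_window), step):
                    sub = seq[off : off + step + len(ref)]
                    cand = edlib.align(ref, sub, mode="HW", task="path")
                    if cand["editDistance"] >= 0 and cand["editDistance"] / len(ref) <= max_dist:
                        a, hit_off = cand, off
                        break
                if a is None:
                    ok = False
                    break
                est, een = a["locations"][0]
                est, een = hit_off + est, hit_off + een + 1
                intron = seq[prev_end:est]
                if not (intron.startswith("GT") and intron.endswith("AG")):
                    defects.append(MISSING_SPLICE)
                if _net_indel(a["cigar"]) % 3 != 0:
                    defects.append(FRAMESHIFT)
                exons.append((est, een))
                prev_end = een
            if not ok:
                continue
            # indel check for the first exon as well
            a0 = edlib.align(refs[0], seq[exons[0][0] : exons[0][1]], mode="NW", task="path")
            if _net_indel(a0["cigar"]) % 3 != 0:
                defects.insert(0, FRAMESHIFT)
            spliced = "".join(seq[s:e] for s, e in exons)
            if "*" in translate(spliced)[:-1]:
                defects.append(STOP_CODON)
            fcoords = [_forward_coords(s, e, strand, n) for s, e in exons]
            fstart = min(s for s, _ in fcoords)
            fend = max(e for _, e in fcoords)
            gene = GermlineGene(
                name="",
                locus=locus_id,
                gene_type="C",
                start=fstart,
                end=fend,
                strand=strand,
                defects=sorted(set(defects), key=defects.index),
                exons=sorted(fcoords),
                nt_sequence=spliced,
            )
            classify_functionality(gene)
            genes.append(gene)
    return _dedup_overlaps(genes)


def _dedup_overlaps(genes: list[GermlineGene]) -> list[GermlineGene]:
    """Drop lower-scoring candidates overlapping a better one by > 50%."""
    kept: list[GermlineGene] = []
    for g in sorted(genes, key=lambda g: (-g.score, g.start)):
        span = g.end - g.start
        clash = any(
            min(g.end, k.end) - max(g.start, k.start) > 0.5 * min(span, k.end - k.start)
            for k in kept
        )
        if not clash:
            kept.append(g)
    kept.sort(key=lambda g: g.start)
    return kept


# ---------------------------------------------------------------------------
# functionality
# ---------------------------------------------------------------------------

def classify_functionality(gene: GermlineGene) -> str:
    """IMGT functionality from the defect list (pure in the defects; idempotent).

    Pseudogene defects take precedence over ORF defects: a gene is P on any
    stop codon, frameshift or degeneracy; otherwise ORF on a non-canonical
    RS, missing anchor or missing splice; otherwise F.
    """
    defects = set(gene.defects)
    if defects & _PSEUDO_DEFECTS:
        gene.functionality = "P"
    elif defects & _ORF_DEFECTS:
        gene.functionality = "ORF"
    else:
        gene.functionality = "F"
    return gene.functionality


# ---------------------------------------------------------------------------
# identity and subgroups
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -1
_aligner.open_end_gap_score = 0
_aligner.extend_end_gap_score = 0


def pairwise_identity(a: str, b: str) -> float:
    """Percent nucleotide identity under an end-gap-free global alignment.

    Identity = matches / aligned columns, where columns inside terminal gap
    runs of either sequence are excluded; reported to 0.1.
    """
    if not a or not b:
        raise TRKitError("pairwise_identity requires non-empty sequences")
    aln = _aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    lead = 0
    while ga[lead] == "-" or gb[lead] == "-":
        lead += 1
    trail = len(ga)
    while ga[trail - 1] == "-" or gb[trail - 1] == "-":
        trail -= 1
    cols = trail - lead
    if cols <= 0:
        raise TRKitError("alignment has no internal columns")
    matches = sum(1 for x, y in zip(ga[lead:trail], gb[lead:trail]) if x == y and x != "-")
    return round(100.0 * matches / cols, 1)


def assign_subgroups(v_genes: list[GermlineGene], threshold: float = 75.0) -> list[list[GermlineGene]]:
    """Single-linkage clustering of V-REGIONs at ``threshold``% identity.

    Subgroups are numbered by the locus position of their 5'-most member;
    genes in multimember subgroups get a ``-k`` member index in locus
    coordinate order. Degenerate relic pseudogenes never enter numeric
    subgroups: they are named with letter suffixes instead.
    """
    ordered = sorted(v_genes, key=lambda g: g.start)
    relics = [g for g in ordered if DEGENERATE in g.defects]
    core = [g for g in ordered if DEGENERATE not in g.defects]
    parent = list(range(len(core)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            ident = pairwise_identity(core[i].nt_sequence, core[j].nt_sequence)
            if ident > threshold or ident >= 100.0:
                parent[find(i)] = find(j)

    clusters: dict[int, list[GermlineGene]] = {}
    for i, g in enumerate(core):
        clusters.setdefault(find(i), []).append(g)
    groups = sorted(clusters.values(), key=lambda grp: min(g.start for g in grp))
    locus = v_genes[0].locus if v_genes else "TR?"
    for k, grp in enumerate(groups, start=1):
        subgroup = f"{locus}V{k}"
        grp.sort(key=lambda g: g.start)
        for m, g in enumerate(grp, start=1):
            g.subgroup = subgroup
            g.name = subgroup if len(grp) == 1 else f"{subgroup}-{m}"
    for i, g in enumerate(relics):
        g.subgroup = None
        g.name = f"{locus}V{chr(65 + i)}"
    return groups + [[g] for g in relics]


# ---------------------------------------------------------------------------
# locus map
# ---------------------------------------------------------------------------

@dataclass
class LocusMap:
    locus_id: str
    genes: list[GermlineGene]
    units: dict = field(default_factory=dict)   # unit index -> gene names
    warnings: list = field(default_factory=list)

    def unit_of(self, gene_name: str) -> int | None:
        for g in self.genes:
            if g.name == gene_name:
                return g.unit
        return None

    def summary(self):
        """Per gene-type x functionality tally (Table-1 style)."""
        import pandas as pd

        rows = [{"gene_type": g.gene_type, "functionality": g.functionality, "locus": g.locus} for g in self.genes]
        df = pd.DataFrame(rows)
        if df.empty:
            return df
        return df.groupby(["locus", "gene_type", "functionality"]).size().rename("count").reset_index()

    def to_gff_entries(self) -> list[dict]:
        entries = []
        for g in self.genes:
            attrs = {
                "Name": g.name,
                "gene_type": g.gene_type,
                "functionality": g.functionality,
            }
            if g.subgroup:
                attrs["subgroup"] = g.subgroup
            if g.unit is not None:
                attrs["unit"] = g.unit
            if g.defects:
                attrs["defects"] = "|".join(g.defects)
            entries.append(
                {
                    "seqid": self.locus_id,
                    "type": "gene",
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "attrs": attrs,
                }
            )
            for rs, side in ((g.rs_5p, "5p"), (g.rs_3p, "3p")):
                if rs is not None and rs.end > rs.start:
                    entries.append(
                        {
                            "seqid": self.locus_id,
                            "type": "recombination_signal",
                            "start": rs.start,
                            "end": rs.end,
                            "strand": g.strand,
                            "attrs": {
                                "Name": f"{g.name}-RS-{side}",
                                "side": side,
                                "spacer": rs.spacer_len,
                                "canonical": str(rs.canonical).lower(),
                            },
                        }
                    )
            for i, (s, e) in enumerate(g.exons, start=1):
                entries.append(
                    {
                        "seqid": self.locus_id,
                        "type": "exon",
                        "start": s,
                        "end": e,
                        "strand": g.strand,
                        "attrs": {"Name": f"{g.name}-EX{i}"},
                    }
                )
        return entries


def build_locus_map(genes: list[GermlineGene], locus_id: str) -> LocusMap:
    """Order genes along the locus and assign cassette / cluster units.

    TRG: the cassette index increments at each V gene that opens a new
    V-J-(J)-C unit (i.e. the first V after a C). TRB/TRD: the D-J-C-cluster
    index increments at each D gene; V genes sit outside clusters (an
    inverted V after the last C stays unitless). The nested TRA/TRD case is
    handled per gene ``locus`` field: the embedded TRD block follows the
    cluster rule, TRA J/C genes form a single terminal J-C unit.
    """
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    warnings: list[str] = []
    if locus_id == "TRG":
        # A cassette reads V..J..C transcriptionally; on the forward strand an
        # inverted cassette therefore reads C..J..V, so the opening gene of a
        # new unit is a V on '+' or a C on '-', once the previous unit holds
        # both a V and a C.
        current = 0
        has_v = has_c = True  # so that the very first opener starts unit 1
        for g in ordered:
            opens = (g.gene_type == "V" and g.strand == "+") or (
                g.gene_type == "C" and g.strand == "-"
            )
            if opens and has_v and has_c:
                current += 1
                has_v = has_c = False
            if g.gene_type == "V":
                has_v = True
            elif g.gene_type == "C":
                has_c = True
            if current == 0 and g.gene_type in ("J", "C"):
                warnings.append(f"{g.gene_type} gene at {g.start} precedes any cassette")
                g.unit = None
            else:
                g.unit = current if current else None
    else:
        # D-J-C-cluster loci (TRB, TRD, and the TRD block inside TRA/TRD)
        current: dict[str, int] = {}
        for g in ordered:
            loc = g.locus
            if g.gene_type == "D":
                current[loc] = current.get(loc, 0) + 1
            if g.gene_type == "V":
                g.unit = None
            elif g.gene_type in ("J", "C"):
                if loc == "TRA":
                    g.unit = 1  # single terminal J-C unit
                elif current.get(loc, 0) == 0:
                    warnings.append(f"{g.gene_type} gene at {g.start} precedes any {loc} cluster")
                    g.unit = None
                else:
                    g.unit = current[loc]
            elif g.gene_type == "D":
                g.unit = current[loc]

    _name_non_v(ordered, locus_id)
    units: dict[int, list[str]] = {}
    for g in ordered:
        if g.unit is not None:
            units.setdefault(g.unit, []).append(g.name)
    return LocusMap(locus_id=locus_id, genes=ordered, units=units, warnings=warnings)


def _name_non_v(ordered: list[GermlineGene], locus_id: str) -> None:
    """Name J genes by unit and within-unit rank, C and D genes by unit."""
    per_unit_j: dict[tuple[str, int | None], int] = {}
    c_count: dict[str, int] = {}
    seq_j: dict[str, int] = {}
    for g in ordered:
        if g.name:
            continue
        loc = g.locus
        if g.gene_type == "J":
            if loc == "TRA":
                seq_j[loc] = seq_j.get(loc, 0) + 1
                g.name = f"{loc}J{seq_j[loc]}"
            else:
                key = (loc, g.unit)
                per_unit_j[key] = per_unit_j.get(key, 0) + 1
                g.name = f"{loc}J{g.unit}-{per_unit_j[key]}" if g.unit else f"{loc}J?{per_unit_j[key]}"
        elif g.gene_type == "C":
            c_count[loc] = c_count.get(loc, 0) + 1
            g.name = f"{loc}C{g.unit}" if (g.unit and locus_id != "TRA") else f"{loc}C"
        elif g.gene_type == "D":
            g.name = f"{loc}D{g.unit}"


# ---------------------------------------------------------------------------
# top-level annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationReference:
    """Training material for the scanners: germline V sequences for the
    profile, reference J sequences, reference C exons and RS PWMs."""

    v_sequences: list[str]
    j_sequences: list[str]
    c_exons: list[str]
    pwm_pair: tuple[PWM, PWM] | None = None


def annotate_locus(
    locus_seq: str,
    reference: AnnotationReference,
    locus_id: str = "TRG",
    spacer_policy: dict | None = None,
    with_d: bool | None = None,
    identity_threshold: float = 75.0,
    report_relics: bool = False,
) -> LocusMap:
    """Run all scanners over a locus and assemble the named, classified map."""
    from .io_formats import DEFAULT_SPACER_POLICY

    policy = dict(DEFAULT_SPACER_POLICY)
    if spacer_policy:
        policy.update(spacer_policy)
    if with_d is None:
        # TRB and TRD carry D genes; a nested TRA/TRD locus is annotated
        # under TRA and still holds the embedded TRD cluster's D genes
        with_d = locus_id != "TRG"
    profile = VGeneProfile.train(reference.v_sequences)
    genes = scan_v_genes(
        locus_seq, profile, reference.pwm_pair, policy["V"], locus_id, report_relics=report_relics
    )
    genes += scan_j_genes(locus_seq, reference.j_sequences, reference.pwm_pair, policy["J"], locus_id)
    if with_d:
        genes += scan_d_genes(locus_seq, reference.pwm_pair, policy["D5"], policy["D3"], locus_id)
    if reference.c_exons:
        genes += scan_c_genes(locus_seq, reference.c_exons, locus_id)
    assign_subgroups([g for g in genes if g.gene_type == "V"], identity_threshold)
    return build_locus_map(genes, locus_id)


# ---------------------------------------------------------------------------
# germline directory container
# ---------------------------------------------------------------------------

@dataclass
class GermlineEntry:
    name: str
    gene_type: str
    locus: str
    functionality: str
    nt_sequence: str
    unit: int | None = None
    anchor_offset: int | None = None


class GermlineSet:
    """Directory of germline gene sequences used by the repertoire stage.

    Carries, per gene, the sequence plus the metadata the pipeline needs:
    functionality (only F/ORF genes rearrange), cassette/cluster unit, and
    the junction anchor offset (cys-104 codon start for V genes, the
    J-PHE/J-TRP-118 codon start for J genes).
    """

    def __init__(self, entries: list[GermlineEntry]):
        self.entries = list(entries)
        self.by_name = {e.name: e for e in self.entries}
        if len(self.by_name) != len(self.entries):
            raise TRKitError("duplicate gene names in germline set")

    def __len__(self) -> int:
        return len(self.entries)

    def of_type(self, gene_type: str, locus: str | None = None) -> list[GermlineEntry]:
        return [
            e
            for e in self.entries
            if e.gene_type == gene_type and (locus is None or e.locus == locus)
        ]

    def eligible(self, gene_type: str, locus: str | None = None) -> list[GermlineEntry]:
        """Genes that can appear in rearrangements: functionality F or ORF."""
        return [e for e in self.of_type(gene_type, locus) if e.functionality in ("F", "ORF")]

    @classmethod
    def from_genes(cls, genes: list[GermlineGene]) -> "GermlineSet":
        entries = [
            GermlineEntry(
                name=g.name,
                gene_type=g.gene_type,
                locus=g.locus,
                functionality=g.functionality,
                nt_sequence=g.nt_sequence,
                unit=g.unit,
                anchor_offset=g.anchor_offset,
            )
            for g in genes
        ]
        return cls(entries)

    @classmethod
    def from_fasta(cls, path) -> "GermlineSet":
        from .io_formats import read_germline_fasta

        entries = []
        for rec in read_germline_fasta(path):
            entries.append(
                GermlineEntry(
                    name=rec["name"],
                    gene_type=rec.get("type", "?"),
                    locus=rec.get("locus", "?"),
                    functionality=rec.get("functionality", "F"),
                    nt_sequence=rec["nt_sequence"],
                    unit=rec.get("unit"),
                    anchor_offset=rec.get("anchor"),
                )
            )
        return cls(entries)


def genes_from_gff3(gff3_path, locus_fasta_path) -> list[GermlineGene]:
    """Rebuild annotated genes (with RS element strings) from a GFF3 + locus
    FASTA pair, as written by the annotation stage."""
    from .io_formats import read_fasta, read_gff3

    seq = read_fasta(locus_fasta_path)[0][1]
    feats = read_gff3(gff3_path)
    genes: dict[str, GermlineGene] = {}
    for f in feats:
        if f["type"] != "gene":
            continue
        a = f["attrs"]
        name = a.get("Name", "?")
        strand = f["strand"]
        nt = seq[f["start"] : f["end"]]
        if strand == "-":
            nt = revcomp(nt)
        genes[name] = GermlineGene(
            name=name,
            locus=f["seqid"],
            gene_type=a.get("gene_type", "?"),
            start=f["start"],
            end=f["end"],
            strand=strand,
            subgroup=a.get("subgroup"),
            functionality=a.get("functionality", "F"),
            defects=a.get("defects", "").split("|") if a.get("defects") else [],
            nt_sequence=nt,
            unit=int(a["unit"]) if "unit" in a else None,
        )
    for f in feats:
        if f["type"] != "recombination_signal":
            continue
        a = f["attrs"]
        name, _, side_tag = a.get("Name", "").rpartition("-RS-")
        if name not in genes:
            continue
        g = genes[name]
        window = seq[f["start"] : f["end"]]
        if g.strand == "-":
            window = revcomp(window)
        spacer_len = int(a.get("spacer", len(window) - 16))
        if side_tag == "3p":
            hept, spacer, non = window[:7], window[7 : 7 + spacer_len], window[7 + spacer_len :]
        else:
            rc = revcomp(window)
            hept, spacer, non = rc[:7], rc[7 : 7 + spacer_len], rc[7 + spacer_len :]
        motif = RSMotif(
            heptamer=hept,
            spacer=spacer,
            nonamer=non,
            side=side_tag,
            score=0.0,
            canonical=is_canonical_rs(hept, non),
            start=f["start"],
            end=f["end"],
        )
        if side_tag == "3p":
            g.rs_3p = motif
        else:
            g.rs_5p = motif
    return sorted(genes.values(), key=lambda g: g.start)
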