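"""Synthetic V(D)J locus and repertoire simulator.

Builds ground-truth T-cell-receptor loci (cassette-organized TRG-style,
D-J-C-cluster TRB-style, or nested TRA/TRD-style) with planted genes and
recombination signals, then simulates 5'RACE-style rearranged amplicons and
paired-end reads from them:

* gene usage follows a configurable distribution over functional (F/ORF)
  V and J genes, with an optional intra-cassette preference;
* exonucleolytic trimming of the V 3' and J 5' ends is geometric;
* non-templated (N) nucleotide insertion by TdT is Poisson-length;
* sequencing errors are per-base substitutions at a configurable rate.

Everything is driven by a single seeded NumPy generator: the same seed
yields bitwise-identical loci, amplicons and FASTQ records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._seq import revcomp, translate
from .germline import (
    DEGENERATE,
    FRAMESHIFT,
    NONCANONICAL_RS,
    STOP_CODON,
    GermlineGene,
    GermlineSet,
    LocusMap,
    RSMotif,
    build_locus_map,
    is_canonical_rs,
    number_v_region,
)
from .io_formats import ConfigError, FastqRead
from .rs_profile import PWM, consensus_pwm

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

#: codons per amino acid (standard table, stops excluded)
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
_AA_CHOICES = sorted(_CODONS_FOR)

#: template-switch adapter prefixed to every 5'RACE amplicon
TS_ADAPTER = "AAGCAGTGGTATCAACGCAG"


# ---------------------------------------------------------------------------
# generating RS model
# ---------------------------------------------------------------------------

def rs_generating_pwms() -> tuple[PWM, PWM]:
    """The frequencies the simulator draws V/J RS elements from.

    The first three heptamer nucleotides (CAC) and the nonamer poly-A tract
    are invariant, as in functional recombination signals; heptamer
    positions 5 and 7 and the last nonamer position carry most of the
    variability.
    """
    hept = consensus_pwm("CACAGTG", "HEPTAMER", strong=1.0)
    hept.freqs = hept.freqs.copy()
    for pos, strong in ((4, 0.80), (6, 0.80)):
        col = np.full(4, (1 - strong) / 3)
        col["ACGT".index("CACAGTG"[pos])] = strong
        hept.freqs[pos] = col
    non = consensus_pwm("ACAAAAACC", "NONAMER", strong=1.0)
    non.freqs = non.freqs.copy()
    col = np.full(4, (1 - 0.75) / 3)
    col["ACGT".index("C")] = 0.75
    non.freqs[8] = col
    for pwm in (hept, non):
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(pwm.freqs > 0, pwm.freqs * np.log2(pwm.freqs), 0.0)
        pwm.info_content = 2.0 + plogp.sum(axis=1)
    return hept, non


def sample_from_pwm(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=pwm.freqs[i] / pwm.freqs[i].sum())] for i in range(pwm.length))


def sample_rs_set(element: str, n: int, seed: int) -> list[str]:
    """Draw ``n`` heptamers or nonamers from the generating model."""
    hept, non = rs_generating_pwms()
    pwm = hept if "HEPTAMER" in element else non
    rng = np.random.default_rng(seed)
    return [sample_from_pwm(pwm, rng) for _ in range(n)]


# ---------------------------------------------------------------------------
# random coding sequence helpers
# ---------------------------------------------------------------------------

def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _aa_to_nt(aa_seq: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_FOR[a][rng.integers(0, len(_CODONS_FOR[a]))] for a in aa_seq)


def _rand_aa(rng: np.random.Generator, n: int, forbid: str = "CW*") -> str:
    choices = [a for a in _AA_CHOICES if a not in forbid]
    return "".join(choices[i] for i in rng.integers(0, len(choices), n))


def _mutate_coding(nt: str, rate: float, rng: np.random.Generator, protected: set[int]) -> str:
    """Substitute bases at ``rate`` outside ``protected`` positions, then
    revert any codon the mutations turned into a stop."""
    seq = list(nt)
    for i in range(len(seq)):
        if i in protected or rng.random() >= rate:
            continue
        seq[i] = BASES[(BASES.index(seq[i]) + 1 + rng.integers(0, 3)) % 4]
    for c in range(len(seq) // 3):
        codon = "".join(seq[3 * c : 3 * c + 3])
        orig = nt[3 * c : 3 * c + 3]
        if codon in _STOPS and orig not in _STOPS:
            seq[3 * c : 3 * c + 3] = list(orig)
    return "".join(seq)


# ---------------------------------------------------------------------------
# blueprints
# ---------------------------------------------------------------------------

@dataclass
class UnitPlan:
    """One cassette (TRG) or D-J-C-cluster (TRB/TRD)."""

    j_plan: list[str]            # functionality per J gene, in order
    c_plan: str | None = "F"     # functionality of the C gene, None = absent
    d_plan: str | None = None    # functionality of the D gene, None = absent


@dataclass
class LocusBlueprint:
    """Ground-truth layout of a synthetic locus.

    ``v_order`` lists the planted subgroup index of each V gene in locus
    order; ``v_func`` the planned functionality of each. Cassette layouts
    place ``v_per_unit[k]`` consecutive V genes at the head of unit k+1;
    cluster layouts put all V genes upstream of the clusters.
    """

    locus_id: str = "TRG"
    layout: str = "cassette"                 # cassette | djc | trad
    subgroup_sizes: list[int] = field(default_factory=list)
    v_order: list[int] = field(default_factory=list)
    v_func: list[str] = field(default_factory=list)
    v_locus: list[str] | None = None         # per-V locus tag (trad layout)
    v_per_unit: list[int] = field(default_factory=list)
    units: list[UnitPlan] = field(default_factory=list)
    inverted_units: list[int] = field(default_factory=list)
    inverted_v_tail: str | None = None       # functionality of a 3' inverted V
    inverted_v_tail_locus: str | None = None
    tra_j_plan: list[str] = field(default_factory=list)  # trad layout only
    tra_c_plan: str | None = None
    c_exon_lengths: list[int] = field(default_factory=lambda: [90, 51, 75])
    n_relics: int = 0
    mutation_rate: float = 0.0               # extra noise over the whole locus
    member_divergence: float = 0.06
    j_divergence: float = 0.15
    c_divergence: float = 0.04
    relic_divergence: float = 0.30

    def __post_init__(self) -> None:
        if self.layout not in ("cassette", "djc", "trad"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        if len(self.v_order) != len(self.v_func):
            raise ConfigError("v_order and v_func must have equal length")
        if self.layout == "cassette":
            if any(u.d_plan for u in self.units):
                raise ConfigError(f"D genes are not allowed in a {self.locus_id} cassette layout")
            if sum(self.v_per_unit) != len(self.v_order):
                raise ConfigError("v_per_unit must partition v_order")
            if len(self.v_per_unit) != len(self.units):
                raise ConfigError("one v_per_unit entry per unit required")
        if max(self.v_order, default=-1) >= len(self.subgroup_sizes):
            raise ConfigError("v_order references an unknown subgroup")


def default_trg_blueprint() -> LocusBlueprint:
    """Five V-J-(J)-C cassettes, 12 V genes in 6 subgroups (two of size 4),
    half the V genes pseudogenized — the cassette organization and the
    functionality mix of a feline-style TRG locus."""
    return LocusBlueprint(
        locus_id="TRG",
        layout="cassette",
        subgroup_sizes=[4, 4, 1, 1, 1, 1],
        v_order=[0, 0, 0, 0, 1, 1, 1, 1, 2, 3, 4, 5],
        v_func=["F", "F", "F", "F", "F", "P", "P", "P", "F", "P", "P", "P"],
        v_per_unit=[4, 2, 2, 2, 2],
        units=[
            UnitPlan(j_plan=["P", "F"]),
            UnitPlan(j_plan=["P", "F"]),
            UnitPlan(j_plan=["ORF", "F"]),
            UnitPlan(j_plan=["P", "F"]),
            UnitPlan(j_plan=["ORF", "P"], c_plan="P"),
        ],
    )


def default_trb_blueprint() -> LocusBlueprint:
    """A V array followed by two D-J-C clusters of one D, six J and one
    four-exon C each, plus a 3' inverted V — TRB-style organization."""
    return LocusBlueprint(
        locus_id="TRB",
        layout="djc",
        subgroup_sizes=[4, 2, 2, 1, 1, 1, 1, 1],
        v_order=[0, 0, 0, 0, 1, 1, 2, 2, 3, 4, 5, 6],
        v_func=["F", "F", "F", "P", "F", "F", "F", "P", "F", "ORF", "P", "F"],
        units=[
            UnitPlan(j_plan=["F", "F", "P", "F", "ORF", "F"], c_plan="F", d_plan="F"),
            UnitPlan(j_plan=["F", "F", "F", "P", "F", "F"], c_plan="F", d_plan="F"),
        ],
        inverted_v_tail="F",
        c_exon_lengths=[90, 51, 75, 30],
    )


def default_trad_blueprint() -> LocusBlueprint:
    """Nested TRA/TRD: TRA and TRD V genes intermingled, an embedded TRD
    D-J-C cluster with a 3' inverted TRDV, then the TRA J array and TRAC."""
    return LocusBlueprint(
        locus_id="TRA",
        layout="trad",
        subgroup_sizes=[2, 1, 1, 1, 1, 1],
        v_order=[0, 0, 1, 2, 3],
        v_func=["F", "F", "F", "P", "F"],
        v_locus=["TRA", "TRA", "TRA", "TRA", "TRD"],
        units=[UnitPlan(j_plan=["F", "ORF"], c_plan="F", d_plan="F")],
        inverted_v_tail="F",
        inverted_v_tail_locus="TRD",
        tra_j_plan=["F", "F", "ORF", "F", "P", "F"],
        tra_c_plan="F",
        c_exon_lengths=[90, 51, 75, 30],
    )


# ---------------------------------------------------------------------------
# gene factories
# ---------------------------------------------------------------------------

def _make_v_ancestor(rng: np.random.Generator, fr2_motif: str | None) -> dict:
    """Random V-REGION whose IMGT numbering is uniquely recoverable."""
    for _ in range(200):
        c1 = int(rng.integers(5, 13))
        c2 = int(rng.integers(4, 11))
        aa = list(_rand_aa(rng, 84 + c1 + c2))
        aa[22] = "C"
        aa[28 + c1] = "W"
        aa[66 + c1 + c2] = "AVLIF"[rng.integers(0, 5)]
        aa[81 + c1 + c2] = "C"
        if fr2_motif:
            aa[26 + c1 : 26 + c1 + len(fr2_motif)] = list(fr2_motif)
        aa = "".join(aa)
        numbering = number_v_region(aa)
        if (
            numbering.ok
            and numbering.cdr1_len == c1
            and numbering.cdr2_len == c2
            and all(numbering.anchors.values())
        ):
            nt = _aa_to_nt(aa, rng)
            return {"nt": nt, "c1": c1, "c2": c2, "anchor_offset": 3 * (81 + c1 + c2)}
    raise RuntimeError("failed to generate a numerable V ancestor")


def _v_protected(c1: int, c2: int, length: int, fr2_motif_len: int) -> set[int]:
    prot: set[int] = set()
    for idx in (22, 28 + c1, 66 + c1 + c2, 81 + c1 + c2):
        prot.update(range(3 * idx, 3 * idx + 3))
    prot.update(range(3 * (26 + c1), 3 * (26 + c1 + fr2_motif_len)))
    prot.update(range(0, 3))
    prot.update(range(length - 3, length))
    return prot


def _plant_v_stops(nt: str, c1: int, c2: int) -> str:
    seq = list(nt)
    for idx, stop in ((50 + c1 + c2, "TAA"), (60 + c1 + c2, "TGA")):
        seq[3 * idx : 3 * idx + 3] = list(stop)
    return "".join(seq)


def _make_j_ancestor(rng: np.random.Generator) -> dict:
    # ~51 nt J-REGION: a short germline CDR3 part, the [FW]GXG motif at
    # positions 118-121, then the FR4 tail ending at the splice donor
    aa = _rand_aa(rng, 3) + "FG" + _rand_aa(rng, 1) + "G" + _rand_aa(rng, 10)
    nt = _aa_to_nt(aa, rng)
    return {"nt": nt, "anchor_offset": 9}


def _j_protected(length: int) -> set[int]:
    prot = set(range(9, 21))  # the [FW]GXG motif codons
    prot.update(range(0, 3))
    prot.update(range(length - 3, length))
    return prot


def _make_c_base(rng: np.random.Generator, exon_lengths: list[int]) -> list[str]:
    total = sum(exon_lengths)
    if total % 3:
        raise ConfigError("C exon lengths must sum to a multiple of 3")
    nt = _aa_to_nt(_rand_aa(rng, total // 3, forbid="*"), rng)
    exons, pos = [], 0
    for ln in exon_lengths:
        exons.append(nt[pos : pos + ln])
        pos += ln
    return exons


def _c_copy(base_exons: list[str], rng: np.random.Generator, divergence: float, pseudo: bool) -> list[str]:
    spliced = "".join(base_exons)
    protected: set[int] = set()
    pos = 0
    for ex in base_exons:
        protected.update(range(pos, pos + 3))
        protected.update(range(pos + len(ex) - 3, pos + len(ex)))
        pos += len(ex)
    mutated = _mutate_coding(spliced, divergence, rng, protected)
    exons, pos = [], 0
    for ex in base_exons:
        exons.append(mutated[pos : pos + len(ex)])
        pos += len(ex)
    if pseudo:
        exons[0] = exons[0][:10] + exons[0][11:]  # 1-nt deletion: frameshift
    return exons


# ---------------------------------------------------------------------------
# locus assembly
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def sequence(self) -> str:
        return "".join(self.parts)


@dataclass
class SyntheticLocus:
    """A built locus: sequence, planted genes (ground truth) and the map."""

    locus_id: str
    sequence: str
    genes: list[GermlineGene]
    locus_map: LocusMap
    blueprint: LocusBlueprint

    @property
    def germline_set(self) -> GermlineSet:
        return GermlineSet.from_genes(self.genes)

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io_formats import write_fasta, write_germline_fasta, write_gff3

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([(self.locus_id, self.sequence)], out / "locus.fa")
        write_gff3(self.locus_map, out / "truth.gff3", locus_length=len(self.sequence))
        write_germline_fasta(self.genes, out / "germline.fa", locus_seq=self.sequence)


def _draw_rs(
    rng: np.random.Generator,
    side: str,
    spacer_len: int,
    pwms: tuple[PWM, PWM] | None,
    canonical: bool = True,
) -> tuple[str, RSMotif]:
    """Return (forward-strand RS string, gene-facing motif record)."""
    if pwms is None or not canonical:
        hept, non = "CACAGTG", "ACAAAAACC"
    else:
        hept = sample_from_pwm(pwms[0], rng)
        non = sample_from_pwm(pwms[1], rng)
    if not canonical:
        # the modeled defect is exactly a non-canonical first heptamer base
        hept = "TGA"[rng.integers(0, 3)] + hept[1:]
    spacer = _rand_nt(rng, spacer_len)
    forward = hept + spacer + non if side == "3p" else revcomp(hept + spacer + non)
    motif = RSMotif(
        heptamer=hept,
        spacer=spacer,
        nonamer=non,
        side=side,
        score=0.0,
        canonical=is_canonical_rs(hept, non),
    )
    return forward, motif


def build_synthetic_locus(blueprint: LocusBlueprint, seed: int) -> SyntheticLocus:
    """Assemble a locus from the blueprint; deterministic per seed."""
    rng = np.random.default_rng(seed)
    bp = blueprint
    vj_pwms = rs_generating_pwms()

    # subgroup ancestors and members
    fr2_motif = "IHWY" if bp.locus_id == "TRG" else None
    families: list[list[dict]] = []
    for size in bp.subgroup_sizes:
        anc = _make_v_ancestor(rng, fr2_motif)
        members = [anc]
        prot = _v_protected(anc["c1"], anc["c2"], len(anc["nt"]), len(fr2_motif or ""))
        for _ in range(size - 1):
            members.append(
                anc | {"nt": _mutate_coding(anc["nt"], bp.member_divergence, rng, prot)}
            )
        families.append(members)
    member_iter = [0] * len(families)

    j_anc = _make_j_ancestor(rng)
    j_prot = _j_protected(len(j_anc["nt"]))
    c_base = _make_c_base(rng, bp.c_exon_lengths)

    genes: list[GermlineGene] = []
    j_pseudo_count = 0

    def make_v(sub_idx: int, func: str, locus: str) -> tuple[str, GermlineGene]:
        nonlocal member_iter
        member = families[sub_idx][member_iter[sub_idx]]
        member_iter[sub_idx] += 1
        nt = member["nt"]
        defects: list[str] = []
        if func == "P":
            nt = _plant_v_stops(nt, member["c1"], member["c2"])
            defects = [STOP_CODON]
        rs_fwd, motif = _draw_rs(rng, "3p", 23, vj_pwms, canonical=func != "ORF")
        if func == "ORF":
            defects = [NONCANONICAL_RS]
        gene = GermlineGene(
            name="",
            locus=locus,
            gene_type="V",
            start=0,
            end=0,
            subgroup=f"__{sub_idx}",
            functionality=func,
            defects=defects,
            rs_3p=motif,
            nt_sequence=nt,
            numbering=number_v_region(translate(nt)),
            anchor_offset=member["anchor_offset"],
        )
        return nt + rs_fwd, gene

    def make_relic() -> tuple[str, GermlineGene]:
        anc = families[0][0]
        ends = set(range(0, 3)) | set(range(len(anc["nt"]) - 3, len(anc["nt"])))
        nt = _mutate_coding(anc["nt"], bp.relic_divergence, rng, ends)
        rs_fwd, motif = _draw_rs(rng, "3p", 23, vj_pwms)
        gene = GermlineGene(
            name="",
            locus=bp.locus_id,
            gene_type="V",
            start=0,
            end=0,
            functionality="P",
            defects=[DEGENERATE],
            rs_3p=motif,
            nt_sequence=nt,
        )
        return nt + rs_fwd, gene

    def make_j(func: str, locus: str) -> tuple[str, GermlineGene]:
        nonlocal j_pseudo_count
        nt = _mutate_coding(j_anc["nt"], bp.j_divergence, rng, j_prot)
        defects: list[str] = []
        anchor = j_anc["anchor_offset"]
        if func == "P":
            if j_pseudo_count % 2 == 0:
                nt = nt[: len(nt) - 4] + nt[len(nt) - 3 :]  # 1-nt deletion after the motif
                defects = [FRAMESHIFT]
                anchor = None
            else:
                nt = nt[:27] + "TAA" + nt[30:]  # stop in the FR4 tail
                defects = [STOP_CODON]
            j_pseudo_count += 1
        rs_fwd, motif = _draw_rs(rng, "5p", 12, vj_pwms, canonical=func != "ORF")
        if func == "ORF":
            defects = [NONCANONICAL_RS]
        gene = GermlineGene(
            name="",
            locus=locus,
            gene_type="J",
            start=0,
            end=0,
            functionality=func,
            defects=defects,
            rs_5p=motif,
            nt_sequence=nt,
            anchor_offset=anchor,
        )
        return rs_fwd + nt + "GT", gene  # GT: splice donor, outside the gene

    def make_d(func: str, locus: str) -> tuple[str, GermlineGene]:
        nt = _rand_nt(rng, int(rng.integers(12, 17)))
        rs5_fwd, m5 = _draw_rs(rng, "5p", 12, None)
        rs3_fwd, m3 = _draw_rs(rng, "3p", 23, None)
        gene = GermlineGene(
            name="",
            locus=locus,
            gene_type="D",
            start=0,
            end=0,
            functionality=func,
            rs_5p=m5,
            rs_3p=m3,
            nt_sequence=nt,
        )
        return rs5_fwd + nt + rs3_fwd, gene

    def make_c(func: str, locus: str) -> tuple[str, GermlineGene, list[tuple[int, int]]]:
        exons = _c_copy(c_base, rng, bp.c_divergence, pseudo=func == "P")
        parts: list[str] = []
        rel_exons: list[tuple[int, int]] = []
        pos = 0
        for i, ex in enumerate(exons):
            if i:
                intron = "GT" + _rand_nt(rng, int(rng.integers(76, 150))) + "AG"
                parts.append(intron)
                pos += len(intron)
            rel_exons.append((pos, pos + len(ex)))
            parts.append(ex)
            pos += len(ex)
        gene = GermlineGene(
            name="",
            locus=locus,
            gene_type="C",
            start=0,
            end=0,
            functionality=func,
            defects=[FRAMESHIFT] if func == "P" else [],
            nt_sequence="".join(exons),
        )
        return "".join(parts), gene, rel_exons

    # --- chunk assembly (a chunk can be reverse-complemented as a whole) ---

    def gap(chunk: _Builder) -> None:
        chunk.add(_rand_nt(rng, int(rng.integers(120, 280))))

    def place(chunk: _Builder, seq: str, gene: GermlineGene, gene_slice: tuple[int, int], exons=None, rs_slices=None) -> None:
        start, _ = chunk.add(seq)
        gene.start = start + gene_slice[0]
        gene.end = start + gene_slice[1]
        if exons is not None:
            gene.exons = [(start + s, start + e) for s, e in exons]
        if rs_slices:
            for side, (s, e) in rs_slices.items():
                motif = gene.rs_5p if side == "5p" else gene.rs_3p
                if motif is not None:
                    motif.start, motif.end = start + s, start + e

    def add_v(chunk: _Builder, sub_idx: int, func: str, locus: str) -> GermlineGene:
        seq, gene = make_v(sub_idx, func, locus)
        glen = len(gene.nt_sequence)
        place(chunk, seq, gene, (0, glen), rs_slices={"3p": (glen, len(seq))})
        gap(chunk)
        return gene

    def add_j(chunk: _Builder, func: str, locus: str) -> GermlineGene:
        seq, gene = make_j(func, locus)
        rs_len = 16 + 12
        place(chunk, seq, gene, (rs_len, len(seq) - 2), rs_slices={"5p": (0, rs_len)})
        gap(chunk)
        return gene

    def add_d(chunk: _Builder, func: str, locus: str) -> GermlineGene:
        seq, gene = make_d(func, locus)
        rs5_len = 16 + 12
        glen = len(gene.nt_sequence)
        place(
            chunk,
            seq,
            gene,
            (rs5_len, rs5_len + glen),
            rs_slices={"5p": (0, rs5_len), "3p": (rs5_len + glen, len(seq))},
        )
        gap(chunk)
        return gene

    def add_c(chunk: _Builder, func: str, locus: str) -> GermlineGene:
        seq, gene, rel_exons = make_c(func, locus)
        place(chunk, seq, gene, (0, len(seq)), exons=rel_exons)
        gap(chunk)
        return gene

    main = _Builder()
    main.add(_rand_nt(rng, 300))

    def merge_chunk(chunk: _Builder, chunk_genes: list[GermlineGene], invert: bool) -> None:
        seq = chunk.sequence()
        if invert:
            seq = revcomp(seq)
        offset = main.pos
        main.add(seq)
        n = len(seq)
        for g in chunk_genes:
            if invert:
                g.start, g.end = n - g.end, n - g.start
                g.strand = "-"
                g.exons = sorted((n - e, n - s) for s, e in g.exons)
                for motif in (g.rs_5p, g.rs_3p):
                    if motif is not None:
                        motif.start, motif.end = n - motif.end, n - motif.start
            g.start += offset
            g.end += offset
            g.exons = [(s + offset, e + offset) for s, e in g.exons]
            for motif in (g.rs_5p, g.rs_3p):
                if motif is not None:
                    motif.start += offset
                    motif.end += offset
            genes.append(g)

    if bp.layout == "cassette":
        v_cursor = 0
        for u, unit in enumerate(bp.units, start=1):
            chunk = _Builder()
            chunk_genes = []
            for _ in range(bp.v_per_unit[u - 1]):
                chunk_genes.append(add_v(chunk, bp.v_order[v_cursor], bp.v_func[v_cursor], bp.locus_id))
                v_cursor += 1
            for jf in unit.j_plan:
                chunk_genes.append(add_j(chunk, jf, bp.locus_id))
            if unit.c_plan:
                chunk_genes.append(add_c(chunk, unit.c_plan, bp.locus_id))
            merge_chunk(chunk, chunk_genes, invert=u in bp.inverted_units)
        for _ in range(bp.n_relics):
            chunk = _Builder()
            seq_rel, gene_rel = make_relic()
            glen = len(gene_rel.nt_sequence)
            place(chunk, seq_rel, gene_rel, (0, glen), rs_slices={"3p": (glen, len(seq_rel))})
            gap(chunk)
            merge_chunk(chunk, [gene_rel], invert=False)
    else:
        chunk = _Builder()
        chunk_genes = []
        v_loci = bp.v_locus or [bp.locus_id] * len(bp.v_order)
        for i, sub_idx in enumerate(bp.v_order):
            chunk_genes.append(add_v(chunk, sub_idx, bp.v_func[i], v_loci[i]))
        merge_chunk(chunk, chunk_genes, invert=False)
        cluster_locus = "TRD" if bp.layout == "trad" else bp.locus_id
        for u, unit in enumerate(bp.units, start=1):
            chunk = _Builder()
            chunk_genes = []
            if unit.d_plan:
                chunk_genes.append(add_d(chunk, unit.d_plan, cluster_locus))
            for jf in unit.j_plan:
                chunk_genes.append(add_j(chunk, jf, cluster_locus))
            if unit.c_plan:
                chunk_genes.append(add_c(chunk, unit.c_plan, cluster_locus))
            merge_chunk(chunk, chunk_genes, invert=False)
        if bp.inverted_v_tail:
            chunk = _Builder()
            tail_locus = bp.inverted_v_tail_locus or bp.locus_id
            tail_sub = len(bp.subgroup_sizes) - 1
            chunk_genes = [add_v(chunk, tail_sub, bp.inverted_v_tail, tail_locus)]
            merge_chunk(chunk, chunk_genes, invert=True)
        if bp.layout == "trad":
            chunk = _Builder()
            chunk_genes = []
            for jf in bp.tra_j_plan:
                chunk_genes.append(add_j(chunk, jf, "TRA"))
            if bp.tra_c_plan:
                chunk_genes.append(add_c(chunk, bp.tra_c_plan, "TRA"))
            merge_chunk(chunk, chunk_genes, invert=False)

    main.add(_rand_nt(rng, 300))
    sequence = main.sequence()
    if bp.mutation_rate > 0:
        arr = list(sequence)
        for i in range(len(arr)):
            if rng.random() < bp.mutation_rate:
                arr[i] = BASES[(BASES.index(arr[i]) + 1 + rng.integers(0, 3)) % 4]
        sequence = "".join(arr)

    _assign_truth_names(genes, bp)
    locus_map = build_locus_map(genes, bp.locus_id)
    return SyntheticLocus(
        locus_id=bp.locus_id,
        sequence=sequence,
        genes=sorted(genes, key=lambda g: g.start),
        locus_map=locus_map,
        blueprint=bp,
    )


def _assign_truth_names(genes: list[GermlineGene], bp: LocusBlueprint) -> None:
    """Name planted V genes with the same convention the annotator uses:
    subgroups numbered by their 5'-most member, members by locus order.
    (J/D/C names were already set by the locus-map builder.)"""
    vs = [g for g in genes if g.gene_type == "V" and DEGENERATE not in g.defects]
    groups: dict[str, list[GermlineGene]] = {}
    for g in sorted(vs, key=lambda g: g.start):
        groups.setdefault(g.subgroup or "", []).append(g)
    ordered = sorted(groups.values(), key=lambda grp: grp[0].start)
    for k, grp in enumerate(ordered, start=1):
        sub = f"{grp[0].locus}V{k}"
        for m, g in enumerate(grp, start=1):
            g.subgroup = sub
            g.name = sub if len(grp) == 1 else f"{sub}-{m}"
    relics = [g for g in genes if g.gene_type == "V" and DEGENERATE in g.defects]
    for i, g in enumerate(sorted(relics, key=lambda g: g.start)):
        g.subgroup = None
        g.name = f"{g.locus}V{chr(65 + i)}"


# ---------------------------------------------------------------------------
# repertoire simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the rearrangement and sequencing model.

    Trimming removes ``Geometric(p) - 1`` nucleotides (support 0, 1, ...;
    mean ``(1-p)/p``) from the V 3' and J 5' coding ends; N-insertion length
    is Poisson(``lambda_n``). ``usage_v``/``usage_j`` are explicit gene ->
    probability maps over functional (F/ORF) genes; when ``usage_j`` is
    absent and the locus has cassettes, J genes are drawn intra-cassette
    with probability ``intra_unit_preference``.
    """

    locus_id: str = "TRG"
    n_reads: int = 10_000
    read_len: int = 300
    error_rate: float = 0.005
    p_trim_v: float = 0.35
    p_trim_j: float = 0.35
    p_trim_d: float = 0.5
    lambda_n: float = 3.0
    with_d: bool | None = None
    intra_unit_preference: float = 0.8
    usage_v: dict | None = None
    usage_j: dict | None = None
    adapter: str = TS_ADAPTER
    c_stub_len: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_trim_v", "p_trim_j", "p_trim_d", "intra_unit_preference"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not 0 <= self.error_rate <= 0.1:
            raise ConfigError("error_rate must be in [0, 0.1]")
        if self.lambda_n < 0:
            raise ConfigError("lambda_n must be >= 0")
        for usage in (self.usage_v, self.usage_j):
            if usage is not None and abs(sum(usage.values()) - 1.0) > 1e-9:
                raise ConfigError("usage probabilities must sum to 1")
        if self.with_d is None:
            self.with_d = self.locus_id in ("TRB", "TRD")


@dataclass
class SimRead:
    """Ground truth for one simulated rearrangement."""

    read_id: str
    sample_id: str
    v_name: str
    j_name: str
    d_name: str | None
    trim_v: int
    trim_j: int
    trim_d5: int
    trim_d3: int
    n1: str
    n2: str
    junction: str | None
    amplicon: str


def _subgroup_of(name: str) -> str:
    base, _, tail = name.rpartition("-")
    return base if base and tail.isdigit() else name


def default_v_usage(germline: GermlineSet, locus: str | None = None, dominant: float = 0.95) -> dict:
    """Concentrate usage on the largest functional subgroup (split evenly
    among its members); remaining eligible genes share the rest evenly."""
    eligible = germline.eligible("V", locus)
    if not eligible:
        raise ConfigError("no functional V genes in the germline set")
    groups: dict[str, list[str]] = {}
    for e in eligible:
        groups.setdefault(_subgroup_of(e.name), []).append(e.name)
    top = max(groups.values(), key=lambda g: (len(g), g[0]))
    others = [n for g in groups.values() for n in g if n not in top]
    usage = {n: dominant / len(top) for n in top}
    if others:
        for n in others:
            usage[n] = (1 - dominant) / len(others)
    else:
        usage = {n: 1 / len(top) for n in top}
    return usage


def reconstruct_amplicon(truth: SimRead, germline: GermlineSet, config: SimConfig) -> str:
    """Rebuild the amplicon from the truth fields; must equal ``truth.amplicon``."""
    v = germline.by_name[truth.v_name].nt_sequence
    j = germline.by_name[truth.j_name].nt_sequence
    parts = [config.adapter, v[: len(v) - truth.trim_v], truth.n1]
    if truth.d_name is not None:
        d = germline.by_name[truth.d_name].nt_sequence
        parts.append(d[truth.trim_d5 : len(d) - truth.trim_d3])
        parts.append(truth.n2)
    parts.append(j[truth.trim_j :])
    parts.append(_c_stub(germline, config))
    return "".join(parts)


def _c_stub(germline: GermlineSet, config: SimConfig) -> str:
    cs = germline.eligible("C") or germline.of_type("C")
    return cs[0].nt_sequence[: config.c_stub_len] if cs else ""


def simulate_repertoire(
    germline: GermlineSet,
    config: SimConfig,
    sample_id: str = "s1",
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[SimRead]]:
    """Draw rearranged amplicons and their ground truth from the germline set.

    Each amplicon is adapter + trimmed V + N + [trimmed D + N] + trimmed J +
    the 5' stub of the constant region (the reverse-primer site of a 5'RACE
    library). Only F/ORF genes rearrange. The truth junction runs from the
    cys-104 codon through the J-PHE/TRP-118 codon inclusive, and is None
    when trimming destroyed either anchor.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    locus = config.locus_id
    v_usage = config.usage_v or default_v_usage(germline, None if locus == "TRA" else locus)
    for name in v_usage:
        if name not in germline.by_name:
            raise ConfigError(f"usage references unknown gene {name!r}")
    v_names = sorted(v_usage)
    v_probs = np.array([v_usage[n] for n in v_names])
    v_probs = v_probs / v_probs.sum()

    eligible_j = germline.eligible("J", None if locus == "TRA" else locus)
    if not eligible_j or not v_names:
        raise ConfigError("germline must contain at least one functional V and J gene")
    if config.usage_j is not None:
        for name in config.usage_j:
            if name not in germline.by_name:
                raise ConfigError(f"usage references unknown gene {name!r}")
        j_names = sorted(config.usage_j)
        j_probs = np.array([config.usage_j[n] for n in j_names])
        j_probs = j_probs / j_probs.sum()
    else:
        j_names = [e.name for e in eligible_j]
        j_probs = None
    j_by_unit: dict[int | None, list[str]] = {}
    for e in eligible_j:
        j_by_unit.setdefault(e.unit, []).append(e.name)

    eligible_d = germline.eligible("D", None if locus == "TRA" else locus) if config.with_d else []
    stub = _c_stub(germline, config)

    amplicons: list[str] = []
    truths: list[SimRead] = []
    for i in range(config.n_reads):
        v_name = v_names[rng.choice(len(v_names), p=v_probs)]
        v_entry = germline.by_name[v_name]
        if j_probs is not None:
            j_name = j_names[rng.choice(len(j_names), p=j_probs)]
        else:
            same = j_by_unit.get(v_entry.unit, [])
            other = [n for n in j_names if n not in same]
            if same and other and rng.random() < config.intra_unit_preference:
                j_name = same[rng.integers(0, len(same))]
            elif same and not other:
                j_name = same[rng.integers(0, len(same))]
            elif other:
                j_name = other[rng.integers(0, len(other))]
            else:
                j_name = j_names[rng.integers(0, len(j_names))]
        j_entry = germline.by_name[j_name]

        v_seq, j_seq = v_entry.nt_sequence, j_entry.nt_sequence
        trim_v = min(int(rng.geometric(config.p_trim_v)) - 1, 15, len(v_seq) - 1)
        trim_j = min(int(rng.geometric(config.p_trim_j)) - 1, 15, len(j_seq) - 1)
        n1 = _rand_nt(rng, int(rng.poisson(config.lambda_n)))
        d_name = None
        trim_d5 = trim_d3 = 0
        n2 = ""
        middle = ""
        if eligible_d:
            d_name = eligible_d[rng.integers(0, len(eligible_d))].name
            d_seq = germline.by_name[d_name].nt_sequence
            trim_d5 = min(int(rng.geometric(config.p_trim_d)) - 1, len(d_seq) // 2)
            trim_d3 = min(int(rng.geometric(config.p_trim_d)) - 1, len(d_seq) - trim_d5)
            n2 = _rand_nt(rng, int(rng.poisson(config.lambda_n)))
            middle = d_seq[trim_d5 : len(d_seq) - trim_d3] + n2

        v_part = v_seq[: len(v_seq) - trim_v]
        j_part = j_seq[trim_j:]
        amplicon = config.adapter + v_part + n1 + middle + j_part + stub

        junction = None
        va, ja = v_entry.anchor_offset, j_entry.anchor_offset
        if va is not None and ja is not None and va + 3 <= len(v_part) and trim_j <= ja:
            js = len(config.adapter) + va
            je = len(config.adapter) + len(v_part) + len(n1) + len(middle) + (ja - trim_j) + 3
            junction = amplicon[js:je]

        read_id = f"{sample_id}:{i}"
        amplicons.append(amplicon)
        truths.append(
            SimRead(
                read_id=read_id,
                sample_id=sample_id,
                v_name=v_name,
                j_name=j_name,
                d_name=d_name,
                trim_v=trim_v,
                trim_j=trim_j,
                trim_d5=trim_d5,
                trim_d3=trim_d3,
                n1=n1,
                n2=n2,
                junction=junction,
                amplicon=amplicon,
            )
        )
    return amplicons, truths


def emit_reads(
    amplicons: list[str],
    read_len: int = 300,
    error_rate: float = 0.005,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "s1",
) -> tuple[list[FastqRead], list[FastqRead]]:
    """Paired reads: R1 from the 5' end, R2 reverse-complemented from the 3'
    end, per-base substitution errors at ``error_rate`` and phred qualities
    consistent with it. Deterministic per seed."""
    if not 0 <= error_rate <= 0.1:
        raise ConfigError("error_rate must be in [0, 0.1]")
    if read_len < 30:
        raise ConfigError("read_len below the minimum overlap floor (30)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Illumina-like quality profile: confident calls are high-Q, the bases
    # that actually carry a substitution get a reduced quality, so a
    # sliding-window Q30 trim removes error-dense stretches rather than
    # whole reads.
    q_hi = 40 if error_rate == 0 else 38
    q_lo = 20
    r1s, r2s = [], []
    for i, amp in enumerate(amplicons):
        fwd = amp[:read_len]
        rev = revcomp(amp)[:read_len]
        out = []
        for seq in (fwd, rev):
            arr = list(seq)
            qual = [q_hi] * len(arr)
            if error_rate > 0:
                hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
                for h in hits:
                    arr[h] = BASES[(BASES.index(arr[h]) + 1 + rng.integers(0, 3)) % 4]
                    qual[h] = q_lo
            out.append(("".join(arr), qual))
        rid = f"{id_prefix}:{i}"
        r1s.append(FastqRead(rid, out[0][0], out[0][1]))
        r2s.append(FastqRead(rid, out[1][0], out[1][1]))
    return r1s, r2s
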