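"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open on the forward strand everywhere in
the package; the GFF3 writer is the single place where they are converted to
the 1-based inclusive convention of the format. Reverse-strand genes store
forward-strand coordinates plus a strand flag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import AA_ALPHABET, NT_ALPHABET


def _read_text(path: str | Path) -> str:
    """Read a text file, transparently decompressing ``.gz``."""
    p = Path(path)
    if p.suffix == ".gz":
        import gzip

        with gzip.open(p, "rt") as fh:
            return fh.read()
    return p.read_text()


class TRKitError(Exception):
    """Base class for all package errors."""


class FormatError(TRKitError):
    """Malformed input file; message names the offending record."""


class SchemaError(TRKitError):
    """Record missing a mandatory field for a tabular schema."""


class ConfigError(TRKitError):
    """Invalid run or simulation configuration."""


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

LOCI = ("TRA", "TRB", "TRG", "TRD")

#: spacer lengths between heptamer and nonamer permitted by the 12/23 rule
VALID_SPACERS = (12, 23)

#: default element spacer policy: V 3'RS uses a 23-nt spacer, J 5'RS a 12-nt
#: spacer, and D genes carry a 12-nt spacer 5' and a 23-nt spacer 3', so that
#: V-J and V-D-J joins both satisfy the 12/23 rule.
DEFAULT_SPACER_POLICY = {"V": 23, "J": 12, "D5": 12, "D3": 23}


@dataclass
class RunConfig:
    """Tunable knobs shared by the annotation and repertoire stages."""

    locus_id: str = "TRG"
    spacer_policy: dict = field(default_factory=lambda: dict(DEFAULT_SPACER_POLICY))
    identity_threshold: float = 75.0  # subgroup cut-off, percent
    trim_quality: int = 30            # sliding-window phred cut-off
    trim_window: int = 4
    rng_seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.locus_id not in LOCI:
            raise ConfigError(f"unknown locus {self.locus_id!r}; expected one of {LOCI}")
        for key, spacer in self.spacer_policy.items():
            if spacer not in VALID_SPACERS:
                raise ConfigError(f"spacer for {key} must be 12 or 23, got {spacer}")
        if not 0 < self.identity_threshold <= 100:
            raise ConfigError("identity_threshold must be in (0, 100]")
        if self.trim_quality < 0:
            raise ConfigError("trim_quality must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read FASTA into an ordered list of ``(id, sequence)``.

    Sequences are upper-cased; in nucleotide mode U is mapped to T. Empty
    files, duplicate ids and characters outside the IUPAC alphabet raise
    :class:`FormatError` naming the record.
    """
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if alphabet == "nt":
            seq = seq.replace("U", "T")
        bad = set(seq) - allowed
        if bad:
            raise FormatError(f"record {name!r}: illegal characters {sorted(bad)}")
        if name in seen:
            raise FormatError(f"duplicate FASTA id {name!r}")
        seen.add(name)
        records.append((name, seq))

    text = _read_text(path)
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise FormatError("FASTA record with empty id")
            chunks = []
        else:
            if name is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Sanger phred+33)
# ---------------------------------------------------------------------------

@dataclass
class FastqRead:
    read_id: str
    seq: str
    qual: list[int]  # phred scores

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(f"read {self.read_id!r}: sequence/quality length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    lines = [ln.rstrip("\n") for ln in _read_text(path).splitlines()]
    if len(lines) % 4:
        raise FormatError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    reads = []
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record near line {i + 1}")
        reads.append(FastqRead(header[1:].split()[0], seq.upper(), [ord(c) - 33 for c in qual]))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qual) + "\n")


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV
# ---------------------------------------------------------------------------

#: mandatory fields for every rearrangement record
AIRR_MANDATORY = ("sequence_id", "v_call", "j_call", "junction", "junction_aa", "productive", "locus")

AIRR_COLUMNS = (
    "sequence_id",
    "sequence",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "cdr3",
    "productive",
    "v_cassette",
    "j_cassette",
    "sample_id",
)

_LIST_FIELDS = ("v_call", "d_call", "j_call")
_INT_FIELDS = ("v_cassette", "j_cassette")


def _as_mapping(rec) -> dict:
    if hasattr(rec, "to_airr_dict"):
        return rec.to_airr_dict()
    if dataclasses.is_dataclass(rec):
        return dataclasses.asdict(rec)
    return dict(rec)


def write_airr(rearrangements: Iterable, path: str | Path) -> None:
    """Write AIRR Rearrangement TSV.

    Multi-gene ambiguous calls are serialized comma-joined in one field, in
    stable locus order as produced upstream. Missing mandatory fields raise
    :class:`SchemaError`.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(AIRR_COLUMNS) + "\n")
        for rec in rearrangements:
            row = _as_mapping(rec)
            for key in AIRR_MANDATORY:
                if key not in row or row[key] is None:
                    if key in ("junction", "junction_aa"):
                        continue  # legitimately empty for unproductive calls
                    raise SchemaError(f"record {row.get('sequence_id')!r} missing field {key!r}")
            cells = []
            for col in AIRR_COLUMNS:
                val = row.get(col)
                if val is None:
                    cells.append("")
                elif col in _LIST_FIELDS and not isinstance(val, str):
                    cells.append(",".join(val))
                elif col == "productive":
                    cells.append("T" if val else "F")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


def read_airr(path: str | Path) -> list[dict]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty AIRR file")
    header = lines[0].split("\t")
    records = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        row: dict = dict(zip(header, cells))
        for key in _LIST_FIELDS:
            if key in row:
                row[key] = row[key].split(",") if row[key] else None
        for key in _INT_FIELDS:
            if key in row:
                row[key] = int(row[key]) if row[key] else None
        if "productive" in row:
            row["productive"] = row["productive"] == "T"
        for key in ("junction", "junction_aa", "cdr3"):
            if key in row and row[key] == "":
                row[key] = None
        records.append(row)
    return records


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(entries, path: str | Path, locus_length: int | None = None) -> None:
    """Write gene/RS features as GFF3.

    ``entries`` is an iterable of dicts with keys ``seqid, source, type,
    start, end, strand, attrs`` where start/end are internal 0-based
    half-open coordinates; objects exposing ``to_gff_entries()`` (e.g. a
    locus map) are accepted directly. Coordinates are converted to 1-based
    inclusive here and nowhere else.
    """
    if hasattr(entries, "to_gff_entries"):
        entries = entries.to_gff_entries()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in entries:
            start, end = e["start"], e["end"]
            if start < 0 or end <= start:
                raise FormatError(f"bad feature interval [{start}, {end})")
            if locus_length is not None and end > locus_length:
                raise FormatError(f"feature end {end} beyond locus length {locus_length}")
            attrs = ";".join(f"{k}={v}" for k, v in e.get("attrs", {}).items())
            fh.write(
                "\t".join(
                    [
                        e.get("seqid", "locus"),
                        e.get("source", "trkit"),
                        e["type"],
                        str(start + 1),
                        str(end),
                        str(e.get("score", ".")),
                        e.get("strand", "+"),
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[dict]:
    """Parse GFF3 back to internal-coordinate feature dicts."""
    feats = []
    for ln in Path(path).read_text().splitlines():
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GFF3 line with {len(cols)} columns: {ln[:60]}")
        attrs = {}
        if cols[8] != ".":
            for item in cols[8].split(";"):
                if item:
                    k, _, v = item.partition("=")
                    attrs[k] = v
        feats.append(
            {
                "seqid": cols[0],
                "source": cols[1],
                "type": cols[2],
                "start": int(cols[3]) - 1,
                "end": int(cols[4]),
                "score": cols[5],
                "strand": cols[6],
                "attrs": attrs,
            }
        )
    return feats


# ---------------------------------------------------------------------------
# germline directory FASTA with tagged headers
# ---------------------------------------------------------------------------

def write_germline_fasta(genes: Sequence, path: str | Path, locus_seq: str | None = None) -> None:
    """Write germline gene sequences with key=value metadata in the header.

    Tags carried: gene type, locus, functionality, cassette/cluster unit and
    the junction anchor offsets (cys104 codon start for V genes, phe/trp-118
    codon start for J genes) that the repertoire stage needs. When the locus
    sequence is provided, C genes additionally get per-exon records
    (``NAME-EXk``) usable as exon references by the annotation stage.
    """
    from ._seq import revcomp

    with open(path, "w") as fh:
        for g in genes:
            tags = [f"type={g.gene_type}", f"locus={g.locus}", f"functionality={g.functionality}"]
            unit = getattr(g, "unit", None)
            if unit is not None:
                tags.append(f"unit={unit}")
            anchor = getattr(g, "anchor_offset", None)
            if anchor is not None:
                tags.append(f"anchor={anchor}")
            fh.write(f">{g.name} {' '.join(tags)}\n{g.nt_sequence}\n")
            exons = getattr(g, "exons", None)
            if exons and locus_seq is not None:
                spans = sorted(exons)
                if getattr(g, "strand", "+") == "-":
                    exon_seqs = [revcomp(locus_seq[s:e]) for s, e in reversed(spans)]
                else:
                    exon_seqs = [locus_seq[s:e] for s, e in spans]
                for k, ex in enumerate(exon_seqs, start=1):
                    fh.write(f">{g.name}-EX{k} type={g.gene_type} locus={g.locus} functionality={g.functionality}\n{ex}\n")


def read_germline_fasta(path: str | Path) -> list[dict]:
    """Read a tagged germline FASTA back to a list of gene dicts."""
    genes = []
    seen = set()
    for ln_block in Path(path).read_text().split(">"):
        if not ln_block.strip():
            continue
        lines = ln_block.splitlines()
        head = lines[0].split()
        name = head[0]
        if name in seen:
            raise FormatError(f"duplicate germline gene {name!r}")
        seen.add(name)
        info = {"name": name, "nt_sequence": "".join(lines[1:]).upper()}
        for tag in head[1:]:
            k, _, v = tag.partition("=")
            info[k] = v
        if "unit" in info:
            info["unit"] = int(info["unit"])
        if "anchor" in info:
            info["anchor"] = int(info["anchor"])
        genes.append(info)
    if not genes:
        raise FormatError(f"no germline records in {path}")
    return genes
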