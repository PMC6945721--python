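"""Position weight matrices and information content for recombination signals.

The recombination signal (RS) flanking every rearranging V, D and J gene is a
conserved heptamer (consensus CACAGTG) and nonamer (poly-A tract, consensus
ACAAAAACC) separated by a 12- or 23-nt spacer. This module builds per-element
nucleotide frequency matrices from annotated gene sets and exports the
per-position heights (frequency x information content) that any sequence-logo
renderer can consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import TRKitError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

#: RS element names: gene type + element
ELEMENTS = ("V-HEPTAMER", "V-NONAMER", "J-HEPTAMER", "J-NONAMER", "D-RS")


@dataclass
class PWM:
    element: str
    counts: np.ndarray  # positions x 4, integers (or weighted counts)
    freqs: np.ndarray   # positions x 4, each row sums to 1
    info_content: np.ndarray  # bits per position, in [0, 2]

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def log_odds(self, background: float = 0.25, floor: float = 1e-3):
        """Log2 odds matrix vs a uniform background; zero frequencies floored."""
        return np.log2(np.maximum(self.freqs, floor) / background)

    def score(self, seq: str, background: float = 0.25) -> float:
        """Summed log-odds of ``seq`` (must match the matrix length)."""
        if len(seq) != self.length:
            raise TRKitError(f"sequence length {len(seq)} != PWM length {self.length}")
        lo = self.log_odds(background)
        idx = [_BASE_INDEX.get(c, -1) for c in seq]
        # unknown bases (N etc.) contribute the background, i.e. zero log-odds
        return float(sum(lo[i, j] for i, j in enumerate(idx) if j >= 0))

    def max_score(self, background: float = 0.25) -> float:
        return float(self.log_odds(background).max(axis=1).sum())


def collect_rs(genes, gene_type: str, element: str, include_orf: bool = False) -> list[str]:
    """Gather aligned RS element strings from annotated genes.

    Follows the convention of profiling potentially functional genes only:
    functionality F by default, optionally also ORF. V genes contribute their
    3' RS, J genes their 5' RS, D genes both.
    """
    wanted = {"F"} | ({"ORF"} if include_orf else set())
    out: list[str] = []
    for g in genes:
        if g.gene_type != gene_type or g.functionality not in wanted:
            continue
        motifs = []
        if gene_type == "V" and g.rs_3p is not None:
            motifs.append(g.rs_3p)
        elif gene_type == "J" and g.rs_5p is not None:
            motifs.append(g.rs_5p)
        elif gene_type == "D":
            motifs.extend(m for m in (g.rs_5p, g.rs_3p) if m is not None)
        for m in motifs:
            out.append(m.heptamer if "HEPTAMER" in element or element == "D-RS" else m.nonamer)
    return out


def build_pwm(rs_set: list[str], pseudocount: float = 0.0, element: str = "RS") -> PWM:
    """Counts -> frequencies -> information content (2 - Shannon entropy, bits).

    ``freqs = (count + pseudocount) / (n + 4 * pseudocount)`` per column.
    """
    if not rs_set:
        raise TRKitError("cannot build a PWM from an empty RS set")
    length = len(rs_set[0])
    if any(len(s) != length for s in rs_set):
        raise TRKitError("ragged RS set: all sequences must have equal length")
    counts = np.zeros((length, 4))
    for s in rs_set:
        for i, c in enumerate(s.upper()):
            j = _BASE_INDEX.get(c)
            if j is not None:
                counts[i, j] += 1
    n = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount) / (n + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PWM(element=element, counts=counts, freqs=freqs, info_content=np.clip(info, 0.0, 2.0))


def consensus_pwm(consensus: str, element: str, strong: float = 0.85) -> PWM:
    """A soft PWM seeded from a consensus string (used before any training data
    exists); the consensus base gets ``strong``, the rest share the remainder."""
    freqs = np.full((len(consensus), 4), (1 - strong) / 3)
    for i, c in enumerate(consensus):
        freqs[i, _BASE_INDEX[c]] = strong
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return PWM(element=element, counts=freqs * 100, freqs=freqs, info_content=info)


def default_rs_pwms() -> tuple[PWM, PWM]:
    """Consensus-seeded (heptamer, nonamer) PWM pair for RS scanning."""
    return (
        consensus_pwm(HEPTAMER_CONSENSUS, "HEPTAMER"),
        consensus_pwm(NONAMER_CONSENSUS, "NONAMER"),
    )


def kl_divergence(pwm: PWM, reference: PWM) -> float:
    """Mean per-position KL divergence (bits) of ``pwm`` from ``reference``."""
    if pwm.length != reference.length:
        raise TRKitError("PWM length mismatch")
    p = np.maximum(pwm.freqs, 1e-12)
    q = np.maximum(reference.freqs, 1e-12)
    return float((p * np.log2(p / q)).sum(axis=1).mean())


def export_logo_data(pwm: PWM, path: str | Path) -> None:
    """Per-position base heights (freq x info content) as TSV for logo rendering."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(BASES) + "\tinfo_bits\n")
        for i in range(pwm.length):
            heights = pwm.freqs[i] * pwm.info_content[i]
            fh.write(
                f"{i + 1}\t" + "\t".join(f"{h:.6f}" for h in heights) + f"\t{pwm.info_content[i]:.6f}\n"
            )


def read_logo_data(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read heights TSV back; returns (heights positions x 4, info per position)."""
    lines = Path(path).read_text().splitlines()[1:]
    rows = [ln.split("\t") for ln in lines if ln]
    heights = np.array([[float(x) for x in r[1:5]] for r in rows])
    info = np.array([float(r[5]) for r in rows])
    return heights, info
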