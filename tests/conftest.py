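"""Shared fixtures: synthetic loci and annotation references.

Everything is generated programmatically from seeded blueprints, so tests
need no external data files.
"""

from __future__ import annotations

import pytest

from trkit.germline import DEGENERATE, AnnotationReference
from trkit.simulate import (
    build_synthetic_locus,
    default_trb_blueprint,
    default_trg_blueprint,
)


def reference_from_truth(locus) -> AnnotationReference:
    """Bootstrap scanner training material from a simulator ground truth:
    in-frame V sequences, functional/ORF J sequences, and the exons of one
    functional C gene."""
    v_seqs = [
        g.nt_sequence for g in locus.genes if g.gene_type == "V" and DEGENERATE not in g.defects
    ]
    j_seqs = [
        g.nt_sequence
        for g in locus.genes
        if g.gene_type == "J" and g.functionality in ("F", "ORF")
    ]
    c_gene = next(g for g in locus.genes if g.gene_type == "C" and g.functionality == "F")
    c_exons = [locus.sequence[s:e] for s, e in c_gene.exons]
    return AnnotationReference(v_sequences=v_seqs, j_sequences=j_seqs, c_exons=c_exons)


@pytest.fixture(scope="session")
def trg_locus():
    return build_synthetic_locus(default_trg_blueprint(), seed=7)


@pytest.fixture(scope="session")
def trb_locus():
    return build_synthetic_locus(default_trb_blueprint(), seed=11)


@pytest.fixture(scope="session")
def trg_reference(trg_locus):
    return reference_from_truth(trg_locus)
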