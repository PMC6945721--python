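# Methods

`trkit` implements the computational core of a T-cell-receptor (TR) locus
study as a reusable pipeline: germline gene discovery and IMGT-style
classification in genomic sequence, recombination-signal (RS) profiling,
expressed-repertoire analysis from paired-end 5'RACE reads, and V-REGION
phylogenetics. Because real TR loci and repertoire libraries are large
external resources, the package ships a ground-truth simulator; every
pipeline stage is validated closed-loop against what the simulator planted.

## Germline annotation model

A V, D or J gene is recognized by the conjunction of two signals:

1. **A recombination signal.** Every candidate must carry an RS — heptamer
   (consensus `CACAGTG`) + 12- or 23-nt spacer + nonamer (consensus
   `ACAAAAACC`) — on the correct side: 3' of V genes, 5' of J genes, both
   sides of D genes. Detection is an exhaustive sliding-window scan scored
   by summed heptamer+nonamer log-odds (log2 vs a uniform background), with
   a default acceptance threshold of half the maximum attainable score.
   The threshold trades sensitivity against false positives: at half-max a
   random window passes with probability ~3e-6, i.e. well below one
   spurious hit per 100 kb scan, while any motif within roughly four
   consensus mismatches still passes.
2. **A coding-region score.** V candidates are scored by a per-length
   position-specific nucleotide log-odds profile trained from a provided
   germline set (in tests, bootstrapped from the simulator truth); the
   acceptance threshold per length is mean(training self-scores) − 3 SD
   (60% of the mean when fewer than three sequences share a length, where
   an SD is not meaningful). A lower "relic" threshold (25% of the mean
   self-score) admits heavily degenerate pseudogenes when requested; relics
   never enter profile training or numeric subgroups and receive lettered
   names. J candidates are matched against reference J sequences by edit
   distance (≤ 25% of length), requiring a `GT` splice donor at the gene
   end (a candidate without one is still reported, with a missing-splice
   defect). C genes are located by exon-wise local similarity to a
   reference exon set with canonical `GT`/`AG` intron boundaries; the
   search takes the *nearest* acceptable match for each successive exon so
   that tandem C copies are not chained together.

**Spacer policy.** Defaults are V 3'RS = 23 nt, J 5'RS = 12 nt, D genes
12 nt (5') / 23 nt (3'), so both direct V–J joins (TRA, TRG) and V–D–J
joins (TRB, TRD) satisfy the 12/23 rule. The policy is configurable per
locus.

**Functionality.** Defects collected during scanning map onto the IMGT
classes by fixed precedence: stop codon, frameshift or degeneracy ⇒
pseudogene (P); otherwise non-canonical RS, missing anchor or missing
splice ⇒ ORF; otherwise functional (F). Frameshifts are called from the
*net* indel (mod 3) of the alignment against the reference — an optimal
edit path may trade two substitutions for a balanced insertion/deletion
pair, which is not a frameshift. For J genes the reading frame is anchored
at the 3' end (the frame that closes at the splice donor), so a 1-nt loss
between the [FW]GXG motif and the gene end shifts the motif out of frame
and is detected as a frameshift even without a reference.

**Canonicality.** The canonical flag on an RS requires the heptamer to
start `CAC` and the nonamer to keep a poly-A tract (≥ 5 adenines over the
nonamer); only the heptamer condition gates F vs ORF, since the first
three heptamer positions are the ones mechanistically required for
recombination. (The poly-A condition is evaluated over the whole nonamer
rather than a fixed sub-window, because the tract sits at positions 3–7 of
the consensus.)

**IMGT numbering.** V-REGION translations are numbered 1–104 with fixed
framework spans (FR1 1–26, FR2 39–55, FR3 66–104) and all length variation
absorbed into CDR1 (27–38, ≤ 12 aa) and CDR2 (56–65, ≤ 10 aa), gaps at the
top of each loop. The placement enumerates CDR lengths and keeps the one
recovering most anchors (C23, W41, hydrophobic 89, C104); ties prefer
longer CDRs, then shorter CDR1. Sequences whose length admits no placement
return an explicit failure value rather than raising.

**Identity and subgroups.** Percent identity uses an end-gap-free global
alignment (match 1, mismatch 0, gap open −5, extend −1); the denominator
excludes terminal-gap columns, and values are reported to 0.1. Subgroups
are single-linkage clusters of V-REGIONs at the configurable cut-off
(default 75%, "more than" — strictly greater, except that exact duplicates
always co-cluster). Subgroups are numbered by the locus position of their
5'-most member; members get a `-k` index in locus order; both choices make
naming deterministic and input-order invariant.

**Locus map.** TRG cassettes are delimited by their transcriptional
opening gene — a V on the forward strand or a C on the reverse strand
(inverted cassettes read C..J..V in forward coordinates) — once the
previous unit holds both a V and a C. TRB/TRD clusters are delimited by
their D gene; V genes, including a 3' inverted V after the last C, sit
outside clusters. In a nested TRA/TRD locus each gene's own locus tag
drives the rule, with TRA J/C genes forming one terminal J-C unit.

## Repertoire pipeline

Reads are quality-trimmed with a sliding window (default width 4, Q30):
the read is cut at the first window whose mean quality drops below the
threshold, and reads shorter than 50 nt are dropped. Pairs merge by the
overlap (≥ 20 nt) with the fewest mismatches (≤ 8; ties to the longer
overlap); disagreements resolve toward the higher-quality base. A fast
path anchors the exact mate prefix in the forward read and falls back to a
full overlap scan.

V and J calls use edit-distance alignment (edlib, infix mode) of each
germline gene against the merged read — V in the 5' part, J downstream of
the V match. Floors: ≥ 60% identity over a ≥ 50-nt V and a ≥ 14-nt J. The
**ambiguity set** contains every gene within 1 edit of the best score, in
locus order; this reproduces the situation where two J genes differing by
a single 5' nucleotide become indistinguishable once that nucleotide is
trimmed. Usage statistics split ambiguous calls fractionally (1/k), which
conserves totals; a merged-category mode ("J2-2/J3-2") is available. D
labelling is best-effort — the longest exact match ≥ 5 nt between the
junction interior and a D gene — and never affects productivity, because
short D remnants are unreliable.

The junction runs from the cys-104 codon through the J-PHE/J-TRP-118 codon
inclusive; CDR3 is the junction minus both anchor codons. The V-side
anchor is mapped through the alignment path from the V 5' end (which is
never trimmed); the J-side anchor is placed relative to the *end* of the J
alignment (the J 3' end is never trimmed), because an optimal alignment of
a 5'-trimmed J may absorb the missing prefix into the N region and
misplace path-mapped positions. Productive requires an in-frame,
stop-free junction with both anchor residues (C … F/W) present.

Per-sample usage frequencies are computed over called rearrangements and
sum to 1; cross-sample medians and quartiles use linear interpolation,
outliers lie beyond 1.5 IQR. The V×J pairing matrix is ordered by
chromosomal gene order, classifies pairs intra- vs inter-cassette through
map unit indices (never names), and tallies per-J-locus totals for nested
TRA/TRD data.

## Simulator

The simulator is the package's source of ground truth, emulating the
structures the annotation stage must recover and the read data the
repertoire stage consumes.

* **Loci.** Blueprints describe cassette (TRG-style: five V-J-(J)-C units,
  12 V genes in 6 subgroups of sizes 4,4,1,1,1,1, half the V genes
  pseudogenized), D-J-C-cluster (TRB-style: a V array, two clusters of one
  D + six J + one four-exon C, a 3' inverted V) and nested TRA/TRD
  layouts. V genes are built from random codons around the four anchors
  (TRG V genes additionally carry the IHWY motif at positions 39–42);
  subgroup members diverge from a common ancestor at 6% per base (J genes
  at 15% — J genes are short, and members must stay separable by more than
  the 1-edit call margin), with anchors, motifs, terminal bases and
  stop-free frames repaired after mutation. Planted defects are the
  detectable kinds the study describes: stop codons in V, frameshifts or
  stops in J, exon frameshifts in C, and a non-canonical first heptamer
  base for ORF genes. Functional V/J RS elements are drawn from a
  generating frequency model whose variable positions (heptamer 5 and 7,
  nonamer 9) are the less-conserved ones; D RS elements are consensus.
* **Rearrangements.** Amplicons are adapter + trimmed V + N +
  [trimmed D + N] + trimmed J + the 5' stub of a constant region,
  mimicking a template-switch 5'RACE library read from a C-region primer.
  Only F/ORF genes rearrange. Trimming is geometric (mean ≈ 1.9 nt per
  side by default), N-insertions Poisson (λ = 3); both distributions are
  conventional choices for repertoire simulation, exposed in the config.
  Default usage concentrates 95% on the largest functional subgroup, and J
  genes are drawn intra-cassette with probability 0.8 — the kind of
  dominance and cassette preference the pipeline is meant to quantify.
* **Reads.** 2 × 300 paired reads from opposite amplicon ends,
  substitution errors at rate ε (default 0.005). Correct bases carry Q38
  (Q40 at ε = 0) and error bases Q20, so a Q30 sliding window removes
  error-dense stretches rather than whole reads; indel sequencing errors
  are not modelled. All randomness flows from one seeded generator —
  a fixed seed reproduces loci, amplicons and FASTQ byte-for-byte.

**What the simulator does not emulate:** PCR amplification bias and
chimeras, UMI structure, somatic hypermutation (not applicable to TR),
allele diversity, leader exons, and indel sequencing errors. Passing
closed-loop tests therefore demonstrates the correctness of the
algorithms under the stated generative model, not performance on real
MiSeq libraries, where primer artefacts and coverage heterogeneity add
failure modes this model excludes.

## Phylogenetics

Distances over aligned V-REGION sets use pairwise gap deletion with either
the raw p-distance (default — robust at the short divergences between
subgroup members) or the Jukes–Cantor correction
d = −(3/4) ln(1 − 4p/3), which rejects saturated pairs (p ≥ 0.75). Trees
are built by Saitou–Nei neighbor joining with the standard Q-criterion;
ties break on the lowest taxon-index pair and negative branch estimates
are clamped to zero and counted, so construction is deterministic.
Bootstrap support is the percentage of column-resampled replicate trees
containing each internal bipartition of the full-data tree; replicates in
which a JC69 pair saturates are skipped (they contribute no support). The
implementation is cross-checked in the test suite against scikit-bio's
independent neighbor-joining on random additive matrices.

## Numerical and design choices

* Internal coordinates are 0-based half-open on the forward strand
  everywhere; only the GFF3 writer converts (to 1-based inclusive).
  Reverse-strand genes store forward coordinates plus a strand flag.
* PWM columns use pseudocount 0 by default (logo heights are raw relative
  frequencies); profile training uses pseudocount 0.5. Log-odds floor
  frequencies at 1e-3 to keep scores finite.
* Overlapping gene candidates (> 50% mutual overlap) are resolved to the
  higher-scoring one.
* The gene-level comparison in closed-loop tests is exact on coordinates,
  strand, type and functionality.
* Problem sizes in tests and in `scripts/acceptance.py` — a ~12 kb TRG
  locus with 27 genes, nine libraries of 10,000 reads at ε = 0.005, one
  5,000-read error-free library, 500-element RS samples, 5–8-taxon trees —
  are chosen so each stage's statistical claims (3-SE bands, KL < 0.01)
  are meaningful while a full run stays in the minutes range on one CPU.

## Known limitations

* The annotator labels every gene of a nested TRA/TRD locus under the one
  locus id it is given; telling TRD-embedded genes from TRA genes requires
  per-locus reference sets and is left to the caller (the simulator's
  germline carries true locus tags, which the pairing analysis uses).
* J genes trimmed beyond the identity floor (~0.5% of reads at default
  trimming) are unassignable, exactly as in real pipelines; attrition is
  independent of gene identity and therefore does not bias usage.
* Allele (\*01/\*02) calling, leader exon modelling, UMI handling and
  clonotype collapsing are out of scope.
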