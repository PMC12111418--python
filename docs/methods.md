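# Methods

This note documents the models, conventions and numerical choices behind
mitochar, and what the synthetic-data tests do and do not establish.

## Coordinate model and circular structure

Coordinates are 1-based and fully inclusive, the convention of published
mitogenome annotation tables; light-strand (L) genes, which such tables print
with descending coordinates, are stored ascending with a strand flag. The
signed spacer between consecutive features is
`downstream.start − upstream.end − 1` (positive gap, negative overlap), and
the wrap-around pair closing the circle contributes
`(length − last.end) + (first.start − 1)`. This makes the closure identity

```
Σ feature sizes + Σ signed spacers = genome length
```

an exact integer invariant of any circular annotation, which the test suite
asserts on the bundled reference annotation (16,558 + 48 = 16,606) and on
every simulated genome. Features wrapping the origin are not supported: the
canonical vertebrate gene order ends with the control region flush against
the origin, so none occur; this is a documented v1 limitation. The wrap
adjacency enters the spacer/overlap censuses only when nonzero, so an
abutting wrap leaves the printed counts unchanged. Feature order is
(start, end, name), a stable tie-break for abutting features.

Stop codons are classified from the coding-strand CDS: complete
TAA/TAG/AGA/AGG when the length is a multiple of three, the incomplete forms
T-- and TA- when one or two bases remain (completed to TAA by
polyadenylation of the mRNA). Overlapping genes are treated independently:
shared bases are counted in both genes' sizes and codon extractions, which
is how the published per-gene sizes are defined. The concatenated-PCG region
is likewise the independent join of the 13 annotated intervals (11,410 bp on
the reference template); the published table prints 11,403 bp for this row
and does not say which 7 bases it excluded, so no adjustment is attempted.

The O_L search scans the longest intergenic gap for the hairpin maximizing
exact Watson–Crick stem length, ties broken by smaller loop then leftmost
position, with loop ≥ 3; it is validated against exhaustive enumeration on
all windows up to 50 bp.

## Composition and skews

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), always computed from
raw counts, never from rounded percentages; N is excluded from all
denominators, and a zero denominator yields a flagged undefined value rather
than 0. Per-gene rows are reported in heavy-strand orientation for parity
with published composition tables — this is what makes the light-strand ND6
row show inverted skews — while codon-position pooling uses coding-strand
orientation, which translation requires. Parity checks against printed
percentage tables use the printed 1-decimal values, so recomputed skews are
compared at the table's own rounding resolution.

## Codon usage

Counting uses NCBI translation table 2 (vertebrate mitochondrial). The
taxon's GTG start and AGA/AGG-as-stop conventions require this table; it is
a parameter everywhere. Complete terminal stop codons are excluded,
incomplete stops contribute no codon, codons containing N are skipped, and
internal stops warn (with position) rather than fail, since real annotations
occasionally contain them. Alternative start codons are counted as their
table amino acid (GTG as Val), not forced to Met — the simplest defensible
rule, flagged here. On the reference template this yields exactly 3794
encoded amino acids, matching the published count, which indicates the
original tally also counted overlap codons once per gene. RSCU follows
count·k/n_aa; unused families are flagged undefined rather than zero.

## NG86 selection analysis

The estimator is the classic Nei–Gojobori counting method with the
conventions DnaSP and MEGA default to:

- per-position fractional synonymous sites over the 9 single-base neighbors,
  with mutations to stop codons excluded from both site classes (so
  S + N ≤ 3 per codon, equal when no neighbor is a stop);
- sites averaged over the two sequences of a pair;
- observed differences averaged with equal weights over all minimal
  mutational pathways, excluding pathways through stop codons; when every
  pathway is blocked, all pathways are used with stop-touching steps counted
  as nonsynonymous (a degenerate case that cannot arise between sense codons
  differing at one position);
- Jukes–Cantor correction of pS and pN, with p ≥ 3/4 flagged saturated.

Codon columns containing gaps, N, or a stop in either sequence are skipped.
The implementation is validated against independent exhaustive-enumeration
oracles (all 60 sense codons for sites; 500 random codon pairs for pathway
averages) and is exactly symmetric in its arguments. Gene-wise summaries
average over all C(n,2) pairs and report both aggregations — mean(Ka)/mean(Ks)
and the mean of defined pairwise ratios — because published per-gene means
rarely state which was used.

## Simulator

The simulator is template-driven: the default template is the reference
annotation, so gene order, sizes, strands and codon forms are reproduced
exactly (GTG start for COX1, TAG stop for ATP8, five T-- and one TA-
incomplete stops). Non-coding regions are sampled i.i.d. from the published
per-region base percentages (D-loop A+T target 66.1%); PCGs are sampled
codon-wise from the published codon-position compositions conditioned on not
being a stop. Where genes overlap, bases written first are locked and later
genes sample codons conditioned on them, so all overlapping reading frames
are simultaneously intact — the same constraint the real genome satisfies.
L-strand features are inserted as reverse complements. A 5+5 bp inverted
repeat with a short loop is planted mid-way in the longest gap to emulate
the O_L hairpin.

The published region rows are not mutually consistent with the printed
full-genome row to better than about one percentage point (their
size-weighted mean gives A ≈ 30.3% against a printed 31.4%), so the
simulator targets regions individually and the composition test compares the
realized genome against the exact expectation implied by the configured
mixture (±1% at 16.6 kb), not against the printed full-genome row.

Family evolution is a continuous-time codon substitution process:
single-nucleotide neighbor moves with transition/transversion factor kappa,
nonsynonymous moves damped by omega, stop-codon targets rejected, simulated
per codon by Gillespie sampling. Branch lengths are expected substitutions
per codon, calibrated against the root sequence's composition. kappa
defaults to 1 because the NG86 estimator assumes no transition bias; the
neutral-recovery test (omega = 1 estimated within ±0.15) is a test of the
estimator, not of bias correction, and raising kappa deliberately introduces
the well-known NG86 underestimation of Ka/Ks. Purifying-regime tests use
star trees with tip branches of 0.25 substitutions/codon, placing pairwise
synonymous divergence in the 0.4–0.6 range typical of congeneric cyprinid
mitogenomes, with omega = 0.1.

Clade datasets evolve each PCG family along a shared guide tree (three
clades use the nested shape cladeA,(cladeB,cladeC); within-clade tip
branches 0.02, between-clade stems 0.25) and paste the evolved CDSs back
into copies of the ancestor genome. Across overlaps the later gene wins, so
extracted overlap codons can disagree between frames — a few codons per
genome, analogous to alignment artifacts in real concatenations, and
irrelevant to distances at supermatrix scale.

What the simulations do not emulate: tRNA secondary structure, indels and
alignment error, rate variation among sites and lineages, base-composition
heterogeneity along branches, and recombination. Passing tests therefore
establish the correctness of the statistics and algorithms under their own
model assumptions, not robustness to real-data violations of them.

## Phylogenetics

Jukes–Cantor distances exclude gap/N sites pairwise; saturated pairs are
flagged and assigned the distance just below saturation at their site count
so downstream joining still works. Neighbor joining is the standard
Saitou–Nei Q-criterion algorithm with two determinism guarantees: ties in Q
are broken by the lexicographically smallest label pair, and negative branch
estimates are clamped to zero with a warning. On additive matrices the
reconstruction reproduces all path lengths to 1e-9, which the tests assert
on 4- and 6-taxon trees. Alignment itself is out of scope; inputs must be
pre-aligned (the simulator emits gap-free homologous sequences). Likelihood
and Bayesian inference, model selection, and bootstrap support belong to
dedicated external tools and are deliberately not reimplemented.

## Problem sizes

Default test and acceptance runs use the 16.6 kb template, families of 6–7
taxa with genes at their template lengths (165–1,824 bp), 500-codon-pair
oracle sweeps, and 4 replicate neutral families of 600 codons — sizes at
which every oracle comparison is exhaustive and the full suite runs in a few
seconds on one core.
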