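# Methods

This note documents the models, estimators and numerical choices behind
`terep`, and what the synthetic-data generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open. RepeatMasker `.out` and
`.align` files and GTF (1-based inclusive) are converted at parse time and
converted back on write, so a parse/write round trip restores the printed
numbers. Conservation is consumed as bedGraph text rather than bigWig: the
toy tracks are small, the format is lossless, and no binary dependency is
needed. The RepeatMasker ID column is used as the copy identifier joining
`.out` rows to `.align` blocks; when absent, `chrom:start-end:subfamily`
is substituted. Missing conservation values are excluded from window
means, never zero-filled (zero-filling would bias site/control contrasts
toward whichever group has more gaps).

## Summit assignment

A binding site is the 1-bp peak summit. A summit is assigned to a TE copy
by point-in-interval containment. RepeatMasker output rarely overlaps
after processing, but where annotations do overlap the copy with the
higher Smith–Waterman score wins, ties broken by smaller interval and then
lexicographic copy id — a deterministic rule independent of input order.
Joined fragments sharing a RepeatMasker ID count as one copy. "Shared
between cell types" is defined at the copy level (the same copy id bound
in both cells), not by base-identical summit coordinates, because summit
positions jitter between experiments.

## Enrichment model

For family *f* with *k* of *n* summits and background proportion
*p₀ = k₀/n₀* (input reads in *f* / input reads sampled), fold enrichment
is `(k/n)/p₀` and significance is an exact two-sided binomial test of *k*
given *(n, p₀)* by the minimum-likelihood rule: the p-value sums P(X = i)
over all *i* with P(X = i) ≤ P(X = k)·(1 + 1e-7). This is the convention
of mainstream statistical software (`scipy.stats.binomtest` implements
exactly this rule and is used as the implementation; the test suite
checks it against independent full-pmf enumeration for all n ≤ 50).
Bonferroni correction uses m = the number of family groups actually
tested in the run, not a hard-coded library size; significance is called
at adjusted p < 0.001. Because the test is two-sided, strongly *depleted*
families can also reach significance — in a small dense toy genome this
dominates unless per-family background proportions are kept low, which is
why the demo uses a 600-kb genome with ~8% TE content (per-family p₀ of
2–3%, comparable to the real ERV1 figure of 2.2% of input reads).
Families with zero input reads and zero peaks get an undefined fold
(NaN; +inf when peaks are present) rather than being dropped.

## K2P divergence

For each copy-vs-consensus alignment, columns with a gap or ambiguous
base in either sequence are excluded; P and Q are the transition and
transversion fractions over the retained columns and
K = −½·ln((1 − 2P − Q)·√(1 − 2Q)), reported ×100. When a log argument is
non-positive (substitution saturation) the copy's divergence is undefined
and excluded from the family mean, with a logged warning. No CpG
adjustment is applied. Family age is the unweighted mean over copies with
defined values.

## Consensus projection and clustering

`project_to_consensus` walks the gapped alignment columns, counting query
bases until it reaches the requested genomic offset (reversed walk for
reverse-orientation hits, whose gapped query is stored in consensus
orientation), and returns the consensus coordinate of that column.
Positions falling in a query insertion (consensus gap) project to nothing
by definition, so deletions in the copy can never produce phantom hits.

Clustering slides a window (default 50 bp, 1-bp step) over the consensus
and takes the maximum-count window; among tied maxima the middle offset
is chosen so that a tight pile of hits is centred in its window rather
than sitting at an edge. The null is uniform placement: the count in one
window is Binomial(n, w/L), tested two-sided and Bonferroni-corrected by
the number of distinct window offsets.

## PWM scanning

Log-odds scores log₂(p/b) are computed after adding a 0.001 pseudocount
to zero matrix entries; scores are scaled by 1000 and rounded to
integers, and the exact null distribution of the window score under the
background base frequencies is built by per-position convolution. The
reported p-value of a window is the exact survival probability of its
integer score. Both strands are scanned; windows containing non-ACGT
bases are skipped. The default reporting threshold is p < 0.01, the
conventional motif-occurrence cut-off. A family is flagged a
"propagation candidate" when its binding-position cluster is significant
(corrected p < α, default 0.001) *and* the cluster window overlaps a
motif match in the consensus; requiring both keeps the false-flag rate of
uniform-hit nulls at the α level even though a motif-free consensus of a
few hundred bp typically contains several chance matches at p < 0.01.

## Acquisition dating

Each binding site's 10-bp window (centred on the summit; the alternative
anchoring at the summit start differs by ≤ 5 bp and is immaterial at
chain-block scale) is mapped through each species' pairwise chains; the
site is present in a species when ≥ 95% of the window maps through a
single chain, mirroring liftOver's `-minMatch` default (exposed as a
parameter). The acquisition clade is the MRCA of human and the most
distant present species, distance measured by MRCA node age; the
polytomous eutherian root is a single node, so any of its non-human
descendants dates a site to Eutheria. `absent` and `unalignable` are
recorded separately but treated identically for inference. A call older
than the host subfamily's known clade distribution is clamped to that
clade and flagged as a spurious mapping. Branch rates divide each origin
node's site count by its branch span (parent age − node age); the root
and zero-length branches yield flagged undefined rates.

## Chromatin states and conservation

Sixteen chromatin-state labels are collapsed to five categories
(cis-regulatory = promoters + enhancers, transcription, quiescent/low,
heterochromatin, other) through a mapping table; a default table ships
with the package and any other mapping can be supplied. Segmentation
training is out of scope — segmentations are inputs. Cis-regulatory
enrichment is the same exact binomial test with p₀ equal to the
cis-regulatory fraction of sampled input positions. Transition matrices
cross-tabulate categories of the same cell-type-specific sites in both
segmentations; sites lacking a state in either cell are excluded from the
matrix but reported in the total, so both denominators are available.
Conservation comparisons use per-site means over a 2-kb window (missing
positions excluded) and Welch's t-test with Welch–Satterthwaite degrees
of freedom.

## Nearest genes and expression classes

Each summit links to the nearest transcript TSS (collapsed to its gene;
ties at equal distance go to the smaller gene id), with no distance cap.
Distances are signed negative when the summit lies upstream of the TSS
relative to transcription. Fold change is log₂((NPC + c)/(ESC + c)) with
pseudocount c = 0.01 (configurable) so zero-RPKM genes stay finite; genes
with zero RPKM in both cells are excluded as uninformative. The strong
classes use |log₂FC| ≥ 3; the boundary is inclusive so that an exact
eightfold effect — the class's defining magnitude — is counted.

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their content:

* **TE copies** are drawn by mutating a family consensus under the K2P
  substitution process at expected distance d (transition:transversion
  rate ratio κ, default 2), using the exact K2P transition probabilities
  at distance d, so the divergence estimator is consistent by
  construction. Indels are off by default (consensus offsets are then
  trivially known); a nonzero indel rate inserts/deletes short segments
  and records the true gapped alignment, exercising the gap-aware
  projector.
* **Motifs**: the PWM consensus string is written into the family
  consensus at position p\*; a fraction f of copies keep it (carriers),
  the rest have the motif window re-randomised before mutation. The
  re-randomised window adds a small apparent divergence
  (≈ 0.75·w/L per non-carrier copy) to motif-bearing families; families
  used for divergence-recovery checks therefore carry no motif.
* **Summits** sit at the genomic centre of each planted motif instance
  (cell types per config, with a configurable shared fraction for
  dual-cell families); background summits are uniform over non-TE
  sequence by default so TE-binding ground truth is unambiguous, with a
  `uniform` mode for null calibrations where summits must follow the
  input-read distribution. Input reads are uniform over the genome.
* **Function layers**: 200-bp state tiles drawn from a quiescent-heavy
  distribution (cis-regulatory ≈ 8% of tiles, matching the order of real
  genome fractions); bound-TE tiles become active enhancers with a
  configured probability, and ESC-only bound tiles transition to
  quiescence in NPC with a configured probability. Nearest genes of
  NPC-bound TEs receive a multiplicative expression effect (default 8×,
  applied with probability `effect_prob`). Ortholog presence marks all
  species inside each copy's true acquisition clade (configurable random
  loss), and per-species chain files covering exactly the present-site
  windows are emitted so the chain mapper can re-derive the presence
  table. Conservation is a binned track elevated by a configured delta
  around bound summits.

Identical seed and config give byte-identical output files.

What the generator does **not** emulate: mappability and read-depth
structure (the real study's MAPQ filtering and its bias against young
TEs), fragmented/nested repeat annotations, non-uniform input-read
coverage, peak-caller artefacts, genuine phylogenetic rate variation, and
expression dispersion beyond a lognormal noise term. Tests passing on
synthetic data therefore validate the estimators and the pipeline
plumbing under the stated models, not robustness to those real-data
complications.

## Problem sizes

The shipped demo uses a 600-kb genome, 140 TE copies in three families,
≈ 100 summits per cell type and 30,000 input reads; divergence-recovery
checks use 200 copies × 500 bp per family; null calibrations use 100
independent replicates of a 10-family all-background genome. These sizes
keep every estimator in its well-behaved regime (binomial backgrounds of
≥ 400 expected TE reads per family; K2P standard errors ≈ 0.1% per
family) while remaining quick to run.

## Known limitations

* The chain mapper handles `+`-strand chains only; strand-flipping
  chains are out of scope for the toy fixtures.
* `infer_acquisition` trusts presence flags; it has no model of
  alignment false positives beyond the TE-age clamp.
* The two-sided enrichment test flags depletion as well as enrichment;
  downstream reporting does not currently separate the two directions
  (the fold column disambiguates).
* PWM p-values assume an i.i.d. background; low-complexity consensus
  sequence will miscalibrate them, as with any zero-order null.
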