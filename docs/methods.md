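# Methods

## The system being modelled

A segmental-duplication locus of the IGHV kind: a region of tens of kb in
which a large unit (here 24,696 bp) exists in two complete tandem copies
plus one truncated copy (961 bp), each complete copy carrying six gene
segments (one functional and two pseudogene segments per family for the two
families modelled). The copies have diverged by point substitution to a
level (~4.4%) overlapping allelic variation, and haplotypes in the
population differ both by deletion of whole repeat units and by further
point divergence. The package's pipeline reconstructs haplotype structure
from single-gamete tag assays and measures the duplication from sequence
alone.

## Synthetic data: what it emulates and what it does not

`ighvdup.synthetic` generates the study material: an ancestral region of
uniform base composition with gene-segment templates placed at controlled or
pseudo-random positions; a planted tandem duplication whose copies are
independently mutated at a per-copy substitution fraction (so two complete
copies sit at roughly twice that fraction pairwise — 2.2% per copy gives the
study-like ~4.4%); and donor haplotype pairs derived by deleting repeat-unit
copies and/or adding extra divergence within the repeat spans.

Mutation is substitution-only by default. This makes every difference count
downstream unambiguous (alignment of equal-length copies is gap-free and the
generator's realized substitution count is the ground truth for difference
accounting). One optional random insertion per duplication
(`DuplicationSpec.insertion_length`) mimics a transposon insertion private
to one copy; it is off by default and excluded from divergence accounting.

Not emulated: realistic base composition and repeat content (uniform
A/C/G/T background), recombination/crossover within the region (each sperm
carries one parental haplotype intact, consistent with the two clean
patterns per donor that motivate the design), gene conversion, microarray
intensity physics (detection is binary with noise), and diploid
contamination. Consequently, passing tests demonstrate the correctness of
the algorithms under the stated generative model, not robustness to
assembly artifacts or crossover in real gamete panels.

The ancestral order of events is truncation-then-duplication by default
(the truncated pseudogene templates are truncated before the unit is
copied), matching the observation that paralogous copies of the truncated
segments have near-identical lengths; the generator accepts templates of
either form, so the opposite order can be produced by supplying full-length
templates and truncating afterwards.

## Tag design

Tags are ≤ 225 bp (default 150 bp) windows chosen greedily left-to-right,
one per 5 kb interval: the first window past the interval boundary that
overlaps no gene segment and occurs exactly once in the region
(forward-strand exact scan; the original genome-wide uniqueness search is
out of scope and an in-region scan is sufficient for synthetic material).
Intervals with no unique non-coding window — e.g. inside an exact tandem
repeat — are skipped and returned as warning records. Names follow the
field's convention: `VHS` + start offset in kb.

Per tag, four oligos: forward and reverse primers at the tag ends, a nested
primer just internal to the forward, and a probe internal and close to the
nested primer in reverse orientation. The probe site is the first placement
whose adjacent template base (the base templating the probe's single-base
extension) is A or G; this base is recorded as `extension_base` (A → ddUTP
channel, G → ddCTP channel — the two-dye bookkeeping is carried but
intensities are not modelled). Primer/probe lengths default to 22/22/21/21
nt within the conventional 18–27 / 20–24 ranges; melting-temperature
balancing is not modelled because no thermodynamic claim is tested.
Primer-dimer screening scores the longest perfect 3'-terminal complementary
overlap between any two primers (threshold 4), symmetric and including
self-complementary 3' ends.

## Detectability and the assay simulation

A tag is undetectable on a haplotype when (a) any oligo footprint has no
match within 1 edit anywhere in the haplotype, (b) the extension-template
base adjacent to the probe differs from the designed A/G, or (c) a primer
carries any mismatch within its 4-base 3'-terminal window (extension from a
mismatched 3' end fails even if the primer anneals). Footprint search uses
edlib infix alignment. These rules reproduce the observed mechanisms: a
two-base substitution mid-probe kills detection at tolerance 1; a
polymorphic extension base alone kills it; a deleted region matches
nothing. They also make deletion of one repeat copy undetectable at
study-level copy divergence (~4.4%): the surviving paralog's sites are
beyond tolerance — so undetectability deliberately conflates deletion with
divergence, exactly the ambiguity the real assay has.

Observation noise is binary and independent per sperm × tag: dropout
(default 0.05 — allele dropout typical of single-cell multiplex PCR) flips
truly detectable entries to undetected; false positives (default 0.01)
flip absent entries to detected. Sperm carry H1 or H2 with probability 1/2.

## Phasing

Sperm are partitioned into two clusters by nearest-centroid refinement.
Seeding from the single most dissimilar row pair can land in a noise-driven
local optimum, so refinement restarts from the five most separated row
pairs and keeps the bipartition with the smallest within-cluster
dispersion (deterministic; no randomness). Per tag and cluster, the
consensus is `+` when ≥ 70% of assigned sperm detected the tag, `ud` when
≥ 70% did not, `-` (unresolved) otherwise. A panel-size precondition of
2×5 sperm and a minimum cluster support of 5 apply.

Gametes from a heterozygous donor segregate 1:1, so a genuine cluster holds
about half the panel; if the smaller cluster ends below max(5, 20% of
sperm), the bipartition is judged no better than a single cluster and both
haplotypes report the common pattern. This keeps homozygous (no-variation)
donors from acquiring phantom haplotype differences out of correlated
dropout.

Downstream logic treats `-` as undetectable but preserves it in output
(the three-symbol alphabet is reported as-is): runs are maximal stretches
of consecutive `ud`/`-` tags; per-tag classes are `undetectable_in_all`
(literally `ud` everywhere), `polymorphic` (detection status differs
across haplotypes) or `non_polymorphic_detected`; the polymorphic region is
the minimal tag interval covering all polymorphic tags plus its nearest
detected non-polymorphic flanking tags.

## Dot-matrix comparison and block inference

Window matching defaults to 9 bp exact, the classic dot-plot setting for
this locus; a per-window mismatch budget is available (pigeonhole seeding,
identical output to the naive definition, verified against a brute-force
oracle). Matches on one diagonal chain into runs when consecutive window
starts are ≤ max_gap apart (default 50 bp — at ~4% pairwise divergence
exact 9-mers survive in fragments whose gaps this bridges); run length
spans first window start to last window end.

Tandem units come from the self-comparison: among positive diagonals with a
chained run ≥ min_unit, the diagonal with the greatest total run length is
the unit length d; the interval spanned by its runs (ignoring isolated
single-window matches, which are indistinguishable from background) is cut
into copies at multiples of d, a copy ≥ 0.9·d being complete and a shorter
trailing prefix incomplete. Boundaries are the chained window extremes —
no base-level realignment — so they are accurate to about one window.
Forward strand only by default: the modelled repeats are direct repeats.

## Divergence accounting

Global alignment is Needleman–Wunsch (Bio.Align.PairwiseAligner) with
match +1, mismatch −1, gap open −4, gap extend −1. The stiff opening
penalty is a deliberate numerical choice: with a cheap opening cost (−2), a
pair of short gaps can strictly out-score three-or-more clustered
substitutions whenever the mutations create accidental shifted homology
(~2% of 400 bp pairs at ≤ 10% divergence), silently converting
substitutions into indels in the counts; at −4 this did not occur in 500
trials. Difference counting and the percent denominator are explicit
conventions: differences default to substitutions plus indel events;
denominators default to the second sequence's length, which is what the
reference table's printed percentages divide by in all but two
repeat-vs-repeat rows (stored per row in `ighvdup.datasets` with the length
cell that reproduces the printed value). Percentages round half-up to two
decimals; the bases-per-1,200-bp translation rounds to one decimal. ORF
status translates concatenated exons in frame; a stop before the final
codon breaks the frame, a terminal stop does not.

## Clock

`t_point = G/(μ·L·f)` treats f = 18/61 as the per-mutation probability of
creating a stop — the convention that the headline 21.7 My figure is built
on. The refined per-mutation-path fraction (stop-creating single-base
changes over all 9·61 changes, which is smaller) is exposed as
`stop_hit_fraction(mode="path")` but is not the default. The all-causes
time divides by (1 + structural_multiplier) with multiplier 2, from the
observed ≈2:1 census of structurally- vs point-inactivated pseudogene
segments. Divergence time uses single-lineage accumulation `d·G/μ`, not the
2-lineage `d·G/2μ` — the reported ages assume the divergence is counted
against one lineage's clock; halving μ-attribution would double them.
Internal values are unrounded; presentation rounds to one decimal in
millions of years (21.7, 7.2, 99.1, 13.7 at the defaults — the formula
gives 99.09 My for d = 4.36%, conventionally quoted as ≈99 My).

## Pipeline and problem sizes

Stage sub-seeds derive from the master seed by SHA-256 of the stage name
(adding a stage never shifts another's randomness); with a fixed master
seed two runs are byte-identical including the manifest. The default
configuration is full study scale (~90 kb, 18 tags, six donors, 49–60
sperm) and completes in a few seconds. The test suite exercises scaled
versions chosen for statistical sufficiency: planted block recovery uses
600 bp units over 100 seeds; phasing recovery uses a ~8.6 kb donor with a
2 kb unit over 100 replicates; alignment self-consistency uses 400 bp
pairs over 100 seeds; dot-match oracle comparisons use ~2 kb sequences.

## Known limitations

* Boundary precision of block inference is window-limited (±9 bp) and
  degrades if copy divergence approaches the window's mismatch budget.
* Phasing assumes exactly two haplotypes, no crossover between tags, and
  1:1 segregation; panels violating these (e.g. diploid contamination)
  are out of scope.
* The difference-count identity between aligner and generator holds for the
  substitution-only model; with real indels the choice of counting
  convention materially changes percentages and must be stated.
* The uniqueness scan is in-region only; tags exported for a real assay
  would still need a genome-wide specificity check.
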