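# Methods

This note records the models, parameter choices and numerical
conventions behind `paleonumt`, and what the synthetic-data experiments
do and do not establish.

## Coordinate and sequence model

All mitochondrial coordinates are 1-based inclusive positions on a
16,569-bp circular reference with the standard human gene geometry
(packaged as `data/rcrs_genes.tsv`; editable TSV, not code). Light-strand
genes (ND6 and several tRNAs) are handled by reverse complementation,
with codon 1 beginning at the annotated `end`. Genes whose annotated
span is not a multiple of three (ND1, ND2, ND3, ND4, COX3, CYTB) end in
an incomplete stop codon completed by polyadenylation; the trailing
bases are flagged rather than forced into a codon. Overlapping reading
frames (ATP8/ATP6, ATP6/COX3 single-base, ND4L/ND4) are preserved;
where a single position must be reported under one gene, the
earlier-starting gene wins and `MtGeneMap.annotations_at` exposes the
full set. Origin-spanning features are rejected: neither locus analysed
here crosses the origin, and supporting them would complicate every
coordinate contract for no benefit.

Translation uses the vertebrate mitochondrial code (AGA/AGG stop,
ATA = Met, TGA = Trp), built from the standard table rather than typed
by hand.

The packaged reference *sequence* is synthetic: `random_mito_reference`
draws a random genome constrained so that every protein gene has an
intact reading frame (start codon, no internal stop, proper or
polyadenylation-completed terminus) including across the overlapping
frames, which are satisfied by constraint propagation plus iterative
local resampling. It has the real gene geometry but unrelated sequence
content; all tests that need a "reference" use it, so no real genome
data ships with the package.

## Numt discovery

Exact k-mer seeds (k = 12) against the doubled (circular) query are
clustered by diagonal (drift ≤ 50 bp, genomic gap ≤ 1 kb), extended by
ungapped X-drop (match +1, mismatch −2, drop 20, score ties resolved in
favour of the longer extension), and the final span is rescored by a
unit-cost global alignment; identity is matches over alignment columns
and the reported score is matches − mismatches − gap columns. Overlapping
candidates keep the highest score (ties: leftmost). Defaults mirror the
standard candidate filters: minimum alignment length 1000 bp, minimum
identity 90%. Scores from dedicated aligners (e.g. BLAT) are not
comparable; lengths and identities are.

The mismatch penalty of 2 for end extension is deliberate: a claimed
tail then requires at least two matches per mismatch, which recovers a
planted boundary exactly whenever terminal mutations are not denser
than one per three bases, while random flanking sequence (25% per-base
match rate) almost never extends past a few broken bases.

## Placement

Distances are Tamura–Nei (1993) with optional gamma rate heterogeneity
(shape α = 0.2 by default, the conventional value for mitochondrial
panels), pairwise deletion of gap/N columns, and a documented ceiling
(5 subs/site) for saturated pairs. Neighbor joining uses the
Studier–Keppler criterion with deterministic lexicographic tie-breaks
and clamps negative branch lengths to zero with a warning. Bootstrap
supports are bipartition frequencies over column resamples; for a
degenerate panel (all distances zero) the arbitrary resolution is
reported with all supports set to 0. During bootstrap the per-pair base
frequencies of the original alignment are reused across replicates
(the resampled frequencies differ negligibly and the reuse makes the
replicates cheap).

The placement verdict is purely topological. With humans H, Neanderthal
N and Pan P: the verdict is `basal_to_human_neanderthal` when H∪N is a
clade without the numt and H∪N∪{numt} is also a clade — i.e. the numt
attaches on the path between the H∪N group and P. `within_human` /
`within_pan` require the numt to attach inside the respective group;
anything else is `unresolved`. The verdict ignores branch lengths and
rooting and is invariant to leaf order.

## Clock dating

The HKY85 transition probabilities are evaluated in closed form
(decomposed as P(t) = A + B·e₂(t) + C·e₃(t) with frequency-only
coefficient matrices, cached), and site patterns are compressed before
pruning. The clock LRT compares the free-branch-length optimum (one
root-adjacent edge fixed at zero — only the sum of the two root edges
is identifiable under a reversible model) against the ultrametric
optimum parameterized by root height and per-node proportions, with κ
estimated in both models and base frequencies taken as empirical. The
statistic is referred to χ² with df = n − 2 for n tips. If the nested
inequality is violated numerically, the free model is restarted from
the clock solution; the statistic is clamped at 0.

`mcmc_date` samples node ages, rate and κ by single-parameter
Metropolis–Hastings updates. Ages are parameterized as a root age with
uniform calibration prior and per-node proportions u ∈ (0,1) with
uniform priors, so parent > child holds by construction and prior-only
runs recover the calibrations exactly (the prior-recovery test).
Optional internal calibrations act as truncations of the implied node
age. Rate and κ carry log-uniform priors over wide bounds
(10⁻¹¹–10⁻⁶ subs/site/yr; 0.5–200). Proposals are reflected sliding
windows (root: 30% of the calibration width; proportions: 0.12) and
log-space windows for rate and κ. ESS is estimated by the initial
positive sequence estimator, with a warning (not an error) below 100.
Because the rate prior is diffuse and scale-free, the root age is
essentially prior-dominated, exactly as in real calibrated dating; the
identifiable quantity is each node's age *relative* to the root.

The four standard calibration models are presets: root (human–chimp)
U(6, 8) or U(5, 6) Myr, with or without a U(0.5, 0.8) Myr calibration on
the human–Neanderthal node.

**Caveat — frozen branches.** A real numt stops evolving at the
mitochondrial rate when it is inserted; its terminal branch accumulates
~15× fewer substitutions than the clock expects. A strict-clock dater
applied to a panel containing the numt therefore *underestimates* the
numt's divergence time (the pipeline demo shows this: planted 620 kyr,
dated ≈ 380–500 kyr) and the clock LRT rejects strongly when the numt
terminal branch carries appreciable missing signal. The sampler's own
statistical calibration is instead validated on clock-consistent data:
with 8 taxa, 5 kb, the true root at 6.0 Myr under a U(5,6) Myr root
calibration, the 95% credible interval for a 0.6-Myr internal node
covers the truth in ≥ 90 of 100 replicates.

## Provenance tests

A site is private to the focal row when its (proper) base differs from
every non-gap state of the comparison rows; the reference state is the
comparison-row consensus and no outgroup polarisation is attempted at
this stage. CpG context (C→T with 3′ G, G→A with 5′ C) is read from the
consensus on the plus strand; edge positions are flagged
context-unknown. The codon-position test is an exact multinomial
goodness-of-fit (total probability of outcomes no more probable than
observed) for totals ≤ 200 and Pearson χ² (df = 2) above; both the
mitochondrial 2:1:5 and neutral 1:1:1 weightings are reported per gene.
Per-gene weighting (rather than genome-wide) matches the per-gene
structure of the substitution report.

Reading-frame scanning reports every codon translating to a stop before
the annotated terminus and every indel of length ≢ 0 (mod 3) inside a
protein gene. Repair policies: replace a premature stop with the
panel-majority codon, exclude the codon, or mask it; frameshifted
codons are always excluded, and codons without a panel consensus are
masked. The edit log drives codon exclusion in all downstream coding
analyses.

The one-line verdict is configuration, not science, and is documented
as such: with defaults, codon-bias p(2:1:5) ≥ 0.05 together with
ts/tv ≥ 4 (or zero transversions) reads as a mitochondrial signature; a
2:1:5 rejection that fits 1:1:1 reads as nuclear; anything else is
mixed. A focal row with no coding private changes is trivially
mitochondrial-signature.

## Selection tests

McDonald–Kreitman counting: per codon, changes are classified against
the human consensus codon, decomposing multi-hit codons position
1 → 3 in fixed order (deterministic; alternative-pathway averaging was
rejected to keep counts reproducible). A site variable within humans is
polymorphism (each derived allele counts once); a site fixed in humans
and different in the ancestral row is divergence; a site that is both
counts as polymorphism only — the standard MK construction. Fisher's
two-tailed exact p comes from summation of hypergeometric point
probabilities (the implementation is cross-checked against a brute
enumeration oracle in the tests). NI = (Pn/Ps)/(Dn/Ds), reported to 3
decimals, undefined when Ps, Dn or Ds is zero.

Amino-acid replacements are assigned to branches by Sankoff parsimony
with solution counting: the reported per-branch count is the expected
number of changes under the uniform distribution over *all*
most-parsimonious labelings, so homoplasy-free sites yield exact
integer counts and genuine ambiguities (including the unrooted
root-edge ambiguity) appear as fractions. Branch dN/dS uses
deterministic parsimony ancestral sequences, codon-by-codon
decomposition of each branch's changes, and Nei–Gojobori-style site
opportunities computed on the parent sequence (stop-creating changes
count as nonsynonymous opportunities). Rate-heterogeneous branches are
flagged by a two-sided binomial test of each branch's syn/nonsyn split
against the pooled split at the conventional Bonferroni-style 0.004
level. This counting estimator reproduces qualitative branch-model
conclusions (ratios < 1, branch heterogeneity) at a small fraction of
the cost of ML codon models, which are out of scope.

## Synthetic data: what it does and does not emulate

The generator evolves a sequence span along a dated hominin tree
(defaults: root 6 Myr, *Pan* split 2.5 Myr, numt divergence-and-insertion
620 kyr, human–Neanderthal split 500 kyr, four humans coalescing by
200 kyr). Mitochondrial-regime events draw sites with 2:1:5
codon-position weights inside protein genes, transitions with
probability 15/16, rate 1.5 × 10⁻⁸ subs/site/yr, and reject
stop-creating changes (purifying selection acts through both the
position weights and nonsense purging; explicit fitness is not
modelled). Nuclear-regime events are uniform across positions with
transition probability 2/3, rate 0.99 × 10⁻⁹ subs/site/yr, and a ×10
rate multiplier at CpG-context sites; because the multiplier raises the
*rate* at CpG sites while the base-change kernel stays κ-driven, CpG
enrichment does not distort the marginal ts/tv fraction. Indels occur
only in the nuclear regime (coding indels are inadmissible in
functional mtDNA). The numt lineage's divergence time equals its
insertion time — the coalescent lag between the two is real biology the
generator does not model, so "insertion age" here is strictly the
mtDNA divergence age.

Truth records carry every event (position, bases, branch, regime) and
replaying them reproduces each emitted sequence exactly.

For planted-genome fixtures the truth span must be *recoverable in
principle*: `plant_numts` resamples up to four flanking background
bases that would extend the homology by chance, and
`make_degraded_insert` keeps the outermost four insert bases
substitution-free. Without these constraints the true endpoint is
undefinable for any detector (a terminal mutation or a matching flank
base changes the maximal alignment), and coordinate-exactness tests
would measure luck rather than correctness.

Passing the synthetic experiments shows the machinery is correct under
the stated generative model. It does not establish performance on real
assemblies, where repeats, numt–numt duplications, heteroplasmy,
within-population coalescence and rate variation among genes all exist
and are out of scope.

## Problem sizes used by the validation experiments

The calibration experiments run at sizes chosen to give tight binomial
bands while staying desk-scale: clock-LRT type-I error over 1000
replicates (4 taxa, 2 kb); posterior coverage over 100 replicates
(8 taxa, 5 kb, 1500-sweep chains after 300 burn-in); scanner recovery
over 20 two-megabase genomes; placement power over 50 panels with
100 bootstrap replicates each; decay calibration over 1000 replicates
of a 5,842-bp numt at 620 kyr (expected 3.59 substitutions, checked to
±10%).
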