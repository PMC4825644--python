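# Methods

## Cross design and genetic model

The package models an F2 intercross between two fully homozygous
(isogenic, habitually self-fertilizing) strains.  The single F1 is
heterozygous at every marker that differs between the parents, and each F2
individual is the union of two independent F1 gametes (egg and sperm from
two meioses of the same fish).  Consequences used throughout:

* every marker segregates 1:2:1 (paternal homozygote : heterozygote :
  maternal homozygote), and the expected heterozygous fraction per F2 is
  exactly ½;
* all paternal alleles lie on one homolog (coupling phase), so two-locus
  genotype classes have the frequencies given below with no phase
  ambiguity;
* genotypes are coded as paternal-allele dosages 0/1/2 with −1 for
  missing, which turns crossover counting into sums of |dosage steps|.

## Recombination-fraction estimation

For loci with recombination fraction r, F1 gametes are parental with
probability (1−r)/2 each and recombinant with r/2 each.  The nine
two-locus F2 classes then have probabilities c², q², 2cq and
(1,1): 2c²+2q², with c=(1−r)/2, q=r/2.  All classes except the double
heterozygote determine their recombinant-gamete count exactly
(|d₁−d₂| ∈ {0,1,2}); the double heterozygote is a mixture of
parental×parental and recombinant×recombinant gamete pairs with expected
recombinant count 2r²/((1−r)²+r²).  The EM update

    r ← [ S_fixed + n₁₁ · 2r²/((1−r)²+r²) ] / (2N)

from r₀ = 0.25, clamped to [0, ½], converges to the MLE; the default
tolerance is |Δr| < 10⁻⁸ with at most 1000 iterations (non-convergence is
flagged, not fatal).  A brute-force likelihood grid is kept in the test
suite as an independent oracle, and a naive count estimator (double
heterozygotes counted as non-recombinant) is available as
``method="count"`` for sensitivity analysis.  Missing genotypes are
handled by pairwise-complete deletion; no imputation.  The all-pairs
matrix is computed with one-hot matrix products and a vectorized EM, so a
~1000-bin panel takes seconds.

LOD is log₁₀ L(r̂) − log₁₀ L(½).  Because the matrix EM iterates until the
slowest pair converges, matrix and scalar estimates agree to the
convergence tolerance rather than bit-exactly.

## Binning

Markers are processed in order of decreasing non-missing count (ties by
input order).  A marker joins an existing bin if it matches the bin's
consensus wherever both are observed; among several compatible bins it
joins the largest (ties to the earliest-created) and is recorded as
ambiguous; otherwise it seeds a new bin.  Joining fills previously missing
consensus positions.  The original analysis assigned ambiguous markers
"arbitrarily"; here the choice is deterministic so runs are reproducible —
it affects membership lists, not bin count or map structure.  A post-hoc
validation checks every member against its bin's final consensus.

## Grouping, ordering, refinement

Grouping is single linkage: connected components of the graph with edges
r̂ ≤ max_rf (default 0.15; the recovered group count is stable across
roughly 0.11–0.18 on clean data).  Components with ≥ 21 bins ("more than
20") are major; singletons are reported as unlinked.  Pairs with no
jointly informative individual contribute no edge.

Ordering starts from the bin pair with minimal r̂ and repeatedly appends
the unplaced bin with minimal r̂ to either chain end (ties: left end, then
earlier bin).  Refinement minimizes the total recombination-event count —
the sum over individuals of minimal crossovers along the ordered consensus
dosages, an integer — by a deterministic first-improvement local search
over (i) all permutations inside a sliding window of 4 bins, (ii) all
2-opt segment reversals, and (iii) relocation of segments of length 1–3 in
both orientations, repeated to a local optimum.  On 200 random 6-bin
instances this search matches exhaustive enumeration in ≈ 97% of cases;
the exhaustive oracle (≤ 9 bins) is available for verification.  The
objective is reversal-invariant, and at the study's sample size (49 F2)
exact ties occur — adjacent bins whose swap leaves the crossover count
unchanged cannot be ordered by the data, which is precisely where manual
reordering was needed in practice; tests therefore assert objective
optimality and rank agreement rather than exact sequence identity.

Double recombination events confined to a single interior bin (x–y–x
across three adjacent bins) are overwhelmingly genotyping errors under an
obligate-chiasma meiosis.  The package flags them
(`flag_double_recombinants`) and applies user-supplied correction files
(marker, individual, new code); it never silently edits genotypes.  The
analysis driver demonstrates the flag → set-to-missing → rebuild cycle,
which on the default noisy simulation deflates the map from ~2540 cM to
~1320 cM (each 1% miscall adds ~2 spurious events; errors at terminal bins
are not flaggable, leaving a small residual).

## Map assembly and statistics

Adjacent-bin r̂ is re-estimated on the final order (so distances reflect
pairwise-complete data at the final adjacency), capped just below ½, and
converted by Kosambi's function d = 25·ln((1+2r)/(1−2r)) cM (inverse
r = tanh(d/50)/2).  Orientation puts the terminal bin with more markers at
0 cM (ties: lexicographically smaller first bin id), making serialization
canonical under input reversal; groups are named LG1… by decreasing marker
count.  Bins are flagged p05/p01 when any member marker's 1:2:1 chi-square
P (raw, unadjusted — matching how such maps annotate distortion) falls
below 0.05/0.01.

Per-group statistics: length, mean adjacent spacing, largest gap, bins
holding ≥ 8% of the group's markers (tip pile-ups), the per-individual
event histogram 0/1/2/3+ with a 1:2:1 chi-square (3+ pooled with 2, since
triple events are rare but the test is 3-category), and per-bin marker
density per local cM.  Mean markers per bin is reported both as total
markers / total bins and as the mean of per-group means — the two
definitions differ slightly and published summaries do not always say
which was used.

## QC filters

Individuals: > 800 missing genotypes, or heterozygous fraction below 0.2.
The low-heterozygosity rule separates true F2 (~50%) from accidental
later-generation selfers (~10%); the exact historical cutoff is not
recorded, so 0.2 was chosen once as a value that cleanly separates the two
regimes, and it is configurable.  Markers: 1:2:1 chi-square P < 10⁻⁴
(filter applied first), then missing in > 7 individuals.  Both rules use
strict inequalities ("more than").  No continuity correction and no
multiple-testing adjustment, because the procedure being reproduced
filters on raw P.

## Phylogenetics

Strain consensus: per strain, a tag is discarded if absent in at least the
strain's threshold of individuals, heterozygous in any individual, or
carrying different homozygous alleles in different individuals (both
heterozygosity and within-strain polymorphism indicate repetitive
sequence); a tag is retained globally if any strain keeps it.

The presence/absence distance is the symmetric-difference count — the only
symmetric reading of "number of absent tags as distance"; an asymmetric
variant is available behind a flag for sensitivity analysis.  Concatenated
SNPs from tags shared by all taxa are compared with the Kimura
2-parameter distance d = −½·ln((1−2P−Q)·√(1−2Q)); saturated pairs raise an
error naming the pair.

Neighbor-joining is authored here with the standard Q criterion and branch
lengths; negative branch lengths are clamped to zero with the deficit
moved to the sibling edge.  Tie-breaking uses the smallest leaf label per
cluster, so the tree is invariant to taxon input order (exact for integer
distances such as tag counts).  On additive matrices the reconstruction is
exact to 10⁻⁹.  Bootstrap support resamples columns (tags or sites) with
replacement and reports the percentage of replicates containing each
internal split of the full-data tree; the default 10,000 replicates
matches common practice, tests use ≤ 1000 for speed.  Maximum parsimony
and maximum likelihood are out of scope: where all methods recover the
same topology, NJ carries the acceptance surface.

## Simulator

What it emulates: homozygous parents with opposite alleles, a fully
heterozygous F1, selfed-F2 meiosis, marker clustering at one chromosome
end, genotyping noise, and tag/SNP evolution on a 5-taxon tree.

* **Obligate chiasma** (default): each bivalent receives exactly one
  chiasma, uniform in cM over the chromosome's marker span; each gamete
  inherits it with probability ½.  Crossovers per gamete are Bernoulli(½),
  events per F2 per chromosome are 2:1:0 in 1:2:1 ratio, and expected map
  length is 50 cM per chromosome independent of the nominal span.  A
  Poisson model (count ~ Poisson(span/100), no interference) is provided
  for contrast.
* **Marker placement**: default "tip_clustered" puts 30% of markers in the
  terminal 1 cM of one end — recombination suppression near an acrocentric
  centromere expressed through marker position, not a separate
  suppression parameter — the rest uniform over a 50 cM span.
* **Noise**: symmetric miscalls (uniform wrong state) at 1% and missing
  calls at 2% by default, applied after genotype construction and fully
  logged (marker, individual, original call) so recovery tests can invert
  them.  Real RAD genotyping error is direction-biased (low-quality
  secondary reads pushing heterozygotes toward homozygous calls);
  symmetric noise suffices to exercise the flagging logic and is simpler
  to reason about — a caveat for extrapolating test results to real data.
* **Defaults as study conditions**: 24 chromosomes, 49 F2, 50 markers per
  chromosome.  50 markers is a deliberate scale-down (the real panel has
  ~414 markers per chromosome); it keeps the full pipeline in seconds.
  One consequence: on *error-free* panels, cosegregation leaves only
  ~19–26 distinct bins per chromosome, so some chromosomes fall under the
  21-bin "major group" cutoff; structural tests that need every
  chromosome comfortably above the cutoff use 100 markers per chromosome.
  Noisy panels (unique error fingerprints per marker) give ~35 bins per
  chromosome and 24 major groups at the default size.
* Tag evolution: root tags lost along each branch with probability
  1 − e^(−rate·length); SNP evolution: site-independent K2P with exact
  transition probabilities.  All randomness flows from one seeded
  generator; outputs are bit-reproducible.

## Numerical and degenerate-input choices

* Adjacent r̂ = ½ (no linkage information at a final adjacency) is capped
  at ½ − 10⁻⁹ before the Kosambi transform rather than producing an
  infinite distance.
* `order_objective` handles missing dosages by per-column forward-fill,
  which is exactly the skip-missing crossover count and fully vectorized.
* Panels refuse construction with an all-missing individual column,
  duplicate ids, or out-of-range codes; unknown genotype codes name the
  offending marker, individual and code.
* Positions serialize at 4 decimals; internal representation is full
  precision.

## Known limitations

* Read-level evidence (depths, secondary reads) is out of scope; only
  genotype-matrix-level flagging and user-driven correction are possible.
* The acceptance surface runs on synthetic data.  The real study's exact
  totals (e.g., its 1157 initial bins and 1247.6 cM) depend on its
  supplementary genotype panel and on manual, read-quality-informed
  corrections, and so are not reproducible from code alone; the pipeline
  reproduces the procedure and its statistical signatures.
* The greedy-plus-local-search ordering is a heuristic; it is validated
  against exhaustive search at small scale, not guaranteed optimal at
  map scale.
* K2P triangle-inequality violations are possible in principle at high
  divergence; distances near saturation raise errors instead of returning
  unstable values.
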