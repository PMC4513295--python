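# Methods

## Scope and data model

`barcodiv` analyses aligned COI barcode records (FASTA plus a tab-separated
metadata table keyed by record id, with species, family and optional
coordinates). Records are padded to the 658-site barcode frame; longer
input is rejected. Two record-inclusion rules reproduce common survey
practice: a length filter keeping records with more than 400 ungapped sites
(default threshold 401, so 407-bp rescue amplicons pass and 400-site reads
do not), and a geographic window for continental surveys — keep records
with longitude ≤ 50°E and, east of a configurable 40°E corridor meridian,
latitude ≥ 43.5°N. The corridor meridian exists so that Mediterranean
records south of 43.5°N are not dropped; only the two boundary numbers are
fixed by the survey design, the meridian is a config knob. Records without
coordinates pass the geographic filter and are flagged in summaries.

## Haplotype collapsing

Distance work uses uncorrected p-distances under pairwise deletion: only
sites where both sequences carry a concrete A/C/G/T are compared; a
`min_overlap` floor (default 100 sites) guards comparisons involving the
shortest (307-bp) amplicons.

Collapsing is conservative. Full-length unambiguous sequences define base
haplotypes by exact identity. Every other sequence is compared to all
haplotypes site-wise on IUPAC sets (R vs Y disjoint, R vs N compatible;
gaps impose no constraint) and joins *every* compatible haplotype; only a
sequence compatible with none founds a new haplotype. Sequences are
processed by decreasing ungapped length with record-id tie-breaks, and a
final sweep recomputes membership against the finished haplotype list, so
the result does not depend on processing order. The guarantee this buys:
truncated or ambiguous copies of existing variation can never inflate the
haplotype count (property-tested). Multi-assigned records contribute 1/k
to fractional haplotype counts in reports; when a single assignment is
needed (specimen-level partitions), the representative is the smallest
haplotype id, a deterministic choice.

## Trees

Neighbor-joining is implemented directly — canonical Q-criterion
agglomeration, negative branch estimates clamped to zero, ties broken by
label order — and is cross-checked in the test suite against an independent
implementation (scikit-bio) and against exact recovery on additive
matrices. Bootstrap supports use Felsenstein column resampling (default
100 replicates, seeded): the support of an edge is the fraction of
replicate NJ trees containing its bipartition.

The delimitation step needs an ultrametric tree. Publication-grade
chronograms (e.g. Bayesian strict-clock trees) are supplied by the user as
newick; the built-in fallback is UPGMA (scipy average linkage, node height
= half the merged clusters' mean distance), which is deterministic,
desk-scale, and sufficient because the threshold model needs only the
relative ordering of node heights. Ultrametricity is checked to a relative
tolerance of 1e-6 on root-to-tip spans.

## The mixed Yule-coalescent model

Branching times are internal-node ages (tips define the present). A
threshold `T` classifies branching events: older — generalized Yule
(diversification); younger — generalized coalescent within each cluster (a
cluster is the tip set of a branch crossing `T`). On each inter-event
interval the total rate is

```
lambda = b_div * n_div^p_div + b_coal * sum_j [n_j (n_j - 1)]^p_coal
```

Lineage accounting, which the literature leaves implicit, is resolved here
as follows: `n_div` on an interval counts branches that originate above `T`
and are still present — above `T` that is every lineage, below `T` the
crossing branches until each ends at its cluster's MRCA (a singleton's
pendant branch persists to the present). `n_j` counts lineages inside
cluster `j`; a lone stem contributes `n(n-1) = 0`. The likelihood is the
broken-exponential sum `log L = sum_i [log lambda_i - lambda_i x_i]`: every
segment between breakpoints (event times plus `T`) contributes its
exponential term, and every branching event, root included, contributes the
log-rate of the segment on its tipward side — the exact likelihood of the
piecewise-constant-rate process read backward in time. Zero-length
segments (tied node heights) contribute log-rate only.

Fitting: candidate thresholds are midpoints between consecutive distinct
branching times plus one between the youngest node and the tips. At each
candidate the four rate parameters are maximized numerically (L-BFGS-B on
`log b`, exponents bounded to [0, 3], three fixed starts with `b` at
{0.1, 1, 10}/tree-height — fully deterministic). The threshold counts as a
parameter: k = 5 for the mixed model, k = 2 for the one-process null
(`lambda = b n^p` over the whole tree), giving the 3-df chi-square
likelihood-ratio test. Entity supports are Akaike weights summed over the
candidate models whose partition contains the entity's exact tip set; the
multimodel (MM) variant reports supports for every entity whose weight sum
clears a 0.01 floor, and the MM score is the weight-averaged AIC of the
candidate set (both score conventions are reported; the point partition of
the selected model is always the maximum-likelihood one).

The exponent bound [0, 3] matters: an unbounded generalized Yule process
with `p ≈ 2–3` can mimic global coalescent behaviour, and the persistence
of diversification lineages below the threshold (above) is what lets the
true mixed model outscore that degenerate single-class fit.

## Classification layers

*Library performance*: a species sharing any haplotype with another species
is `shared` (sharing has precedence); otherwise it is `monophyletic` if its
haplotype tips form a clade (single-haplotype species are monophyletic by
convention, flagged as uninformative), else `para_polyphyletic`.

*Delimitation audit*: with entity set `E(S)` per species — one entity,
purely conspecific → single entity (SE); one entity shared with other
species → lumped; several entities, all conspecific → ME-pure; several
entities, some shared → ME-mixed. Split species are annotated with the
minimum between-entity p-distance (closest cross pair, percent, 1 decimal)
and sympatry: two entities are sympatric when their closest occurrence
points lie under 50 km by haversine (Earth radius 6371 km) — closest-record
linkage, not centroids. Report percentages round half away from zero to
one decimal; raw fractions are always emitted beside them, since published
tables occasionally truncate instead (83/299 prints as 27.8 here versus a
truncated 27.7).

## Suitability diagnostics

Synonymous-site diversity uses Nei–Gojobori counting under the invertebrate
mitochondrial code: per codon, fractional synonymous sites from one-step
neighbours (changes to stops are non-synonymous); per codon pair,
synonymous differences averaged over mutational pathways that avoid stops
(all pathways if none avoids them); codons with gaps or ambiguity in either
sequence are excluded pairwise; `pi_syn` is the unweighted mean over all
sequence pairs, computed for species with at least 10 specimens. The
reading frame is chosen to minimize internal stops; a frame is rejected
only when most sequences exceed a 2%-of-codons stop density — a frameshift
signature — because an occasional stop (sequencing error, or drift in
unconstrained simulations) merely excludes its codon.

Haploid `Ne = pi_syn / (2 mu)` (uniparental marker, theta = 2 Ne mu), with
`mu` from the slow (0.0075) or fast (0.0115) per-site-per-Myr COI rates and
a default one generation per year (univoltine convention; configurable).
The speciation rate is the zero-extinction crown estimator
`(ln n - ln 2)/t` with a 110-Myr default crown age. Products `Ne x SR` are
compared to the reliability window `[1.8e3, 8e5]`; the verdict is `pass`
when at least half the products fall inside.

## The synthetic-data generator

The generator emulates the survey's sampling design with known truth.
Species tree: Yule process started at the crown (two lineages), waiting
times Exp(k·λ) between the k → k+1 events, plus one final Exp(n·λ) hold so
no pendant edge is zero; default birth rate 0.0455/Myr, the continental
butterfly crown estimate. Genealogy: censored multispecies coalescent —
within each species-tree branch, j lineages coalesce at rate j(j−1)/(2Ne)
per generation, survivors entering the ancestral population — so lumping
under shallow splits arises naturally. Default haploid Ne = 2e5 (inside
the 4e4–1.8e7 range such surveys report; Ne × SR = 9.1e3, within the
reliability window). Sequences: HKY (default κ = 2; κ = 1 is Jukes–Cantor)
evolved site-independently with per-branch transition matrices `expm(Q t)`,
default μ = 1.15e-8/site/generation (the fast COI rate at one generation
per year), root sequence stop-free in frame 0. Degradation mimics the real
amplicon geometry: truncation to 609 or 307 sites from the 5' end or 407
sites from the 3' end (weights 0.5/0.35/0.15 reflecting fallback primer
usage), plus per-site N injection. Coordinates scatter around per-species
range centres in an Iberia-like window with a km-scale dispersion;
designated overlap pairs get centres within a few km to exercise the
sympatry rule. Everything is driven by one integer seed through a single
`numpy` generator; outputs are byte-identical across runs.

What the simulator does *not* model: purifying selection (so deep
genealogies accumulate occasional stop codons real COI would not),
rate heterogeneity among sites or lineages, migration, recombination, and
identification error in the species labels. Passing recovery tests on this
generator therefore demonstrates correctness of the delimitation machinery
under the model's own assumptions, not robustness to those violations.

## Performance expectations and problem sizes

With the default study conditions (10 species × 10 samples), partition
recovery against truth averages ARI ≈ 0.93–0.95 over 20-replicate batches;
residual error is dominated by genuinely unsorted recent splits, which the
single-threshold model lumps. At the large-Ne end of the realistic range
(Ne ≈ 1.6e6) recovery drops to ≈ 0.55 for the same reason — a regime choice,
not an optimizer failure; the likelihood-ratio test stays well calibrated
under a pure-coalescent null (≈ 95% non-significant at the 5% level).
Test-suite and acceptance-script simulations use 10 × 10 datasets,
200-replicate coalescent calibrations, and 50 small trees for the
exhaustive-search check of the optimizer, keeping full runs in the minutes
range on one core.

## Numerical choices and edge cases

- Node ages clamp tiny negative values to zero; tips define age 0 exactly.
- `0^p` is defined as 0 in the rate law even at `p = 0` (an absent class
  contributes nothing).
- Optimizer failures at a candidate threshold skip that candidate; the fit
  errors only if every candidate fails.
- NJ ties are broken by the first minimum in row-major label order; UPGMA
  inherits scipy's deterministic merge order.
- An all-ambiguous record joins every haplotype and is effectively
  uninformative; p-distance raises below the overlap floor rather than
  returning a noisy estimate.
- Empty coordinate sets make sympatry undefined (`None` in reports), never
  silently false.
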