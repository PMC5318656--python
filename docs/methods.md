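# Methods

This note records the models, parameter choices and known limitations of
`gammamap` — what the pipeline computes, why its defaults are what they
are, and what the synthetic studies it is tested on do and do not show
about real data.

## Broad-island calling

The caller is the classic broad-mark island scheme: fixed windows, a
genome-wide Poisson background, gap-tolerant fusion of signal-eligible
windows, and a per-island control test.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `window` | 1,000 bp | bin width; kb-scale because γH2AX domains span tens of kb |
| `gap` | 3 windows | ineligible run bridged inside one island |
| `p0` | 0.01 | per-window Poisson upper-tail eligibility threshold |
| `fc_min` | 2.0 | minimum chip/control fold change of a retained island |
| `fdr_max` | 0.01 | BH-adjusted ceiling for the island-level control test |
| `pseudo` | 1 tag | pseudocount protecting ratios against empty controls |

**Why p0 = 0.01 rather than the 0.2 familiar from sparse-window island
callers.** The 0.2 convention comes from settings where λ per window is
far below 1, so Poisson discreteness makes the *realized* chance
eligibility a few percent at most. The libraries this package targets
(and its default synthetic study: 5 M tags on a 20 Mb genome at W = 1 kb)
have λ ≈ 250 per window; there the tail is effectively continuous and a
0.2 threshold marks ~20% of pure-background windows eligible. With a gap
tolerance of 3, chance-eligible windows then chain onto island flanks —
an expected extension of several windows per side — which destroys the
positional specificity of island boundaries for genes shorter than ~10
kb. At p0 = 0.01 the chance-extension probability per flank is ≈ 4%, and
boundary resolution is about one window. The retention filters (FC and
FDR against the control), not p0, carry the genome-wide error control:
under a signal-free chip the caller retains nothing because candidate
islands sit at fold change ≈ 1.

The island interval runs from the first to the last eligible window; the
score sums −ln of the eligible windows' tail probabilities. Control
counts are scaled by the global library-size ratio only — no local
background, matching a single isotype normalization.

nRPM may be negative (a region can be depleted relative to control);
cross-condition specificity floors negative nRPM at zero before forming
the ratio (nRPM_A + ε)/(nRPM_B + ε), ε = 1 RPM, to avoid sign-flip
artifacts.

## Region merging, ranking, annotation

Condition lists merge by interval union; overlapping or bookended regions
fuse and carry the union of their condition labels ("common" = both).
Ranking is by fold change, with regions sharing an overlapped gene
collapsed to one row carrying the arithmetic mean FC; ties break by nRPM,
then coordinate.

Gene assignment intersects flank-extended regions (default ±10 kb) with
gene spans, strand-blind — damage is not stranded; strand matters only in
the orientation analysis. Feature classes use the fixed precedence
TSS > TES > body > flank (the precedence is a determinism choice; a
region covering a whole gene is "TSS-overlapping").

Meta-gene profiles use 100 length-scaled body bins and 10-kb flanks in
500-bp bins. Bin values are depth-normalized *densities* (RPM per kb) so
body and flank bins share units regardless of gene length; chip and
control densities combine by subtraction (default) or ratio. Minus-strand
genes are flipped before averaging. Genes shorter than the bin count or
whose flanks leave the chromosome are skipped and logged.

## Expression and H3K27ac integration

"Expressed" means FPKM > 0 by default. Expressed genes split into
high/low at their median FPKM (ties at the median fall to "low").
Differential expression is a transparent pseudocounted fold-change call:
|log2((FPKM_A + 0.1)/(FPKM_B + 0.1))| ≥ 1 — this package makes no
count-level dispersion claims, and the binary call is all the downstream
analyses need. Per-gene damage signal is nRPM over the ±10-kb-extended
gene span. The damage/active-chromatin comparison computes
background-subtracted RPM for both marks over extended regions, calls a
region positive for a mark when that value exceeds zero, and reports the
double-positive fraction together with the Pearson r on the
double-positive subset.

## Orientation classes

Every gene is classified against its neighborhood: overlapping (any
intersecting gene, with precedence over all other classes), isolated (no
gene within 10 kb end-to-start), else by the nearest neighbor — same
strand → tandem; plus-strand gene left of a minus-strand gene →
convergent (3′ ends face); the reverse → divergent. Ties in distance
break toward the right-hand (larger-coordinate) neighbor. Geometry fixes
the symmetries: mirroring coordinates (keeping strand labels) swaps
convergent↔divergent, as does flipping every strand in place, while
their composition — a true reverse complement — leaves all classes
unchanged; the test suite asserts all three. Category damage profiles cut
each gene body into equal fractions (default 40), form pseudocounted
per-bin chip/control fold changes (ε = 0.1 RPM), and compare per-gene
mean FCs between categories with the Mann-Whitney U test.

## RLFS model

Defaults follow the QmRLFS parameterization: G-tracts ≥ 3 (m1) or ≥ 4
(m2); ≥ 2 tracts chained with ≤ 10 non-G nt between them; RIZ overall
≥ 50% G; linker ≤ 50 nt; REZ read in 100-nt steps each ≥ 40% G, truncated
at 2 kb; every constant is exposed in `RlfsParams`. N breaks tracts and
counts against G-fraction denominators. For each RIZ the longest REZ over
all admissible linker offsets wins (shortest linker on ties). Overlapping
same-model matches merge to their union so enrichment counts are not
inflated; note that merged-match *counts* are not guaranteed monotone
under parameter tightening (removing a bridging match can split a fused
blob), so the monotonicity guarantees — and the tests — are stated on
unmerged matches and on union coverage. Gene-level counts are strand-blind
over gene spans; a match crossing two genes increments both.

## Permutation and contingency machinery

Empirical p-values always use (1 + #{null at least as extreme})/(N + 1),
so p ≥ 1/(N+1) > 0. The gene-sampling null redraws |target| genes
uniformly without replacement (optionally within a restricted population,
e.g. the 1,000 most highly expressed genes); when the number of possible
draws is below N the null is enumerated exhaustively. The
region-shuffling null re-places each query region at a uniform start on a
length-weighted random chromosome (or its own chromosome), preserving
every region's length, and counts ≥ 1-bp overlaps in both directions.
Default N = 10,000 permutations, consistent with resolving p-values near
10⁻⁴. No gene-length, expression or isochore matching is applied beyond
the explicit restriction option. Contingency enrichment is the two-sided
Fisher exact test on [[A∩B, A∖B], [B∖A, U−A∪B]], with the Haldane 0.5
correction applied to the odds ratio when a cell is zero; analyses are
reported standalone, without cross-analysis multiplicity correction.

## The synthetic-study generator

The generator emulates the input constellation of a damage-mapping study
with every planted feature recorded as ground truth.

Defaults: 2 chromosomes × 10 Mb; 300 genes with log-uniform lengths
2–100 kb placed in orientation-controlled units (10% overlapping, 30%
isolated, 20% each tandem/convergent/divergent; units separated by more
than 10 kb so classes are exact by construction); 30 damage-hotspot genes
(24 shared between the two oncogene conditions, 3 per condition
specific), at most one per pair unit so planted islands never fuse across
close pairs; FPKM log-normal(μ=1, σ=1) with 20% silent genes, hotspot
genes boosted in log-space (damage tracks transcription) and
condition-specific hotspots differentially expressed toward their own
condition; 5 M single-bp tags per library. Damage libraries mix a uniform
background with reads placed uniformly in hotspot gene bodies at per-base
factor 1 + (enrichment − 1)(1 + c·log1p(FPKM)), enrichment 5, c = 0.5; the
isotype control is purely uniform. The library size (no accession exists
for comparable raw data) and the per-condition hotspot split are free
choices sized so every statistic is exercised at seconds-to-minutes
scale.

The active-chromatin (H3K27ac-like) library is promoter-centric — TSS
± 1 kb of every expressed gene at the same expression-coupled factor —
plus 20% of that enrichment spread across the expressed gene body. The
body component is deliberate: a strictly punctate promoter mark cannot
co-vary with a broad, length-dominated damage signal across regions
(the promoter term is length-independent while region signal scales with
gene length), whereas real acetylation blankets active loci broadly; the
20% body share makes the generator reproduce the empirically observed
damage/activity correlation regime.

Genome sequence is i.i.d. at 40% GC; RLFS-flagged genes (all hotspot
genes plus 10 background genes) receive one cassette on their coding
strand — `GGGTTGGGTTGGG`, a 20-nt A linker, and a 200-nt tail with
exactly 60 G per 100-nt block so the elongation-zone criterion holds
deterministically.

What the generator does **not** model: fragment lengths (reads are 5′
positions; every downstream statistic is count-based), sequencing error,
mappability, duplicates, replicates, isoforms, GC waves or isochores, and
any genome-wide coupling of damage to expression outside the planted
hotspot set. Passing tests therefore certify the *algorithms* —
recovery, calibration, symmetry, oracle equivalence — under a clean
generative model, not performance on the artifacts of real libraries.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open internally; GTF converts exactly at the
I/O boundary. BH correction and all distribution tails come from scipy.
Window binning keeps the final partial window. Empty libraries produce
zero tracks and λ = 0 (count 0 is never eligible). RPM of a zero-total
library raises. Fewer than two chromosomes make the coverage correlation
undefined (raise); fewer than three double-positive regions make the
H3K27ac r undefined (raise). The Mann-Whitney implementation is the
asymptotic, tie-corrected form — adequate at the n ≥ tens this pipeline
compares, and verified against exact enumeration at small n in the test
suite.

## Test and acceptance problem sizes

The unit suite runs on a 2 × 1 Mb, 60-gene, 200k-tag study; the
acceptance checks run the full default study (2 × 10 Mb, 300 genes, 5 M
tags), 20 seeds of recovery/null calling, 500-dataset calibration of both
permutation nulls at N = 199, 200 random 500-nt sequences for scanner
equivalence, and 100 random tracks for caller equivalence — sizes chosen
so the whole suite completes in a few minutes on one CPU while every
claim is still measured, not assumed.
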