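# gammamap

Mapping and statistical analysis of broad γH2AX DNA-damage domains from
ChIP tag libraries.

## The problem

When a DNA double-strand break forms, the histone variant H2AX is
phosphorylated (γH2AX) over a broad chromatin domain around the break.
ChIP-seq against γH2AX therefore maps damage-prone regions genome-wide —
but the signal is diffuse (kilobases to hundreds of kilobases), so
punctate peak callers are the wrong tool, and the interesting questions
are downstream of the calling itself: which genes do the damage domains
cover, how does damage relate to transcription and active chromatin
(H3K27ac), to convergent/divergent gene neighborhoods, to R-loop-forming
sequences (RLFS), and to external fragile-site interval sets?

`gammamap` is a library + CLI for that analysis chain, aimed at people
studying transcription-associated fragility (e.g. in transformed B-cell
precursors, where lineage-specific, highly expressed genes become damage
hotspots). Because raw damage-ChIP data are rarely portable, the package
ships a first-class synthetic-study generator with complete ground truth,
so every stage is testable end to end.

## The model

**Island calling.** Tags are binned into windows of width *W* (default
1 kb). With a library of *N* tags on a genome of length *G*, the uniform
background expectation per window is λ = *N·W/G*. A window with count *c*
is *eligible* iff the Poisson upper tail P(X ≥ c; λ) < p₀. Runs of
eligible windows, tolerating gaps of up to *g* ineligible windows
(default 3), fuse into islands with score

&nbsp;&nbsp;&nbsp;&nbsp;S = Σ<sub>eligible windows</sub> −ln P(X ≥ cᵢ; λ)

Each island is then tested against the isotype/input control: the chip
count over the island is compared with a Poisson mean given by the
library-size-scaled control count (plus a pseudocount); p-values are
Benjamini-Hochberg corrected across islands, and an island is retained iff
q ≤ fdr_max and FC ≥ fc_min (defaults 0.01 and 2).

**Signal metrics.** For an interval with chip count *c* and control count
*k*: RPM = c·10⁶/N; nRPM = RPM_chip − RPM_ctrl;
FC = (c + ψ)/(k·N_chip/N_ctrl + ψ); RPKM = c / (len<sub>kb</sub> ·
N<sub>chip,millions</sub>).

**RLFS prediction.** An R-loop-forming sequence is modeled as an
initiation zone (RIZ: ≥ 2 clustered G-tracts, tract length ≥ 3 for model
m1 / ≥ 4 for m2, spacers ≤ 10 non-G nt, overall ≥ 50% G), a linker of
≤ 50 nt, and an elongation zone (REZ: consecutive 100-nt windows each
≥ 40% G, up to 2 kb). Both strands are scanned.

**Enrichment statistics.** Gene-set statements use empirical permutation
p-values with the add-one rule, p = (1 + #{null ≥ observed})/(N + 1):
a gene-sampling null for per-gene RLFS counts and a length-preserving
region-shuffling null for interval-set overlap; two-by-two contingency
claims use the two-sided Fisher exact test. Expression-category and
orientation-category signal contrasts use the two-sided Mann-Whitney U
test.

## Worked example

```python
from gammamap.simulate import GenomeSpec, simulate_study
from gammamap.regions import IslandParams, bin_tags, call_islands

spec = GenomeSpec(chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000}, seed=7)
study = simulate_study(spec=spec, n_genes=60, n_reads=200_000,
                       length_range=(1_000, 15_000), n_hotspot=12, seed=7)

sizes = dict(spec.chrom_sizes)
chip = bin_tags(study.libraries["chip_A"], 1000, sizes)
ctrl = bin_tags(study.libraries["control"], 1000, sizes)
islands = call_islands(chip, ctrl, IslandParams(), origin="A")

planted = [iv for iv, factor in study.truth.hotspot_intervals["A"]]
print(f"background lambda per 1-kb window: {chip.lambda_bg:.1f}")
print(f"planted hotspot genes (condition A): {len(planted)}")
print(f"islands retained: {len(islands)}")
top = max(islands, key=lambda r: r.fc)
print(f"strongest island: {top.interval.chrom}:{top.interval.start}-"
      f"{top.interval.end}  FC={top.fc:.1f}  nRPM={top.nrpm:.0f}  "
      f"q={top.qvalue:.2e}")
```

prints

```
background lambda per 1-kb window: 100.0
planted hotspot genes (condition A): 9
islands retained: 9
strongest island: chr1:125000-137000  FC=8.9  nRPM=45615  q=0.00e+00
```

Nine damage hotspots were planted for condition A on this toy genome and
the caller retains exactly nine islands; the strongest one covers a
planted gene body at 8.9-fold enrichment over the isotype control.

The same analyses are available from the shell via the `gammamap` CLI
(`simulate`, `callregions`, `merge`, `specific`, `annotate`, `metagene`,
`chromstats`, `expression`, `k27corr`, `orientation`, `rlfs`,
`permute-genes`, `permute-overlap`, `contingency`, `run`); `gammamap run
--config cfg.yaml --seed 1 --outdir out/` executes the full stage chain
and writes a manifest.

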