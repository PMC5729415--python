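# Methods

## Scope and model

`mitochip` implements the computational side of a cross-species mitochondrial
gene-expression platform: (i) design of one oligonucleotide probe per
mitochondrial gene that hybridizes to the orthologous transcript of two
species (tobacco and Arabidopsis roles), falling back to species-specific
probes where that is impossible; (ii) similarity screening of probes against
decoy sequences such as a plastid genome; (iii) absolute quantification of
single-channel spotted-array data via spike-in calibration curves; and (iv)
analysis of sucrose-gradient fraction profiles (free vs ribosome-bound mRNA)
and qPCR CT summaries.

## Probe design

**Inputs.** Two annotated organelle genomes (GenBank flat files), optional
per-species C-to-U RNA-editing tables (TSV: gene, cds_position, from, to), and
an optional gene-name map for spelling variants. Coordinates are 0-based
half-open internally; the GenBank reader converts at the boundary. Gene
sequences are extracted strand-aware and exon-joined (sense/mRNA-like), and
each species' editing table is applied to its own sequences so probes match
the edited transcript, not the genomic DNA. Orthologs are paired by gene
symbol only — no similarity-based inference.

**Constraints.** Probe length 68–71 nt; GC as close to 50% as possible; for a
shared probe at most 3 cross-species mismatches, placed as terminally as
possible because central mismatches destabilize the duplex most. These are
constraints, not an objective, so the package concretizes them as a composite
score over each gapless window of the global ortholog alignment
(match +1, mismatch −1, gap open −5, gap extend −1):

    score(w) = w_gc * |GC_B(w) − 0.5| + w_pos * Σ_i c(p_i, L)
    c(p, L)  = 1 − 2*|p/(L−1) − 1/2|        (0 at either end, 1 at center)

with default weights w_gc = w_pos = 1. All window lengths 68–71 are scanned
jointly; ties are broken by fewer mismatches, then longer window, then
smaller species-B offset, which makes output deterministic. A window is
infeasible if it contains a gap column, an N, more than 3 mismatches, or
spans a splice junction of either species (probes must bind the mature,
spliced transcript — for trans-spliced genes this means a downstream exon).
The shared probe always carries the species-B (Arabidopsis-role) window, and
probes are sense-strand because the labeled target is first-strand cDNA.

If no feasible window exists, two species-specific probes are designed, each
the best window of its own sequence scored on GC deviation alone. Genes
present in only one genome, or shorter than 68 nt in one species, get a
single specific probe. tRNA and rRNA genes receive probes but are flagged
non-quantifiable (rRNA spots saturate; tRNA spots cross-hybridize with
plastid-encoded tRNAs). The search is exhaustive — the window space is at
most ~4·L per gene — and the designer is verified against an independent
brute-force oracle in the test suite.

## Cross-hybridization screen

Each probe (both strands) is locally aligned against every decoy sequence;
identity = matched bases / full probe length, so partial matches score
proportionally (hybridization risk scales with total complementary bases).
Alignment scoring is match +1 / mismatch −1 / gap open −5 / gap extend −2:
stringent gap costs are deliberate, because permissive ones let gappy
alignments of unrelated random 70-mers against a 10-kb decoy inflate the
match count to the flagging threshold. The default threshold is 0.70, the
lower end of the identity range observed between mitochondrial and
plastid-encoded tRNAs. Flagged probes are only marked, never removed.

## Array quantification

Per spot: net signal = foreground mean − local background; negative values
become missing. Spots with foreground at ≥95% of the detector ceiling are
treated as saturated: saturated calibration spots are excluded from the fit,
saturated gene spots from quantification (this reproduces the rRNA-spot
behaviour). Per slide, an OLS line of net signal vs known spike amount
(linear scale; the spike series spans 1 pg–10 ng) is fitted on the
unsaturated reference spots; a slide needs ≥3 usable points over ≥2 amounts
and a positive slope or it is rejected. Gene abundances are net signal /
slope, in pg-equivalents per spot; with the fixed RNA input per hybridization
this reads as abundance per µg RNA. The six replicate blocks of a slide are
averaged.

Replicate slides of a sample are median-corrected multiplicatively: each
replicate is rescaled so its median equals the grand median (median of
per-replicate medians). Multiplicative rather than additive correction was
chosen because additive shifts can create negative abundances and break the
log2 ratio step; this is the one place where the source procedure was
ambiguous. Per-gene means and SDs are taken across replicates (unbalanced
designs such as 4/4/3/3/2 replicates per organ are supported); a gene
missing in more than half the replicates is reported not-quantifiable.

Ratios are log2(tissue/reference); the reference column is identically zero
and zero/missing denominators propagate as missing. Significance marking
fits a gene × tissue cell-means ANOVA on log2 abundances with the pooled
within-cell variance as error term, then tests each (gene, tissue) cell
against the gene's reference cell with a t contrast, flagged at p < 0.05
unadjusted (Benjamini–Hochberg available behind a flag, off by default).
Constant data yields no finite statistic and is flagged degenerate, never
significant. The pooled error variance is identical to the residual mean
square of the equivalent statsmodels OLS fit, which the test suite checks as
an independent route. The whole pipeline is scale-equivariant: rescaling all
raw signals and calibration signals together leaves abundances unchanged.

## Polysome and qPCR analysis

Gradient profiles hold exactly ten equal-volume fractions, light to heavy.
Free signal = Σ fractions 1–5, bound = Σ fractions 6–10, loading ratio =
bound/free (flagged infinite when free = 0); the split is config-exposed for
other gradient designs. The puromycin control passes iff the bound share
under puromycin is strictly below the untreated bound share; the shift
magnitude is the difference of bound shares. ΔCT summaries assume ~100%
primer efficiency: mito-DNA content as CT_mito − CT_nuclear (sign convention
configurable and echoed in output), expression as 40 − (CT_target −
mean(CT_references)) with one or more reference genes (e.g. EF1α, GAPDH).

## Synthetic data

The generators are first-class, tested code and define the conditions the
rest of the suite runs under. Sequence side: species-B gene sequences are
sampled i.i.d. at 45% GC, ~900 nt (typical plant-mitochondrial coding
values), species A derived by planting substitutions (default rate 1%,
matching the low cross-species divergence of these coding regions); editing
sites are planted on C positions (~15 per protein gene). Genome fixtures
assemble genes with spacers and include a minus-strand gene, a two-exon
gene, a tRNA, an rRNA, divergent genes whose substitution spacing (every
17 nt) makes every 68-nt window exceed the mismatch budget by construction,
and species-unique genes — so expected probe counts are fixed by
construction. Slide side: signal = clip(slope·abundance·LN(σ) + background,
0, ceiling) with a 16-bit ceiling (65535), lognormal σ = 0.1, additive
background ~N(50, 5), slope 50 units/pg, six replicate blocks, spike series
of 21 points (five per decade, 1–10 000 pg). This is the minimal model
reproducing the three phenomena the pipeline must handle: linearity,
saturation of rRNA-like spots, and replicate scatter requiring median
correction. Gradient side: bound mass r/(1+r) of the total spread over
fractions 6–10 with Dirichlet jitter (α = 200), puromycin moving a fraction
d (default 0.9) of bound mass into 1–5. CT side: ct = ct_unit − log2(level),
so copy-number doublings map exactly onto one-cycle shifts.

What the generators do **not** emulate: real sequence evolution (no
substitution matrices or phylogeny — planted differences only), spatial
artefacts and gridding errors on slides, probe-specific hybridization
efficiencies, partial ribosome run-off between gradient fractions, and
primer-efficiency variation in qPCR. Passing recovery tests therefore show
the pipeline's arithmetic and statistical calibration are correct under the
declared noise model, not that the platform is robust to every artefact of
real scans.

## Problem sizes and numerics

The acceptance script and tests run the designer on genome pairs of ~11–13
genes, oracle comparisons on 100–200 random ortholog pairs ≤300 nt,
quantification recovery on 1000 genes × 4 replicate slides, ANOVA
calibration on 1000 null datasets (5 genes × 3 tissues × 4 replicates), a
16-point loading-ratio sweep, and 100 planted + 100 random cross-hyb cases
— sizes chosen so the whole suite completes in well under a minute per
component on one CPU while keeping Monte-Carlo error small relative to the
tolerances tested. Calibration fits are on the linear scale; medians ignore
missing values; all randomness flows from explicit integer seeds and every
generator is byte-reproducible for a fixed seed.

## Known limitations

- Ortholog pairing is name-based only; diverged paralogs or annotation
  disagreements need a user-supplied name map.
- No melting-temperature or secondary-structure model in probe design; the
  centrality penalty is a linear surrogate for duplex destabilization.
- Identity in the cross-hyb screen depends on the declared alignment
  scoring; it is a screen, not a thermodynamic cross-hybridization model.
- The ANOVA assumes log-normal abundances with homoscedastic within-cell
  variance across genes and tissues.
- ΔCT assumes perfect primer efficiency; no efficiency correction.
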