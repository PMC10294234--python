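# Methods

## The experimental design being modelled

The pipeline analyses serial exome data from an *in vitro* drug-resistance
model: a TKI-sensitive parental CML line and, per biological replicate, two
derived sublines resistant to a low and a high drug concentration
(imatinib: 0.5 / 2 µM; nilotinib: 0.05 / 0.1 µM; four imatinib and two
nilotinib replicates by default). Because every resistant subline descends
from the same parent, a variant's VAF trajectory across
sensitive → low → high reads as clonal dynamics: emergence of a resistant
clone raises the VAF of its variants, clonal replacement lowers them.

## Filter cascade and trajectory classes

For each variant key (chrom, pos, ref, alt, gene) in the union of a trio's
calls, the VAF is recomputed as alt-depth/depth (AF tags are ignored); a
stage without a call is ABSENT and enters deltas as 0 — zero alternate
reads, not missing data. The cascade applies, in order:

1. **Coverage** — fail unless depth ≥ `min_depth` (default 10) in at least
   one sample where the variant is called. A variant-level percentage
   coverage is not well defined for exome data, so the depth reading is the
   default; the alternative fraction-of-mean-depth reading remains available
   via `FilterConfig.coverage_mode="fraction_of_mean"`.
2. **Pre-existing** — fail if the sensitive-parent VAF ≥ 0.05.
3. **Deep intronic** — fail if the consequence is intronic and the position
   lies more than `deep_intronic_distance` (default 20 bp, the conventional
   splice-region bound) from the nearest exonic base. Distances count
   0-based positions to the nearest exonic base, so position 250 against an
   exon [100, 200) is 50 bp away.
4. **Gain** — fail unless max(ΔVAF_low, ΔVAF_high) > 0.15, strictly.

All comparisons are strict in the direction of the ">" rules; a variant
exactly on a threshold fails. PASS variants are classified:
`ACQUIRED_HIGH` (Δhigh > t ≥ Δlow), `LOW_ONLY` (Δlow > t ≥ Δhigh),
`SHARED_REDUCED_HIGH` (both above t and VAF_low − VAF_high > t), else
`SHARED_CONSTANT`. The class boundary for the reduced-at-high case reuses
the ΔVAF threshold, since no separate bound is established for it.

Burden tables report both per-stage counts (PASS variants whose delta in
that subline exceeds t) and trio-level unique PASS counts, because either
convention can be meant by a per-subline total.

## Driver annotation

Only PASS variants are annotated. Catalogue intersection is case-insensitive
and order-independent; TRUNCATING = stop-gain or frameshift, MISSENSE =
missense, everything else OTHER. ClinVar flags attach on exact
(chrom, pos, ref, alt) match and are taken at face value. MULTIHIT is
defined **within one subline** (≥ 2 distinct qualifying variants of a gene);
recurrence of a gene across replicates is biologically different (parallel
evolution rather than biallelic/compound hits) and is reported in a separate
recurrence table. A variant exceeding the gain threshold in both low and
high of one replicate marks both subline columns. Gene rows are ordered by
the number of mutated sublines, ties alphabetical.

## Mutational signatures

Spectra use PASS SNVs only (indels are retained through filtering and driver
annotation but excluded here). Channels follow the fixed 96-channel
convention: purine-centred sites are reverse-complemented so the central
base is C or T, labels are `5'[REF>ALT]3'`, ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G) then by 5' and 3' flank. Decomposition is
non-negative least squares on the count vector normalised to sum 1; the
residual is the 2-norm on that normalised scale, and exposures are
renormalised to sum 1. No sparsity penalty or signature pre-selection is
applied — the signature matrix is an opaque input in COSMIC layout (Type
column + one column per signature), and which catalogue/version to use is
the caller's choice. Dominance of a particular real-world signature is
therefore verified here only as a synthetic-recovery property, not asserted
for any real dataset. Ties for the dominant signature resolve to the
lexicographically first id and are flagged.

## Network propagation

Mutated genes of a subline seed a heat vector F₀ (binary per-gene weights by
default, VAF-summed weights optionally), normalised to sum 1; genes absent
from the graph are dropped with a logged count. The iteration
F ← α·W′·F + (1−α)·F₀ with the symmetrically degree-normalised adjacency
W′ = D^(−1/2)·A·D^(−1/2) contracts (spectral radius of αW′ ≤ α < 1), so the
steady state equals the direct solve of (I − αW′)F = (1−α)F₀; the iterative
result is tested against that closed form to 1e−6. α defaults to 0.5 and is
always recorded in run metadata, since the diffusion literature offers no
single canonical value.

One numerical subtlety: symmetric normalisation does not conserve L1 mass on
irregular graphs. `propagate` returns the raw fixed point (which satisfies
the fixed-point residual bound exactly); the assembled gene × subline score
matrix then renormalises each subline column to sum 1 so heats are
comparable across sublines and the all-genes gene-set score equals 1/|V|
identically. Components without seeds receive exactly zero heat.

Gene-set scores are the mean propagated heat over the set's graph genes,
z-scaled per set across sublines; sets with no graph genes or zero variance
are dropped with a warning. Clustering is agglomerative with average linkage
on 1 − Pearson distance; k is user-set when a fixed cut is wanted, otherwise
chosen by the largest silhouette over k ∈ [2, min(10, n−1)]. Comparison with
an externally computed expression-enrichment matrix (e.g. GSVA output, which
this package deliberately does not reimplement) is per-row Spearman
correlation plus its median, with no significance claim.

## Synthetic data generator

The generator emulates the modelled study's conditions and these defaults are
fixed, not tuning knobs: mean depth 60× (Poisson-distributed per site,
floored at 1 read), four imatinib and two nilotinib trios, 140 acquired
background variants per trio plus planted drivers and 2 hitchhikers each
(putting per-subline burdens in the observed 100–200 range), 40 parental
decoys at VAF 0.3–0.6 (removed by the pre-existing rule), and deep-intronic
decoys at 10 % of the background count (removed by the intronic rule, placed
beyond the same distance threshold the filter uses). Alternate reads are
Binomial(depth, true VAF); a variant whose sampled alternate count is zero
is not called in that subline, so ABSENT stages emit exactly zero alternate
reads. Planted driver trajectories mirror the VAF patterns recovered in the
modelled experiment (acquired-high RAS-pathway hits, a two-variant multihit
gene, shared and low-only variants, with their ClinVar ids).

Background variant contexts are drawn from a configured signature mixture
(default 0.7/0.3 over a synthetic 4-signature matrix of spiky Dirichlet
columns; real catalogues are licensed data and the matrix is an opaque
input), and each variant is placed at a genomic position whose actual
trinucleotide context matches the drawn channel, so the emitted spectrum is
real on the emitted reference. One contig per gene keeps gene assignment
trivial. The PPI graph is a planted two-community partition (intra/inter
edge probability 0.3/0.02); each trio is biased (0.9) to mutate genes of its
home community, assigned by replicate parity, which is what the subline
clustering recovers. All randomness flows from one integer seed through
`numpy.random.SeedSequence`, spawning child streams in fixed order
(reference, signature matrix, PPI, gene sets/catalogue, then one per trio),
so outputs are byte-identical across runs.

**What the generator does not emulate** — and hence what green tests do not
show about real data: alignment and calling artefacts, indel realignment,
strand bias, copy-number changes and aneuploidy (the modelled cell line is
triploid; VAFs here assume a uniform allele count), tumor purity, mutation
rate heterogeneity along the genome, and realistic PPI topology (degree
distributions are Bernoulli-block, not scale-free). Recovery results on
synthetic data validate the pipeline's logic and numerics, not variant
calling.

## Numerical and edge-case choices

- Zero-depth calls are retained at read time with undefined VAF and fall to
  the coverage rule; their VAF enters deltas as 0.
- Half-up decimal rounding (not banker's) for percentage rendering, which is
  reporting-only; all filtering uses full-precision fractions.
- At 10,000× simulated depth the binomial standard error is ≈ 0.005, so VAF
  recovery is asserted in aggregate (mean and 90th-percentile deviation
  < 0.01, max < 0.05) rather than per draw; trajectory classes of planted
  drivers and background variants are asserted exactly at that depth because
  their true VAFs keep ≥ 0.03 margins to every decision threshold.
  Hitchhikers are excluded from the exact-recovery assertion by design:
  their true VAFs are jittered ±0.05 around the driver's and may legitimately
  land on a threshold.
- Class accuracy at the 60× design depth is asserted at ≥ 0.9 for variants
  with ΔVAF ≥ 0.25, the regime where a 60× binomial VAF estimate rarely
  crosses the 0.15 rule.
- Graphs are handled densely in the propagation oracle paths (≤ a few
  thousand nodes is the intended scale); isolated nodes get zero normalised
  degree and keep only their restart heat.

## Known limitations

Consequence annotation is taken from the VCF (one gene symbol and one
consequence per call); there is no VEP-style prediction, liftover, or
structural-variant support. Signature fitting has no confidence intervals.
Cluster counts on real data depend on the chosen k (or silhouette), the
linkage, and the restart parameter; all are exposed as configuration and
recorded in run metadata rather than fixed.
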