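# tkiclone

Clonal-evolution analysis of tyrosine-kinase-inhibitor (TKI) resistant CML
sublines, built for *in vitro* resistance models in which a drug-sensitive
parental line (e.g. BCR::ABL1-positive K-562) is driven to resistance against
stepwise-increasing imatinib or nilotinib concentrations, and each biological
replicate is exome-sequenced at three stages: sensitive parent, low-dose
resistant, high-dose resistant.

The package answers the questions such a model raises:

1. **Which variants were acquired during resistance?** For every variant
   observed anywhere in a sensitive/low/high trio, the variant allele
   frequency VAF = AD/DP is tracked across the stages and a filter cascade is
   applied: minimum read depth (≥ 10 in at least one sample), removal of
   variants already present in the sensitive parent (VAF ≥ 0.05), removal of
   deep-intronic variants (> 20 bp from any exon), and the gain criterion
   ΔVAF > 0.15 over the parent in at least one resistant stage. Survivors are
   classified by trajectory: `ACQUIRED_HIGH`, `LOW_ONLY`,
   `SHARED_REDUCED_HIGH`, or `SHARED_CONSTANT`.
2. **Which of them hit cancer driver genes?** PASS variants are intersected
   with a driver-gene catalogue and a ClinVar-style lookup, and assembled
   into an oncoplot matrix (gene × subline, cells ⊆ {MISSENSE, TRUNCATING,
   CLINVAR, MULTIHIT}).
3. **What mutational process generated them?** Acquired SNVs are binned into
   the 96 pyrimidine-centred trinucleotide channels and decomposed against a
   reference signature matrix by non-negative least squares:
   min ‖S·x − p‖₂ s.t. x ≥ 0, exposures = x/Σx.
4. **Where do they act in the interactome?** Mutated genes are heat sources
   on a PPI graph; the walk-with-restart iteration
   F ← α·W′·F + (1−α)·F₀ with W′ = D^(−1/2)·A·D^(−1/2) is run to steady
   state, gene sets are scored by mean propagated heat, and sublines/gene
   sets are co-clustered (average linkage, 1 − Pearson distance).

A first-class synthetic-data module generates **every** input — reference
FASTA, exon BED, per-subline VCF trios with planted clonal dynamics,
signature matrix, driver catalogue, ClinVar lookup, PPI edge list, GMT gene
sets — with known ground truth, so the whole pipeline runs and is verified
without any external dataset.

## Worked example

The packaged driver-hit table for twelve TKI-resistant K-562 sublines (four
imatinib and two nilotinib replicate pairs at low/high dose) builds into an
oncoplot:

```python
>>> from tkiclone.drivers import hits_from_table, build_oncoplot
>>> onc = build_oncoplot(hits_from_table())
>>> onc.genes_per_subline["highIM-R1"], onc.genes_per_subline.min()
(5, 2)
>>> onc.cells.loc["LRP1B", "highIM-R1"]
'MISSENSE,MULTIHIT'
>>> onc.cells.loc["NRAS", "lowN-R2"]
'CLINVAR,MISSENSE'
```

Every subline carries between two and five distinct driver genes; LRP1B is
hit by two distinct variants in highIM-R1 (a multihit cell); the NRAS
p.(Gln61Lys)-style hit carries its ClinVar flag. VAF reporting rounds
half-up:

```python
>>> from tkiclone.filtering import format_vaf_percent
>>> format_vaf_percent(24/72), format_vaf_percent(88/127, decimals=0)
('33.3%', '69%')
```

The full synthetic pipeline runs from the command line:

```bash
tkiclone simulate --seed 7 --out run/
tkiclone filter --workdir run/
tkiclone drivers --workdir run/
tkiclone signatures --workdir run/
tkiclone propagate --workdir run/ --k-sublines 2
tkiclone report --workdir run/
```

`run/report.json` then contains the per-subline burden (~100–160 PASS
variants each at the default 60× design), the driver table with every
planted driver gene, per-subline dominant signatures (SIG1, the 0.7-weight
component of the generating mixture), and the subline cluster memberships,
which recover the two planted PPI communities exactly. Thresholds (0.05
sensitive VAF, 0.15 ΔVAF, depth 10) and the restart parameter α = 0.5 are
config-file or flag overridable, and every stage writes a metadata JSON with
the effective values and a config hash.

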