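# tagdge

Tag-based digital gene expression (DGE) analysis for NlaIII/MmeI 21-bp
tag libraries — the SAGE-style assay in which each transcript is
represented by the 4-bp CATG restriction site plus the next 17 bp of
cDNA, and expression is measured by counting those signatures in
millions-of-tags libraries.

The package re-implements, as a reusable and tested pipeline, the
analysis used to profile the nine stages of cotton somatic
embryogenesis (hypocotyl explants at 0/6/24/48 h of dedifferentiation,
non-embryogenic and embryogenic callus, and globular/torpedo/cotyledon
embryos): from a reference transcriptome FASTA and per-library raw tag
counts to differentially expressed gene calls, developmental-process
partitions, expression-profile clusters, saturation curves and qRT-PCR
cross-validation. A first-class synthetic-data generator replaces the
raw sequencing with libraries of known ground truth. It is aimed at
anyone analysing legacy tag-DGE/SAGE datasets or studying the
statistics of replicate-free count-based expression profiling.

## The statistics at the core

* **Virtual tag reference**: every CATG+17 window of every reference
  sequence, both strands; clean tags map against it with ≤ 1 mismatch
  (exact hits take precedence) and are classified unambiguous /
  ambiguous / unknown by the matched gene set.
* **Clean-tag definition**: length 21, no adaptor prefix, only ACGT,
  library copy number ≥ 2.
* **Quantification**: TPM = count / clean-tag total × 10⁶, after a
  one-pass proportional distribution of tags matching 2–20 genes
  (ERANGE-style multi-read handling).
* **Differential expression** (no replicates): the Audic–Claverie
  exact test. Given count *x* in a library of N₁ tags, the count in a
  library of N₂ follows P(Y=k | x) ∝ (N₂/N₁)ᵏ (x+k)!/(x!k!) /
  (1+N₂/N₁)^(x+k+1); the two-sided p is twice the smaller of P(Y≤y)
  and P(Y>y). A gene is DE iff TPM ≥ 20 in ≥ 1 stage, p ≤ 0.001,
  |log₂ ratio| ≥ 1 and Benjamini–Hochberg FDR < 0.05.
* **Trajectories**: up/down histograms per consecutive-stage
  comparison; three-process Venn partition (dedifferentiation /
  NEC→EC transition / embryo development); k-means clustering under
  Pearson correlation distance on standardized log₂(TPM+1) profiles,
  with the number of clusters chosen by leave-one-stage-out
  figure-of-merit analysis.
* **Cross-platform validation**: 2^−ΔΔCt qRT-PCR quantification and
  Pearson R² against log₂ TPM ratios.

See `docs/methods.md` for the full model, conventions, and the
generator's scope.

## Worked example

Simulate a nine-stage dataset (500 genes, 50k clean tags per library,
half of the tags off-reference, 0.5% per-base error) and run the full
pipeline:

```sh
tagdge simulate --outdir demo/sim --n-genes 500 --depth 50000 --seed 7
tagdge run --fasta demo/sim/transcriptome.fasta \
    --tags 0h=demo/sim/tags_0h.tsv --tags 6h=demo/sim/tags_6h.tsv \
    --tags 24h=demo/sim/tags_24h.tsv --tags 48h=demo/sim/tags_48h.tsv \
    --tags NEC=demo/sim/tags_NEC.tsv --tags EC=demo/sim/tags_EC.tsv \
    --tags GE=demo/sim/tags_GE.tsv --tags TE=demo/sim/tags_TE.tsv \
    --tags CE=demo/sim/tags_CE.tsv \
    --outdir demo/out --seed 1
```

The mapping summary (`demo/out/mapping_summary.tsv`) is the standard
tag-accounting table — clean tags, unambiguously mapped tags and
unknown tags per library, with percentages recomputed from each row:

```
         clean_tags  unambiguous_tags  unambiguous_pct  unknown_tags  unknown_pct
0h            49307             24410            49.51         24897        50.49
6h            49190             24029            48.85         25161        51.15
...
Total        444373            219557            49.41        224816        50.59
Average       49375             24395            49.41         24980        50.59
```

About half of the clean tags are unknown — exactly the off-reference
fraction the generator planted, and the composition real libraries
showed. Downstream, `demo/out/updown_histogram.tsv` counts DE genes per
consecutive comparison (e.g. 22 up / 8 down at 0h→6h in this run),
`process_venn.tsv` partitions the 68 DE genes over the three
developmental processes (16 in all three), and `clusters.tsv` assigns
each DE gene to one of five expression types with nested sub-clusters.

The generator's truth files (`demo/sim/truth.tsv`) let you score any of
these calls against the planted abundances.

## Command-line interface

`tagdge refdb | simulate | preprocess | map | saturation | detest |
cluster | run` — each verb is a thin wrapper over the library
(`tagdge.refdb`, `tagdge.preprocess`, `tagdge.tagmap`,
`tagdge.quantify`, `tagdge.detest`, `tagdge.trajectory`,
`tagdge.crossval`, `tagdge.simulate`, `tagdge.report`). All inputs and
outputs are plain text: FASTA, tag TSVs (`tag<TAB>count`), expression
and result TSVs, a JSON manifest with seeds and checksums.
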