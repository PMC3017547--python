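# imprintarray

Analysis pipeline for comparing uniparental (parthenote-derived) and
biparental human ES cell lines on Infinium-style methylation beadarrays,
plus the ΔΔCt fold-regulation layer used for PCR arrays. The package covers:

- **β-values** from paired methylated/unmethylated signal intensities,
  with per-probe **range-scaling normalization** anchored on fully
  methylated / fully unmethylated / half-methylated control samples.
- **Three-state calling** (unmethylated / partial / methylated, plus a
  failure flag) on replicate-aggregated, line-level β.
- An **imprinted-locus filter**: imprinted-gene probes that are partially
  methylated in at least (N_tissue − d) tissue samples, with a discordance
  sweep over d.
- The **definitive fraction** statistic — (unmethylated + methylated) /
  (unmethylated + methylated + partial) — with tissue-baseline subtraction.
- **Uniparental-origin consistency**: definitive parthenote calls scored
  against the maternal-only expectation (maternally methylated DMRs fully
  methylated, paternally methylated DMRs fully unmethylated).
- **Differential methylation of imprinted genes** between line groups,
  **correlation-based average-linkage clustering**, and
  **agreement-vs-correlation curves** over all sites or imprinted sites.
- **qPCR arrays**: ΔΔCt fold change / fold regulation and up/down scatter
  classification.
- A **synthetic-experiment generator** that plants imprinted DMRs with known
  directions, class-wise true means, controls in triplicate and technical
  replicates, so every stage is testable offline against ground truth.

All tables are plain UTF-8 TSV (missing values `NA`); β matrices are also
readable in the GEO series-matrix text dialect. IDAT parsing is out of
scope.

## CLI

One executable with per-stage subcommands (exit 0 on success, 2 on format
errors):

```sh
imprintarray --config sim.yaml --seed 7 simulate --out data/
imprintarray beta       --signals data/signals.tsv --alpha 0 --out beta.tsv
imprintarray normalize  --beta beta.tsv --samples data/samples.tsv \
                        --eps-range 0.3 --out beta_norm.tsv --anchors-out anchors.tsv
imprintarray call       --beta beta_norm.tsv --samples data/samples.tsv \
                        --t-low 0.3 --t-high 0.7 --out states.tsv
imprintarray imprint    --states states.tsv --annotation data/annotation.tsv \
                        --samples data/samples.tsv --discordance 0 --sweep 5 --out sites.tsv
imprintarray consistency --sites sites.tsv --states states.tsv \
                        --annotation data/annotation.tsv --samples data/samples.tsv \
                        --out consistency.tsv
imprintarray differential --beta beta_norm.tsv --samples data/samples.tsv \
                        --annotation data/annotation.tsv --delta 0.2 --out diff.tsv
imprintarray cluster    --beta beta_norm.tsv --samples data/samples.tsv \
                        --out tree.nwk --correlations-out corr.tsv
imprintarray qpcr       --ct ct.tsv --test phESC --reference hESC \
                        --threshold 4 --out foldreg.tsv
imprintarray report     --sites sites.tsv --states states.tsv \
                        --samples data/samples.tsv --out summary.tsv
```

`sim.yaml` holds `SimulationConfig` keys (`n_probes`, `n_imprinted_genes`,
`kappa` — use `"inf"` for noise-free data — and so on).

## Library use

```python
import imprintarray as ia

ds = ia.simulate_dataset(ia.SimulationConfig(seed=7, kappa=200.0))
beta = ia.compute_beta(ds.signals)
profile = ia.build_control_profile(beta, ds.samples)
norm = ia.range_scale_normalize(beta, profile)
line_beta = ia.aggregate_replicates(norm, ds.samples)
states = ia.call_states(line_beta, t_low=0.3, t_high=0.7)
sites = ia.tissue_partial_filter(states, ds.annotation, ds.samples, d=0)
report = ia.maternal_consistency(
    sites, states, ds.annotation, ds.samples.lines_of_class("parthenote_esc")
)
assert report.consistency_fraction == 1.0
```
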