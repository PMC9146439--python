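# rhizostab

Assemblage-stability analysis of rhizosphere (and other replicated)
microbiome surveys. Given an OTU count table, per-sample metadata with a
grouping factor such as wetland recovery age, a taxonomy, and a rooted
phylogeny, the package computes everything a recovery-chronosequence
study needs to ask *"does the microbial assemblage become more stable
with restoration time, and which taxa carry that stability?"*:

- **Stability.** The average variation degree (AVD) of sample *k* is the
  mean absolute standardised deviation of taxon abundances,
  `AVD_k = (1/m) Σ_i |x_ki − μ_i| / σ_i`, over the m taxa retained by a
  mean relative-abundance filter (> 0.001% by default); each taxon is
  standardised across all samples of the analysed table and a taxon with
  σ_i = 0 contributes nothing. The stability index is −AVD: higher is
  more stable.
- **Indicators and core taxa.** Group-size-corrected IndVal
  (`√(specificity × fidelity)`, maximised over group combinations, label
  permutation p-values) crossed with a negative-binomial likelihood-ratio
  test using TMM-normalised offsets; OTUs significant in both (p < 0.05)
  are the core taxa.
- **Co-occurrence networks.** Positive Spearman correlations (ρ > 0.7,
  p < 0.001) between TMM-CPM profiles; greedy (Clauset–Newman–Moore)
  modularity modules; keystone taxa = top 1% of node degree.
- **Diversity and associations.** Faith's whole-tree phylogenetic
  diversity, one-way ANOVA, Bray–Curtis ANOSIM, and linear/quadratic
  regressions of the stability index against diversity and the
  accumulated abundances of indicators, core and keystone taxa, fitted on
  group × season mean units.
- **Synthetic studies.** A seeded generator that emulates a 4-recovery-
  group × 3-season × 14-transect design (168 samples, 850 OTUs across two
  kingdoms) with planted indicator OTUs, planted co-varying modules and a
  per-group overdispersion gradient, plus the ground truth to score
  recovery against.

## Worked example

```bash
rhizostab run-all --simulate --seed 7 --out-dir run7
```

simulates the default study and runs every stage into `run7/`
(`wrote 26 outputs to run7`). The stability table it produced:

```text
$ cut -f1,2,3,4 run7/stability_groups.tsv | head -5
group_years  mean_avd       n_samples  mean_stability_index
10           0.8913168018   36         -0.8913168018
20           0.7248477235   60         -0.7248477235
30           0.6404020424   36         -0.6404020424
40           0.6106996058   36         -0.6106996058
```

AVD falls — the stability index rises — monotonically with recovery age,
which is exactly the gradient the generator plants through per-group
overdispersion (φ = 0.8 at 10 y down to 0.2 at 40 y). `run7/indval.tsv`
lists each OTU's best group combination with its permutation p,
`run7/network_nodes.tsv` the module and keystone assignments, and
`run7/associations.tsv` the R² of the stability index against diversity
and accumulated abundances on the 12 group × season cells. Every stage
can also be run on its own files (`rhizostab stability --otu-table ...`,
`rhizostab network ...`, etc.; see `rhizostab --help`).

The same run is reproducible byte for byte: repeating the command with
the same seed rewrites identical outputs, and `run7/manifest.json`
records the merged configuration and per-stage seeds.

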