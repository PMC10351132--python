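# lncpath

Pipeline for discovering pathway-associated lncRNAs in bulk expression data
and turning them into molecular subtypes and a survival risk model:

1. **association** — for each lncRNA, rank all mRNAs by the first-order
   partial correlation with the lncRNA controlling for tumor purity, its
   normal-approximation p-value, and the signed rank index
   `ri = -ln(p) * sign(pcc)`.
2. **gsea_tes** — preranked enrichment of each ranking against a pathway
   gene set (weighted Kolmogorov–Smirnov running sum), a permutation p-value
   (sample-permutation null by default; classic gene-set permutation also
   available), Benjamini–Hochberg FDR across lncRNAs, the composite statistic
   `tes = (1 - 2p) * sign(es)`, and the joint `|TES| > 0.99 & FDR < 0.05`
   screen.
3. **consensus** — consensus clustering of samples on the screened lncRNAs:
   PAM (k-medoids, deterministic build+swap) with Spearman-correlation
   distance over bootstrap subsamples, per-k consensus matrices, CDF-area and
   PAC summaries, PAC-based choice of k (overridable).
4. **signatures** — ssGSEA, marker-mean and rank-based stromal/immune
   scoring, ANOVA/Wilcoxon group comparisons, one-vs-rest differential
   expression with the `|log2fc| > log2(1.2) & p < 0.05` rule.
5. **survival_risk** — univariate Cox screen, 1:1 split, L1-penalized Cox
   path with cross-validated lambda, bidirectional stepwise-AIC refinement,
   linear risk score with median stratification, from-scratch log-rank test,
   IPCW time-dependent AUC, multivariate Cox with a binned calibration table.
6. **synthetic_data** — a cohort generator that plants purity confounding,
   pathway-associated lncRNAs, latent subtypes and Cox survival, with a
   ground-truth record for recovery tests. No external data required.

A six-term published risk-model fixture ships at
`src/lncpath/data/published_model.json`, alongside editable GMT signature
fixtures (22 immune cell types, 10 MCP populations, stromal/immune,
IFN-γ/CYT/TCR/BCR).

## CLI

All stages are exposed as `lncpath <subcommand>` with global flags
`--config` (flat `key = value` file), `--seed`, `--outdir`, `--log-level`:

```bash
lncpath --seed 1 --outdir cohort simulate
lncpath associate --expr cohort/expression.tsv --biotypes cohort/biotype.tsv \
    --purity cohort/purity.tsv --out rankings.tsv
lncpath --seed 1 tes --expr cohort/expression.tsv --biotypes cohort/biotype.tsv \
    --purity cohort/purity.tsv --gmt cohort/gene_sets.gmt --set-name PATHWAY \
    --out tes.tsv
lncpath --seed 1 subtype --expr cohort/expression.tsv --biotypes cohort/biotype.tsv \
    --lnc-list screened.txt --out subtypes
lncpath signatures --expr cohort/expression.tsv --biotypes cohort/biotype.tsv \
    --gmt src/lncpath/data/immune_cells_22.gmt --method ssgsea --out scores.tsv
lncpath --seed 1 risk --expr cohort/expression.tsv --biotypes cohort/biotype.tsv \
    --clin cohort/clinical.tsv --out risk
lncpath report --deg --expr cohort/expression.tsv --biotypes cohort/biotype.tsv \
    --labels subtypes.labels.tsv --out report
```

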