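# coregulon

Cooperative gene-regulatory-network inference and transcription-factor
influence analysis for time-course expression data, with a ground-truthed
synthetic-data generator that makes every stage testable offline.

## The problem

Complex phenotypes such as lipid accumulation in the oleaginous yeast
*Yarrowia lipolytica* arise from *cooperative* regulation: groups of
transcription factors (TFs) jointly activating or repressing target genes as
the environment changes (here, a rising carbon-to-nitrogen ratio driving
nitrogen limitation). Identifying those co-regulators, their condition-specific
activity, and the phases of the response from a gene × sample expression
matrix is the job of this package. It is aimed at systems biologists who have
a time-course expression matrix, a curated regulator list, and (optionally) a
protein–protein-interaction (PPI) evidence file.

## The method

1. **Preprocess** — replicate columns are averaged; each gene is centered and
   ternarized: state +1 if the centered value ≥ *k*·σ, −1 if ≤ −*k*·σ, else 0
   (σ = standard deviation of the full centered matrix, default *k* = 1).
2. **Co-regulator mining** — all TF sets whose *collective state* (the
   unanimous nonzero state of every member) is nonzero in at least
   `min_coreg_support` of samples (default 0.2), by a levelwise
   frequent-itemset search with downward closure.
3. **Local models** — for each gene, candidate (co-activator set A,
   co-inhibitor set I) pairs are screened by discrete agreement
   (prediction sign(a − i)) and scored by a sign-constrained least-squares
   fit of the gene on the set means: coef(m_A) ≥ 0, coef(m_I) ≤ 0, score =
   adjusted R². PPI evidence contributes the fraction of within-side TF
   pairs with known interactions; the gene's model is the argmax of the
   unweighted mean of the scores.
4. **Cooperativity network** — TF pairs sharing enough same-side targets
   (hypergeometric-gated) form the "heterarchy", with evidence-backed edges
   flagged.
5. **Influence** — for regulator *r* with activated targets A^r and repressed
   targets I^r, the per-sample activity proxy is the Welch statistic

   influence(r) = ( mean E(A^r) − mean E(I^r) ) / sqrt( s²_A/|A^r| + s²_I/|I^r| )

   computed only for TFs with at least `min_target` (10) targets, on
   replicate means.
6. **Downstream** — exact multivariate change-point segmentation of the
   influence matrix into phases; per-phase TF ranking (signed influence) and
   overall ranking (absolute influence) aggregated with the robust
   rank-aggregation ρ score (minimum Beta(k, n−k+1) order-statistic tail);
   master-regulator detection by one-sided hypergeometric enrichment of
   regulons in a gene list.

## Worked example

```python
import coregulon as cg

truth = cg.generate_truth(n_tfs=20, n_genes=200, n_phases=4, seed=42)
expr  = cg.simulate_expression(truth, n_replicates=3, noise_sd=0.1, replicate_sd=0.05)
avg   = cg.average_replicates(expr, expr.sample_meta["replicate_group"].to_dict())
disc  = cg.discretize(avg)
grn   = cg.infer_grn(avg, disc, truth.regulator_list())
print(cg.score_recovery(grn, truth))
```

prints (on this machine):

```
{'precision': 0.8763213530655392, 'recall': 0.9150110375275938, 'f1': 0.8952483801295896, 'n_inferred': 946, 'n_true': 906}
```

i.e. at noise 0.1 about 90 % of the planted signed TF→gene edges are
recovered; rerunning with `noise_sd=0, replicate_sd=0` gives precision =
recall = 1.0. Continuing,

```python
infl = cg.influence_matrix(avg, grn, min_target=10)
seg  = cg.segment_phases(infl)
print(seg.n_phases, seg.boundaries)   # -> 4 [6, 13, 20]
```

recovers the planted four-phase structure exactly: the influence matrix
alone identifies the physiological phase changes. See `examples/` for
narrative scripts covering each capability, and the `coregulon` command-line
tool (`simulate`, `preprocess`, `infer`, `influence`, `phases`, `rank`,
`mr`, `run-all`) for shell use.

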