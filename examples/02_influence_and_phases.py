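"""TF influence over the time course and automatic phase segmentation.

The influence of a regulator in a sample is a Welch-t statistic comparing
the expression of its activated vs repressed targets; change points in the
influence pattern mark physiological phases.
"""

import coregulon as cg

truth = cg.generate_truth(seed=42)
expr = cg.simulate_expression(truth, noise_sd=0.1, replicate_sd=0.05)
avg = cg.average_replicates(expr, expr.sample_meta["replicate_group"].to_dict())
disc = cg.discretize(avg)
grn = cg.infer_grn(avg, disc, truth.regulator_list())

infl = cg.influence_matrix(avg, grn, min_target=10)
print(f"influence matrix: {len(infl.tf_ids)} TFs x {len(infl.sample_ids)} "
      f"time points (TFs with fewer than 10 targets are excluded)")
tf0 = infl.tf_ids[0]
row = infl.values.loc[tf0]
print(f"example: {tf0} influence ranges {row.min():.2f}..{row.max():.2f}; "
      "positive = activated targets above repressed ones (TF acting)")

seg = cg.segment_phases(infl, max_phases=8)
print(f"detected {seg.n_phases} phases; new phases start at time indices "
      f"{seg.boundaries} (planted: {truth.phase_boundaries})")
print("the segmentation minimizes within-phase squared deviation of the")
print("influence pattern, with a penalized choice of the phase count")
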