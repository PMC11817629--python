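"""Stability diagnostics: PC subsampling robustness and seed-to-seed agreement.

First refits principal components on a random 50% gene subsample and reports
the |cosine| of each leading component against the full-data baseline.  Then
trains two ensembles under different master seeds (different negative draws)
and reports the Pearson correlation of their confident annotations
(mean probability > 0.6 or < 0.4 in both).
"""

import hybridgo as hg

cfg = hg.SyntheticConfig(missing_frac=0.0, seed=4)
ds = hg.generate_dataset(cfg)

cos = hg.subsample_robustness(ds.expression, n_components=3, fraction=0.5, seed=4)
print("PC |cosine| to baseline after 50% gene subsampling:")
for name, value in cos.items():
    print(f"  {name}: {value:.3f}")

prepared = hg.prepare_synthetic(ds)
table = prepared.assemble(5, "hybrid")


def ensemble_probs(seed):
    plan = hg.make_split_plan(prepared.positives, set(table.gene_ids),
                              n_bootstrap=10, n_folds=5, master_seed=seed)
    ens = hg.fit_full({"pc5": table}, plan, hg.ModelSpec("random_forest", seed=seed))
    labeled = plan.positives | set().union(*(it.negatives for it in plan.iterations))
    unlabeled = [g for g in table.gene_ids if g not in labeled]
    return hg.predict_unlabeled(ens, {"pc5": table}, unlabeled).mean_prob


a, b = ensemble_probs(10), ensemble_probs(11)
shared = a.index.intersection(b.index)
r, n = hg.agreement(a.loc[shared], b.loc[shared])
print(f"\nagreement between master seeds 10 and 11: Pearson r = {r:.3f} "
      f"over {n} confident genes")
print("-> high r means the bootstrap-averaged annotations are driven by the "
      "data, not by any particular negative draw.")
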