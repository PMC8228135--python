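"""Population structure: DAPC and EM admixture with Evanno delta-K.

Chooses the retained PC count by alpha-score, fits the discriminant
analysis on the five origin groups, then runs replicate admixture fits
over K = 1..6 and selects K by the Evanno second-difference criterion.
The per-group mean ancestry table is the synthetic analogue of the
admixture-proportion table.
"""

import pandas as pd

from _common import SEED, make_panel, outdir
from canid import admixture, dapc

ds, truth = make_panel()
out = outdir("04_structure")

# ---- DAPC -------------------------------------------------------------
pca_res = dapc.pca(ds)
cap = dapc.n_pcs_for_variance(pca_res, 0.95)
cands = sorted({c for c in (2, 5, 10, 20) if c <= cap})
a_table, n_pcs = dapc.a_score(ds, ds.groups, cands, n_permutations=25,
                              seed=SEED, pca_res=pca_res)
fit = dapc.dapc_fit(pca_res, ds.groups, n_pcs)
a_table.to_csv(out / "a_score.tsv", sep="\t", index=False)
coords = pd.DataFrame(fit.coords, columns=[f"DF{i+1}" for i in range(fit.n_df)])
coords.insert(0, "sample_id", ds.samples["sample_id"])
coords.insert(1, "group", ds.samples["group"])
coords.to_csv(out / "dapc_coords.tsv", sep="\t", index=False)
print(f"alpha-score selected {n_pcs} PCs; {fit.n_df} discriminant functions; "
      f"reassignment {100 * fit.reassignment_accuracy():.1f}%; "
      f"variance represented {100 * fit.variance_represented:.1f}%")

# ---- admixture --------------------------------------------------------
# the EM sweep uses every second marker: ancestry signal saturates well
# below the full panel and the replicate sweep stays desk-scale
import numpy as np

thin = ds.subset_markers(np.arange(0, ds.n_markers, 2))
runs = admixture.run_replicates(thin, range(1, 6), n_replicates=5, seed=SEED,
                                max_iter=150, tol=1e-3)
table, best_k = admixture.evanno_delta_k(runs)
table.to_csv(out / "delta_k.tsv", sep="\t", index=False)
print("\nEvanno table:")
print(table.round(2).to_string(index=False))
print(f"selected K = {best_k}")

best = max((r for r in runs if r.K == best_k), key=lambda r: r.loglik)
by_group = admixture.admixture_by_group(best.Q, ds.groups)
by_group.to_csv(out / "admixture_by_group.tsv", sep="\t")
print("\nmean ancestry by group (clusters named by majority group):")
print(by_group.round(3).to_string())
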