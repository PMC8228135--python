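"""Candidate-gene panel stratification: per-category PCA and factor analysis.

Maps SNPs into the packaged gene panel (synthetic coordinates on the
simulated genome), then runs panel-restricted PCA and per-gene factor
analysis for each phenotype category (ATO, BM, CC, SE).
"""

import pandas as pd

from _common import make_panel, outdir
from canid import gene_panels

ds, _ = make_panel()
out = outdir("06_gene_panels")

panel = gene_panels.load_panel()
assignment, subsets = gene_panels.map_snps_to_genes(ds.markers, panel)
assignment.to_csv(out / "panel_assignment.tsv", sep="\t", index=False)
print(f"{assignment['marker_id'].nunique()} SNPs assigned across "
      f"{assignment['gene'].nunique()} genes")

for cat in gene_panels.CATEGORIES:
    if cat not in subsets:
        print(f"{cat}: no SNPs in panel, skipped")
        continue
    idx = subsets[cat]
    pca_res = gene_panels.panel_pca(ds, idx)
    k = min(3, pca_res.scores.shape[1])
    scores = pd.DataFrame(pca_res.scores[:, :k], columns=[f"PC{i+1}" for i in range(k)])
    scores.insert(0, "sample_id", ds.samples["sample_id"])
    scores.insert(1, "group", ds.samples["group"])
    scores.to_csv(out / f"{cat}_pca_scores.tsv", sep="\t", index=False)

    n_genes = assignment.loc[assignment["category"] == cat, "gene"].nunique()
    fa = gene_panels.factor_analysis(ds, idx, n_factors=min(n_genes, 3),
                                     rotation="varimax", aggregate_by_gene=assignment)
    fa.loadings.round(4).to_csv(out / f"{cat}_factor_loadings.tsv", sep="\t")
    print(f"{cat}: {idx.size:3d} SNPs in {n_genes} genes; "
          f"PC1 explains {100 * pca_res.explained[0]:.1f}%; "
          f"mean communality {fa.communalities.mean():.2f}")
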