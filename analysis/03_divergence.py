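"""Group divergence: pairwise Weir-Cockerham F_ST and Nei distances.

Writes the combined square table (F_ST below the diagonal, Nei-1972
distance above) and the wolf-row summaries, mirroring the group-level
divergence table of the empirical study.
"""

from _common import make_panel, outdir
from canid import divergence

ds, _ = make_panel()
out = outdir("03_divergence")

freqs = divergence.allele_freqs(ds)
nei = divergence.nei_distance(freqs, "nei1972")
fst = divergence.wc_fst_pairwise(ds)
table = divergence.combined_table(fst, nei)
table.to_csv(out / "divergence_table.tsv", sep="\t")
nei.to_frame().to_csv(out / "nei1972.tsv", sep="\t")
fst.to_frame().to_csv(out / "fst.tsv", sep="\t")

print("combined table (F_ST below diagonal, Nei above):")
print(table.round(3).to_string())
mean_d, sd_d = divergence.summarize_vs_group(nei, "GW")
mean_f, sd_f = divergence.summarize_vs_group(fst, "GW")
print(f"\nGW vs dogs: D = {mean_d:.2f} +/- {sd_d:.2f}, F_ST = {mean_f:.2f} +/- {sd_f:.2f}")
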