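"""Generate the synthetic five-breed SNP panel and record its truth.

Writes the panel as PLINK PED/MAP plus BED/BIM/FAM under scratch/ (bulky,
regenerable) and a small truth summary under results/01_panel/.
"""

from pathlib import Path

import pandas as pd

from _common import SEED, make_panel, outdir
from canid.genotype_io import genome_span, write_plink

ds, truth = make_panel()
out = outdir("01_panel")
scratch = Path(__file__).resolve().parents[1] / "scratch" / "panel"
scratch.mkdir(parents=True, exist_ok=True)

write_plink(ds, scratch / "panel", "ped_map")
write_plink(ds, scratch / "panel", "bed_bim_fam")

total_bp, per_chrom = genome_span(ds)
per_chrom.to_csv(out / "genome_spans.tsv", sep="\t", index=False)

summary = (
    ds.samples.groupby("group").size().rename("n_samples").reset_index()
    .merge(
        truth.realized_froh.rename("froh").rename_axis("sample_id").reset_index()
        .merge(ds.samples, on="sample_id")
        .groupby("group")["froh"].mean().rename("mean_implanted_froh").reset_index(),
        on="group",
    )
)
summary.to_csv(out / "panel_summary.tsv", sep="\t", index=False)

print(f"panel: {ds.n_samples} samples x {ds.n_markers} SNPs, seed {SEED}")
print(f"SNP-covered genome: {total_bp / 1e6:.1f} Mbp over {len(per_chrom)} chromosomes")
print(summary.to_string(index=False))
print(f"PLINK files -> {scratch}")
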