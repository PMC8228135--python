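"""Shared study conditions for the numbered analysis drivers.

One synthetic five-breed panel stands in for the empirical genotype data
(which was never publicly deposited): four diverged source groups plus a
GSD x GW hybrid cohort (CWD) with implanted autozygous tracts.  All
drivers regenerate it from the same seed, so every stage sees the same
panel and the whole analysis is reproducible end to end.
"""

from pathlib import Path

from canid.simulate import five_breeds_preset

SEED = 42
N_LOCI = 6000

RESULTS = Path(__file__).resolve().parents[1] / "results"


def make_panel():
    return five_breeds_preset(seed=SEED, n_loci=N_LOCI)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
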