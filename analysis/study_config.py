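"""Shared configuration for the numbered analysis scripts.

One seeded configuration drives the whole synthetic study: the gene-set
inventory mirrors the real study (14 human + 24 mouse cell types, 35 synaptic
sets of >= 50 genes, top 1600 genes per cell type, pLI > 0.9), enrichment is
planted in the constrained (PI) set plus one human and one mouse cell set,
and both analysis arms run at the generator's default scale (12,000 genes,
GWAS N = 105,318, 4000 cases / 4000 controls).
"""

from pathlib import Path

from gsconverge.pipeline_io import RunConfig
from gsconverge.synthetic_data import SimConfig

SEED = 20260920
RESULTS = Path(__file__).resolve().parent.parent / "results"


def make_config() -> RunConfig:
    return RunConfig(seed=SEED, sim=SimConfig(seed=SEED))
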