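import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pooledscan.simulate import (
    EffectLocus,
    PoolSetSpec,
    SimulationSpec,
    SnpDef,
    make_snp_panel,
)


def flat_panel(n_snps, maf=0.2, spacing=5_000, chrom="1", start=1_000_000):
    """A panel of identical-MAF SNPs at even spacing."""
    return tuple(
        SnpDef(
            snp_id=f"s{i:04d}", chrom=chrom, pos=start + i * spacing,
            allele_a="A", allele_b="G", maf=maf,
        )
        for i in range(n_snps)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def small_spec():
    """One 15-SNP LD block carrying a strong risk locus, one small pool set."""
    panel = flat_panel(15)
    return SimulationSpec(
        n_cases=120,
        n_controls=120,
        snp_panel=panel,
        ld_block_length=15,
        ld_r=0.9,
        effect_loci=(EffectLocus(panel[7].snp_id, 2.0),),
        pool_sets=(
            PoolSetSpec(set_id="I", pool_size=20,
                        pools_per_group={"CASE": 6, "CTRL": 6}),
        ),
        noise_sd=0.02,
        seed=11,
    )
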