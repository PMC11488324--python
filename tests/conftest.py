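import numpy as np
import pandas as pd
import pytest

from mitoscatac import (
    GenotypingConfig,
    SimConfig,
    VariantSpec,
    make_peaks,
    mouse_mito_genome,
    human_mito_genome,
    simulate_cells,
    simulate_fragments,
)


@pytest.fixture(scope="session")
def mouse_genome():
    return mouse_mito_genome()


@pytest.fixture(scope="session")
def human_genome():
    return human_mito_genome()


@pytest.fixture(scope="session")
def small_dataset(mouse_genome):
    """A small but complete simulated sample shared by read-level tests:
    40 cells with content-driven mito reads and two planted heteroplasmies."""
    g = mouse_genome
    cfg = SimConfig(
        n_cells=40,
        seed=101,
        variants=(
            VariantSpec(9821, "T", pi=0.2, beta_a=1.0, beta_b=9.0),
            VariantSpec(15219, "C", pi=0.2, beta_a=1.0, beta_b=9.0),
        ),
        frag_log_mean=float(np.log(600)),
        frag_log_sigma=0.3,
    )
    truth = simulate_cells(cfg, g)
    peaks = make_peaks(g, cfg)
    frags, reads = simulate_fragments(truth, cfg, g, peaks)
    return {"config": cfg, "truth": truth, "peaks": peaks, "frags": frags, "reads": reads}


@pytest.fixture()
def geno_config():
    return GenotypingConfig()


def make_tensor(counts_by_site, barcodes, genome, config=None):
    """Build an AlleleCountTensor by hand from
    {(pos, allele, strand): per-cell counts} entries."""
    from mitoscatac.genotyping import AlleleCountTensor, _CODE

    config = config or GenotypingConfig()
    counts = np.zeros((len(barcodes), genome.mito_length + 1, 4, 2), dtype=np.int64)
    for (pos, allele, strand), per_cell in counts_by_site.items():
        s = 0 if strand == "+" else 1
        counts[:, pos, _CODE[allele], s] = per_cell
    return AlleleCountTensor(np.asarray(barcodes), counts, genome.mito_length, config)
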