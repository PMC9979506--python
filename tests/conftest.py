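import warnings

import numpy as np
import pandas as pd
import pytest

from driftscan import genio, simdata

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def neutral_design():
    """One neutral chromosome of the two-line design (session-wide)."""
    cfg = simdata.SimConfig(n_chrom=1, chrom_length_bp=2_000_000,
                            n_snps_per_chrom=400, burnin_gens=60, seed=42)
    haps, truth = simdata.simulate_design(cfg, [])
    return cfg, haps, truth


@pytest.fixture(scope="session")
def neutral_matrix(neutral_design):
    _, haps, _ = neutral_design
    return genio.from_haplotypes(haps)


def make_matrix(dosage, pops, chrom=None, pos=None):
    """Hand-build a GenotypeMatrix from a (n_var, n_samples) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_var, n_samp = dosage.shape
    samples = [f"s{i}" for i in range(n_samp)]
    variants = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * n_var,
        "pos": pos if pos is not None else np.arange(1, n_var + 1),
        "ref": "A", "alt": "G"})
    return genio.GenotypeMatrix(variants, dosage, samples,
                                dict(zip(samples, pops)))
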