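import numpy as np
import pandas as pd
import pytest

from woodgen.config import desk_preset
from woodgen.genio import GenotypeMatrix
from woodgen.simulate import run_simulation


def make_matrix(dosage, chrom=None, pos=None, sex=None, status=None,
                is_z=None) -> GenotypeMatrix:
    """Small hand-built genotype matrix for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    chrom = np.asarray(chrom if chrom is not None else ["1"] * L)
    pos = np.asarray(pos if pos is not None else np.arange(L) * 1000 + 1)
    is_z = np.asarray(is_z if is_z is not None else (chrom == "Z"))
    samples = pd.DataFrame({
        "id": np.arange(n),
        "sex": sex if sex is not None else ["M"] * n,
        "status": status if status is not None else ["local"] * n,
    })
    loci = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "G",
                         "is_z": is_z})
    return GenotypeMatrix(dosage=dosage, samples=samples, loci=loci)


def hwe_genotypes(p, n, rng) -> np.ndarray:
    """(n, len(p)) dosages drawn under Hardy-Weinberg proportions."""
    p = np.atleast_1d(p)
    return (rng.random((n, 2, len(p))) < p).sum(axis=1).astype(np.int8)


@pytest.fixture(scope="session")
def small_sim():
    """A compact but fully featured simulated population."""
    cfg = desk_preset(n_boxes=120, n_years=10, n_autosomal_snps=600,
                      n_z_snps=150, seed=7)
    sim = run_simulation(cfg)
    assert not sim.extinct
    return sim


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
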