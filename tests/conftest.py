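import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cobdge.annotation import revcomp
from cobdge.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TAG_LEN = 21


def naive_match(genome: dict[str, str], tag: str, max_mm: int = 1):
    """Brute-force Hamming scan of a 21-mer over both strands; the oracle the
    indexed matcher must reproduce exactly."""
    hits = []
    for chrom, seq in genome.items():
        s = np.frombuffer(seq.encode(), dtype=np.uint8)
        n_win = len(s) - TAG_LEN + 1
        if n_win <= 0:
            continue
        for strand, t in (("+", tag), ("-", revcomp(tag))):
            tb = np.frombuffer(t.encode(), dtype=np.uint8)
            mm = np.zeros(n_win, dtype=np.int64)
            for j in range(TAG_LEN):
                mm += s[j : j + n_win] != tb[j]
            for p in np.nonzero(mm <= max_mm)[0]:
                hits.append((chrom, int(p) + 1, strand, int(mm[p])))
    return sorted(hits)


@pytest.fixture(scope="session")
def noise_free_ds(tmp_path_factory):
    """Small noiseless dataset: counts are exactly recoverable from reads."""
    cfg = SimulationConfig(
        n_genes=40, n_junction_genes=3, n_exclusive=4, de_fraction=0.1,
        library_depth=20_000, error_rate=0.0, dispersion=0.0, seed=7,
    )
    outdir = tmp_path_factory.mktemp("noise_free")
    ds = simulate_dataset(cfg, str(outdir))
    ds["config"] = cfg
    ds["outdir"] = str(outdir)
    return ds


@pytest.fixture(scope="session")
def noisy_ds(tmp_path_factory):
    """Dataset with sequencing errors and NB noise."""
    cfg = SimulationConfig(
        n_genes=30, library_depth=10_000, error_rate=0.02, dispersion=0.1, seed=11,
    )
    outdir = tmp_path_factory.mktemp("noisy")
    ds = simulate_dataset(cfg, str(outdir))
    ds["config"] = cfg
    ds["outdir"] = str(outdir)
    return ds
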