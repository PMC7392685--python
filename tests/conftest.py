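import numpy as np
import pytest

from mhcpop.core import AlleleSequence
from mhcpop.seqstats import AlignedPanel
from mhcpop.simulate import SimulationConfig, simulate_allele_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_allele_config():
    """Minimal single-locus config with two alleles at 0.5/0.5."""
    panel = simulate_allele_panel(2, 60, 6, seed=7, name_prefix="L*")
    return SimulationConfig(
        seed=11,
        n_individuals=50,
        allele_panel_per_locus={"L": panel},
        allele_frequencies={"L": np.array([0.5, 0.5])},
        primers={"L": ("ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG")},
        depth_mean=2000.0,
    )


def make_panel(seqs, mult=None, names=None, locus="test"):
    names = names or [f"h{i}" for i in range(len(seqs))]
    return AlignedPanel(locus, names, list(seqs), mult)


@pytest.fixture
def small_panel():
    return make_panel(["ACGT", "ACGA", "ACCA"])


def random_panel(rng, n_rows, length, n_sites, mult_max=1):
    """Random aligned panel for property checks (guaranteed >= 1 seg site)."""
    alleles = simulate_allele_panel(n_rows, length, n_sites, seed=int(rng.integers(2**31)))
    mult = rng.integers(1, mult_max + 1, size=n_rows).tolist() if mult_max > 1 else None
    return make_panel([a.seq for a in alleles], mult)
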