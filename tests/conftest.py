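import numpy as np
import pytest

from mrpipe.summary_io import HarmonizedInstrument, InstrumentSet
from mrpipe.mr_core import wald_ratios


def make_instruments(bx, sx, by, sy, prefix="rs"):
    return InstrumentSet(
        instruments=tuple(
            HarmonizedInstrument(
                rsid=f"{prefix}{i}",
                beta_x=float(a),
                se_x=float(b),
                beta_y=float(c),
                se_y=float(d),
                aligned_allele="A",
            )
            for i, (a, b, c, d) in enumerate(zip(bx, sx, by, sy))
        )
    )


@pytest.fixture
def four_snp_panel():
    """Small hand-constructed panel with unequal weights."""
    return make_instruments(
        bx=[0.10, 0.08, 0.12, 0.05],
        sx=[0.010, 0.012, 0.008, 0.011],
        by=[0.012, 0.006, 0.018, 0.002],
        sy=[0.004, 0.005, 0.003, 0.006],
    )


@pytest.fixture
def four_snp_ratios(four_snp_panel):
    return wald_ratios(four_snp_panel)


@pytest.fixture
def rng():
    return np.random.default_rng(20240518)


def random_panel(rng, j=8, theta=0.1):
    """Random but well-conditioned panel for property tests."""
    bx = rng.uniform(0.03, 0.15, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.005, 0.02, j)
    sy = rng.uniform(0.003, 0.01, j)
    by = theta * bx + rng.normal(0, sy)
    return make_instruments(bx, sx, by, sy)
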