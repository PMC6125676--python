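import numpy as np
import pytest

from hpoxbs import presets
from hpoxbs.conversion import IDEAL_BS, IDEAL_OXBS, derive_emission_parameters
from hpoxbs.model import DivisionSchedule


@pytest.fixture(scope="session")
def demo_ref():
    return presets.demo_reference()


@pytest.fixture(scope="session")
def ideal_emissions():
    return {"BS": IDEAL_BS, "oxBS": IDEAL_OXBS}


@pytest.fixture(scope="session")
def afp_emissions():
    """Measured linker-control rates of the Afp amplicon, both treatments."""
    return derive_emission_parameters(
        {"unmodC": 0.996, "5mC": 0.0674, "5hmC": 0.0765},
        {"unmodC": 0.996, "5mC": 0.0636, "5hmC": 0.920},
    )


@pytest.fixture(scope="session")
def esc_schedule():
    return DivisionSchedule(
        days=presets.DEFAULT_SCHEDULE_DAYS,
        divisions=presets.DEFAULT_SCHEDULE_DIVISIONS,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def perfect_read_seq(ref, umi="ATGAT"):
    """Error-free read of a fully methylation-retaining molecule: genomic and
    control cytosines read C, non-control linker cytosines are converted
    (they are unmodified by construction, so they always read T)."""
    seq = list(ref.alignment_reference())
    for pos, base in zip(ref.umi_composite_positions, umi):
        seq[pos] = base
    return "".join(seq)
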