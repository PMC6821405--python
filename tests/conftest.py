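import numpy as np
import pytest

from gt2spec.conservation import CladeAlignment
from gt2spec.io_formats import SequenceRecord
from gt2spec.synthetic_data import MsaParams, TrajParams, gen_clade_msa, gen_interaction_traj


def make_alignment(columns_by_clade: dict[str, list[str]], reference_id: str | None = None):
    """Build a CladeAlignment from per-clade lists of equal-length sequences."""
    records = []
    clade_of = {}
    for clade, seqs in columns_by_clade.items():
        for i, seq in enumerate(seqs):
            sid = f"{clade}_{i}"
            records.append(SequenceRecord(id=sid, description="", residues=seq))
            clade_of[sid] = clade
    if reference_id is None:
        reference_id = records[0].id
    return CladeAlignment(records=records, clade_of=clade_of, reference_id=reference_id)


@pytest.fixture(scope="session")
def planted_msa():
    """Noiseless planted alignment: 3 clades x 20 sequences x 100 columns."""
    return gen_clade_msa(MsaParams(), seed=11)


@pytest.fixture(scope="session")
def toy_trajectory():
    """Jittered toy trajectory with planted interaction states."""
    return gen_interaction_traj(TrajParams(n_frames=400), seed=7)


@pytest.fixture(scope="session")
def clean_trajectory():
    """Noiseless toy trajectory (sigma = 0)."""
    return gen_interaction_traj(TrajParams(n_frames=5, sigma=0.0), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
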