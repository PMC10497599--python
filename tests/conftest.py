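import numpy as np
import pytest

from whalepop.dataset import Dataset
from whalepop.demography.models import EpochModel, TwoPopModel
from whalepop.synthetic import assign_annotations, simulate_genotypes


@pytest.fixture(scope="session")
def twopop_ds() -> Dataset:
    """Small two-deme coalescent dataset with annotations (shared,
    read-only across tests)."""
    model = TwoPopModel(
        n_anc=800, n1=600, n2=80, t_split=400,
        m_1_to_2=5e-3, m_2_to_1=5e-4,
    )
    ds = simulate_genotypes(
        model, {"ENP": 10, "GOC": 8}, seq_len=400_000, mu=1e-7, rec=1e-8, seed=11
    )
    return assign_annotations(ds, exon_fraction=0.3, del_fraction=0.5, seed=5)


@pytest.fixture(scope="session")
def onepop_ds() -> Dataset:
    ds = simulate_genotypes(
        EpochModel.one_epoch(500), 12, seq_len=300_000, mu=1e-7, rec=1e-8, seed=7
    )
    return ds


def make_dataset(genotypes, positions=None, pops=None, **kw):
    g = np.asarray(genotypes, dtype=np.int8)
    if positions is None:
        positions = np.arange(g.shape[1]) * 100
    if pops is None:
        pops = ["A"] * g.shape[0]
    return Dataset(genotypes=g, positions=np.asarray(positions),
                   pop_labels=np.asarray(pops), **kw)
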