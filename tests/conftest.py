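import numpy as np
import pandas as pd
import pytest

from pbsakit import (
    ClusterSpec,
    Dataset,
    DeltaTerms,
    MolecularStructure,
    SyntheticStudySpec,
    gen_cluster,
    gen_study,
)

PDB_TEXT = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA BALA A   1      11.700   6.100  -5.200  1.00  0.00           C
ATOM      4  O   ALA A   1      12.050   7.500  -4.900  1.00  0.00           O
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(PDB_TEXT)
    return p


def single_sphere(radius=1.7, probe_radius=1.4, cell_half=20.0) -> MolecularStructure:
    """One carbon-like sphere centred in a cubic cell of edge 2*cell_half."""
    return MolecularStructure(
        elements=np.array(["C"], dtype=object),
        centers=np.zeros((1, 3)),
        radii=np.array([radius]),
        cell_min=np.full(3, -cell_half),
        cell_max=np.full(3, cell_half),
    )


@pytest.fixture
def sphere():
    return single_sphere()


@pytest.fixture
def cluster5():
    return gen_cluster(ClusterSpec(n_atoms=5, seed=1), margin=2.0)


def make_delta(**overrides) -> DeltaTerms:
    base = dict(
        complex_id="c1",
        dE_vdw=-40.0,
        dE_ele=-30.0,
        dG_pb=50.0,
        dSASA=-800.0,
        dSAV=-750.0,
        dE_disp=-20.0,
        dE_sp=-70.0,
        n_rot=5,
    )
    base.update(overrides)
    return DeltaTerms(**base)


@pytest.fixture
def delta():
    return make_delta()


def study_dataset(seed=0, noise_sd=0.0, n=54, regime="spt",
                  coefficients=None, pair=None, **kw):
    """Synthetic per-complex dataset with known ground truth."""
    spec_kw = dict(n_complexes=n, regime=regime, noise_sd=noise_sd, seed=seed, **kw)
    if coefficients is not None:
        spec_kw["coefficients"] = coefficients
    if pair is not None:
        spec_kw["pair"] = pair
    spec = SyntheticStudySpec(**spec_kw)
    frames, deltas, exp, truth = gen_study(spec)
    return Dataset(terms=deltas, exp=exp), truth
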