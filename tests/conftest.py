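import numpy as np
import pandas as pd
import pytest

from resicor import ActivityTable, EnergyMatrix, load_paper_fixture


@pytest.fixture(scope="session")
def paper():
    """The packaged 8-compound x 12-residue study dataset."""
    return load_paper_fixture()


@pytest.fixture
def toy():
    """4 compounds x 3 residues with an exactly known structure.

    ALA1 is perfectly anti-correlated with activity, LEU2 perfectly
    correlated, SER3 is neither.
    """
    y = ActivityTable({"c1": 6.0, "c2": 7.0, "c3": 8.0, "c4": 9.0})
    E = EnergyMatrix(
        pd.DataFrame(
            {
                "ALA1": [-6.0, -7.0, -8.0, -9.0],
                "LEU2": [-9.0, -8.0, -7.0, -6.0],
                "SER3": [-5.0, -9.0, -5.0, -9.0],
            },
            index=["c1", "c2", "c3", "c4"],
        )
    )
    return E, y


def random_dataset(rng, n_compounds=6, n_residues=4):
    """An unstructured random matrix/activity pair for property tests."""
    comps = [f"c{i}" for i in range(n_compounds)]
    E = EnergyMatrix(
        pd.DataFrame(
            rng.normal(-8, 3, size=(n_compounds, n_residues)),
            index=comps,
            columns=[f"ALA{j + 1}" for j in range(n_residues)],
        )
    )
    A = ActivityTable(pd.Series(rng.normal(7.8, 0.7, size=n_compounds), index=comps))
    return E, A
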