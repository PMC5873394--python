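import numpy as np
import pytest

from hgtclock.calibration import read_clade_definitions
from hgtclock.chronotree import Chronogram
from hgtclock.simulate import JitterSpec, simulate_posterior_trace
from hgtclock.workflow import data_path


@pytest.fixture(scope="session")
def truth_chronogram() -> Chronogram:
    """The bundled synthetic 15-leaf dated species tree (root 3900 Ma)."""
    return Chronogram.from_newick(data_path("synthetic_truth.nwk").read_text())


@pytest.fixture(scope="session")
def clade_defs(truth_chronogram):
    return read_clade_definitions(str(data_path("synthetic_clades.tsv")))


@pytest.fixture(scope="session")
def jitter_run(truth_chronogram):
    """A moderate-noise pseudo-posterior trace plus its truth ledger."""
    spec = JitterSpec(truth=truth_chronogram, sd=150.0, n_samples=200, seed=20260924)
    return simulate_posterior_trace(spec)


def make_comb_chronogram(ages_by_clade: dict[str, float]) -> Chronogram:
    """4-cherry tree with directly controlled cherry/internal ages.

    Keys: 'ab', 'cd', 'ef', 'gh' (cherry ages), 'abcd', 'efgh', 'root'.
    """
    a = ages_by_clade
    nwk = (
        f"(((A:{a['ab']},B:{a['ab']}):{a['abcd'] - a['ab']},"
        f"(C:{a['cd']},D:{a['cd']}):{a['abcd'] - a['cd']}):{a['root'] - a['abcd']},"
        f"((E:{a['ef']},F:{a['ef']}):{a['efgh'] - a['ef']},"
        f"(G:{a['gh']},H:{a['gh']}):{a['efgh'] - a['gh']}):{a['root'] - a['efgh']});"
    )
    return Chronogram.from_newick(nwk)
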