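import numpy as np
import pandas as pd
import pytest

from pathpair.dataset import build_dataset
from pathpair.molgraph import MolecularGraph, parse_molfile, read_molfile_dir
from pathpair.synthetic import GeneratorConfig, generate_universe

# ethanol with explicit hydrogens: C-C-O skeleton plus six H
ETHANOL_MOLFILE = """ethanol
  test

  9  8  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000   -1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    1.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
"""


@pytest.fixture(scope="session")
def ethanol() -> MolecularGraph:
    return parse_molfile(ETHANOL_MOLFILE)


def random_graph(rng: np.random.Generator, n_atoms: int | None = None) -> MolecularGraph:
    """A small random connected molecular graph (shared test helper)."""
    n = int(n_atoms if n_atoms is not None else rng.integers(1, 10))
    atoms = tuple(rng.choice(["C", "N", "O", "S"], size=n))
    bonds = []
    for i in range(1, n):
        bonds.append((int(rng.integers(0, i)), i, int(rng.integers(1, 5))))
    return MolecularGraph("R", atoms, tuple(sorted((min(a, b), max(a, b), o) for a, b, o in bonds)))


@pytest.fixture(scope="session")
def tiny_universe(tmp_path_factory):
    """A small synthetic corpus with full planted signal, built once."""
    out = tmp_path_factory.mktemp("tiny_universe")
    config = GeneratorConfig(
        n_metabolites=60, n_pathways_l3=5, n_pathways_l2=2,
        pathway_size_median=10.0, signal_strength=1.0, seed=11,
    )
    manifest = generate_universe(config, out)
    return {"dir": out, "config": config, "manifest": manifest}


@pytest.fixture(scope="session")
def tiny_dataset(tiny_universe):
    graphs = read_molfile_dir(tiny_universe["dir"] / "molfiles")
    membership = pd.read_csv(tiny_universe["dir"] / "membership.tsv", sep="\t", dtype=str)
    ds, defs = build_dataset(graphs, membership)
    return {"dataset": ds, "definitions": defs, "graphs": graphs, "membership": membership}
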