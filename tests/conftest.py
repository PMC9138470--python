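import numpy as np
import pytest

from cdrflex import (ConformationalEnsemble, SyntheticEnsembleSpec,
                     generate_multibasin_ensemble, rmsd_matrix)

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.953   2.853   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.470   2.731   0.110  1.00  0.00           C
ATOM      8  O   GLY A   2       6.009   1.625   0.220  1.00  0.00           O
ATOM      9  N   SER A   3       6.180   3.857   0.080  1.00  0.00           N
ATOM     10  CA  SER A   3       7.630   3.870   0.170  1.00  0.00           C
ATOM     11  C   SER A   3       8.220   5.270   0.090  1.00  0.00           C
ATOM     12  O   SER A   3       7.510   6.270   0.000  1.00  0.00           O
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def multi_model_pdb(tmp_path):
    """5-model PDB built by shifting the toy structure."""
    lines = []
    for m in range(1, 6):
        lines.append(f"MODEL     {m:4d}\n")
        for row in TOY_PDB.splitlines():
            x = float(row[30:38]) + 0.1 * m
            lines.append(row[:30] + f"{x:8.3f}" + row[38:] + "\n")
        lines.append("ENDMDL\n")
    path = tmp_path / "multi.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture(scope="session")
def basin_spec():
    """Reference 3-basin study conditions, scaled for unit tests."""
    return SyntheticEnsembleSpec(populations=(0.6, 0.3, 0.1), n_frames=800,
                                 noise_sigma=0.02, seed=42)


@pytest.fixture(scope="session")
def basin_ensemble(basin_spec):
    ensemble, labels = generate_multibasin_ensemble(basin_spec)
    return ensemble, labels


@pytest.fixture(scope="session")
def basin_matrix(basin_spec, basin_ensemble):
    ensemble, _ = basin_ensemble
    return rmsd_matrix(ensemble, basin_spec.region_set(), "CDR3")


@pytest.fixture(scope="session")
def biased_ensemble():
    """Uniform basin sampling carrying a reweight-to-target bias."""
    spec = SyntheticEnsembleSpec(populations=(0.6, 0.3, 0.1), n_frames=800,
                                 noise_sigma=0.02, seed=43,
                                 bias_mode="reweight-to-target")
    ensemble, labels = generate_multibasin_ensemble(spec)
    return spec, ensemble, labels
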