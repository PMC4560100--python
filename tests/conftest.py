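"""Shared fixtures: toy transporters and hand-written PDB snippets."""

from __future__ import annotations

import numpy as np
import pytest

from swapsmith.builder import run_repeat_swap
from swapsmith.synthetic import ToySpec, make_toy_transporter

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""

# residues A10, A10 with insertion code A, A11 — three distinct residues
ICODE_PDB = """\
ATOM      1  CA  ALA A  10       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A  10A      3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  SER A  11       7.600   0.000   0.000  1.00  0.00           C
END
"""

# one CA with two alternate locations (B has the higher occupancy) plus a
# tied-occupancy pair on residue 2 (alphabetical tiebreak -> A)
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA AALA A   2       5.000   0.000   0.000  0.50  0.00           C
ATOM      4  CA BALA A   2       6.000   0.000   0.000  0.50  0.00           C
END
"""

HETATM_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2 NA    NA A 500      10.000   0.000   0.000  1.00  0.00          NA
HETATM    3  O   HOH A 600       1.000   2.000   3.000  1.00  0.00           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      4  CA  ALA A   1       0.000   0.000   9.000  1.00  0.00           C
ATOM      5  CA  ALA A   2       3.800   0.000   9.000  1.00  0.00           C
ATOM      6  CA  ALA A   3       7.600   0.000   9.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    """Factory: write PDB text to a temp file and return its path."""

    def write(text: str, name: str = "input.pdb"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write


@pytest.fixture(scope="session")
def toy_default():
    """Default-condition toy (20° swing, 5 Å shift, 0.1 Å jitter)."""
    return make_toy_transporter(ToySpec(seed=0))


@pytest.fixture(scope="session")
def toy_clean():
    """Noise-free toy without peripherals: exact-geometry checks."""
    return make_toy_transporter(
        ToySpec(noise_A=0.0, peripheral_helices=0, seed=0)
    )


@pytest.fixture(scope="session")
def toy_symmetric():
    """Perfectly symmetric noise-free toy (no asymmetry at all)."""
    return make_toy_transporter(
        ToySpec(
            asymmetry_angle_deg=0.0,
            asymmetry_shift_A=0.0,
            noise_A=0.0,
            peripheral_helices=0,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def toy_pipeline(toy_default):
    """Full repeat-swap pipeline result on the default toy (run once)."""
    toy, truth = toy_default
    return toy, truth, run_repeat_swap(toy, truth.repeat_def)


def ca_rmsd_by_key(a, b, ranges=None):
    """RMSD over Cα atoms paired by residue key (optionally range-limited)."""
    bca = {r.key: r.ca.coords for r in b.residues if r.ca is not None}
    diffs = []
    for r in a.residues:
        if r.ca is None or r.key not in bca:
            continue
        if ranges is not None and not ranges.contains(r.chain_id, r.res_seq):
            continue
        diffs.append(r.ca.coords - bca[r.key])
    return float(np.sqrt((np.asarray(diffs) ** 2).sum(axis=1).mean()))
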