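"""Published repeat/domain definitions for the calibration transporters.

Residue ranges are author numbering, as published with the respective
structures:

* **Glt_Ph** (aspartate/glutamate transporter homolog, PDB 3KBC inward /
  1XFH outward, trimer — analyses use one protomer, chain A by default):
  RU1 = 12–108 + 335–416, RU2 = 150–334; helices TM4a/4b (109–149) are
  peripheral.  Scaffold/oligomerization = 12–77 + 129–218; transport =
  78–128 + 219–416.  Ligand restraints: the two Na⁺ ions and any aspartate
  heavy atom to any protein heavy atom within 5 Å.
* **VcCNT** (concentrative nucleoside transporter, PDB 3TIJ inward):
  RU1 = 119–229, RU2 = 294–416.  Scaffold = 2–137 + 241–311; transport =
  138–229 + 312–416.  Ligand restraints: uridine heavy atoms to protein
  heavy atoms within 3.5 Å, plus the Na⁺ coordinated by the backbone O of
  N149, V152 and I184, the hydroxyl O (OG) of S183, and a crystallographic
  water — named pairs applied regardless of distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from swapsmith.repeats import RepeatDefinition
from swapsmith.restraints import DomainDefinition
from swapsmith.structure import ProteinStructure, ResidueRangeSet

__all__ = ["TransporterPreset", "GLTPH", "VCCNT", "vccnt_sodium_named_pairs", "PRESETS"]


@dataclass(frozen=True)
class TransporterPreset:
    """Repeat/domain ranges plus ligand selections for one transporter."""

    name: str
    pdb_template: str
    repeat_def: RepeatDefinition
    domain_def: DomainDefinition
    ligand_names: tuple[str, ...] = ()
    ligand_cutoff: float = 5.0
    chain: str = "A"
    notes: str = ""


def _rr(text: str, chain: str = "A") -> ResidueRangeSet:
    return ResidueRangeSet.from_string(text, default_chain=chain)


GLTPH = TransporterPreset(
    name="GltPh",
    pdb_template="3KBC",
    repeat_def=RepeatDefinition(
        ru1=_rr("12-108,335-416"),
        ru2=_rr("150-334"),
        peripheral=_rr("109-149"),
    ),
    domain_def=DomainDefinition(
        scaffold=_rr("12-77,129-218"),
        transport=_rr("78-128,219-416"),
    ),
    ligand_names=("NA", "ASP"),
    ligand_cutoff=5.0,
    notes=(
        "Inward-occluded template 3KBC; outward comparison structure 1XFH. "
        "The bound aspartate substrate appears as HETATM residue ASP."
    ),
)

VCCNT = TransporterPreset(
    name="VcCNT",
    pdb_template="3TIJ",
    repeat_def=RepeatDefinition(
        ru1=_rr("119-229"),
        ru2=_rr("294-416"),
    ),
    domain_def=DomainDefinition(
        scaffold=_rr("2-137,241-311"),
        transport=_rr("138-229,312-416"),
    ),
    ligand_names=("URI", "NA"),
    ligand_cutoff=3.5,
    notes="Inward-facing template 3TIJ; uridine substrate plus one Na+.",
)

PRESETS: dict[str, TransporterPreset] = {"gltph": GLTPH, "vccnt": VCCNT}

# Na+ coordination shell in VcCNT: backbone carbonyl O of N149/V152/I184,
# the S183 hydroxyl O, and a crystallographic water O
VCCNT_NA_PARTNERS: tuple[tuple[int, str], ...] = (
    (149, "O"),
    (152, "O"),
    (184, "O"),
    (183, "OG"),
)


def vccnt_sodium_named_pairs(
    s: ProteinStructure,
    chain: str = "A",
    water_cutoff: float = 4.0,
):
    """Explicit Na⁺ coordination pairs for VcCNT-style restraints.

    Resolves the published partner atoms on the given structure and adds
    the nearest crystallographic water O within ``water_cutoff`` Å of the
    Na⁺.  Returns a ``named_pairs`` list for
    :func:`swapsmith.restraints.ligand_restraints`.
    """
    import numpy as np

    na = None
    for r in s.residues:
        if r.name == "NA" and r.chain_id == chain:
            na = r
            break
    if na is None:
        raise ValueError(f"no Na+ (het-name NA) found on chain {chain}")
    na_atom = na.atoms[0]
    pairs = []
    for res_seq, atom_name in VCCNT_NA_PARTNERS:
        pairs.append(
            ((chain, na.res_seq, na_atom.name), (chain, res_seq, atom_name))
        )
    best = None
    best_d = water_cutoff
    for r in s.residues:
        if not r.is_water:
            continue
        o = r.atom("O")
        if o is None:
            continue
        d = float(np.linalg.norm(o.coords - na_atom.coords))
        if d < best_d:
            best, best_d = r, d
    if best is not None:
        pairs.append(((chain, na.res_seq, na_atom.name), (best.chain_id, best.res_seq, "O")))
    return pairs
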