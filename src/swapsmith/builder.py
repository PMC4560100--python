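"""Naive swapped-model building and Modeller-ready input bundles.

Restraint-based comparative modeling is performed by external software
(Modeller); this module emits a complete, self-consistent input bundle for
it.  For dependency-free testing of the whole protocol — and for a quick
first look at the predicted conformation — a naive coordinate-transfer
builder is provided: each target residue inherits its aligned template
residue's backbone coordinates.  The naive builder is *not* a substitute
for restraint-based modeling; it exists so the pipeline and the motion
analysis are fully testable without external binaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from swapsmith.alignio import PirEntry, read_pir, write_pir
from swapsmith.geometry import superpose
from swapsmith.repeats import (
    RepeatDefinition,
    SwapAlignment,
    SwappedTemplate,
    align_repeats,
    assemble_swapped_template,
    build_swap_alignment,
)
from swapsmith.restraints import RestraintSet
from swapsmith.structure import (
    AtomRecord,
    ProteinStructure,
    Residue,
    ResidueRangeSet,
    read_pdb,
    select_residues,
    write_pdb,
)

__all__ = [
    "ModelingConfig",
    "build_naive_model",
    "emit_modeling_inputs",
    "validate_bundle",
    "restraint_violation_score",
    "run_repeat_swap",
    "RepeatSwapResult",
]

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class ModelingConfig:
    """Iteration counts and options for the emitted Modeller run.

    200 model-building iterations suffice for alignment-refinement rounds;
    the restrained stages use 2000 iterations so that sampling has a chance
    to satisfy every input restraint simultaneously.
    """

    n_models_initial: int = 200
    n_models_restrained: int = 2000
    include_ligands: bool = False
    random_seed: int = -8123  # Modeller convention: negative seed

    def __post_init__(self) -> None:
        if self.n_models_initial < 1 or self.n_models_restrained < 1:
            raise ValueError("model counts must be >= 1")


def build_naive_model(
    template: SwappedTemplate,
    aln: SwapAlignment,
) -> ProteinStructure:
    """Coordinate-transfer model: aligned targets inherit template backbones.

    Every aligned target residue receives the backbone (N, CA, C, O, and Cβ
    when present) coordinates of its template counterpart.  Unaligned
    target residues (linkers, gap regions) get a Cα placed by linear
    interpolation between the flanking aligned anchors and are marked
    low-confidence with occupancy 0.0.  Deterministic by construction.
    """
    tpl_by_key = {r.key: r for r in template.structure.residues}
    # consistency: every template residue referenced by the alignment must
    # exist in the template structure with a matching residue letter
    for col_idx, (t_key, s_key) in enumerate(aln.columns):
        if s_key is None:
            continue
        if s_key not in tpl_by_key:
            raise ValueError(
                f"alignment/template mismatch at column {col_idx}: "
                f"template residue {s_key} absent from the swapped template"
            )
        letter = aln.letters.get(s_key, "X")
        actual = tpl_by_key[s_key].one_letter()
        if letter != "X" and actual != "X" and letter != actual:
            raise ValueError(
                f"alignment/template mismatch at column {col_idx}: "
                f"alignment says {letter!r}, template has {actual!r} at {s_key}"
            )

    target_keys = aln.target_order()
    pair_map = dict(aln.pairs())
    placed: dict = {}
    model_residues: list[Residue | None] = []
    for t_key in target_keys:
        s_key = pair_map.get(t_key)
        chain, res_seq, i_code = t_key
        res_name = THREE_LETTER.get(aln.letters.get(t_key, "X"), "UNK")
        if s_key is None:
            model_residues.append(None)  # interpolate later
            continue
        tpl_res = tpl_by_key[s_key]
        atoms = []
        serial = 0
        for name in BACKBONE_ATOMS:
            a = tpl_res.atom(name)
            if a is None:
                continue
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, altloc="", res_name=res_name,
                    chain_id=chain, res_seq=res_seq, i_code=i_code,
                    x=a.x, y=a.y, z=a.z, occupancy=1.0, element=a.element,
                )
            )
        if not atoms:
            raise ValueError(f"template residue {s_key} has no backbone atoms")
        res = Residue(chain, res_seq, i_code, res_name, atoms)
        placed[t_key] = res
        model_residues.append(res)

    # interpolate unaligned stretches between flanking anchors
    n = len(target_keys)
    anchor_ca = [
        placed[k].ca.coords if k in placed and placed[k].ca is not None else None
        for k in target_keys
    ]
    for i in range(n):
        if model_residues[i] is not None:
            continue
        left = right = None
        for k in range(i - 1, -1, -1):
            if anchor_ca[k] is not None:
                left = k
                break
        for k in range(i + 1, n):
            if anchor_ca[k] is not None:
                right = k
                break
        if left is not None and right is not None:
            frac = (i - left) / (right - left)
            pos = anchor_ca[left] * (1 - frac) + anchor_ca[right] * frac
        elif left is not None:
            pos = anchor_ca[left] + 3.8 * (i - left) * np.array([1.0, 0.0, 0.0])
        elif right is not None:
            pos = anchor_ca[right] - 3.8 * (right - i) * np.array([1.0, 0.0, 0.0])
        else:
            raise ValueError("no aligned residues: cannot place any coordinates")
        chain, res_seq, i_code = target_keys[i]
        res_name = THREE_LETTER.get(aln.letters.get(target_keys[i], "X"), "UNK")
        model_residues[i] = Residue(
            chain, res_seq, i_code, res_name,
            [
                AtomRecord(
                    serial=1, name="CA", altloc="", res_name=res_name,
                    chain_id=chain, res_seq=res_seq, i_code=i_code,
                    x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
                    occupancy=0.0, element="C",
                )
            ],
        )
    return ProteinStructure(
        [r for r in model_residues if r is not None],
        title="naive repeat-swap model",
        provenance="build_naive_model",
    )


# ---------------------------------------------------------------------------
# Modeller bundle


def emit_modeling_inputs(
    template: SwappedTemplate,
    aln: SwapAlignment,
    restraints: RestraintSet,
    cfg: ModelingConfig,
    outdir: str | Path,
    target_code: str = "target",
    template_code: str = "swapped_template",
) -> dict[str, Path]:
    """Write a self-consistent Modeller input bundle into ``outdir``.

    Files: the renumbered swapped-template PDB, the PIR alignment
    (structureX entry for the template, sequence entry for the target), a
    restraint stanza with one Gaussian distance restraint per line, a
    driver script parameterized by ``cfg``, and a README.  Restraints are
    re-addressed from template numbering to the renumbered template file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tpl_path = outdir / f"{template_code}.pdb"
    write_pdb(template.structure, tpl_path, renumber_from=1)
    paths["template_pdb"] = tpl_path

    n_tpl = len(template.structure)
    chain = template.structure.residues[0].chain_id if n_tpl else "A"
    pir_path = outdir / "alignment.pir"
    write_pir(
        [
            PirEntry(
                code=template_code, kind="structureX",
                gapped_seq=aln.template_gapped,
                source_file=tpl_path.name, begin="1", end=str(n_tpl), chain=chain,
            ),
            PirEntry(code=target_code, kind="sequence", gapped_seq=aln.target_gapped),
        ],
        pir_path,
    )
    paths["alignment_pir"] = pir_path

    tsv_path = outdir / "restraints.tsv"
    restraints.to_tsv(tsv_path)
    paths["restraints_tsv"] = tsv_path

    # one rsr.add(...) line per restraint, addressed CA:<resnum>:<chain> on
    # the renumbered template/model numbering
    stanza_lines = []
    for r in restraints:
        a = f"{r.atom_a[2]}:{r.atom_a[1]}:{r.atom_a[0]}"
        b = f"{r.atom_b[2]}:{r.atom_b[1]}:{r.atom_b[0]}"
        stanza_lines.append(
            "rsr.add(forms.gaussian(group=physical.xy_distance, "
            f"feature=features.distance(at['{a}'], at['{b}']), "
            f"mean={r.target:.4f}, stdev={r.sigma:.4f}))"
        )
    stanza_path = outdir / "special_restraints.py"
    stanza_path.write_text("\n".join(stanza_lines) + ("\n" if stanza_lines else ""))
    paths["restraint_stanza"] = stanza_path

    driver = f"""# Modeller driver skeleton (requires Modeller v9+, not bundled)
from modeller import *
from modeller.automodel import *

env = Environ(rand_seed={cfg.random_seed})
env.io.hetatm = {cfg.include_ligands}


class RepeatSwapModel(AutoModel):
    def special_restraints(self, aln):
        rsr = self.restraints
        at = self.atoms
        exec(open('special_restraints.py').read())


a = RepeatSwapModel(
    env,
    alnfile='alignment.pir',
    knowns='{template_code}',
    sequence='{target_code}',
)
a.starting_model = 1
# initial alignment-refinement rounds: {cfg.n_models_initial} models
a.ending_model = {cfg.n_models_restrained}
a.make()
"""
    driver_path = outdir / "run_modeller.py"
    driver_path.write_text(driver)
    paths["driver"] = driver_path

    readme = (
        "Repeat-swap modeling input bundle\n"
        "=================================\n"
        f"Template: {tpl_path.name} (swapped repeat order, renumbered from 1)\n"
        f"Alignment: {pir_path.name} (PIR; structureX=template, sequence=target)\n"
        f"Restraints: {tsv_path.name} / {stanza_path.name} "
        f"({len(restraints)} Gaussian distance restraints)\n"
        f"Driver: {driver_path.name} "
        f"({cfg.n_models_restrained} restrained model-building iterations)\n\n"
        "Assess models with MolPDF (restraint satisfaction), ProQM\n"
        "(membrane-protein quality) and Procheck (stereochemistry); pick the\n"
        "lowest MolPDF and/or highest ProQM/Procheck model.\n"
    )
    readme_path = outdir / "README.txt"
    readme_path.write_text(readme)
    paths["readme"] = readme_path
    return paths


def validate_bundle(outdir: str | Path) -> list[str]:
    """Re-read an emitted bundle and check cross-consistency.

    Returns a list of problems (empty = bundle is self-consistent).
    """
    outdir = Path(outdir)
    problems: list[str] = []
    pir_path = outdir / "alignment.pir"
    entries = read_pir(pir_path)
    by_kind = {e.kind: e for e in entries}
    if "structureX" not in by_kind or "sequence" not in by_kind:
        problems.append("alignment.pir must contain structureX and sequence entries")
        return problems
    tpl_entry = by_kind["structureX"]
    if len(tpl_entry.gapped_seq) != len(by_kind["sequence"].gapped_seq):
        problems.append("PIR entries differ in gapped length")
    tpl_pdb = outdir / tpl_entry.source_file
    if not tpl_pdb.exists():
        problems.append(f"template file {tpl_entry.source_file} missing")
    else:
        tpl = read_pdb(tpl_pdb)
        tpl_seq = tpl.sequence()
        degapped = tpl_entry.gapped_seq.replace("-", "")
        if tpl_seq != degapped:
            problems.append(
                f"template PIR sequence ({len(degapped)} aa) does not match "
                f"template PDB ({len(tpl_seq)} aa)"
            )
    tsv = outdir / "restraints.tsv"
    stanza = outdir / "special_restraints.py"
    if tsv.exists() and stanza.exists():
        import pandas as pd

        n_tsv = len(pd.read_csv(tsv, sep="\t"))
        n_stanza = len([l for l in stanza.read_text().splitlines() if l.strip()])
        if n_tsv != n_stanza:
            problems.append(f"restraint counts differ: TSV {n_tsv} vs stanza {n_stanza}")
    return problems


def restraint_violation_score(s: ProteinStructure, restraints: RestraintSet) -> float:
    """Sum of squared z-scores ``((d_obs − target)/σ)²`` over resolvable restraints.

    A crude internal ranking aid for candidate models; it is not a model
    quality score in the MolPDF/ProQM/Procheck sense.
    """
    lookup = {}
    for r in s.residues:
        for a in r.atoms:
            lookup[(r.chain_id, r.res_seq, a.name)] = a.coords
    total = 0.0
    for r in restraints:
        pa = lookup.get(r.atom_a)
        pb = lookup.get(r.atom_b)
        if pa is None or pb is None:
            continue
        d = float(np.linalg.norm(pa - pb))
        total += ((d - r.target) / r.sigma) ** 2
    return total


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class RepeatSwapResult:
    """Everything the repeat-swap pipeline produced for one input structure."""

    pair_alignment: object
    repeat_tm: float
    swap_alignment: SwapAlignment
    template: SwappedTemplate
    model: ProteinStructure
    oriented_model: ProteinStructure
    metadata: dict = field(default_factory=dict)


def run_repeat_swap(
    structure: ProteinStructure,
    rep: RepeatDefinition,
    ss: dict | None = None,
    refine: bool = True,
) -> RepeatSwapResult:
    """Run the full naive repeat-swap pipeline on one structure.

    Stages: structurally align RU1 to RU2, duplicate the alignment into the
    full-length swap alignment, refine it by relocating gaps out of
    template helices (``ss`` maps residue keys to secondary-structure
    characters; default: the Cα-geometry helix assigner), assemble the
    swapped template (building a peripheral-free initial model first when
    peripheral segments need reorienting), build the naive
    coordinate-transfer model, and orient the model by superposing it onto
    the input structure — the convention for placing models in the
    membrane frame of the input.
    """
    from swapsmith.repeats import assign_ss_ca, refine_alignment

    ru1 = select_residues(structure, rep.ru1)
    ru2 = select_residues(structure, rep.ru2)
    pair_aln, _, repeat_tm = align_repeats(ru1, ru2)
    aln = build_swap_alignment(structure, rep, pair_aln)
    if refine:
        if ss is None:
            ca_res = structure.polymer().ca_residues()
            ss_str = assign_ss_ca(structure.polymer())
            ss = {r.key: c for r, c in zip(ca_res, ss_str)}
        ss_template = "".join(ss.get(k, "-") for k in aln.template_order())
        aln = refine_alignment(aln, ss_template)
    if rep.peripheral.ranges:
        rep0 = RepeatDefinition(rep.ru1, rep.ru2, ResidueRangeSet(()))
        aln0 = build_swap_alignment(structure, rep0, pair_aln)
        tpl0 = assemble_swapped_template(structure, rep0, aln=aln0)
        model0 = build_naive_model(tpl0, aln0)
        template = assemble_swapped_template(
            structure, rep, initial_model=model0, aln=aln
        )
    else:
        template = assemble_swapped_template(structure, rep, aln=aln)
    model = build_naive_model(template, aln)

    # orient: superpose the model onto the input structure over all shared
    # full-occupancy Cα (the repeat-swap model is "upside-down" otherwise)
    ref_ca = {r.key: r.ca for r in structure.residues if r.ca is not None}
    mob = []
    ref = []
    for r in model.residues:
        if r.ca is not None and r.ca.occupancy > 0 and r.key in ref_ca:
            mob.append(r.ca.coords)
            ref.append(ref_ca[r.key].coords)
    tf, _ = superpose(np.vstack(mob), np.vstack(ref))
    oriented = model.transformed(tf.rotation, tf.translation)
    oriented.title = model.title + " (oriented)"
    return RepeatSwapResult(
        pair_alignment=pair_aln,
        repeat_tm=repeat_tm,
        swap_alignment=aln,
        template=template,
        model=model,
        oriented_model=oriented,
        metadata={"n_template_residues": len(template.structure)},
    )
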