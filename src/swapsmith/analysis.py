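"""Quantifying the conformational change between two conformers.

Given a model (or second crystal structure) and a reference conformer of
the same protein, the analysis superposes the pair on the scaffold domain,
fits the residual rigid-body transform of the transport domain, decomposes
it into rotation axis/angle and membrane-frame translation, and profiles
per-residue Cα displacements.  For an elevator-type transporter the
signature result is a large rotation about an axis lying in the membrane
plane combined with a translation along the membrane normal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from swapsmith.geometry import (
    MembraneFrame,
    MotionDecomposition,
    decompose,
    displacement_profile,
    superpose,
    tm_score,
)
from swapsmith.restraints import DomainDefinition
from swapsmith.structure import ProteinStructure, ResidueRangeSet

__all__ = [
    "ConfChangeReport",
    "analyze_change",
    "plot_displacement_profile",
    "membrane_frame_from_trimer",
]


def membrane_frame_from_trimer(
    structure: ProteinStructure,
    chains: tuple[str, str] = ("A", "B"),
) -> MembraneFrame:
    """Estimate the membrane frame of a trimeric transporter.

    For homotrimers such as glutamate-transporter homologs and
    concentrative nucleoside transporters the membrane normal coincides
    with the trimer's three-fold axis.  Superposing one protomer onto the
    next (residues paired by author numbering) yields a ~120° rotation
    whose axis is that three-fold axis; deposited coordinates are thereby
    analyzable without external membrane-positioning services.  Structures
    already OPM-oriented can simply use the default ``MembraneFrame()``.
    """
    ca = {(r.chain_id, r.res_seq): r.ca for r in structure.residues if r.ca is not None}
    a, b = chains
    shared = sorted(
        n for c, n in ca if c == a and (b, n) in ca
    )
    if len(shared) < 3:
        raise ValueError(f"chains {a} and {b} share fewer than 3 Cα residues")
    mob = np.vstack([ca[(a, n)].coords for n in shared])
    ref = np.vstack([ca[(b, n)].coords for n in shared])
    tf, _ = superpose(mob, ref)
    motion = decompose(tf)
    normal = motion.axis
    if normal[2] < 0:
        normal = -normal
    origin = structure.ca_coords().mean(axis=0)
    return MembraneFrame(normal=normal, origin=origin)


@dataclass
class ConfChangeReport:
    """Rotation/translation of the transport domain plus similarity metrics.

    ``scaffold_rmsd``/``transport_rmsd`` are each domain's own least-squares
    superposition RMSD (the length-dependent counterpart of the TM-scores);
    the motion decomposition describes the transport domain's residual
    rigid-body transform after the scaffold superposition, expressed in the
    reference structure's membrane frame.
    """

    motion: MotionDecomposition
    scaffold_rmsd: float
    transport_rmsd: float
    scaffold_tm: float
    transport_tm: float
    displacement: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scaffold_rmsd < 0 or self.transport_rmsd < 0:
            raise ValueError("RMSD must be non-negative")
        for tm in (self.scaffold_tm, self.transport_tm):
            if not 0 < tm <= 1:
                raise ValueError(f"TM-score {tm} outside (0, 1]")

    def to_dict(self) -> dict:
        return {
            "motion": self.motion.as_dict(),
            "scaffold_rmsd_A": self.scaffold_rmsd,
            "transport_rmsd_A": self.transport_rmsd,
            "scaffold_tm": self.scaffold_tm,
            "transport_tm": self.transport_tm,
            "displacement_range_A": [
                float(self.displacement.displacement_A.min()),
                float(self.displacement.displacement_A.max()),
            ],
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def displacement_to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.displacement.to_csv(path, sep="\t", index=False, float_format="%.3f")
        return path

    def summary(self) -> str:
        d = self.motion.centroid_displacement
        return (
            "Conformational change (transport domain vs scaffold)\n"
            f"  rotation:            {self.motion.angle_deg:7.1f} deg\n"
            f"  axis vs membrane:    {self.motion.axis_membrane_angle_deg:7.1f} deg\n"
            f"  displacement (x,y,z): ({d[0]:.1f}, {d[1]:.1f}, {d[2]:.1f}) A\n"
            f"  scaffold  RMSD {self.scaffold_rmsd:5.2f} A   TM-score {self.scaffold_tm:.2f}\n"
            f"  transport RMSD {self.transport_rmsd:5.2f} A   TM-score {self.transport_tm:.2f}\n"
        )


def _domain_cas(
    model: ProteinStructure,
    reference: ProteinStructure,
    ranges: ResidueRangeSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired Cα coordinates over shared residues of one domain."""
    ref_ca = {r.key: r.ca for r in reference.residues if r.ca is not None}
    mob, ref = [], []
    for r in model.residues:
        if r.ca is None or r.key not in ref_ca:
            continue
        if ranges.contains(r.chain_id, r.res_seq):
            mob.append(r.ca.coords)
            ref.append(ref_ca[r.key].coords)
    if len(mob) < 3:
        raise ValueError(
            f"fewer than 3 shared Cα residues in domain {ranges}"
        )
    return np.vstack(mob), np.vstack(ref)


def analyze_change(
    model: ProteinStructure,
    reference: ProteinStructure,
    dom: DomainDefinition,
    frame: MembraneFrame | None = None,
    fit_ranges: ResidueRangeSet | None = None,
) -> ConfChangeReport:
    """Quantify the model→reference conformational change.

    Steps: (1) superpose the model onto the reference using the scaffold
    Cα (or ``fit_ranges``, e.g. only the oligomerization-interface
    helices); (2) least-squares fit of the scaffold-fitted transport domain
    onto the reference transport domain, giving the residual rigid-body
    transform; (3) decomposition of that transform into axis/angle and
    membrane-frame centroid displacement; (4) per-domain RMSD and TM-score;
    (5) a per-residue Cα displacement profile after the scaffold fit.

    Residues are paired by author numbering (same protein in two
    conformations); for model-vs-structure comparisons with offset
    numbering, renumber first (``write_pdb(..., renumber_from=...)``).
    """
    frame = frame or MembraneFrame()
    fit = fit_ranges or dom.scaffold

    fit_mob, fit_ref = _domain_cas(model, reference, fit)
    tf_scaffold, _ = superpose(fit_mob, fit_ref)
    fitted = model.transformed(tf_scaffold.rotation, tf_scaffold.translation)

    sc_mob, sc_ref = _domain_cas(fitted, reference, dom.scaffold)
    _, scaffold_rmsd = superpose(sc_mob, sc_ref)
    tr_mob, tr_ref = _domain_cas(fitted, reference, dom.transport)
    tf_transport, transport_rmsd = superpose(tr_mob, tr_ref)

    centroid = tr_mob.mean(axis=0)
    motion = decompose(tf_transport, frame, centroid)

    scaffold_tm = tm_score(sc_mob, sc_ref)
    transport_tm = tm_score(tr_mob, tr_ref)
    profile = displacement_profile(model, reference, fit)

    return ConfChangeReport(
        motion=motion,
        scaffold_rmsd=scaffold_rmsd,
        transport_rmsd=transport_rmsd,
        scaffold_tm=scaffold_tm,
        transport_tm=transport_tm,
        displacement=profile,
        metadata={
            "model": model.title,
            "reference": reference.title,
            "fit_ranges": str(fit),
            "scaffold": str(dom.scaffold),
            "transport": str(dom.transport),
            "frame_normal": frame.normal.tolist(),
            "n_scaffold_pairs": int(len(sc_mob)),
            "n_transport_pairs": int(len(tr_mob)),
        },
    )


def plot_displacement_profile(
    report: ConfChangeReport,
    dom: DomainDefinition | None = None,
    ax=None,
):
    """Per-residue displacement along the sequence (transport shaded)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    df = report.displacement
    ax.plot(df.res_seq, df.displacement_A, color="black", lw=1)
    if dom is not None:
        for chain, start, end in dom.transport.ranges:
            ax.axvspan(start, end, color="orange", alpha=0.2)
    ax.set_xlabel("residue")
    ax.set_ylabel(r"C$\alpha$ displacement ($\AA$)")
    return ax
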