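"""Toy inverted-repeat "transporter" structures with known ground truth.

The generator builds a Cα-trace poly-alanine protein from ideal α-helices
(1.5 Å rise, 100° twist per residue) arranged as two repeat units: RU2 is
RU1 mapped through an exact 180° rotation about an axis lying in the
membrane plane — the inverted-topology relationship.  A designated
"transport" sub-repeat of RU2 is then swung by a chosen angle about an
in-plane axis and shifted along the membrane normal, creating the
conformational asymmetry of (say) an inward-open state.  The ground truth
records the symmetry operation, the true RU1↔RU2 residue correspondence,
the asymmetry parameters, and — crucially — the exact swapped-conformation
structure, in which RU1 adopts RU2's conformation and vice versa.  That
swapped structure is what a repeat-swap pipeline should reconstruct, so
every stage of the protocol is testable without downloading anything.

What the toys do *not* emulate: side chains, sequence divergence between
repeats (both repeats are poly-alanine with identical geometry), loops
with realistic geometry, and crystallographic artifacts.  Coordinate
jitter (``noise_A``) stands in for coordinate uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from swapsmith.geometry import (
    MembraneFrame,
    MotionDecomposition,
    RigidTransform,
    compose,
    decompose,
    superpose,
)
from swapsmith.repeats import RepeatDefinition
from swapsmith.restraints import DomainDefinition
from swapsmith.structure import AtomRecord, ProteinStructure, Residue, ResidueRangeSet

__all__ = ["ToySpec", "ToyGroundTruth", "make_toy_transporter", "make_swapped_truth"]

HELIX_RISE = 1.5  # Å per residue along the helix axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å, Cα radius of an ideal α-helix
HELIX_SPACING = 9.0  # Å between adjacent helix axes
ROW_OFFSET = 6.0  # Å, distance of each repeat's helix row from the symmetry axis
LINKER_LEN = 3  # residues in straight-line connectors
HELIX_BEND_RADIUS = 45.0  # Å; gentle arc, like the bent TM helices of real transporters


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one toy transporter.

    The defaults are the conditions used throughout the test-bed: four
    helices per repeat (half scaffold, half transport), a 20° swing with a
    5 Å membrane-normal shift for the asymmetry, one peripheral helix, and
    0.1 Å coordinate jitter.
    """

    helices_per_repeat: int = 4
    helix_length: int = 12
    asymmetry_angle_deg: float = 20.0
    asymmetry_shift_A: float = 5.0
    peripheral_helices: int = 1
    noise_A: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helices_per_repeat < 2:
            raise ValueError("need at least 2 helices per repeat")
        if self.helix_length < 4:
            raise ValueError("helices shorter than 4 residues are not helices")
        for name in ("asymmetry_angle_deg", "asymmetry_shift_A", "noise_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.peripheral_helices < 0:
            raise ValueError("peripheral_helices must be >= 0")


@dataclass
class ToyGroundTruth:
    """Generator bookkeeping: everything a test needs to verify the pipeline."""

    spec: ToySpec
    symmetry_op: RigidTransform  # exact 180° rotation mapping RU1 onto RU2
    correspondence: list[tuple[tuple, tuple]]  # (RU1 key, RU2 key) pairs
    repeat_def: RepeatDefinition
    domain_def: DomainDefinition
    frame: MembraneFrame
    asymmetry: RigidTransform  # the swing applied to RU2's transport sub-repeat
    transport_motion: RigidTransform  # exact Kabsch fit, original → swapped truth
    motion: MotionDecomposition  # decomposition of transport_motion
    swapped_structure: ProteinStructure = None  # noisy swapped-truth conformer
    _noiseless: ProteinStructure = None
    _noiseless_swapped: ProteinStructure = None


def _ideal_helix(length: int, bend_phase_deg: float = 0.0) -> np.ndarray:
    """Cα trace of an α-helix along +z, centered on z = 0, gently bent.

    The bend (constant curvature, radius ``HELIX_BEND_RADIUS``, plane set by
    ``bend_phase_deg``) mimics the curvature of real transmembrane helices
    and makes helix fragments register-distinctive: a straight ideal helix
    is nearly invariant under a one-turn screw shift, which would make
    structural alignment of repeats ambiguous in a way real helices are not.
    """
    i = np.arange(length)
    phi = np.deg2rad(HELIX_TWIST * i)
    z = HELIX_RISE * i
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(phi), HELIX_RADIUS * np.sin(phi), z]
    )
    # bend about an axis parallel to y at x = R: x' = R - (R - x) cos a,
    # z' = (R - x) sin a with a = z / R
    rc = HELIX_BEND_RADIUS
    a = coords[:, 2] / rc
    x, y, z = coords.T
    bent = np.column_stack([rc - (rc - x) * np.cos(a), y, (rc - x) * np.sin(a)])
    # rotate the bend plane so different helices curve in different directions
    th = np.deg2rad(bend_phase_deg)
    rot = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    bent = bent @ rot.T
    bent -= bent.mean(axis=0)
    return bent


def _flip_down(coords: np.ndarray) -> np.ndarray:
    """Rotate a helix 180° about its local x-axis (runs downward)."""
    return coords * np.array([1.0, -1.0, -1.0])


def _linker(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    frac = (np.arange(n) + 1) / (n + 1)
    return a[None, :] * (1 - frac)[:, None] + b[None, :] * frac[:, None]


def _repeat_unit_coords(spec: ToySpec) -> tuple[np.ndarray, np.ndarray]:
    """RU1 Cα coordinates and a boolean mask marking transport residues.

    Helices alternate up/down (transmembrane topology); the last
    ⌈H/2⌉ helices form the transport sub-repeat.  Linker residues between
    two transport helices count as transport; boundary linkers count as
    neither (they are excluded from the domain ranges).
    """
    h = spec.helices_per_repeat
    n_transport_helices = (h + 1) // 2
    first_transport = h - n_transport_helices
    coords: list[np.ndarray] = []
    labels: list[str] = []  # per-residue: scaffold / transport / boundary
    prev_end = None
    for k in range(h):
        helix = _ideal_helix(spec.helix_length, bend_phase_deg=73.0 * k)
        if k % 2 == 1:
            helix = _flip_down(helix)
        helix = helix + np.array([HELIX_SPACING * k, ROW_OFFSET, 0.0])
        role = "transport" if k >= first_transport else "scaffold"
        if prev_end is not None:
            link = _linker(prev_end, helix[0], LINKER_LEN)
            if k > first_transport:
                link_role = "transport"
            elif k == first_transport:
                link_role = "boundary"
            else:
                link_role = "scaffold"
            coords.append(link)
            labels.extend([link_role] * LINKER_LEN)
        coords.append(helix)
        labels.extend([role] * spec.helix_length)
        prev_end = helix[-1]
    all_coords = np.vstack(coords)
    transport_mask = np.array([lab == "transport" for lab in labels])
    scaffold_mask = np.array([lab == "scaffold" for lab in labels])
    return all_coords, np.where(transport_mask, 1, np.where(scaffold_mask, 0, -1))


def _peripheral_coords(spec: ToySpec) -> np.ndarray:
    coords: list[np.ndarray] = []
    prev_end = None
    for p in range(spec.peripheral_helices):
        helix = _ideal_helix(spec.helix_length, bend_phase_deg=73.0 * (p + 11))
        if p % 2 == 1:
            helix = _flip_down(helix)
        helix = helix + np.array([-HELIX_SPACING * (p + 1), 0.0, 0.0])
        if prev_end is not None:
            coords.append(_linker(prev_end, helix[0], LINKER_LEN))
        coords.append(helix)
        prev_end = helix[-1]
    return np.vstack(coords) if coords else np.empty((0, 3))


def _structure_from_coords(coords: np.ndarray, title: str) -> ProteinStructure:
    residues = []
    for i, (x, y, z) in enumerate(coords, start=1):
        residues.append(
            Residue(
                "A", i, "", "ALA",
                [
                    AtomRecord(
                        serial=i, name="CA", altloc="", res_name="ALA",
                        chain_id="A", res_seq=i, i_code="",
                        x=float(x), y=float(y), z=float(z),
                        occupancy=1.0, element="C",
                    )
                ],
            )
        )
    return ProteinStructure(residues, title=title, provenance="synthetic")


def make_toy_transporter(spec: ToySpec) -> tuple[ProteinStructure, ToyGroundTruth]:
    """Build a toy transporter and its ground truth.

    Layout in sequence order: RU1 block, peripheral block (if any), RU2
    block, with 3-residue straight linkers between blocks.  RU2 is the
    exact image of RU1 under a 180° rotation about the x-axis (which lies
    in the membrane plane; the membrane normal is z).  The asymmetry swing
    is applied to RU2's transport range; the swapped-truth conformer
    carries the conjugate swing on RU1's transport range instead.
    Deterministic for a fixed seed.
    """
    ru_coords, roles = _repeat_unit_coords(spec)
    n_ru = len(ru_coords)
    peri = _peripheral_coords(spec)
    n_peri = len(peri)

    # exact two-fold symmetry: 180° about the x-axis through the origin
    sym = compose(axis=[1.0, 0.0, 0.0], angle_deg=180.0)
    ru2_coords = sym.apply(ru_coords)

    blocks = [ru_coords]
    if n_peri:
        blocks.append(_linker(ru_coords[-1], peri[0], LINKER_LEN))
        blocks.append(peri)
        blocks.append(_linker(peri[-1], ru2_coords[0], LINKER_LEN))
    else:
        blocks.append(_linker(ru_coords[-1], ru2_coords[0], LINKER_LEN))
    blocks.append(ru2_coords)
    base = np.vstack(blocks)

    # residue numbering (1-based, consecutive)
    ru1_start = 1
    ru1_end = n_ru
    if n_peri:
        peri_start = ru1_end + LINKER_LEN + 1
        peri_end = peri_start + n_peri - 1
        ru2_start = peri_end + LINKER_LEN + 1
    else:
        peri_start = peri_end = None
        ru2_start = ru1_end + LINKER_LEN + 1
    ru2_end = ru2_start + n_ru - 1

    rep = RepeatDefinition(
        ru1=ResidueRangeSet.from_ranges([("A", ru1_start, ru1_end)]),
        ru2=ResidueRangeSet.from_ranges([("A", ru2_start, ru2_end)]),
        peripheral=(
            ResidueRangeSet.from_ranges([("A", peri_start, peri_end)])
            if n_peri
            else ResidueRangeSet(())
        ),
    )

    def ranges_from_mask(offset: int, want: int) -> list[tuple[str, int, int]]:
        out = []
        start = None
        for i, role in enumerate(list(roles) + [-2]):
            num = offset + i
            if role == want and start is None:
                start = num
            elif role != want and start is not None:
                out.append(("A", start, num - 1))
                start = None
        return out

    scaffold_ranges = ranges_from_mask(ru1_start, 0) + ranges_from_mask(ru2_start, 0)
    if n_peri:
        scaffold_ranges.append(("A", peri_start, peri_end))
    transport_ranges = ranges_from_mask(ru1_start, 1) + ranges_from_mask(ru2_start, 1)
    dom = DomainDefinition(
        scaffold=ResidueRangeSet.from_ranges(scaffold_ranges),
        transport=ResidueRangeSet.from_ranges(transport_ranges),
    )

    # the swing: rotation about an in-plane (y) axis through the transport
    # sub-repeat's projection onto the symmetry axis, then a shift along z
    t_mask = roles == 1
    t_center_x = float(ru_coords[t_mask, 0].mean())
    swing = compose(
        axis=[0.0, 1.0, 0.0],
        angle_deg=spec.asymmetry_angle_deg,
        center=[t_center_x, 0.0, 0.0],
        translation=[0.0, 0.0, spec.asymmetry_shift_A],
    )
    conj_swing = sym.compose(swing).compose(sym)  # the same swing seen by RU1

    ru1_idx = np.arange(ru1_start - 1, ru1_end)  # 0-based into `base`
    ru2_offset = ru2_start - 1
    ru2_idx = np.arange(ru2_offset, ru2_offset + n_ru)

    original = base.copy()
    original[ru2_idx[t_mask]] = swing.apply(original[ru2_idx[t_mask]])
    swapped = base.copy()
    swapped[ru1_idx[t_mask]] = conj_swing.apply(swapped[ru1_idx[t_mask]])

    # exact transport-domain motion original → swapped (noiseless Kabsch fit)
    frame = MembraneFrame()
    t_all = np.concatenate([ru1_idx[t_mask], ru2_idx[t_mask]])
    motion_tf, _ = superpose(original[t_all], swapped[t_all])
    motion = decompose(motion_tf, frame, centroid=original[t_all].mean(axis=0))

    rng = np.random.default_rng(spec.seed)
    noisy = original + rng.normal(0.0, spec.noise_A, original.shape)
    noisy_swapped = swapped + rng.normal(0.0, spec.noise_A, swapped.shape)

    structure = _structure_from_coords(noisy, f"toy transporter (seed {spec.seed})")
    swapped_structure = _structure_from_coords(
        noisy_swapped, f"toy swapped truth (seed {spec.seed})"
    )
    correspondence = [
        (("A", int(ru1_start + i), ""), ("A", int(ru2_start + i), ""))
        for i in range(n_ru)
    ]
    truth = ToyGroundTruth(
        spec=spec,
        symmetry_op=sym,
        correspondence=correspondence,
        repeat_def=rep,
        domain_def=dom,
        frame=frame,
        asymmetry=swing,
        transport_motion=motion_tf,
        motion=motion,
        swapped_structure=swapped_structure,
        _noiseless=_structure_from_coords(original, "toy (noiseless)"),
        _noiseless_swapped=_structure_from_coords(swapped, "toy swapped (noiseless)"),
    )
    return structure, truth


def make_swapped_truth(spec: ToySpec, truth: ToyGroundTruth) -> ProteinStructure:
    """The conformer in which RU1 adopts RU2's conformation and vice versa.

    This is the target a repeat-swap pipeline applied to the original toy
    should reconstruct (up to the naive builder's limitations).
    """
    if truth.spec != spec:
        raise ValueError("ground truth was generated from a different spec")
    return truth.swapped_structure
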