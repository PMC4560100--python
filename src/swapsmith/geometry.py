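"""Rigid-body superposition, motion decomposition, TM-score and displacement.

These primitives quantify elevator-type conformational changes: after
superposing two conformers on the static scaffold domain, the residual
rigid-body transform of the transport domain is decomposed into a rotation
(axis + angle) and a translation expressed in the membrane frame, and
per-residue Cα displacements are profiled along the sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from swapsmith.structure import ProteinStructure, ResidueRangeSet

__all__ = [
    "RigidTransform",
    "MembraneFrame",
    "MotionDecomposition",
    "superpose",
    "decompose",
    "compose",
    "tm_score",
    "tm_d0",
    "displacement_profile",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x' = R x + t`` (rotation + translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-6):
            raise ValueError("rotation matrix determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane coordinate frame: unit normal plus an origin on the midplane.

    The default matches OPM-oriented structures, whose membrane normal is
    the z-axis.  In-plane axes are completed deterministically from the
    normal (x̂ projected into the plane, else ŷ).
    """

    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("membrane normal must be non-zero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))

    def basis(self) -> np.ndarray:
        """Rows are (u, v, n): two in-plane axes and the normal."""
        n = self.normal
        u = np.array([1.0, 0.0, 0.0]) - n[0] * n
        if np.linalg.norm(u) < 1e-8:
            u = np.array([0.0, 1.0, 0.0]) - n[1] * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return np.vstack([u, v, n])

    def to_frame(self, vec: np.ndarray) -> np.ndarray:
        """Express a displacement vector in (u, v, normal) components."""
        return self.basis() @ np.asarray(vec, dtype=float)


@dataclass(frozen=True)
class MotionDecomposition:
    """Axis-angle + membrane-frame translation view of a rigid transform."""

    angle_deg: float
    axis: np.ndarray
    centroid_displacement: np.ndarray  # (du, dv, dn) in the membrane frame, Å
    axis_membrane_angle_deg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float).reshape(3))
        object.__setattr__(
            self,
            "centroid_displacement",
            np.asarray(self.centroid_displacement, dtype=float).reshape(3),
        )

    def as_dict(self) -> dict:
        dx, dy, dz = self.centroid_displacement
        return {
            "angle_deg": self.angle_deg,
            "axis": self.axis.tolist(),
            "displacement_A": {"x": dx, "y": dy, "z": dz},
            "axis_membrane_angle_deg": self.axis_membrane_angle_deg,
        }


# ---------------------------------------------------------------------------
# superposition


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
) -> tuple[RigidTransform, float]:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rigid transform and the post-fit RMSD in Å.
    Requires ≥ 3 non-collinear points in each equal-length set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"length mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    if np.linalg.matrix_rank(mob0, tol=1e-9) < 2 or np.linalg.matrix_rank(ref0, tol=1e-9) < 2:
        raise ValueError("degenerate input: points are collinear or coincident")
    rot, _ = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    diff = mobile @ R.T + t - reference
    rmsd = float(np.sqrt((diff ** 2).sum() / mobile.shape[0]))
    return RigidTransform(R, t), rmsd


def compose(
    axis: np.ndarray,
    angle_deg: float,
    center: np.ndarray | None = None,
    translation: np.ndarray | None = None,
) -> RigidTransform:
    """Rotation by ``angle_deg`` about ``axis`` through ``center``, then translate."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    extra = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    t = center - R @ center + extra
    return RigidTransform(R, t)


def decompose(
    t: RigidTransform,
    frame: MembraneFrame | None = None,
    centroid: np.ndarray | None = None,
) -> MotionDecomposition:
    """Decompose a rigid transform into axis/angle and membrane-frame shift.

    The angle follows from the rotation-matrix trace and lies in [0, 180]°
    (scipy's rotation-vector representation; near 180° the axis comes from
    the dominant eigenvector of the symmetric part, which is what the
    rotation-vector of a straight-angle rotation reduces to).  The centroid
    displacement is ``t(c) − c`` expressed in membrane-frame components.
    """
    frame = frame or MembraneFrame()
    centroid = np.zeros(3) if centroid is None else np.asarray(centroid, dtype=float)
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-12:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = rotvec / angle
    disp = t.apply(centroid) - centroid
    cosang = float(np.clip(abs(np.dot(axis, frame.normal)), 0.0, 1.0))
    return MotionDecomposition(
        angle_deg=float(np.rad2deg(angle)),
        axis=axis,
        centroid_displacement=frame.to_frame(disp),
        axis_membrane_angle_deg=float(np.rad2deg(np.arccos(cosang))),
    )


# ---------------------------------------------------------------------------
# TM-score


def tm_d0(l_norm: int) -> float:
    """Length-dependent TM-score distance scale, clamped below at 0.5 Å."""
    if l_norm <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


def _tm_of_distances(d: np.ndarray, d0: float, l_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def _refine_subset(
    mob: np.ndarray,
    ref: np.ndarray,
    seed_idx: np.ndarray,
    d0: float,
    l_norm: int,
    max_iter: int = 20,
) -> float:
    """Superpose on a seed subset, then iterate the distance-cutoff refinement."""
    best = 0.0
    subset = seed_idx
    prev: set[int] | None = None
    for _ in range(max_iter):
        if subset.size < 3:
            break
        try:
            tf, _ = superpose(mob[subset], ref[subset])
        except ValueError:
            break
        d = np.linalg.norm(tf.apply(mob) - ref, axis=1)
        best = max(best, _tm_of_distances(d, d0, l_norm))
        cutoff = max(d0, 0.5)
        new = np.nonzero(d < cutoff)[0]
        while new.size < 3 and cutoff < d.max() + 1.0:
            cutoff += 0.5
            new = np.nonzero(d < cutoff)[0]
        key = set(new.tolist())
        if prev is not None and key == prev:
            break
        prev = key
        subset = new
    return best


def tm_score(
    mobile: np.ndarray,
    reference: np.ndarray,
    l_norm: int | None = None,
    pairing: list[tuple[int, int]] | None = None,
) -> float:
    """Template-modeling score of an aligned residue pairing.

    ``TM = max over superpositions of (1/L_norm) Σ 1/(1 + (dᵢ/d₀)²)`` with
    ``d₀ = 1.24 (L_norm − 15)^⅓ − 1.8`` (clamped at 0.5 Å).  The maximization
    uses the standard heuristic: superpositions seeded from contiguous
    aligned fragments of length L, L/2 and L/4, each refined by iterating a
    distance-cutoff inclusion rule to convergence.

    Parameters
    ----------
    mobile, reference:
        (n, 3) Cα coordinates.
    pairing:
        Aligned index pairs into mobile/reference; default pairs them 1:1.
    l_norm:
        Normalization length (≥ number of pairs); default = number of pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pairing is None:
        if mobile.shape != reference.shape:
            raise ValueError("without explicit pairing, inputs must have equal length")
        pairing = list(zip(range(len(mobile)), range(len(reference))))
    n = len(pairing)
    if n < 3:
        raise ValueError(f"need at least 3 aligned pairs, got {n}")
    if l_norm is None:
        l_norm = n
    if l_norm < n:
        raise ValueError(f"l_norm ({l_norm}) must be >= number of pairs ({n})")
    mob = mobile[[i for i, _ in pairing]]
    ref = reference[[j for _, j in pairing]]
    d0 = tm_d0(l_norm)
    best = 0.0
    frag_lens = sorted({n, max(3, n // 2), max(3, n // 4)}, reverse=True)
    for fl in frag_lens:
        for start in range(0, n - fl + 1):
            seed = np.arange(start, start + fl)
            best = max(best, _refine_subset(mob, ref, seed, d0, l_norm))
    if n <= 10:
        # tiny inputs: the fragment heuristic is replaced by exhaustive
        # subset seeding, making the search provably optimal over seeds
        from itertools import combinations

        for size in range(3, n + 1):
            for seed in combinations(range(n), size):
                best = max(best, _refine_subset(mob, ref, np.array(seed), d0, l_norm))
    return best


# ---------------------------------------------------------------------------
# displacement profiles


def displacement_profile(
    model: ProteinStructure,
    reference: ProteinStructure,
    fit_ranges: ResidueRangeSet,
) -> pd.DataFrame:
    """Per-residue Cα displacement after superposing on ``fit_ranges`` only.

    The model is fitted onto the reference using the Cα atoms inside
    ``fit_ranges`` (typically the scaffold domain), then every residue
    shared by both structures is reported as the distance between its Cα
    positions.  Columns: ``chain``, ``res_seq``, ``displacement_A``.
    """
    ref_ca = {r.key: r.ca for r in reference.residues if r.ca is not None}
    mod_ca = {r.key: r.ca for r in model.residues if r.ca is not None}
    shared = [k for k in mod_ca if k in ref_ca]
    fit_keys = [k for k in shared if fit_ranges.contains(k[0], k[1])]
    if len(fit_keys) < 3:
        raise ValueError("fewer than 3 shared Cα atoms in the fit ranges")
    mob = np.vstack([mod_ca[k].coords for k in fit_keys])
    ref = np.vstack([ref_ca[k].coords for k in fit_keys])
    tf, _ = superpose(mob, ref)
    rows = []
    for r in model.residues:
        k = r.key
        if k not in mod_ca or k not in ref_ca:
            continue
        moved = tf.apply(mod_ca[k].coords)
        dist = float(np.linalg.norm(moved - ref_ca[k].coords))
        rows.append({"chain": k[0], "res_seq": k[1], "displacement_A": dist})
    return pd.DataFrame(rows, columns=["chain", "res_seq", "displacement_A"])
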