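"""Structure-geometry measurements: solvent-accessible and buried interface
areas, inter-Cα distances, sequence mass, two-fold symmetry axes and hybrid
assembly by axis alignment.

The interface area follows the PISA convention: half the total buried area
(SASA(A) + SASA(B) − SASA(AB))/2; the unhalved buried area and its share of
the total surface are also reported, since both conventions appear in the
structural literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import StructureModel
from .tables import (DEFAULT_VDW_RADIUS, ONE_TO_THREE, RESIDUE_TABLE,
                     VDW_RADII, WATER_MASS, AVERAGE_RESIDUE)

logger = logging.getLogger(__name__)

__all__ = [
    "sasa", "buried_interface_area", "inter_ca_distance", "sequence_mass",
    "find_c2_axis", "align_axes", "SymmetryAxis", "InterfaceArea",
]


def _sphere_points(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def sasa(structure: StructureModel, probe_radius: float = 1.4,
         n_points: int = 960):
    """Shrake–Rupley solvent-accessible surface area.

    Returns (total Å², per-atom Å² array). Unknown elements fall back to the
    default carbon radius with a warning.
    """
    radii = np.empty(len(structure))
    unknown = set()
    for i, a in enumerate(structure.atoms):
        r = VDW_RADII.get(a.element)
        if r is None:
            unknown.add(a.element)
            r = DEFAULT_VDW_RADIUS
        radii[i] = r + probe_radius
    if unknown:
        logger.warning("unknown elements %s: default radius used", sorted(unknown))
    xyz = structure.xyz
    sphere = _sphere_points(n_points)
    tree = cKDTree(xyz)
    areas = np.zeros(len(structure))
    rmax = radii.max()
    for i in range(len(structure)):
        pts = xyz[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(xyz[i], radii[i] + rmax)
                 if j != i]
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - xyz[neigh][None, :, :], axis=2)
            exposed = np.all(d >= radii[neigh][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return float(areas.sum()), areas


@dataclass
class InterfaceArea:
    interface_area: float   # PISA-style half-buried area, Å²
    buried_area: float      # unhalved, Å²
    total_area: float       # SASA of the complex, Å²
    fraction_buried: float  # buried_area / (SASA(A)+SASA(B))


def buried_interface_area(structure: StructureModel, selA: dict, selB: dict,
                          probe_radius: float = 1.4,
                          n_points: int = 960) -> InterfaceArea:
    """Buried area between two selections (kwargs for StructureModel.select).

    interface_area = (SASA(A) + SASA(B) − SASA(A∪B))/2 — the PISA headline
    convention; buried_area is the unhalved difference.
    """
    a = structure.select(**selA)
    b = structure.select(**selB)
    keysA = {(at.chain, at.resnum, at.name) for at in a.atoms}
    keysB = {(at.chain, at.resnum, at.name) for at in b.atoms}
    if keysA & keysB:
        raise ValueError("selections overlap")
    ab = StructureModel(a.atoms + b.atoms)
    sA, _ = sasa(a, probe_radius, n_points)
    sB, _ = sasa(b, probe_radius, n_points)
    sAB, _ = sasa(ab, probe_radius, n_points)
    buried = sA + sB - sAB
    return InterfaceArea(buried / 2.0, buried, sAB,
                         buried / (sA + sB) if sA + sB > 0 else 0.0)


def inter_ca_distance(structure: StructureModel, resA: tuple,
                      resB: tuple) -> float:
    """Euclidean Cα–Cα distance between (chain, resnum) pairs."""

    def _ca(chain, resnum):
        for i, a in enumerate(structure.atoms):
            if a.chain == chain and a.resnum == resnum and a.name == "CA":
                return structure.xyz[i]
        raise ValueError(f"no CA atom for residue {chain}:{resnum}")

    return float(np.linalg.norm(_ca(*resA) - _ca(*resB)))


def sequence_mass(seq_or_structure, n_chains: int = 1) -> float:
    """Mass in kDa of a residue sequence (one- or three-letter) or of every
    chain in a structure: Σ average residue masses + one water per chain."""
    if isinstance(seq_or_structure, StructureModel):
        total = 0.0
        for chain in seq_or_structure.chains:
            sub = seq_or_structure.select(chain=chain)
            names = [r[2] for r in sub.residues()]
            total += _chain_mass(names)
        return total / 1e3
    seq = seq_or_structure
    if isinstance(seq, str):
        seq = [s for s in seq.strip()]
        names = [ONE_TO_THREE.get(s.upper()) for s in seq]
        if any(n is None for n in names):
            bad = sorted({s for s, n in zip(seq, names) if n is None})
            raise ValueError(f"unknown residue codes {bad}")
    else:
        names = [str(s).upper() for s in seq]
        for nm in names:
            if nm not in RESIDUE_TABLE:
                raise ValueError(f"unknown residue code {nm!r}")
    if not names:
        raise ValueError("empty sequence")
    return n_chains * _chain_mass(names) / 1e3


def _chain_mass(resnames) -> float:
    if not resnames:
        raise ValueError("empty chain")
    m = 0.0
    for nm in resnames:
        m += RESIDUE_TABLE.get(nm, (0, 0, AVERAGE_RESIDUE[2]))[2]
    return m + WATER_MASS


@dataclass
class SymmetryAxis:
    point: np.ndarray
    direction: np.ndarray
    rotation_angle: float   # degrees
    is_twofold: bool = True
    rmsd: float = 0.0


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rotation R, translation t with Q ≈ P @ R.T + t."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    return R, t


def find_c2_axis(structure: StructureModel, chainA: str, chainB: str,
                 angle_tolerance: float = 10.0) -> SymmetryAxis:
    """Two-fold axis of a homodimer from the A→B Cα superposition.

    Matches residues common to both chains, superposes A onto B, and extracts
    the rotation axis/angle and a point on the axis from the screw
    decomposition; flags non-two-fold when the angle deviates from 180° by
    more than ``angle_tolerance`` degrees.
    """
    caA = {a.resnum: structure.xyz[i] for i, a in enumerate(structure.atoms)
           if a.chain == chainA and a.name == "CA"}
    caB = {a.resnum: structure.xyz[i] for i, a in enumerate(structure.atoms)
           if a.chain == chainB and a.name == "CA"}
    common = sorted(set(caA) & set(caB))
    if len(common) < 3:
        raise ValueError("fewer than 3 matched CA pairs between chains")
    P = np.array([caA[r] for r in common])
    Q = np.array([caB[r] for r in common])
    R, t = _kabsch(P, Q)
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    # rotation axis: eigenvector of R for eigenvalue 1
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    # orient consistently (largest-magnitude component positive)
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    # point on axis: least-squares solution of (I − R)p = t restricted to the
    # plane perpendicular to the axis (screw decomposition)
    t_perp = t - (t @ axis) * axis
    point = np.linalg.pinv(np.eye(3) - R) @ t_perp
    return SymmetryAxis(point, axis, angle,
                        abs(angle - 180.0) <= angle_tolerance, rmsd)


def align_axes(mobile: StructureModel, mobile_axis: SymmetryAxis,
               target_axis: SymmetryAxis, spin_angle: float = 0.0):
    """Rigid transform making the mobile axis colinear and co-located with
    the target axis; residual freedom about the shared axis is fixed by
    ``spin_angle`` (degrees). Returns (transformed structure, R, t)."""
    a = mobile_axis.direction / np.linalg.norm(mobile_axis.direction)
    b = target_axis.direction / np.linalg.norm(target_axis.direction)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("degenerate axis")
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        R1 = np.eye(3) if c > 0 else _any_perp_rotation(a)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R1 = np.eye(3) + vx + vx @ vx / (1.0 + c)
    spin = np.radians(spin_angle)
    K = np.array([[0, -b[2], b[1]], [b[2], 0, -b[0]], [-b[1], b[0], 0]])
    R2 = np.eye(3) + np.sin(spin) * K + (1 - np.cos(spin)) * (K @ K)
    R = R2 @ R1
    # use each axis's point closest to the origin so that the transform is
    # unique (no arbitrary slide along the shared axis) and idempotent
    pm = np.asarray(mobile_axis.point, float)
    pm = pm - (pm @ a) * a
    pt = np.asarray(target_axis.point, float)
    pt = pt - (pt @ b) * b
    t = pt - R @ pm
    return mobile.transformed(R, t), R, t


def _any_perp_rotation(a: np.ndarray) -> np.ndarray:
    """180° rotation about any axis perpendicular to a (for anti-parallel)."""
    p = np.cross(a, [1.0, 0.0, 0.0])
    if np.linalg.norm(p) < 1e-8:
        p = np.cross(a, [0.0, 1.0, 0.0])
    p /= np.linalg.norm(p)
    return 2.0 * np.outer(p, p) - np.eye(3)
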