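"""Core domain containers shared by every stage of the pipeline.

Unit conventions (used throughout the package):

* coordinates and distances in Å
* scattering vector modulus ``q = 4π sin(θ)/λ`` in Å⁻¹
* intensities on an absolute scale (cm⁻¹) or arbitrary units, recorded in
  ``ScatteringCurve.meta['units']``
* effective scattering lengths in excess electrons (the Thomson length is a
  global prefactor that cancels in every fit performed here)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScatteringCurve",
    "StructureModel",
    "DensityMap",
    "BeadModel",
    "Atom",
]


@dataclass
class ScatteringCurve:
    """Measured or simulated intensity I(q) with per-point 1-σ uncertainty.

    ``sigma`` may be all zero for noise-free model curves; such curves are
    flagged via ``meta['sigma_is_placeholder']`` and must not be used as the
    weighting side of a χ² fit.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I and sigma must have identical length")
        if self.q.ndim != 1:
            raise ValueError("curve arrays must be one-dimensional")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not self.meta.get("sigma_is_placeholder", False) and np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive (or flag sigma_is_placeholder)")

    def __len__(self) -> int:
        return self.q.size

    def crop(self, qmin: float = 0.0, qmax: float = np.inf) -> "ScatteringCurve":
        m = (self.q >= qmin) & (self.q <= qmax)
        return ScatteringCurve(self.q[m], self.I[m], self.sigma[m], dict(self.meta))


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    xyz: tuple
    occ: float = 1.0
    b: float = 0.0


class StructureModel:
    """Atomic model: flat atom records plus numpy coordinate access.

    A deliberately thin carrier between file readers (gemmi) and the
    coarse-graining / geometry code; selection is by chain id and residue
    number range.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("empty structure model")
        self.atoms = atoms
        self._xyz = np.array([a.xyz for a in atoms], dtype=float)
        if not np.all(np.isfinite(self._xyz)):
            raise ValueError("non-finite coordinates")

    @property
    def xyz(self) -> np.ndarray:
        return self._xyz

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list:
        seen: dict = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def select(self, chain: str | None = None,
               res_range: tuple[int, int] | None = None) -> "StructureModel":
        """Sub-model by chain and inclusive residue-number range."""
        picked = [
            a for a in self.atoms
            if (chain is None or a.chain == chain)
            and (res_range is None or res_range[0] <= a.resnum <= res_range[1])
        ]
        if not picked:
            raise ValueError(f"empty selection chain={chain!r} res_range={res_range!r}")
        return StructureModel(picked)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Rigid transform x -> R x + t applied to every atom."""
        new_xyz = self._xyz @ np.asarray(R, float).T + np.asarray(t, float)
        return StructureModel([
            Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                 tuple(new_xyz[i]), a.occ, a.b)
            for i, a in enumerate(self.atoms)
        ])

    def residues(self):
        """Iterate (chain, resnum, resname, atom index list) in file order."""
        out: dict = {}
        order: list = []
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resnum)
            if key not in out:
                out[key] = (a.resname, [])
                order.append(key)
            out[key][1].append(i)
        for key in order:
            resname, idx = out[key]
            yield key[0], key[1], resname, idx


@dataclass
class DensityMap:
    """3-D scalar density on a regular grid, axis order (x, y, z)."""

    grid: np.ndarray
    voxel_size: np.ndarray  # Å per voxel along each axis
    origin: np.ndarray      # Å position of grid[0,0,0]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with >= 2 voxels per axis")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive")

    @property
    def is_empty(self) -> bool:
        return bool(np.all(self.grid == 0))

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """Physical coordinates of the voxels selected by a boolean mask."""
        idx = np.argwhere(mask)
        return self.origin + idx * self.voxel_size


@dataclass
class BeadModel:
    """Coarse-grained scatterer list for the Debye engine.

    ``b_eff`` is the excess scattering length per bead (electron units),
    ``gauss_width`` the Gaussian form-factor width σᵢ (Å) so that
    fᵢ(q) = b_eff·exp(−q²σᵢ²/2); ``kind`` distinguishes protein beads from
    hydration-shell beads; ``body_id`` labels rigid-body membership.
    """

    positions: np.ndarray
    b_eff: np.ndarray
    gauss_width: np.ndarray
    kind: np.ndarray | None = None          # 'protein' | 'hydration'
    body_id: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = self.positions.shape[0]
        self.b_eff = np.broadcast_to(
            np.asarray(self.b_eff, dtype=float), (n,)).copy()
        self.gauss_width = np.broadcast_to(
            np.asarray(self.gauss_width, dtype=float), (n,)).copy()
        if self.kind is None:
            self.kind = np.full(n, "protein", dtype=object)
        else:
            self.kind = np.asarray(self.kind, dtype=object)
        if self.body_id is None:
            self.body_id = np.zeros(n, dtype=int)
        else:
            self.body_id = np.asarray(self.body_id, dtype=int)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite bead positions")
        if not np.all(np.isfinite(self.b_eff)):
            raise ValueError("non-finite b_eff")
        if np.any(self.gauss_width < 0):
            raise ValueError("gauss_width must be >= 0")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def radius_of_gyration(self) -> float:
        """b-weighted Rg of the bead cloud."""
        w = np.abs(self.b_eff)
        c = np.average(self.positions, axis=0, weights=w)
        return float(np.sqrt(np.average(
            np.sum((self.positions - c) ** 2, axis=1), weights=w)))

    def concat(self, other: "BeadModel") -> "BeadModel":
        return BeadModel(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.b_eff, other.b_eff]),
            np.concatenate([self.gauss_width, other.gauss_width]),
            np.concatenate([self.kind, other.kind]),
            np.concatenate([self.body_id, other.body_id]),
            dict(self.meta),
        )
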