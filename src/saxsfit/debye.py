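"""Forward SAXS calculator: coarse-graining, hydration layer, Debye equation.

The scattering model is a sum of Gaussian beads,

    I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q·rᵢⱼ)/(q·rᵢⱼ),   fᵢ(q) = bᵢ exp(−q²σᵢ²/2),

the exact orientational average for isotropic scatterers. Beads come from
per-residue (or per-atom) coarse-graining with excluded-volume contrast
b = electrons − ρ_s·V, optionally augmented by a hydration shell of
excess-density beads on the solvent-exposed surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit, prange
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .core import BeadModel, ScatteringCurve, StructureModel
from .tables import (ATOM_ELECTRONS, ATOM_VOLUMES, AVERAGE_RESIDUE,
                     GAUSS_WIDTH_K, RESIDUE_TABLE, SOLVENT_EDENS, WATER_EDENS)

logger = logging.getLogger(__name__)

__all__ = [
    "coarse_grain", "add_hydration_layer", "debye_intensity",
    "fit_scale_background", "FitResult",
]


@dataclass
class FitResult:
    scale: float
    background: float
    chi2_red: float
    n_points: int
    n_params: int = 2


def coarse_grain(structure: StructureModel, level: str = "residue",
                 solvent_edens: float = SOLVENT_EDENS) -> BeadModel:
    """One bead per residue (at the heavy-atom centroid) or per heavy atom.

    b_eff = Σ electrons − ρ_solvent·V with tabulated residue (or atomic
    displaced) volumes; the Gaussian width follows σ = K·V^{1/3} so the bead's
    second moment matches a uniform sphere of the same volume.
    """
    if level == "residue":
        pos, b, sig = [], [], []
        unknown = set()
        for chain, resnum, resname, idx in structure.residues():
            ne, vol, _ = RESIDUE_TABLE.get(resname, (None, None, None))
            if ne is None:
                unknown.add(resname)
                ne, vol, _ = AVERAGE_RESIDUE
            pos.append(structure.xyz[idx].mean(axis=0))
            b.append(ne - solvent_edens * vol)
            sig.append(GAUSS_WIDTH_K * vol ** (1.0 / 3.0))
        if unknown:
            logger.warning("unknown residues %s: using average-residue parameters",
                           sorted(unknown))
        return BeadModel(np.array(pos), np.array(b), np.array(sig))
    if level == "atom":
        pos, b, sig = [], [], []
        for i, a in enumerate(structure.atoms):
            ne = ATOM_ELECTRONS.get(a.element)
            vol = ATOM_VOLUMES.get(a.element)
            if ne is None:
                logger.warning("unknown element %r: treated as carbon", a.element)
                ne, vol = ATOM_ELECTRONS["C"], ATOM_VOLUMES["C"]
            pos.append(structure.xyz[i])
            b.append(ne - solvent_edens * vol)
            sig.append(GAUSS_WIDTH_K * vol ** (1.0 / 3.0))
        return BeadModel(np.array(pos), np.array(b), np.array(sig))
    raise ValueError(f"unknown coarse-graining level {level!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def add_hydration_layer(beads: BeadModel, thickness: float = 3.0,
                        contrast_fraction: float = 0.10,
                        area_per_bead: float = 15.0) -> BeadModel:
    """Place excess-density water beads on the solvent-exposed bead surface.

    Candidate points are sampled at distance (R_bead + thickness) from each
    protein bead (one point per ``area_per_bead`` Å² of that sphere) and
    rejected when they fall inside any other bead's exclusion sphere; the
    survivors are thinned to the target surface density. Shell-bead volume is
    area_per_bead × thickness and b = contrast_fraction · ρ_water · V.
    """
    if thickness <= 0:
        raise ValueError("hydration thickness must be positive")
    prot = beads.kind == "protein"
    if not np.any(prot):
        raise ValueError("no protein beads to hydrate")
    pos = beads.positions[prot]
    # bead radius consistent with the Gaussian width convention: R = √5 σ
    rad = np.sqrt(5.0) * beads.gauss_width[prot]
    rad = np.where(rad > 0, rad, 1.5)
    shell_r = rad + thickness
    pts = []
    for c, r in zip(pos, shell_r):
        n = max(4, int(np.ceil(4 * np.pi * r * r / area_per_bead)))
        pts.append(c + r * _fibonacci_sphere(n))
    pts = np.vstack(pts)
    # reject points buried inside another bead's shell sphere
    tree = cKDTree(pos)
    rmax = shell_r.max()
    keep = np.ones(len(pts), bool)
    neigh = tree.query_ball_point(pts, rmax * 0.999)
    for i, nb in enumerate(neigh):
        for j in nb:
            if np.linalg.norm(pts[i] - pos[j]) < shell_r[j] * 0.999:
                keep[i] = False
                break
    pts = pts[keep]
    # thin to ~one bead per area_per_bead (min spacing = sqrt(area))
    min_d = np.sqrt(area_per_bead)
    ptree = cKDTree(pts)
    alive = np.ones(len(pts), bool)
    for i in range(len(pts)):
        if not alive[i]:
            continue
        for j in ptree.query_ball_point(pts[i], min_d):
            if j > i:
                alive[j] = False
    pts = pts[alive]
    v_shell = area_per_bead * thickness
    b_shell = contrast_fraction * WATER_EDENS * v_shell
    shell = BeadModel(
        pts,
        np.full(len(pts), b_shell),
        np.full(len(pts), GAUSS_WIDTH_K * v_shell ** (1.0 / 3.0)),
        np.full(len(pts), "hydration", dtype=object),
        np.full(len(pts), -1, dtype=int),
    )
    out = beads.concat(shell)
    out.meta["n_hydration"] = len(pts)
    return out


@njit(parallel=True, cache=True)
def _debye_exact(pos, b, sig, q):  # pragma: no cover - numba kernel
    n = pos.shape[0]
    nq = q.shape[0]
    out = np.zeros(nq)
    for iq in prange(nq):
        qi = q[iq]
        f = b * np.exp(-0.5 * qi * qi * sig * sig)
        s = 0.0
        for i in range(n):
            s += f[i] * f[i]
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                x = qi * r
                if x < 1e-12:
                    s += 2.0 * f[i] * f[j]
                else:
                    s += 2.0 * f[i] * f[j] * np.sin(x) / x
        out[iq] = s
    return out


def _accumulate_pair_hist(pa, pc, edges, hist, chunk=1024):
    """Add pair-distance counts between pa and pc (or within pa if pc is None)."""
    from scipy.spatial.distance import cdist
    if pc is None:
        n = len(pa)
        for i in range(0, n, chunk):
            block = pa[i:i + chunk]
            h, _ = np.histogram(pdist(block), bins=edges)
            hist += h
            rest = pa[i + len(block):]
            if len(rest):
                h, _ = np.histogram(cdist(block, rest).ravel(), bins=edges)
                hist += h
    else:
        for i in range(0, len(pa), chunk):
            h, _ = np.histogram(cdist(pa[i:i + chunk], pc).ravel(), bins=edges)
            hist += h


def _debye_hist(beads: BeadModel, q: np.ndarray, dr: float) -> np.ndarray:
    """Pair-distance-histogram Debye sum with per-type-pair histograms."""
    types, inv = np.unique(
        np.stack([beads.b_eff, beads.gauss_width], axis=1),
        axis=0, return_inverse=True)
    nt = types.shape[0]
    fq = types[:, 0][:, None] * np.exp(
        -0.5 * (q[None, :] ** 2) * (types[:, 1][:, None] ** 2))  # (nt, nq)
    I = np.zeros_like(q)
    # self terms
    counts = np.bincount(inv, minlength=nt).astype(float)
    I += np.sum(counts[:, None] * fq ** 2, axis=0)
    span = beads.positions.max(axis=0) - beads.positions.min(axis=0)
    dmax = float(np.linalg.norm(span)) + dr
    edges = np.arange(0.0, dmax + dr, dr)
    rc = 0.5 * (edges[:-1] + edges[1:])
    for a in range(nt):
        pa = beads.positions[inv == a]
        for c in range(a, nt):
            hist = np.zeros(len(rc))
            if c == a:
                if len(pa) < 2:
                    continue
                _accumulate_pair_hist(pa, None, edges, hist)
            else:
                _accumulate_pair_hist(pa, beads.positions[inv == c], edges, hist)
            nz = hist > 0
            if not np.any(nz):
                continue
            x = np.outer(q, rc[nz])
            with np.errstate(invalid="ignore", divide="ignore"):
                sinc = np.where(x < 1e-12, 1.0, np.sin(x) / x)
            I += 2.0 * fq[a] * fq[c] * (sinc @ hist[nz])
    return I


def debye_intensity(beads: BeadModel, q_grid, method: str = "exact",
                    dr: float = 0.5) -> ScatteringCurve:
    """Debye-equation intensity of a bead model on a q grid.

    ``method='exact'`` is the O(N²) double sum (numba); ``method='hist'``
    bins pair distances (width ``dr``, per-type-pair histograms) and is
    accurate to ≲0.5% at dr = 0.5 Å for protein-sized models.
    """
    if len(beads) == 0:
        raise ValueError("empty bead model")
    q = np.asarray(q_grid, float)
    if method == "exact":
        I = _debye_exact(np.ascontiguousarray(beads.positions),
                         np.ascontiguousarray(beads.b_eff),
                         np.ascontiguousarray(beads.gauss_width), q)
    elif method == "hist":
        I = _debye_hist(beads, q, dr)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScatteringCurve(q, I, np.zeros_like(q),
                           meta={"sigma_is_placeholder": True,
                                 "model": "debye", "method": method})


def fit_scale_background(model_curve: ScatteringCurve, data: ScatteringCurve,
                         fit_background: bool = True) -> FitResult:
    """Weighted linear least squares of data = scale·I_model + background.

    The model is interpolated to the data grid with a cubic spline when the
    grids differ; χ²_red = Σ((c·Im + b − Id)/σ)² / (N − n_params).
    """
    n = len(data)
    if n <= 2:
        raise ValueError("need more than 2 data points")
    if model_curve.q.shape == data.q.shape and np.allclose(model_curve.q, data.q):
        im = model_curve.I
    else:
        im = CubicSpline(model_curve.q, model_curve.I)(data.q)
    w = 1.0 / data.sigma
    if fit_background:
        A = np.column_stack([im * w, w])
        coef, *_ = np.linalg.lstsq(A, data.I * w, rcond=None)
        scale, background = float(coef[0]), float(coef[1])
        npar = 2
    else:
        scale = float(np.sum(im * data.I * w * w) / np.sum(im * im * w * w))
        background = 0.0
        npar = 1
    resid = (scale * im + background - data.I) * w
    chi2 = float(np.sum(resid ** 2) / (n - npar))
    return FitResult(scale, background, chi2, n, npar)
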