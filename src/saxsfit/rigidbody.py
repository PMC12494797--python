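"""Rigid-body refinement of a multi-body model against a SAXS curve.

A coarse-grained model is partitioned into K rigid bodies joined by soft
connectivity springs at the chain cut points. Metropolis simulated annealing
proposes random single-body rotations/translations and accepts on the
penalised objective

    total = χ²_red + w_conn·E_conn + w_ev·E_ev,

with E_conn = Σ max(0, dist − (rest+slack))² over springs and E_ev the
quadratic inter-body clash penalty. An unspecific-oligomer structure factor
I(q) → I(q)·(1 + f·sin(qd)/(qd)) (mass-fraction convention: forward
scattering scales as 1+f) can be co-fitted to model a population of
transient dimers-of-dimers at centre-of-mass distance d.

Intensities are maintained as per-body-pair Debye blocks so that moving one
body only recomputes its K−1 cross blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .core import BeadModel, ScatteringCurve, StructureModel
from .debye import FitResult, coarse_grain, fit_scale_background

logger = logging.getLogger(__name__)

__all__ = [
    "RigidBodyDecomposition", "OligomerParams", "RBConfig", "RBResult",
    "decompose", "objective", "apply_oligomer", "rb_refine",
]


@dataclass
class RigidBodyDecomposition:
    beads: BeadModel
    springs: list          # (bead index a, bead index b, rest Å, slack Å)
    K: int

    def body_indices(self) -> list:
        return [np.flatnonzero(self.beads.body_id == k + 1)
                for k in range(self.K)]


@dataclass
class OligomerParams:
    f: float = 0.0
    d: float = 65.0

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("oligomer fraction must be in [0, 1]")
        if self.d <= 0:
            raise ValueError("inter-dimer distance must be positive")


@dataclass
class RBConfig:
    n_runs: int = 10
    n_steps: int = 3000
    rot_sigma: float = 8.0       # degrees
    trans_sigma: float = 3.0     # Å
    w_conn: float = 10.0
    w_ev: float = 1.0
    r_clash: float = 3.8         # bead-centre clash cutoff, Å
    T_start: float = 2.0
    T_end: float = 0.01
    seed: int = 0
    fit_oligomer: bool = False
    fit_background: bool = True
    oligo_refit_interval: int = 250
    #: std-dev (degrees) of the random per-body hinge rotations applied at
    #: the start of every run except the first — multistart diversification
    start_rot_deg: float = 45.0
    #: body ids (1-based) held fixed, e.g. a reference body; only relative
    #: placement is observable in I(q), so fixing one body is conventional
    fixed_bodies: tuple = ()


@dataclass
class RunRecord:
    run_id: int
    seed: int
    chi2_red: float
    E_conn: float
    E_ev: float
    total: float
    oligo: OligomerParams
    scale: float
    background: float
    positions: np.ndarray = field(repr=False, default=None)
    transforms: list = field(repr=False, default=None)  # (R, t) per body


@dataclass
class RBResult:
    runs: list
    best_run: int

    @property
    def best(self) -> RunRecord:
        return self.runs[self.best_run]


def decompose(structure: StructureModel, segment_defs: list,
              slack_per_residue: float = 1.5) -> RigidBodyDecomposition:
    """Partition a structure into rigid bodies by (chain, residue-range)
    segments and auto-generate connectivity springs at the cut points.

    Each sequence-adjacent residue pair split across two bodies gets a spring
    with rest length 3.8 Å × (sequence gap) and slack 1.5 Å × gap. Residues
    covered by no segment are assigned to the spatially nearest body with a
    warning; a residue covered twice is an error.
    """
    beads = coarse_grain(structure, level="residue")
    res_keys = [(c, r) for c, r, _, _ in structure.residues()]
    n = len(res_keys)
    body = np.zeros(n, dtype=int)
    for b_id, (chain, rng) in enumerate(segment_defs, start=1):
        lo, hi = rng
        for i, (c, r) in enumerate(res_keys):
            if c == chain and lo <= r <= hi:
                if body[i] != 0:
                    raise ValueError(
                        f"residue {c}:{r} assigned to bodies {body[i]} and {b_id}")
                body[i] = b_id
    unassigned = np.flatnonzero(body == 0)
    if unassigned.size:
        logger.warning("%d residues uncovered by segments; assigning to "
                       "nearest body", unassigned.size)
        assigned = np.flatnonzero(body != 0)
        d = cdist(beads.positions[unassigned], beads.positions[assigned])
        body[unassigned] = body[assigned[np.argmin(d, axis=1)]]
    K = len(segment_defs)
    springs = []
    for i in range(n - 1):
        (c1, r1), (c2, r2) = res_keys[i], res_keys[i + 1]
        if c1 != c2:
            continue
        gap = r2 - r1
        if gap >= 1 and body[i] != body[i + 1]:
            springs.append((i, i + 1, 3.8 * gap, slack_per_residue * gap))
    beads.body_id = body
    return RigidBodyDecomposition(beads, springs, K)


def apply_oligomer(I_unit: np.ndarray, q: np.ndarray,
                   oligo: OligomerParams) -> np.ndarray:
    """Unspecific dimer-of-dimers structure factor (decoupling approximation):
    I(q) = I_unit(q)·(1 + f·sin(qd)/(qd)); I(0) scales as 1+f."""
    x = np.asarray(q, float) * oligo.d
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(np.abs(x) < 1e-12, 1.0, np.sin(x) / x)
    return np.asarray(I_unit, float) * (1.0 + oligo.f * sinc)


def _conn_energy(positions: np.ndarray, springs) -> float:
    e = 0.0
    for a, b, rest, slack in springs:
        d = float(np.linalg.norm(positions[a] - positions[b]))
        excess = d - (rest + slack)
        if excess > 0:
            e += excess * excess
    return e


def _clash_energy(positions: np.ndarray, body_id: np.ndarray,
                  r_clash: float) -> float:
    d = cdist(positions, positions)
    inter = body_id[:, None] != body_id[None, :]
    m = inter & (d < r_clash)
    np.fill_diagonal(m, False)
    return float(np.sum((r_clash - d[m]) ** 2) / 2.0)


def objective(decomp: RigidBodyDecomposition, data: ScatteringCurve,
              oligo: OligomerParams | None = None,
              w_conn: float = 10.0, w_ev: float = 1.0,
              r_clash: float = 3.8):
    """(χ²_red, E_conn, E_ev, total) of a decomposition against data."""
    from .debye import debye_intensity
    model = debye_intensity(decomp.beads, data.q, method="exact")
    I = model.I if oligo is None else apply_oligomer(model.I, data.q, oligo)
    fit = fit_scale_background(
        ScatteringCurve(data.q, I, np.zeros_like(I),
                        meta={"sigma_is_placeholder": True}), data)
    e_conn = _conn_energy(decomp.beads.positions, decomp.springs)
    e_ev = _clash_energy(decomp.beads.positions, decomp.beads.body_id, r_clash)
    total = fit.chi2_red + w_conn * e_conn + w_ev * e_ev
    return fit.chi2_red, e_conn, e_ev, total


@njit(cache=True)
def _cross_block(pk, pl, fk, fl, q):  # pragma: no cover - numba kernel
    nk, nl, nq = pk.shape[0], pl.shape[0], q.shape[0]
    out = np.zeros(nq)
    for i in range(nk):
        for j in range(nl):
            dx = pk[i, 0] - pl[j, 0]
            dy = pk[i, 1] - pl[j, 1]
            dz = pk[i, 2] - pl[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            for iq in range(nq):
                x = q[iq] * r
                if x < 1e-12:
                    out[iq] += fk[i, iq] * fl[j, iq]
                else:
                    out[iq] += fk[i, iq] * fl[j, iq] * np.sin(x) / x
    return out


class _BlockDebye:
    """Per-body-pair Debye blocks with O(K·n_body²) single-body updates.

    Diagonal blocks are rigid and never recomputed after construction."""

    def __init__(self, positions, b, sig, bodies, q):
        self.q = np.asarray(q, float)
        self.pos = np.array(positions, float)
        self.bodies = bodies
        self.f = np.ascontiguousarray(
            b[:, None] * np.exp(-0.5 * (self.q[None, :] ** 2)
                                * (sig[:, None] ** 2)))  # (N, nq)
        K = len(bodies)
        self.S = np.zeros((K, K, self.q.size))
        for k in range(K):
            for l in range(k, K):
                self.S[k, l] = self._block(k, l)

    def _block(self, k, l):
        bk, bl = self.bodies[k], self.bodies[l]
        return _cross_block(np.ascontiguousarray(self.pos[bk]),
                            np.ascontiguousarray(self.pos[bl]),
                            np.ascontiguousarray(self.f[bk]),
                            np.ascontiguousarray(self.f[bl]), self.q)

    def update_body(self, k):
        for l in range(len(self.bodies)):
            if l == k:
                continue  # intra-body distances are rigid
            a, b = min(k, l), max(k, l)
            self.S[a, b] = self._block(a, b)

    def intensity(self):
        K = len(self.bodies)
        I = np.zeros_like(self.q)
        for k in range(K):
            I += self.S[k, k]
            for l in range(k + 1, K):
                I += 2.0 * self.S[k, l]
        return I


def perturb_body_about_hinge(decomp: RigidBodyDecomposition, body: int,
                             angle_deg: float, axis=None,
                             seed: int | None = None) -> np.ndarray:
    """Rotate one body about its first connecting spring's cut point.

    Produces a connectivity-consistent alternative conformation (the spring
    anchor stays fixed, so E_conn remains 0) — the natural way to generate
    ground-truth targets for refinement recovery tests or to explore hinge
    motions. Returns a new position array.
    """
    idx = np.flatnonzero(decomp.beads.body_id == body)
    if idx.size == 0:
        raise ValueError(f"no beads in body {body}")
    hinge = None
    for a, b, _, _ in decomp.springs:
        if decomp.beads.body_id[a] == body:
            hinge = decomp.beads.positions[b]
            break
        if decomp.beads.body_id[b] == body:
            hinge = decomp.beads.positions[a]
            break
    if hinge is None:
        hinge = decomp.beads.positions[idx].mean(axis=0)
    if axis is None:
        axis = np.random.default_rng(seed).normal(size=3)
    R = _rotation_matrix(np.asarray(axis, float), np.deg2rad(angle_deg))
    pos = decomp.beads.positions.copy()
    pos[idx] = (pos[idx] - hinge) @ R.T + hinge
    return pos


def superposed_rmsd(P: np.ndarray, Q: np.ndarray,
                    fit_idx=None, rmsd_idx=None) -> float:
    """RMSD of P vs Q after least-squares (proper-rotation) superposition.

    I(q) is invariant under global rotation/translation, so refined models
    must be superposed before their placements can be compared.
    """
    from .geometry import _kabsch
    fit_idx = slice(None) if fit_idx is None else fit_idx
    rmsd_idx = slice(None) if rmsd_idx is None else rmsd_idx
    R, t = _kabsch(P[fit_idx], Q[fit_idx])
    Pt = P @ R.T + t
    return float(np.sqrt(np.mean(np.sum((Pt[rmsd_idx] - Q[rmsd_idx]) ** 2,
                                        axis=1))))


def _fast_scale_bg(im: np.ndarray, Id: np.ndarray, w: np.ndarray,
                   background: bool = True) -> FitResult:
    """Closed-form weighted scale (+ optional background) fit on a shared
    q grid."""
    a = im * w
    y = Id * w
    n = Id.size
    if background:
        b = w
        aa, ab, bb = a @ a, a @ b, b @ b
        ay, by = a @ y, b @ y
        det = aa * bb - ab * ab
        scale = (ay * bb - by * ab) / det
        bg = (aa * by - ab * ay) / det
        resid = scale * a + bg * b - y
        return FitResult(float(scale), float(bg),
                         float(resid @ resid / (n - 2)), n, 2)
    scale = (a @ y) / (a @ a)
    resid = scale * a - y
    return FitResult(float(scale), 0.0,
                     float(resid @ resid / (n - 1)), n, 1)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _fit_oligomer(I_unit, data, f_grid=None, d_grid=None, background=True):
    """Grid search over (f, d) then Nelder–Mead polish; returns
    (OligomerParams, FitResult)."""
    if f_grid is None:
        f_grid = np.arange(0.0, 1.0001, 0.05)
    if d_grid is None:
        d_grid = np.arange(30.0, 120.1, 5.0)

    w = 1.0 / data.sigma

    def chi2_of(f, d):
        I = apply_oligomer(I_unit, data.q, OligomerParams(f, d))
        return _fast_scale_bg(I, data.I, w, background)

    best = (np.inf, 0.0, d_grid[0])
    for f in f_grid:
        for d in d_grid:
            c = chi2_of(f, d).chi2_red
            if c < best[0]:
                best = (c, f, d)
    res = minimize(
        lambda x: chi2_of(np.clip(x[0], 0, 1), max(x[1], 1.0)).chi2_red,
        x0=[best[1], best[2]], method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
    f = float(np.clip(res.x[0], 0, 1))
    d = float(max(res.x[1], 1.0))
    oligo = OligomerParams(f, d)
    return oligo, chi2_of(f, d)


def _single_run(decomp, data, config, seed, run_id):
    rng = np.random.default_rng(seed)
    bodies = decomp.body_indices()
    K = len(bodies)
    pos = np.array(decomp.beads.positions, float)
    engine = _BlockDebye(pos, decomp.beads.b_eff, decomp.beads.gauss_width,
                         bodies, data.q)
    transforms = [(np.eye(3), np.zeros(3)) for _ in range(K)]
    oligo = OligomerParams(0.0, 65.0) if config.fit_oligomer else None
    start_kick = (run_id > 0 and config.start_rot_deg > 0)

    w = 1.0 / data.sigma

    def evaluate():
        I = engine.intensity()
        if oligo is not None:
            I = apply_oligomer(I, data.q, oligo)
        fit = _fast_scale_bg(I, data.I, w, config.fit_background)
        e_conn = _conn_energy(engine.pos, decomp.springs)
        e_ev = _clash_energy(engine.pos, decomp.beads.body_id, config.r_clash)
        total = fit.chi2_red + config.w_conn * e_conn + config.w_ev * e_ev
        return fit, e_conn, e_ev, total

    # spring anchor beads per body: pivots for hinge-type proposals
    anchors = [[] for _ in range(K)]
    for a, b, _, _ in decomp.springs:
        ka = decomp.beads.body_id[a] - 1
        kb = decomp.beads.body_id[b] - 1
        anchors[ka].append(b)
        anchors[kb].append(a)

    movable = [k for k in range(K) if (k + 1) not in config.fixed_bodies]
    if not movable:
        raise ValueError("all bodies are fixed")
    if start_kick:
        for k in movable:
            idx = bodies[k]
            pivot = (engine.pos[anchors[k][int(rng.integers(len(anchors[k])))]]
                     if anchors[k] else engine.pos[idx].mean(axis=0))
            R = _rotation_matrix(rng.normal(size=3),
                                 np.deg2rad(rng.normal(0.0, config.start_rot_deg)))
            engine.pos[idx] = (engine.pos[idx] - pivot) @ R.T + pivot
            R_old, t_old = transforms[k]
            transforms[k] = (R @ R_old, R @ (t_old - pivot) + pivot)
        for k in range(K):
            engine.update_body(k)

    fit, e_conn, e_ev, total = evaluate()
    if not np.isfinite(total):
        raise ValueError("non-finite objective at refinement start")
    best = (total, fit, e_conn, e_ev, engine.pos.copy(),
            [t for t in transforms], oligo)
    temps = np.geomspace(config.T_start, config.T_end, config.n_steps)
    rot_sigma = np.deg2rad(config.rot_sigma)
    for step, T in enumerate(temps):
        k = movable[int(rng.integers(len(movable)))]
        idx = bodies[k]
        # proposal size anneals with temperature for a sharp final polish
        amp = max(np.sqrt(T / config.T_start), 0.15)
        axis = rng.normal(size=3)
        if anchors[k] and rng.random() < 0.5:
            # hinge move: rotate about a spring anchor (E_conn-preserving
            # manifold of the connected conformations)
            centroid = engine.pos[anchors[k][int(rng.integers(len(anchors[k])))]]
            angle = rng.normal(0.0, 2.0 * rot_sigma * amp)
            shift = np.zeros(3)
        else:
            centroid = engine.pos[idx].mean(axis=0)
            angle = rng.normal(0.0, rot_sigma * amp)
            shift = rng.normal(0.0, config.trans_sigma * amp, size=3)
        R = _rotation_matrix(axis, angle)
        old_block_row = {l: engine.S[min(k, l), max(k, l)].copy()
                         for l in range(K)}
        old_pos = engine.pos[idx].copy()
        engine.pos[idx] = (old_pos - centroid) @ R.T + centroid + shift
        engine.update_body(k)
        new_fit, new_conn, new_ev, new_total = evaluate()
        accept = (new_total <= total or
                  rng.random() < np.exp(-(new_total - total) / T))
        if accept:
            fit, e_conn, e_ev, total = new_fit, new_conn, new_ev, new_total
            R_old, t_old = transforms[k]
            # x' = R(x − c) + c + s  composed with the previous transform
            transforms[k] = (R @ R_old,
                             R @ (t_old - centroid) + centroid + shift)
            if total < best[0]:
                best = (total, fit, e_conn, e_ev, engine.pos.copy(),
                        [t for t in transforms], oligo)
        else:
            engine.pos[idx] = old_pos
            for l, blk in old_block_row.items():
                engine.S[min(k, l), max(k, l)] = blk
        if (config.fit_oligomer and step > 0
                and step % config.oligo_refit_interval == 0):
            oligo, _ = _fit_oligomer(engine.intensity(), data,
                                  background=config.fit_background)
            fit, e_conn, e_ev, total = evaluate()
            if total < best[0]:
                best = (total, fit, e_conn, e_ev, engine.pos.copy(),
                        [t for t in transforms], oligo)
    if config.fit_oligomer:
        # final oligomer polish on the best structure
        final_pos = best[4]
        engine.pos[:] = final_pos
        for k in range(K):
            engine.update_body(k)
        oligo, fit = _fit_oligomer(engine.intensity(), data,
                                   background=config.fit_background)
        e_conn = _conn_energy(final_pos, decomp.springs)
        e_ev = _clash_energy(final_pos, decomp.beads.body_id, config.r_clash)
        total = fit.chi2_red + config.w_conn * e_conn + config.w_ev * e_ev
        if total <= best[0]:
            best = (total, fit, e_conn, e_ev, final_pos,
                    best[5], oligo)
    total, fit, e_conn, e_ev, pos_best, transforms_best, oligo_best = best
    return RunRecord(run_id, seed, fit.chi2_red, e_conn, e_ev, total,
                     oligo_best if oligo_best is not None
                     else OligomerParams(0.0, 65.0),
                     fit.scale, fit.background, pos_best, transforms_best)


def rb_refine(decomp: RigidBodyDecomposition, data: ScatteringCurve,
              config: RBConfig | None = None) -> RBResult:
    """Multi-run simulated-annealing rigid-body refinement.

    Each run is independently seeded from ``config.seed``; the best run
    minimises the penalised objective (ties → lowest run index).
    """
    if config is None:
        config = RBConfig()
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    runs = []
    for i in range(config.n_runs):
        runs.append(_single_run(decomp, data, config, int(seeds[i] % (2**31)), i))
        logger.info("run %d: chi2_red=%.3f total=%.3f f=%.2f d=%.1f",
                    i, runs[-1].chi2_red, runs[-1].total,
                    runs[-1].oligo.f, runs[-1].oligo.d)
    totals = [r.total for r in runs]
    best = int(np.argmin(totals))
    return RBResult(runs, best)
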