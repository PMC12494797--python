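"""Readers and writers for the external formats: SAXS .dat, PDB/mmCIF, MRC/CCP4.

Conventions: q in Å⁻¹ (an explicit ``q_unit='nm^-1'`` converts on read, never
auto-detected), coordinates in Å. The SASBDB three-column dialect (q, I, σ
with an optional free-text header block) is the reference .dat dialect.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import gemmi
import numpy as np

from .core import Atom, DensityMap, ScatteringCurve, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_curve", "write_curve", "read_structure", "write_structure",
    "read_map", "write_map", "write_report",
]


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _numeric_rows(path: Path):
    rows = []
    for line in path.read_text().splitlines():
        parts = re.split(r"[\s,;]+", line.strip())
        parts = [p for p in parts if p]
        if not parts:
            continue
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            continue  # header / comment line
    return rows


def read_curve(path, units: str = "unknown", q_unit: str = "A^-1",
               allow_no_errors: bool = False) -> ScatteringCurve:
    """Read a whitespace/comma-separated SAXS curve (q, I, σ).

    Rows with non-finite values or σ ≤ 0 are dropped (count logged).
    Two-column files are accepted only with ``allow_no_errors=True``; σ is
    then synthesised as 1% of I.
    """
    path = Path(path)
    rows = _numeric_rows(path)
    if not rows:
        raise FormatError(f"{path}: no numeric data rows")
    ncol = min(len(r) for r in rows)
    if ncol < 3:
        if ncol == 2 and allow_no_errors:
            arr = np.array([r[:2] for r in rows], float)
            arr = np.column_stack([arr, 0.01 * np.abs(arr[:, 1])])
        else:
            raise FormatError(
                f"{path}: {ncol} columns; need 3 (q, I, sigma) "
                "or pass allow_no_errors for 2-column data")
    else:
        arr = np.array([r[:3] for r in rows], float)
    good = np.all(np.isfinite(arr), axis=1) & (arr[:, 2] > 0)
    n_bad = int(np.sum(~good))
    if n_bad:
        logger.warning("%s: dropped %d rows (non-finite or sigma<=0)", path, n_bad)
    arr = arr[good]
    if arr.shape[0] == 0:
        raise FormatError(f"{path}: no valid rows after filtering")
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # collapse exact duplicate q (strictly-increasing invariant)
    keep = np.concatenate([[True], np.diff(arr[:, 0]) > 0])
    arr = arr[keep]
    q = arr[:, 0]
    if q_unit == "nm^-1":
        q = q / 10.0
    elif q_unit != "A^-1":
        raise ValueError(f"unknown q_unit {q_unit!r}")
    return ScatteringCurve(q, arr[:, 1], arr[:, 2],
                           meta={"source": str(path), "units": units,
                                 "dropped_rows": n_bad})


def write_curve(curve: ScatteringCurve, path, header: str | None = None) -> None:
    path = Path(path)
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    lines.append("# q(A^-1)  I  sigma")
    for qi, ii, si in zip(curve.q, curve.I, curve.sigma):
        lines.append(f"{qi:.8e} {ii:.8e} {si:.8e}")
    path.write_text("\n".join(lines) + "\n")


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    return el if el else "C"


def read_structure(path, include_waters: bool = False,
                   include_hydrogens: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties → first encountered); waters and hydrogens are excluded by default.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise FormatError(f"{path}: cannot parse structure: {exc}") from exc
    st.setup_entities()
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if not include_waters and res.is_water():
                continue
            # altloc resolution: best occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if not include_hydrogens and at.is_hydrogen():
                    continue
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > prev.occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                atoms.append(Atom(chain.name, res.seqid.num, res.name,
                                  at.name, _element_of(at),
                                  (at.pos.x, at.pos.y, at.pos.z),
                                  float(at.occ), float(at.b_iso)))
    if not atoms:
        raise FormatError(f"{path}: structure contains no atoms")
    return StructureModel(atoms)


def write_structure(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file."""
    path = Path(path)
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        x, y, z = a.xyz
        lines.append(
            f"ATOM  {i % 100000:5d} {a.name:^4s}{a.resname:>4s} "
            f"{a.chain[:1]:1s}{a.resnum % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occ:6.2f}{a.b:6.2f}"
            f"          {a.element:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4-2014 map; axis order normalised to (x, y, z)."""
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse map: {exc}") from exc
    # reorder axes so the array is indexed (x, y, z) without resampling
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(ccp4.grid, copy=True, dtype=float)
    cell = ccp4.grid.unit_cell
    nx, ny, nz = grid.shape
    voxel = np.array([cell.a / ccp4.grid.nu, cell.b / ccp4.grid.nv,
                      cell.c / ccp4.grid.nw])
    # origin: ORIGIN words if set, else NXSTART-style start indices
    origin_words = np.array([ccp4.header_float(50), ccp4.header_float(51),
                             ccp4.header_float(52)])
    if np.any(origin_words != 0):
        origin = origin_words
    else:
        start = np.array([ccp4.header_i32(5), ccp4.header_i32(6),
                          ccp4.header_i32(7)], float)
        origin = start * voxel
    m = DensityMap(np.nan_to_num(grid), voxel, origin)
    if m.is_empty:
        logger.warning("%s: map is all zeros", path)
    return m


def write_map(dmap: DensityMap, path) -> None:
    """Write a DensityMap as CCP4-2014 (mode 2, axis order x,y,z)."""
    path = Path(path)
    nx, ny, nz = dmap.grid.shape
    cell = gemmi.UnitCell(nx * dmap.voxel_size[0], ny * dmap.voxel_size[1],
                          nz * dmap.voxel_size[2], 90, 90, 90)
    grid = gemmi.FloatGrid(np.asarray(dmap.grid, dtype=np.float32), cell)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2)
    for k, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(k, float(v))
    ccp4.write_ccp4_map(str(path))


def write_report(results: dict, path, fitted_curve=None) -> None:
    """Serialise fit results to JSON; optional fitted-curve .dat alongside.

    ``fitted_curve`` is (q, I_exp, sigma, I_model) arrays; written as a
    4-column .dat next to the report.
    """
    path = Path(path)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    path.write_text(json.dumps(_clean(results), indent=2) + "\n")
    if fitted_curve is not None:
        q, iexp, sig, imod = (np.asarray(a, float) for a in fitted_curve)
        datp = path.with_suffix(".fit.dat")
        lines = ["# q  I_exp  sigma  I_model"]
        for row in zip(q, iexp, sig, imod):
            lines.append(" ".join(f"{v:.8e}" for v in row))
        datp.write_text("\n".join(lines) + "\n")
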