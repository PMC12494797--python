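"""Pipeline orchestration: primary curve analysis → p(r) → model scattering →
rigid-body (+ oligomer) refinement → map check → geometry, from one config.

The config is a plain mapping (or YAML file) with input paths, stage toggles
and per-stage parameter overrides; every enabled stage consumes the outputs
of the previous ones and contributes to a single machine-readable summary.
A fixed global seed makes re-runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

from . import debye, geometry, ift, invariants, io, mapfit, rigidbody

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_CONFIG"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "curve": None,            # path to SAXS .dat
    "model": None,            # path to PDB/mmCIF
    "map": None,              # path to MRC/CCP4
    "bodies": None,           # list of [chain, [first, last]] segments
    "stages": {
        "guinier": True, "kratky": True, "invariants": True, "pr": True,
        "model_fit": True, "rigid_body": False, "map_check": True,
        "geometry": True,
    },
    "guinier_qmax_rg": 1.3,
    "pr_dmax": None,
    "pr_mode": "bayes",
    "hydration": False,
    "oligomer": False,
    "rb": {},                 # RBConfig overrides
    "map_levels": 25,
    "max_beads": 20000,
    "seed": 0,
    "outdir": "saxsfit_out",
}


def _merged(config) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in dict(config).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config) -> dict:
    """Run all enabled stages; returns the summary dict (also written to
    ``<outdir>/summary.json`` with per-stage artefacts alongside).

    ``config`` may be a mapping or a YAML file path. Raises
    :class:`PipelineError` naming the first failing stage; artefacts of the
    completed stages are kept.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merged(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    try:
        pkg_version = version("saxsfit")
    except PackageNotFoundError:
        pkg_version = "unversioned"
    summary: dict = {
        "saxsfit_version": pkg_version,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
        "seed": cfg["seed"],
        "config": cfg,
    }

    curve = guinier = None
    model_curve = None
    if cfg["curve"]:
        curve = io.read_curve(cfg["curve"])
        summary["n_points"] = len(curve)
    structure = io.read_structure(cfg["model"]) if cfg["model"] else None

    def stage(name, enabled, fn):
        if not (enabled and stages.get(name, False)):
            return
        try:
            fn()
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    def _guinier():
        nonlocal guinier
        guinier = invariants.guinier_fit(curve, cfg["guinier_qmax_rg"])
        summary["guinier"] = {
            "Rg": guinier.Rg, "I0": guinier.I0, "Rg_sigma": guinier.Rg_sigma,
            "q_range": list(guinier.q_range), "n_points": guinier.n_points}

    def _kratky():
        x, y, plateau = invariants.kratky_dimensionless(curve, guinier)
        peak = int(np.argmax(y[x < 3.0])) if np.any(x < 3.0) else int(np.argmax(y))
        summary["kratky"] = {"peak_x": float(x[peak]), "peak_y": float(y[peak]),
                             "plateau": plateau}

    def _invariants():
        inv = invariants.compute_invariants(curve, guinier)
        summary["invariants"] = {
            "porod_Q": inv.porod_Q, "Vp": inv.Vp, "Vc": inv.Vc,
            "mass_porod_kDa": inv.mass_porod, "mass_vc_kDa": inv.mass_vc}

    def _pr():
        pofr = ift.pr_transform(curve, Dmax_hint=cfg["pr_dmax"],
                                alpha_mode=cfg["pr_mode"], guinier=guinier)
        summary["pr"] = {"Dmax": pofr.Dmax, "Rg_pr": pofr.Rg_pr,
                         "I0_pr": pofr.I0_pr, "chi2": pofr.chi2_fit,
                         "alpha": pofr.alpha}
        np.savetxt(outdir / "pr.out.dat",
                   np.column_stack([pofr.r, pofr.p]),
                   header="r(A)  p(r)")

    def _model_fit():
        nonlocal model_curve
        beads = debye.coarse_grain(structure)
        if cfg["hydration"]:
            beads = debye.add_hydration_layer(beads)
        model_curve = debye.debye_intensity(
            beads, curve.q, method="exact" if len(beads) < 3000 else "hist")
        fit = debye.fit_scale_background(model_curve, curve)
        summary["model_fit"] = {"chi2_red": fit.chi2_red, "scale": fit.scale,
                                "background": fit.background,
                                "n_beads": len(beads)}
        io.write_report({"model_fit": summary["model_fit"]},
                        outdir / "model_fit.json",
                        (curve.q, curve.I, curve.sigma,
                         fit.scale * model_curve.I + fit.background))

    def _rigid_body():
        segs = [(c, tuple(r)) for c, r in cfg["bodies"]]
        decomp = rigidbody.decompose(structure, segs)
        rb_cfg = rigidbody.RBConfig(seed=cfg["seed"],
                                    fit_oligomer=cfg["oligomer"],
                                    **cfg["rb"])
        result = rigidbody.rb_refine(decomp, curve, rb_cfg)
        best = result.best
        summary["rigid_body"] = {
            "chi2_best": best.chi2_red, "total": best.total,
            "E_conn": best.E_conn, "E_ev": best.E_ev,
            "oligomer_f": best.oligo.f, "oligomer_d": best.oligo.d,
            "best_run": result.best_run,
            "chi2_per_run": [r.chi2_red for r in result.runs]}
        np.savetxt(outdir / "rb_best_beads.xyz.dat", best.positions,
                   header="x y z (A), refined bead centres")

    def _map_check():
        dmap = io.read_map(cfg["map"])
        scan = mapfit.threshold_scan(dmap, curve, n_levels=cfg["map_levels"],
                                     max_beads=cfg["max_beads"])
        summary["map_check"] = {
            "best_threshold": scan.best_threshold,
            "best_chi2": scan.best_chi2,
            "n_beads_best": int(scan.n_beads[np.argmin(scan.chi2_red)])}
        np.savetxt(outdir / "map_scan.dat",
                   np.column_stack([scan.thresholds, scan.chi2_red,
                                    scan.n_beads]),
                   header="threshold  chi2_red  n_beads")

    def _geometry():
        chains = structure.chains
        geom: dict = {"mass_kDa": geometry.sequence_mass(structure)}
        if len(chains) >= 2:
            a, b = chains[0], chains[1]
            iface = geometry.buried_interface_area(
                structure, {"chain": a}, {"chain": b}, n_points=240)
            geom["interface_area"] = iface.interface_area
            geom["buried_area"] = iface.buried_area
            geom["total_area"] = iface.total_area
            try:
                ax = geometry.find_c2_axis(structure, a, b)
                geom["c2_angle"] = ax.rotation_angle
                geom["c2_is_twofold"] = ax.is_twofold
            except ValueError as exc:
                geom["c2_error"] = str(exc)
        summary["geometry"] = geom

    stage("guinier", curve is not None, _guinier)
    stage("kratky", curve is not None and guinier is not None, _kratky)
    stage("invariants", curve is not None and guinier is not None, _invariants)
    stage("pr", curve is not None, _pr)
    stage("model_fit", curve is not None and structure is not None, _model_fit)
    stage("rigid_body", curve is not None and structure is not None
          and cfg["bodies"] is not None, _rigid_body)
    stage("map_check", curve is not None and cfg["map"] is not None, _map_check)
    stage("geometry", structure is not None, _geometry)

    io.write_report(summary, outdir / "summary.json")
    return summary
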