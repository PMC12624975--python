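"""Desk-scale study drivers shared by the test suite and the acceptance
script.

These functions bundle the package's components into the study designs the
analyses call for: the strain-ordering solve on a reduced array, the
magnitude/angle sweep, the single-shank mesh-convergence sweep, and the
synthetic-recording recovery/calibration studies.  Problem sizes (grid,
tissue margins, mesh sizes, recording durations) are the package's
desk-scale defaults: a 4x4 grid with 3 um tip refinement delivered through
global-local submodeling, reduced tissue margins, and short multi-session
recordings.  They preserve the qualitative structure of the full-scale
setup (shank geometry and material are untouched) at single-CPU cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fem import (
    BoundaryConditions,
    MicromotionResult,
    SolverParams,
    electrode_table_for_displacement,
    mesh_convergence_study,
    refine_table_with_submodels,
    run_micromotion_case,
)
from .geometry import ArraySpec, TissueSpec
from .meshing import MeshSpec
from .pipeline import normalize_and_aggregate, session_metrics
from .stats import anova_tukey, spearman
from .synth import (
    LinkModel,
    simulate_evoked,
    simulate_ground_truth,
    simulate_impedances,
    simulate_spontaneous,
)

__all__ = [
    "desk_array_spec",
    "desk_tissue_spec",
    "DESK_GLOBAL_MESH",
    "DESK_FINE_MESH",
    "strain_ordering_study",
    "magnitude_angle_study",
    "convergence_study",
    "group_means",
    "ordering_anova",
    "ptpv_recovery_study",
    "link_recovery_study",
    "evoked_recovery_study",
    "null_false_positive_study",
]


def desk_array_spec(rows: int = 4, cols: int = 4) -> ArraySpec:
    """Reduced grid with the full-scale shank geometry and pitch."""
    return ArraySpec(rows=rows, cols=cols,
                     base_lx=(cols - 1) * 400.0 + 400.0,
                     base_ly=(rows - 1) * 400.0 + 400.0,
                     base_lz=100.0)


def desk_tissue_spec() -> TissueSpec:
    return TissueSpec(margin_below_tips=250.0, margin_lateral=250.0)


# coarse global mesh: wall-scale resolution, modest tip refinement
DESK_GLOBAL_MESH = MeshSpec(sphere_of_influence_radius=3.0,
                            tip_max_edge=32.0, global_target_edge=256.0,
                            shank_refine_factor=8.0, growth_slope=2.0)
# fine per-tip submodel mesh: the relaxed 3 um tip refinement
DESK_FINE_MESH = MeshSpec(sphere_of_influence_radius=2.0, tip_max_edge=3.0,
                          global_target_edge=192.0, shank_refine_factor=3.0,
                          growth_slope=2.0)


def group_means(table: pd.DataFrame, value: str = "avg_strain") -> dict:
    """corner / edge / interior group means of a per-electrode table."""
    g3 = table["group3"] if "group3" in table else None
    if g3 is None:
        ring = table["ring_label"].to_numpy()
        corner = table["is_corner"].to_numpy()
        g3 = np.where(corner, "corner",
                      np.where(ring == ring.max(), "edge", "interior"))
        g3 = pd.Series(g3, index=table.index)
    return {k: float(table.loc[g3 == k, value].mean())
            for k in ("corner", "edge", "interior")}


def ordering_anova(table: pd.DataFrame, value: str = "avg_strain"):
    """One-way ANOVA (with Tukey HSD) over the three location groups."""
    ring = table["ring_label"].to_numpy()
    corner = table["is_corner"].to_numpy()
    g3 = np.where(corner, "corner",
                  np.where(ring == ring.max(), "edge", "interior"))
    groups = {k: table[value].to_numpy()[g3 == k]
              for k in ("corner", "edge", "interior")}
    return anova_tukey(groups)


@dataclass
class OrderingStudyResult:
    result: MicromotionResult
    coarse_table: pd.DataFrame
    fine_table: pd.DataFrame
    group_means: dict
    anova: object
    checkpoints: dict = field(default_factory=dict)  # magnitude -> table


def strain_ordering_study(rows: int = 4, cols: int = 4,
                          magnitudes=(1.0, 5.0, 10.0, 20.0, 50.0),
                          submodel_magnitude: float = 10.0,
                          submodel_half_width: float = 55.0,
                          global_mesh: MeshSpec | None = None,
                          fine_mesh: MeshSpec | None = None,
                          params: SolverParams | None = None,
                          sub_params: SolverParams | None = None
                          ) -> OrderingStudyResult:
    """Rigid-array micromotion solve of a reduced grid with tip submodels.

    One continuation solve ramps the Y displacement to max(magnitudes),
    capturing the ROI strain table at every intermediate magnitude; the
    table at ``submodel_magnitude`` is then recomputed on fine (3 um tip)
    submodels for the ordering ANOVA.
    """
    arr = desk_array_spec(rows, cols)
    tis = desk_tissue_spec()
    gspec = global_mesh or DESK_GLOBAL_MESH
    fspec = fine_mesh or DESK_FINE_MESH
    params = params or SolverParams(n_load_steps=5, newton_rtol=1e-6)
    sub_params = sub_params or SolverParams(n_load_steps=2,
                                            newton_rtol=1e-5)
    mags = sorted(set(float(m) for m in magnitudes))
    mmax = mags[-1]
    bc = BoundaryConditions(displacement_magnitude=mmax, angle_deg=0.0)
    cps = [m / mmax for m in mags]
    res = run_micromotion_case(arr, tis, gspec, bc, params=params,
                               checkpoints=cps)
    tables = {}
    for m in mags:
        f = m / mmax
        if abs(f - 1.0) < 1e-12:
            tables[m] = res.electrode_table
        else:
            u = res.displacement.checkpoints.get(f)
            if u is not None:
                tables[m] = electrode_table_for_displacement(res, u)
    coarse = tables[submodel_magnitude]
    bc_sub = BoundaryConditions(displacement_magnitude=submodel_magnitude,
                                angle_deg=0.0)
    u_sub = (res.displacement.u
             if abs(submodel_magnitude - mmax) < 1e-12 else
             res.displacement.checkpoints[submodel_magnitude / mmax])
    res_at = MicromotionResult(
        mesh=res.mesh, model=res.model, layout=res.layout,
        displacement=replace_displacement(res, u_sub),
        strain=res.strain, electrode_table=coarse)
    fine = refine_table_with_submodels(
        res_at, fspec, half_width=submodel_half_width, params=sub_params,
        bc=bc_sub)
    return OrderingStudyResult(
        result=res, coarse_table=coarse, fine_table=fine,
        group_means=group_means(fine), anova=ordering_anova(fine),
        checkpoints=tables)


def replace_displacement(res: MicromotionResult, u: np.ndarray):
    from .fem import DisplacementField

    return DisplacementField(u=u, solved_nodes=res.displacement.solved_nodes)


def magnitude_angle_study(ordering: OrderingStudyResult,
                          angles=(22.5, 45.0),
                          angle_magnitude: float = 10.0,
                          params: SolverParams | None = None) -> dict:
    """Edge-vs-interior ordering across magnitudes and in-plane angles.

    Magnitude tables come from the continuation checkpoints of the
    ordering study; each additional angle is a fresh solve on the same
    mesh.  Returns group-mean tables keyed by (magnitude, angle).
    """
    params = params or SolverParams(n_load_steps=3, newton_rtol=1e-6)
    out = {}
    for m, table in ordering.checkpoints.items():
        out[(m, 0.0)] = group_means(table)
    res = ordering.result
    from .fem import solve_static, strain_from_displacement
    from .roi import electrode_strain_table
    from .fem import OgdenMaterial, ElasticMaterial

    materials = {"tissue": OgdenMaterial(), "array": ElasticMaterial()}
    for ang in angles:
        bc = BoundaryConditions(displacement_magnitude=angle_magnitude,
                                angle_deg=ang)
        disp = solve_static(res.mesh, materials, bc, model=res.model,
                            mode="rigid", params=params)
        strain = strain_from_displacement(res.mesh, disp)
        table = electrode_strain_table(res.mesh, strain, res.layout)
        out[(angle_magnitude, ang)] = group_means(table)
    return out


def convergence_study(edge_sizes=(3.0, 2.0, 1.0, 0.5),
                      params: SolverParams | None = None,
                      half_width: float = 50.0) -> pd.DataFrame:
    """Single-shank tip-refinement sweep at the desk scale."""
    arr = ArraySpec(rows=1, cols=1, base_lx=400, base_ly=400, base_lz=100)
    tis = desk_tissue_spec()
    gspec = replace(DESK_GLOBAL_MESH, tip_max_edge=12.0,
                    shank_refine_factor=4.0)
    fspec = replace(gspec, sphere_of_influence_radius=2.0,
                    shank_refine_factor=3.0)
    bc = BoundaryConditions(displacement_magnitude=10.0)
    params = params or SolverParams(n_load_steps=2, newton_rtol=3e-4,
                                    krylov_rtol=1e-4,
                                    refresh_iteration_threshold=35)
    return mesh_convergence_study(
        arr, tis, edge_sizes, bc, global_mesh_spec=gspec,
        fine_base_spec=fspec, half_width=half_width, params=params)


# ---------------------------------------------------------------------------
# synthetic-recording recovery and calibration studies
# ---------------------------------------------------------------------------

def _motor_layout(n_rows: int = 10, n_cols: int = 10,
                  connectivity: str = "corners_unconnected"):
    from .geometry import build_geometry, build_layout

    arr = ArraySpec(rows=n_rows, cols=n_cols,
                    base_lx=(n_cols - 1) * 400.0 + 400.0,
                    base_ly=(n_rows - 1) * 400.0 + 400.0)
    model = build_geometry(arr, TissueSpec())
    return build_layout(model, connectivity)


def ptpv_recovery_study(n_seeds: int = 200, duration_s: float = 4.0,
                        base_seed: int = 0) -> pd.DataFrame:
    """Planted-amplitude recovery: representative PTPV vs ground truth.

    One electrode per seed, template SNR >= 5 (amplitude 120 uV over a
    6 uV noise floor).  Returns per-seed planted and recovered PTPVs.
    """
    from .pipeline import bandpass, detect_and_extract, representative_ptpv
    from .synth import spike_template

    tmpl = spike_template()
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        link = LinkModel(sigma_a=0.0, sigma_session=0.0, firing_rate=25.0)
        truth = simulate_ground_truth(np.array([0.05]), link, seed=seed,
                                      n_sessions=1)
        rec = simulate_spontaneous(truth, duration_s=duration_s,
                                   n_sessions=1)
        filt = bandpass(rec.data[0][0].astype(float))
        snips = detect_and_extract(filt)
        rows.append({
            "seed": seed,
            "planted": float(truth.amplitude[0]),
            "recovered": representative_ptpv(snips),
            "n_events": snips.n_events,
        })
    df = pd.DataFrame(rows)
    df["rel_error"] = (df["recovered"] - df["planted"]) / df["planted"]
    return df


def link_recovery_study(n_seeds: int = 25, n_electrodes: int = 96,
                        duration_s: float = 3.0, n_sessions: int = 2,
                        base_seed: int = 0, alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Power of the pipeline to recover the planted negative
    strain-impedance and strain-PTPV links on a 96-electrode motor-style
    array (10x10 with unconnected corners)."""
    layout = _motor_layout()
    connected = layout.table["connected"].to_numpy()
    strain_base = _ring_strain_map(layout)
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        link = LinkModel()  # motor regime: beta_z, beta_a < 0
        truth = simulate_ground_truth(strain_base, link, seed=seed,
                                      n_sessions=n_sessions)
        rec = simulate_spontaneous(truth, duration_s=duration_s,
                                   n_sessions=n_sessions)
        imp = truth.impedance
        per = session_metrics(rec, imp, layout)
        norm = normalize_and_aggregate(per)
        merged = norm.merge(
            pd.DataFrame({"electrode_id": np.arange(len(strain_base)),
                          "avg_strain": strain_base}), on="electrode_id")
        keep = merged["functional"] & merged["connected"]
        m = merged[keep]
        r_imp = spearman(m["avg_strain"], m["impedance_norm"])
        ok_ptpv = np.isfinite(m["ptpv_norm"])
        r_ptpv = spearman(m["avg_strain"][ok_ptpv], m["ptpv_norm"][ok_ptpv])
        rows.append({
            "seed": seed, "n": int(keep.sum()),
            "rho_impedance": r_imp.statistic, "p_impedance": r_imp.p_value,
            "rho_ptpv": r_ptpv.statistic, "p_ptpv": r_ptpv.p_value,
            "hit_impedance": (r_imp.statistic < 0) and (r_imp.p_value < alpha),
            "hit_ptpv": (r_ptpv.statistic < 0) and (r_ptpv.p_value < alpha),
        })
    return pd.DataFrame(rows)


def evoked_recovery_study(n_seeds: int = 15, n_electrodes_grid: int = 8,
                          n_trials: int = 15, base_seed: int = 0,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Recovery of the planted positive evoked-gain link (V4 regime) as a
    positive Spearman correlation between strain and evoked SNR."""
    from .pipeline import emua, evoked_snr

    layout = _motor_layout(n_rows=n_electrodes_grid,
                           n_cols=n_electrodes_grid, connectivity="all")
    strain_base = _ring_strain_map(layout)
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        link = LinkModel.regime("v4")
        truth = simulate_ground_truth(strain_base, link, seed=seed,
                                      n_sessions=1)
        rec = simulate_evoked(truth, n_trials=n_trials, baseline_s=0.25,
                              stim_s=0.25, n_sessions=1)
        per = int(round(rec.trial_length_s * 1000))
        snrs = np.empty(len(strain_base))
        for e in range(len(strain_base)):
            env = emua(rec.data[0][e].astype(float))
            env = env[: rec.n_trials * per].reshape(rec.n_trials, per)
            snrs[e] = evoked_snr(env, rec.baseline_window, rec.stim_window)
        r = spearman(strain_base, snrs)
        rows.append({"seed": seed, "rho_evoked": r.statistic,
                     "p_evoked": r.p_value,
                     "hit_evoked": (r.statistic > 0) and (r.p_value < alpha)})
    return pd.DataFrame(rows)


def null_false_positive_study(n_seeds: int = 500, n_electrodes: int = 96,
                              base_seed: int = 0, alpha: float = 0.05
                              ) -> pd.DataFrame:
    """Type-I calibration: with all links flat the strain-impedance
    Spearman test should reject at about the nominal alpha."""
    layout = _motor_layout()
    strain_base = _ring_strain_map(layout)
    connected = layout.table["connected"].to_numpy()
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        link = LinkModel.regime("null")
        imp = simulate_impedances(strain_base, link, seed=seed)["impedance"]
        keep = connected
        r = spearman(strain_base[keep], imp.to_numpy()[keep])
        rows.append({"seed": seed, "rho": r.statistic, "p": r.p_value,
                     "reject": r.p_value < alpha})
    return pd.DataFrame(rows)


def _ring_strain_map(layout) -> np.ndarray:
    """Deterministic edge-high strain map used as the studies' ground
    truth (mirrors the mechanical shielding pattern)."""
    t = layout.table
    ring = t["ring_label"].to_numpy().astype(float)
    corner = t["is_corner"].to_numpy().astype(float)
    base = ring / ring.max() + 0.3 * corner
    # small deterministic within-ring spread so ranks are unique
    jitter = 0.01 * np.sin(3.7 * np.arange(len(base)))
    return 0.05 * (0.2 + base + jitter)
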