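"""End-to-end orchestration of the 2D-vs-3D morphometric analysis.

One call runs, in order: interpolation of missing landmarks, bilateral
asymmetry checks, midsagittal orientation and side averaging, diet
covariates, per-lever-subset 3D and 2D shape analyses (GPA, allometry
correction, tangent PCA, Procrustes ANOVAs, watershed vector
comparisons), 2D-3D shape-space correlations, the common 2D-3D shape
space (disparity ANCOVAs and cross-space vector comparisons), and the
kinematic branch (KT/LR estimates in 2D and 3D, size correction,
ANCOVAs/PERMANOVAs, kinematic PCA, cross-space vectors).

Every stochastic step draws its seed from the run's master seed in a
fixed order, so equal configurations give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import dimension, diet as diet_mod, gpa, kinematics, shape_stats
from .io import LandmarkDataset

__all__ = ["AnalysisOptions", "AnalysisReport", "run_analysis",
           "DEFAULT_SUBSETS"]

#: Landmark-number subsets for the trophic lever systems (config data).
DEFAULT_SUBSETS: dict[str, tuple[int, ...]] = {
    "op4": (1, 2, 3, 4),
    "mand": (3, 4, 5, 6),
    "max4": (3, 6, 7, 8),
    "complete": (1, 2, 3, 4, 5, 6, 7, 8),
}


@dataclass
class AnalysisOptions:
    """Tunable analysis parameters.

    ``n_perm`` applies to ANOVA-type tests, ``n_perm_pairwise`` to the
    vector comparisons (9,999 random permutations plus the observed
    arrangement = 10,000 total) and ``n_perm_mantel`` to Mantel tests
    (999 + observed = 1,000 total).  Joint-axis tilts are polar angles
    from Z in degrees, tilted within the YZ plane by default.
    """

    seed: int = 0
    n_perm: int = 999
    n_perm_pairwise: int = 9_999
    n_perm_mantel: int = 999
    subsets: dict = field(default_factory=lambda: dict(DEFAULT_SUBSETS))
    covariates: tuple = ("habitat", "diet_ld", "simpson")
    op4_input_axis_polar: float = 30.0
    max4_output_axis_polar: float = 20.0
    axis_azimuth: float = 0.0
    input_rotation: float = 10.0
    allometry_log_size: bool = True


@dataclass
class AnalysisReport:
    """Bundle of result tables; ``write`` exports them plus a manifest."""

    manifest: dict
    symmetry: dict
    diet: dict
    shape_anovas: pd.DataFrame
    pca_variance: pd.DataFrame
    vector_comparisons: dict
    correlations: pd.DataFrame
    common_space: dict
    kinematics: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ff = "%.10g"
        self.shape_anovas.to_csv(out / "shape_anovas.tsv", sep="\t",
                                 float_format=ff)
        self.pca_variance.to_csv(out / "pca_variance.tsv", sep="\t",
                                 float_format=ff)
        self.correlations.to_csv(out / "correlations_2d3d.tsv", sep="\t",
                                 float_format=ff)
        self.kinematics["estimates"].to_csv(out / "kinematic_estimates.tsv",
                                            sep="\t", float_format=ff)
        self.kinematics["anovas"].to_csv(out / "kinematic_anovas.tsv",
                                         sep="\t", float_format=ff)
        self.common_space["disparity_anovas"].to_csv(
            out / "disparity_anovas.tsv", sep="\t", float_format=ff)
        self.common_space["cross_space_vectors"].to_csv(
            out / "cross_space_vectors.tsv", sep="\t", float_format=ff)
        rows = []
        for key, vc in self.vector_comparisons.items():
            ang = vc.angles.copy()
            for a in ang.index:
                for b in ang.columns:
                    if a < b:
                        rows.append({
                            "analysis": key, "group_a": a, "group_b": b,
                            "angle_deg": ang.loc[a, b],
                            "p_angle": vc.p_angles.loc[a, b],
                            "magnitude_diff": vc.magnitude_diff.loc[a, b],
                            "p_magnitude": vc.p_magnitude.loc[a, b],
                        })
        pd.DataFrame(rows).to_csv(out / "watershed_vector_angles.tsv",
                                  sep="\t", index=False, float_format=ff)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


class _SeedStream:
    """Deterministic named seed draws from one master seed."""

    def __init__(self, master: int):
        self._rng = np.random.default_rng(master)
        self.log: dict[str, int] = {}

    def __call__(self, name: str) -> int:
        s = int(self._rng.integers(2 ** 31))
        self.log[name] = s
        return s


def _anova_rows(fit: shape_stats.RrppFit, **labels) -> list[dict]:
    rows = []
    for term, r in fit.table.iterrows():
        rows.append({**labels, "term": term, **r.to_dict(),
                     "n_perm": fit.n_perm, "seed": fit.seed})
    return rows


def _attach_diet_covariates(metadata: pd.DataFrame,
                            diet_table: diet_mod.DietTable | None
                            ) -> tuple[pd.DataFrame, dict]:
    """Per-specimen design frame with habitat plus population diet axes."""
    design = metadata.copy()
    design["habitat"] = design["habitat"].astype(str)
    design["watershed"] = design["watershed"].astype(str)
    diet_out: dict = {}
    if diet_table is None:
        return design, diet_out
    transformed = diet_mod.hellinger(diet_table)
    lda = diet_mod.diet_lda(transformed, diet_table.habitat,
                            diet_table.population)
    simpson = {}
    for pop in diet_table.population.unique():
        rows = diet_table.population == pop
        totals = diet_table.proportions.loc[rows.to_numpy()].sum(axis=0)
        simpson[pop] = diet_mod.gini_simpson(totals.to_numpy())
    popkey = design["watershed"] + "-" + design["habitat"]
    design["diet_ld"] = popkey.map(lda.population_means).astype(float)
    design["simpson"] = popkey.map(simpson).astype(float)
    diet_out = {
        "lda": lda,
        "classification_rate": lda.classification_rate,
        "population_diet_ld": lda.population_means,
        "population_simpson": pd.Series(simpson, name="simpson"),
    }
    return design, diet_out


def _kt_with_fallback(fn, *args, **kwargs) -> tuple[float, str]:
    """Evaluate KT with the jaw-opening sign, falling back to the other
    rotation sense if the mechanism locks."""
    rot = kwargs.pop("input_rotation")
    for sign in (1.0, -1.0):
        try:
            return fn(*args, input_rotation=sign * rot, **kwargs), ""
        except kinematics.MechanismError:
            continue
    return float("nan"), "locked in both senses"


def run_analysis(
    dataset3d: LandmarkDataset,
    diet_table: diet_mod.DietTable | None = None,
    options: AnalysisOptions | None = None,
    outdir=None,
) -> AnalysisReport:
    """Run the full 3D / 2D / common-space / kinematic analysis."""
    opt = options or AnalysisOptions()
    seeds = _SeedStream(opt.seed)

    # ---- data preparation -------------------------------------------
    ds = dataset3d
    if ds.has_missing():
        ds = gpa.tps_interpolate_missing(ds)
    design, diet_out = _attach_diet_covariates(
        ds.metadata.loc[ds.specimen_ids], diet_table)
    covariates = [c for c in opt.covariates
                  if c == "habitat" or c in design.columns]

    pairs = ds.pairs
    oriented = ds.copy()
    for i in range(ds.n_specimens):
        oriented.coords[i] = dimension.orient_midsagittal(
            ds.coords[i], pairs)

    symmetry = {
        "3d": gpa.symmetry_decompose(oriented, n_perm=opt.n_perm,
                                     seed=seeds("symmetry_3d")),
        "2d": gpa.symmetry_decompose(
            dimension.project_dataset(oriented, orient=False),
            n_perm=opt.n_perm, seed=seeds("symmetry_2d")),
    }

    one3d = gpa.side_average(oriented)          # one-sided, K=8, D=3
    one2d = dimension.project_dataset(one3d, orient=False)

    # ---- per-subset shape analyses ----------------------------------
    lm_index = {num: i for i, num in enumerate(range(1, 9))}
    anova_rows: list[dict] = []
    pca_rows: list[dict] = []
    vector_comparisons: dict = {}
    corr_rows: list[dict] = []
    common_out: dict = {"paired_distances": {}, "disparity_rows": [],
                        "cross_rows": []}

    for subset, numbers in opt.subsets.items():
        idx = [lm_index[n] for n in numbers]
        sub3 = one3d.subset_landmarks(idx)
        sub2 = one2d.subset_landmarks(idx)
        aligned = {}
        residual = {}
        for dim_name, sub in (("3d", sub3), ("2d", sub2)):
            al = gpa.gpa_align(sub)
            allo = gpa.allometry_residuals(al, log_size=opt.allometry_log_size)
            aligned[dim_name] = al
            residual[dim_name] = allo
            pca = gpa.tangent_pca(allo)
            for pc in range(min(4, len(pca.variance_fractions))):
                pca_rows.append({"subset": subset, "space": dim_name,
                                 "pc": pc + 1,
                                 "variance_fraction":
                                     pca.variance_fractions[pc]})
            y = allo.flat()
            for cov in covariates:
                terms = ["watershed", cov, f"watershed:{cov}"]
                fit = shape_stats.rrpp_fit(
                    y, design, terms, n_perm=opt.n_perm,
                    seed=seeds(f"anova_{subset}_{dim_name}_{cov}"))
                anova_rows += _anova_rows(fit, subset=subset,
                                          space=dim_name, model=cov)
                if cov != "habitat":
                    vector_comparisons[f"{subset}_{dim_name}_{cov}"] = \
                        shape_stats.pairwise_vectors(
                            fit, "watershed", cov,
                            n_perm=opt.n_perm_pairwise,
                            seed=seeds(f"pair_{subset}_{dim_name}_{cov}"))
            if {"diet_ld", "simpson"} <= set(design.columns):
                fit = shape_stats.rrpp_fit(
                    y, design, ["diet_ld", "simpson", "diet_ld:simpson"],
                    n_perm=opt.n_perm,
                    seed=seeds(f"anova_{subset}_{dim_name}_type_div"))
                anova_rows += _anova_rows(fit, subset=subset,
                                          space=dim_name,
                                          model="diet_ld*simpson")

        # 2D-3D shape-space correlations
        r_cons, p_cons = shape_stats.distance_correlation_2d3d(
            residual["2d"], residual["3d"])
        d2 = squareform(pdist(residual["2d"].coords.reshape(
            sub2.n_specimens, -1)))
        d3 = squareform(pdist(residual["3d"].coords.reshape(
            sub3.n_specimens, -1)))
        r_man, p_man = shape_stats.mantel(
            d2, d3, n_perm=opt.n_perm_mantel, seed=seeds(f"mantel_{subset}"))
        corr_rows.append({"subset": subset,
                          "consensus_distance_r": r_cons,
                          "consensus_distance_p": p_cons,
                          "mantel_r": r_man, "mantel_p": p_man})

        # common 2D-3D shape space
        common = dimension.build_common_space(sub3, sub2)
        dists = dimension.paired_2d3d_distances(common)
        common_out["paired_distances"][subset] = dists
        frame = common.frame(design)
        for cov in covariates:
            if cov == "habitat":
                continue
            fit = shape_stats.disparity_ancova(
                dists.to_numpy(), design, cov, n_perm=opt.n_perm,
                seed=seeds(f"disparity_{subset}_{cov}"))
            common_out["disparity_rows"] += _anova_rows(
                fit, subset=subset, model=cov)
            cfit = shape_stats.rrpp_fit(
                common.aligned.flat(), frame,
                ["space", cov, f"space:{cov}"], n_perm=opt.n_perm,
                seed=seeds(f"common_{subset}_{cov}"))
            cross = shape_stats.compare_vectors_across_spaces(
                cfit, cov, dim="space", within="watershed",
                n_perm=opt.n_perm_pairwise,
                seed=seeds(f"cross_{subset}_{cov}"))
            ov = cross["overall"]
            common_out["cross_rows"].append({
                "subset": subset, "model": cov, "watershed": "(all)",
                "angle_deg": ov.angles.iloc[0, 1],
                "p_angle": ov.p_angles.iloc[0, 1],
                "magnitude_diff": ov.magnitude_diff.iloc[0, 1],
                "p_magnitude": ov.p_magnitude.iloc[0, 1]})
            for _, row in cross["per_group"].iterrows():
                common_out["cross_rows"].append({
                    "subset": subset, "model": cov,
                    "watershed": row["watershed"],
                    "angle_deg": row["angle_deg"],
                    "p_angle": row["p_angle"],
                    "magnitude_diff": row["magnitude_diff"],
                    "p_magnitude": row["p_magnitude"]})

    # ---- kinematics --------------------------------------------------
    kin = _kinematic_branch(one3d, one2d, design, covariates, opt, seeds)

    # ---- bundle ------------------------------------------------------
    opt_dict = {k: (v if np.isscalar(v) or isinstance(v, (tuple, str))
                    else str(v)) for k, v in asdict(opt).items()}
    manifest = {
        "seed": opt.seed,
        "stage_seeds": seeds.log,
        "n_perm": opt.n_perm,
        "n_perm_pairwise": opt.n_perm_pairwise,
        "n_specimens": ds.n_specimens,
        "options": {k: str(v) for k, v in opt_dict.items()},
        "config_hash": hashlib.sha256(
            json.dumps(opt_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": _versions(),
    }
    report = AnalysisReport(
        manifest=manifest,
        symmetry=symmetry,
        diet=diet_out,
        shape_anovas=pd.DataFrame(anova_rows),
        pca_variance=pd.DataFrame(pca_rows),
        vector_comparisons=vector_comparisons,
        correlations=pd.DataFrame(corr_rows),
        common_space={
            "paired_distances": common_out["paired_distances"],
            "disparity_anovas": pd.DataFrame(common_out["disparity_rows"]),
            "cross_space_vectors": pd.DataFrame(common_out["cross_rows"]),
        },
        kinematics=kin,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def _kinematic_branch(one3d, one2d, design, covariates, opt, seeds) -> dict:
    n = one3d.n_specimens
    op4_axis = kinematics.axis_from_angles(opt.op4_input_axis_polar,
                                           opt.axis_azimuth)
    max4_axis = kinematics.axis_from_angles(opt.max4_output_axis_polar,
                                            opt.axis_azimuth)
    z_axis = np.array([0.0, 0.0, 1.0])
    rows, notes = [], []
    for i, sid in enumerate(one3d.specimen_ids):
        cfg3 = one3d.coords[i]
        cfg2 = one2d.coords[i]
        op4_3, max4_3, lever3 = kinematics.build_linkages(cfg3)
        op4_2, max4_2, lever2 = kinematics.build_linkages(cfg2)
        kt_op4_3d, n1 = _kt_with_fallback(
            kinematics.spatial_kt, op4_3, op4_axis, z_axis,
            input_rotation=opt.input_rotation)
        kt_max4_3d, n2 = _kt_with_fallback(
            kinematics.spatial_kt, max4_3, z_axis, max4_axis,
            input_rotation=opt.input_rotation)
        kt_op4_2d, n3 = _kt_with_fallback(
            kinematics.planar_kt, op4_2, input_rotation=opt.input_rotation)
        kt_max4_2d, n4 = _kt_with_fallback(
            kinematics.planar_kt, max4_2, input_rotation=opt.input_rotation)
        lr_open_3d, lr_close_3d = kinematics.lever_ratios(lever3)
        lr_open_2d, lr_close_2d = kinematics.lever_ratios(lever2)
        for note in (n1, n2, n3, n4):
            if note:
                notes.append(f"{sid}: {note}")
        rows.append({
            "specimen_id": sid,
            "kt_op4_2d": kt_op4_2d, "kt_op4_3d": kt_op4_3d,
            "kt_max4_2d": kt_max4_2d, "kt_max4_3d": kt_max4_3d,
            "lr_open_2d": lr_open_2d, "lr_open_3d": lr_open_3d,
            "lr_close_2d": lr_close_2d, "lr_close_3d": lr_close_3d,
            "cs_3d": gpa.centroid_size(cfg3),
            "cs_2d": gpa.centroid_size(cfg2),
        })
    est = pd.DataFrame(rows).set_index("specimen_id")

    resid = {}
    for dim_name in ("2d", "3d"):
        cols = [f"kt_op4_{dim_name}", f"kt_max4_{dim_name}",
                f"lr_open_{dim_name}", f"lr_close_{dim_name}"]
        block = pd.DataFrame(index=est.index)
        for c in cols:
            block[c.replace(f"_{dim_name}", "")] = \
                kinematics.size_correct_function(
                    est[c].to_numpy(), est[f"cs_{dim_name}"].to_numpy())
        resid[dim_name] = block

    anova_rows = []
    stats_out = {}
    for dim_name in ("2d", "3d"):
        for cov in covariates:
            terms = ["watershed", cov, f"watershed:{cov}"]
            res = kinematics.kinematic_stats(
                resid[dim_name], design, terms, n_perm=opt.n_perm,
                seed=seeds(f"kin_{dim_name}_{cov}"))
            stats_out[(dim_name, cov)] = res
            for var, fit in res["univariate"].items():
                anova_rows += _anova_rows(fit, space=dim_name, model=cov,
                                          variable=var)
            anova_rows += _anova_rows(res["multivariate"], space=dim_name,
                                      model=cov, variable="(multivariate)")

    # 2D-vs-3D kinematic vectors in a shared functional space
    both = pd.concat([resid["2d"], resid["3d"]])
    frame = pd.concat([design.loc[est.index]] * 2).reset_index(drop=True)
    frame["space"] = ["2d"] * n + ["3d"] * n
    cross_rows = []
    for cov in covariates:
        if cov == "habitat":
            continue
        fit = shape_stats.rrpp_fit(
            both.to_numpy(), frame, ["space", cov, f"space:{cov}"],
            n_perm=opt.n_perm, seed=seeds(f"kin_common_{cov}"))
        cross = shape_stats.compare_vectors_across_spaces(
            fit, cov, dim="space", within="watershed",
            n_perm=opt.n_perm_pairwise, seed=seeds(f"kin_cross_{cov}"))
        ov = cross["overall"]
        cross_rows.append({"model": cov, "watershed": "(all)",
                           "angle_deg": ov.angles.iloc[0, 1],
                           "p_angle": ov.p_angles.iloc[0, 1],
                           "magnitude_diff": ov.magnitude_diff.iloc[0, 1],
                           "p_magnitude": ov.p_magnitude.iloc[0, 1]})
        for _, row in cross["per_group"].iterrows():
            cross_rows.append({"model": cov, "watershed": row["watershed"],
                               "angle_deg": row["angle_deg"],
                               "p_angle": row["p_angle"],
                               "magnitude_diff": row["magnitude_diff"],
                               "p_magnitude": row["p_magnitude"]})

    pca_loadings = stats_out[("3d", covariates[0])]["pca_loadings"]
    return {
        "estimates": est,
        "residuals": resid,
        "anovas": pd.DataFrame(anova_rows),
        "stats": stats_out,
        "cross_space_vectors": pd.DataFrame(cross_rows),
        "pca_loadings": pca_loadings,
        "notes": notes,
    }


def habitat_recovery_experiment(
    n_replicates: int = 100,
    effect_norm: float = 0.2,
    z_fraction: float = 0.5,
    n_perm: int = 199,
    seed: int = 0,
    spaces: tuple = ("3d",),
    config_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Replicated habitat-effect detection/recovery on generator data.

    Each replicate draws a fresh lake-stream dataset (habitat effect of
    the given norm and width fraction, no watershed x habitat interaction
    so the habitat null is exact), runs the shape branch (orientation,
    side averaging, projection for the 2D space, GPA, allometric
    correction) and tests the habitat term in a watershed + habitat RRPP
    model.  Returns one row per replicate with the habitat p-value per
    space and, for the 3D space, the angle between the fitted habitat
    contrast and the generator's true effect vector.

    With ``effect_norm=0`` the rejection rate at alpha estimates the
    test's type-I error; with an effect it estimates power.
    """
    from . import simulate as sim
    from .gpa import optimal_rotation, similarity_tangent_project

    kwargs = dict(habitat_effect_norm=effect_norm,
                  habitat_effect_z_fraction=z_fraction,
                  interaction_sd=0.0)
    kwargs.update(config_kwargs or {})
    base = np.random.SeedSequence(seed)
    rep_seeds = base.generate_state(2 * n_replicates) % (2 ** 31)
    rows = []
    for r in range(n_replicates):
        cfg = sim.SimulationConfig(seed=int(rep_seeds[2 * r]), **kwargs)
        ds, truth = sim.simulate_landmarks(cfg)
        oriented = ds.copy()
        for i in range(ds.n_specimens):
            oriented.coords[i] = dimension.orient_midsagittal(
                ds.coords[i], ds.pairs)
        one3d = gpa.side_average(oriented)
        datasets = {"3d": one3d}
        if "2d" in spaces:
            datasets["2d"] = dimension.project_dataset(one3d, orient=False)
        row: dict = {"replicate": r}
        design = ds.metadata.loc[ds.specimen_ids].reset_index()
        for space in spaces:
            aligned = gpa.gpa_align(datasets[space])
            allo = gpa.allometry_residuals(aligned)
            fit = shape_stats.rrpp_fit(
                allo.flat(), design, ["watershed", "habitat"],
                n_perm=n_perm, seed=int(rep_seeds[2 * r + 1]))
            row[f"p_{space}"] = fit.table.loc["habitat", "p_perm"]
            if space == "3d" and effect_norm > 0:
                lake = (design["habitat"] == "lake").to_numpy()
                fitted = (allo.residuals[~lake].mean(axis=0)
                          - allo.residuals[lake].mean(axis=0))
                # bring the true left-side effect pattern into the
                # consensus frame via the template's superimposition
                tmpl = truth["template"][:8]
                t0 = tmpl - tmpl.mean(axis=0)
                s = np.sqrt((t0 ** 2).sum())
                t0 = t0 / s
                rot = optimal_rotation(t0, aligned.consensus)
                v = (truth["habitat_effect"][:8] / s) @ rot
                v = similarity_tangent_project(v, aligned.consensus)
                cos = np.clip(
                    (fitted.ravel() @ v.ravel())
                    / (np.linalg.norm(fitted) * np.linalg.norm(v)), -1, 1)
                row["angle_deg"] = float(np.degrees(np.arccos(cos)))
        rows.append(row)
    return pd.DataFrame(rows)


def _versions() -> dict:
    import numpy, pandas, scipy
    from . import __version__
    return {"morphodim": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}
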