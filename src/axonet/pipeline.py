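"""End-to-end pipeline driver.

Chains the stages in the reference order: synthetic generation (or file
input) -> connectome QC -> edge models + NBS (and threshold sweep) ->
ROI volume models -> robust component-level clinical regressions ->
bootstrap mediation. Writes delimited-text and JSON reports plus a run
manifest declaring every decided default, so no analysis choice is
silent. All randomness derives from the single config seed through
``numpy.random.SeedSequence`` spawning (documented order: cohort,
volumes, connectomes, NBS permutations, mediation bootstrap).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, generate_roi_volumes, \
    generate_connectomes
from .connectome import qc_connectomes, read_connectome
from .io import RunConfig, read_participants, read_manifest, \
    write_participants
from .nbs import NBS
from .clinical import (Mediation, RobustComponentModel, impute_lod,
                       exclude_outliers, mean_component_connectivity)
from .volumes import VolumeModel, compare_groups

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_CLINICAL_PREDICTORS = ["bmi_sds", "illness_duration", "leptin_imputed",
                        "bdi2", "edi_dt", "edi_bd"]


def _load_inputs(config: RunConfig, seeds):
    if config.synthetic:
        cc = CohortConfig(n_per_group=config.n_per_group,
                          seed=int(seeds[0].generate_state(1)[0] % 2**31))
        cohort = generate_cohort(cc)
        volumes = generate_roi_volumes(
            cohort, seed=int(seeds[1].generate_state(1)[0] % 2**31))
        # default planting: one five-edge component, mediation-designated
        comp = [(0, 1), (1, 2), (1, 3), (3, 4), (4, 5)]
        conns = generate_connectomes(
            cohort, n_nodes=config.n_nodes,
            planted_components=[comp], mediation_components=[comp],
            seed=int(seeds[2].generate_state(1)[0] % 2**31))
        matrices = {pid: pair[config.weight_kind]
                    for pid, pair in conns.items()}
    else:
        cohort = read_participants(config.participants_path)
        volumes = pd.read_csv(config.volumes_path, sep="\t", index_col=0)
        manifest = read_manifest(config.manifest_path)
        matrices = {pid: read_connectome(paths[config.weight_kind],
                                         weight_kind=config.weight_kind)
                    for pid, paths in manifest.items()}
    return cohort, volumes, matrices


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger("axonet").addHandler(fh)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    stage = "input"
    try:
        cohort, volumes, matrices = _load_inputs(config, seeds)
        write_participants(out / "participants.tsv", cohort)

        stage = "outlier_exclusion"
        keep = exclude_outliers(cohort["log_nfl"].to_numpy(),
                                cohort["group"].to_numpy(),
                                k=config.outlier_sd_exclusion)
        cohort = cohort.loc[keep].reset_index(drop=True)
        volumes = volumes.loc[cohort["id"]]
        matrices = {p: matrices[p] for p in cohort["id"]}

        stage = "group_comparison"
        comparison = compare_groups(cohort)
        comparison.table.to_csv(out / "group_comparisons.tsv", sep="\t")

        stage = "qc"
        qc = qc_connectomes(matrices,
                            cohort.set_index("id")["group"],
                            config.qc_presence_threshold,
                            config.qc_outlier_sd,
                            config.qc_max_missing)
        qc.summary().to_csv(out / "qc_report.tsv", sep="\t")

        stage = "volume_models"
        vres = VolumeModel(volumes, cohort, group=config.group).fit()
        vres.summary().to_csv(out / "volume_models.tsv", sep="\t")

        stage = "nbs"
        grp = cohort[cohort["group"] == config.group].set_index("id")
        covs = pd.DataFrame({
            "wm_volume": volumes.loc[grp.index, "CorticalWhiteMatter"],
            "motion": grp["motion"],
            "age": grp["age"],
        })[list(config.nbs_covariates)]
        mats = {p: matrices[p] for p in grp.index}
        if config.weight_kind == "NOS":
            from .connectome import ConnectivityMatrix
            mats = {p: ConnectivityMatrix(np.log1p(m.values), "NOS",
                                          m.labels)
                    for p, m in mats.items()}
        mask = qc.edge_mask[config.group]
        model = NBS(mats, grp["log_nfl"], covs, edge_mask=mask)
        nbs_seed = int(seeds[3].generate_state(1)[0] % 2**31)
        res = model.fit(config.threshold, config.n_perm, config.direction,
                        seed=nbs_seed, alpha=config.alpha)
        res.summary().to_csv(out / "nbs_components.tsv", sep="\t",
                             index=False)
        labels = next(iter(mats.values())).labels
        comp_report = [
            {"component": i + 1, "fwe_p": c.fwe_p, "n_edges": c.size,
             "edges": c.edge_table(labels).to_dict("records")}
            for i, c in enumerate(res.components)]
        (out / "nbs_components.json").write_text(
            json.dumps(comp_report, indent=1))
        np.savetxt(out / "nbs_null_distribution.txt", res.null_max_size,
                   fmt="%d")
        sweep = model.threshold_sweep(
            sorted({round(config.threshold + d, 2) for d in (-0.7, 0.0, 0.8)}),
            n_perm=max(100, config.n_perm // 10), direction=config.direction,
            seed=nbs_seed)
        sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)

        stage = "clinical"
        sig = res.significant
        mediation_report = {}
        if sig:
            mean_conn = pd.DataFrame(
                {f"C{config.weight_kind}{i + 1}":
                 {p: mean_component_connectivity(mats[p], c)
                  for p in grp.index}
                 for i, c in enumerate(sig)})
            grp = grp.copy()
            grp["wm_volume"] = volumes.loc[grp.index, "CorticalWhiteMatter"]
            grp["leptin_imputed"] = impute_lod(
                grp["leptin"].to_numpy(),
                grp.get("leptin_censored", pd.Series(False, grp.index)
                        ).to_numpy(bool),
                lod=config.lod, method=config.imputation_method,
                seed=int(seeds[4].generate_state(1)[0] % 2**31))
            preds = [p for p in _CLINICAL_PREDICTORS
                     if p in grp.columns and grp[p].notna().sum() >= 10]
            rob = RobustComponentModel(
                mean_conn, grp.reset_index(),
                predictors=preds,
                nuisances=("age", "wm_volume", "motion")).fit()
            rob.table.to_csv(out / "component_clinical.tsv", sep="\t",
                             index=False)

            stage = "mediation"
            for comp_name in mean_conn.columns:
                med = Mediation(grp["leptin_imputed"], mean_conn[comp_name],
                                grp["log_nfl"],
                                estimator="ols").fit(
                    n_boot=config.n_boot,
                    seed=int(seeds[4].generate_state(1)[0] % 2**31))
                mediation_report[comp_name] = {
                    "summary": med.summary().reset_index().to_dict("records"),
                    "paths": med.paths, "n": med.n}
            pd.concat({k: pd.DataFrame(v["summary"]).set_index("effect")
                       for k, v in mediation_report.items()}
                      ).to_csv(out / "mediation.tsv", sep="\t")
        else:
            logger.info("no significant components; clinical and mediation "
                        "stages have nothing to test")
            (out / "component_clinical.tsv").write_text(
                "predictor\tcomponent\tstd_beta\tp\tq\n")
            (out / "mediation.tsv").write_text("")

        stage = "manifest"
        manifest = {
            "axonet_version": __version__,
            "seed": config.seed,
            "stream_splitting": "SeedSequence(seed).spawn(5): cohort, "
                                "volumes, connectomes, nbs, mediation",
            "defaults": {
                "threshold": config.threshold, "n_perm": config.n_perm,
                "alpha": config.alpha, "direction": config.direction,
                "imputation_method": config.imputation_method,
                "lod": config.lod, "estimator": config.estimator,
                "fdr_method": config.fdr_method,
                "qc_presence_threshold": config.qc_presence_threshold,
                "qc_outlier_sd": config.qc_outlier_sd,
                "qc_max_missing": config.qc_max_missing,
                "outlier_sd_exclusion": config.outlier_sd_exclusion,
                "volume_tests": config.volume_tests,
                "component_tests": config.component_tests,
            },
            "n_participants": int(len(cohort)),
            "n_significant_components": len(sig),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest,
                                                          indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("axonet").removeHandler(fh)
        fh.close()
    return out
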