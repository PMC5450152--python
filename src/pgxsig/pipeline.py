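"""End-to-end pipeline orchestration: stages I-IV in sequence with
deterministic artifacts."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from pgxsig import bma, characterize, evaluate, io, phenotypes, qc, screen, simulate
from pgxsig.datatypes import ClinicalTable, GenotypeMatrix, PgxError, SignatureModel

log = logging.getLogger("pgxsig")

ALL_STAGES = ("simulate", "label", "qc", "screen", "fit", "evaluate", "characterize")


class PipelineError(PgxError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": list(ALL_STAGES),
    "simulate": {
        "cohorts": {
            "GALA": {"n_subjects": 400, "arm": "active"},
            "FORTE": {"n_subjects": 300, "arm": "active"},
            "PLACEBO": {"n_subjects": 200, "arm": "placebo"},
        },
        "n_snps": 11,
        "maf": 0.25,
        "coefficients": [-0.68, -0.52, -0.61, -1.46],
        "intercept": 1.5,
    },
    "qc": {"call_rate_min": 0.95, "hwe_alpha": 1.0e-4},
    "screen": {
        "steps": [
            {"step_id": 1, "thresholds": {"GALA": 0.05, "FORTE": 0.05}},
            {
                "step_id": 4,
                "thresholds": {"GALA": 0.01, "FORTE": 0.05},
                "phenotype": "highest_extreme",
            },
        ],
        "placebo_alpha": 0.05,
        "placebo_cohort": "PLACEBO",
        "discovery_cohorts": ["GALA", "FORTE"],
    },
    "fit": {
        "n_iterations": 50_000,
        "burn_in_fraction": 0.1,
        "expected_model_size": 5.0,
        "pip_min": 0.80,
    },
}


def _simulate_cohorts(cfg: dict, seed: int) -> dict[str, tuple[GenotypeMatrix, ClinicalTable]]:
    sim = cfg["simulate"]
    coefs = tuple(sim.get("coefficients", ()))
    codings = tuple(sim.get("codings", ()))
    specs = simulate.default_snp_specs(
        sim.get("n_snps", 11), sim.get("maf", 0.25), coefs, codings
    )
    out = {}
    for k, (name, spec) in enumerate(sorted(sim["cohorts"].items())):
        config = simulate.SimulationConfig(
            n_subjects=spec["n_subjects"],
            snp_specs=specs,
            intercept=sim.get("intercept", 1.5),
            placebo_flag=spec.get("arm", "active") == "placebo",
            cohort=name,
            seed=seed * 1000 + k,
        )
        out[name] = simulate.simulate_cohort(config)
    return out


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages in order, writing per-stage artifacts.

    Returns a manifest of artifact paths.  Re-running with an identical
    config reproduces identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(ALL_STAGES))
    seed = int(config.get("seed", 1))
    fingerprint = io.config_fingerprint(config)
    manifest: dict = {"config_fingerprint": fingerprint, "artifacts": {}}
    log.info("run_pipeline seed=%d fingerprint=%s stages=%s", seed, fingerprint, stages)

    io.dump_yaml_config(config, outdir / "config.yaml")
    manifest["artifacts"]["config"] = str(outdir / "config.yaml")

    # ---- stage 0: inputs ---------------------------------------------
    cohorts: dict[str, tuple[GenotypeMatrix, ClinicalTable]] = {}
    if "simulate" in stages:
        cohorts = _simulate_cohorts(config, seed)
        for name, (geno, clin) in cohorts.items():
            io.write_vcf(geno, outdir / f"{name}.vcf")
            clin.to_csv(outdir / f"{name}.clinical.csv")
            manifest["artifacts"][f"genotypes_{name}"] = str(outdir / f"{name}.vcf")
            manifest["artifacts"][f"clinical_{name}"] = str(
                outdir / f"{name}.clinical.csv"
            )
    elif "inputs" in config:
        for name, paths in config["inputs"].items():
            geno = io.read_genotypes(paths["genotypes"])
            clin = ClinicalTable.from_csv(paths["clinical"])
            cohorts[name] = (geno, clin)
    else:
        raise PipelineError("simulate", "no simulation enabled and no inputs given")

    # ---- labels ------------------------------------------------------
    labels: dict[str, pd.DataFrame] = {}
    if "label" in stages:
        for name, (_, clin) in cohorts.items():
            lab = phenotypes.compute_labels(clin)
            labels[name] = lab
            path = outdir / f"{name}.labels.csv"
            lab.to_csv(path)
            manifest["artifacts"][f"labels_{name}"] = str(path)

    scr_cfg = config.get("screen", {})
    discovery = scr_cfg.get("discovery_cohorts") or list(cohorts)[:2]
    placebo_name = scr_cfg.get("placebo_cohort")

    # ---- QC ----------------------------------------------------------
    if "qc" in stages:
        qc_cfg = config.get("qc", {})
        call_rate_min = qc_cfg.get("call_rate_min", 0.95)
        hwe_alpha = qc_cfg.get("hwe_alpha", 1e-4)
        # HWE verdicts come from the reference (placebo) cohort when one
        # exists; call-rate verdicts are per cohort.  A SNP survives only
        # if it passes in every cohort.
        hwe_name = placebo_name if placebo_name in cohorts else discovery[0]
        reports = []
        keep: set[str] | None = None
        for name, (geno, clin) in cohorts.items():
            report = qc.qc_report(
                geno,
                call_rate_min=call_rate_min,
                hwe_alpha=hwe_alpha if name == hwe_name else 0.0,
            )
            reports.append(report.assign(cohort=name))
            kept = set(report.index[report["verdict"] == "keep"])
            keep = kept if keep is None else keep & kept
        surviving = [s for s in cohorts[hwe_name][0].snp_ids if s in (keep or set())]
        cohorts = {
            name: (geno.subset(snps=surviving), clin)
            for name, (geno, clin) in cohorts.items()
        }
        qc_path = outdir / "qc_report.tsv"
        io.write_tsv(pd.concat(reports), qc_path, fingerprint)
        manifest["artifacts"]["qc_report"] = str(qc_path)

    # ---- stage I: association funnel + placebo filter ----------------
    selected: list[str] = []
    codings: dict[str, str] = {}
    if "screen" in stages:
        if not labels:
            raise PipelineError("screen", "labels stage is required before screening")
        steps = [
            screen.FunnelStep(
                step_id=s["step_id"],
                thresholds=s["thresholds"],
                candidate_set=tuple(s["candidate_set"])
                if s.get("candidate_set")
                else None,
                phenotype=s.get("phenotype", "extreme"),
            )
            for s in scr_cfg.get("steps", [])
        ]
        funnel_input = {name: (cohorts[name][0], labels[name]) for name in discovery}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            funnel = screen.run_funnel(funnel_input, steps)
        selected, codings = funnel.selected, funnel.codings
        if placebo_name and placebo_name in cohorts and selected:
            selected, placebo_report = screen.placebo_filter(
                selected,
                cohorts[placebo_name][0],
                labels[placebo_name],
                alpha_prognostic=scr_cfg.get("placebo_alpha", 0.05),
                codings=codings,
            )
            io.write_tsv(placebo_report, outdir / "placebo_filter.tsv", fingerprint)
            manifest["artifacts"]["placebo_filter"] = str(outdir / "placebo_filter.tsv")
        screen_path = outdir / "screen_results.tsv"
        io.write_tsv(funnel.provenance, screen_path, fingerprint)
        (outdir / "selected_snps.json").write_text(
            json.dumps({"selected": selected, "codings": codings}, indent=2, sort_keys=True)
            + "\n"
        )
        manifest["artifacts"]["screen_results"] = str(screen_path)
        manifest["artifacts"]["selected_snps"] = str(outdir / "selected_snps.json")

    # ---- stage II: spike-and-slab BMA --------------------------------
    model_path = outdir / "signature_model.json"
    if "fit" in stages:
        if not selected:
            raise PipelineError("fit", "no SNPs selected by the screening stage")
        fit_cfg = config.get("fit", {})
        design, outcome, covs = _stage2_design(cohorts, labels, discovery, selected, codings)
        ss_config = bma.SpikeSlabConfig(
            n_iterations=int(fit_cfg.get("n_iterations", 50_000)),
            burn_in_fraction=float(fit_cfg.get("burn_in_fraction", 0.1)),
            expected_model_size=float(fit_cfg.get("expected_model_size", 5.0)),
            seed=seed,
        )
        post_without = bma.fit_spike_slab(design, outcome, ss_config)
        post_with = bma.fit_spike_slab(
            pd.concat([design, covs], axis=1), outcome, ss_config
        )
        signature = bma.select_signature(
            post_with, post_without, snp_terms=list(design.columns),
            pip_min=float(fit_cfg.get("pip_min", 0.80)),
        )
        io.write_tsv(post_without.summary(), outdir / "posterior_no_covariates.tsv", fingerprint)
        io.write_tsv(post_with.summary(), outdir / "posterior_with_covariates.tsv", fingerprint)
        io.write_tsv(bma.diagnostics(post_without), outdir / "mcmc_diagnostics.tsv", fingerprint)
        manifest["artifacts"]["posterior_no_covariates"] = str(
            outdir / "posterior_no_covariates.tsv"
        )
        manifest["artifacts"]["posterior_with_covariates"] = str(
            outdir / "posterior_with_covariates.tsv"
        )
        if not signature:
            raise PipelineError("fit", "no SNP met the signature selection rule")
        model = bma.refit_final(design[signature], outcome, codings=codings)
        model.meta["config_fingerprint"] = fingerprint
        model.meta["seed"] = seed
        model.to_json(model_path)
        manifest["artifacts"]["signature_model"] = str(model_path)

    # ---- stage III: evaluation ---------------------------------------
    if "evaluate" in stages:
        if not model_path.exists():
            raise PipelineError(
                "evaluate", "missing signature model (stage II disabled or failed)"
            )
        model = SignatureModel.from_json(model_path)
        eval_rows = {}
        disc_probs, disc_truth = _cohort_probs(model, cohorts, labels, discovery)
        roc = evaluate.roc_auc(disc_probs.to_numpy(), disc_truth)
        model.threshold = roc.top_left_threshold
        model.to_json(model_path)
        eval_rows["discovery"] = (disc_probs, disc_truth)
        for name in cohorts:
            if name in discovery:
                continue
            probs, truth = _cohort_probs(model, cohorts, labels, [name])
            if np.unique(truth[~np.isnan(truth)]).size == 2:
                eval_rows[name] = (probs, truth)
        perf = evaluate.performance_report(eval_rows, model.threshold)
        io.write_tsv(perf, outdir / "performance.tsv", fingerprint)
        manifest["artifacts"]["performance"] = str(outdir / "performance.tsv")

        sig = evaluate.classify_signature(disc_probs, model.threshold)
        clin_disc = _concat_clinical(cohorts, discovery)
        arr = evaluate.group_arr_change(sig, clin_disc)
        arr_summary = pd.DataFrame(
            [
                {
                    "group": evaluate.SIG_POS,
                    "relapses": arr.relapses_pos,
                    "exposure_years": arr.exposure_pos,
                    "mean_arr": arr.arr_pos,
                },
                {
                    "group": evaluate.SIG_NEG,
                    "relapses": arr.relapses_neg,
                    "exposure_years": arr.exposure_neg,
                    "mean_arr": arr.arr_neg,
                },
            ]
        ).set_index("group")
        arr_summary["percent_change"] = [arr.percent_change, 0.0]
        io.write_tsv(arr_summary, outdir / "group_arr.tsv", fingerprint)
        manifest["artifacts"]["group_arr"] = str(outdir / "group_arr.tsv")

    # ---- stage IV: characterization ----------------------------------
    if "characterize" in stages:
        if not model_path.exists():
            raise PipelineError(
                "characterize", "missing signature model (stage II disabled or failed)"
            )
        model = SignatureModel.from_json(model_path)
        disc_probs, _ = _cohort_probs(model, cohorts, labels, discovery)
        bins = characterize.quintile_bins(disc_probs)
        labels_disc = pd.concat([labels[name] for name in discovery])
        table = characterize.bin_summaries(
            bins, labels_disc, _concat_clinical(cohorts, discovery)
        )
        io.write_tsv(table, outdir / "bin_summaries.tsv", fingerprint)
        (outdir / "bin_summaries.json").write_text(
            table.to_json(orient="index", indent=2) + "\n"
        )
        manifest["artifacts"]["bin_summaries"] = str(outdir / "bin_summaries.tsv")

    # manifest records artifact names relative to the output directory so
    # identical runs are byte-identical wherever they land
    manifest["artifacts"] = {
        k: Path(v).name for k, v in manifest["artifacts"].items()
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _stage2_design(cohorts, labels, discovery, selected, codings):
    """Coded design + relapse-free outcome + baseline covariates for the
    pooled discovery cohorts."""
    genos = []
    outcome = []
    covs = []
    for name in discovery:
        geno, clin = cohorts[name]
        lab = labels[name]
        y = phenotypes.relapse_free_outcome(lab)
        cols = {}
        for snp in selected:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols[snp] = qc.encode_snp(
                    geno.column(snp), codings.get(snp, "additive")
                )
        genos.append(pd.DataFrame(cols, index=list(geno.subject_ids)))
        outcome.append(y)
        df = clin.df.set_index("subject_id")
        covs.append(
            pd.DataFrame(
                {
                    "baseline_edss": df["baseline_edss"],
                    "log_pre_relapses": np.log(df["pre_study_relapses"] + 1.0),
                    "baseline_t2_volume": df["baseline_t2_volume"],
                    "baseline_t1_status": df["baseline_t1_status"].astype(float),
                }
            )
        )
    design = pd.concat(genos)
    y = pd.concat(outcome).to_numpy(dtype=float)
    covariates = pd.concat(covs)
    return design, y, covariates


def _cohort_probs(model, cohorts, labels, names):
    probs = []
    truth = []
    for name in names:
        geno, _ = cohorts[name]
        p = evaluate.predict_probs(model, geno)
        y = phenotypes.relapse_free_outcome(labels[name])
        probs.append(p)
        truth.append(y.to_numpy(dtype=float))
    return pd.concat(probs), np.concatenate(truth)


def _concat_clinical(cohorts, names) -> ClinicalTable:
    frames = []
    for name in names:
        df = cohorts[name][1].df.copy()
        df.attrs = {}
        frames.append(df)
    return ClinicalTable(pd.concat(frames, ignore_index=True))
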