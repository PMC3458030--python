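"""End-to-end orchestration: simulate -> call CN -> breakpoints -> associate -> haplotype fits.

``run_study`` drives the whole chain from a single seeded configuration and
writes every intermediate product (cohort table, CN calls, breakpoint JSON,
association table, haplotype-regression reports) into an output directory.
Every random draw descends from the single top-level seed, and each output
carries the configuration hash, so a run is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import depthcn, haploreg, io, presets
from .assoc import MarkerDosage, conditional_regression, dosage_regression
from .breakhmm import call_breakpoints, correlation_statistic, fit_breakpoint_hmm
from .synthcohort import (
    CovariateSpec,
    DepthSimConfig,
    HaplotypeModel,
    simulate_cohort,
    simulate_depth,
)

__all__ = ["RunConfig", "run_study", "load_config", "save_config", "config_hash"]

logger = logging.getLogger("cnphap")


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run."""

    seed: int = 1
    n: int = 2000
    sigma_e: float = presets.CPD_RESIDUAL_SD
    model: str = "cpd_gwas"  # preset name, or "custom" with model_spec
    model_spec: dict | None = None
    use_covariates: bool = True
    depth: dict = field(default_factory=dict)  # DepthSimConfig overrides
    depth_n: int = 89  # samples carried into the depth/breakpoint stages
    tau: float = 1e-250
    n_boot: int = 50
    reference: str = "T/1"
    out_dir: str = "cnphap_run"

    def haplotype_model(self) -> HaplotypeModel:
        if self.model == "cpd_gwas":
            return presets.cpd_gwas_model()
        if self.model == "cpd_replication":
            return presets.cpd_replication_model()
        if self.model == "custom":
            if not self.model_spec:
                raise ValueError("model=custom requires model_spec")
            return HaplotypeModel.from_percent(**self.model_spec)
        raise ValueError(f"unknown model preset {self.model!r}")

    def depth_config(self) -> DepthSimConfig:
        return DepthSimConfig(**self.depth)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (the output path does not count)."""
    d = asdict(cfg)
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def _stage(name: str, log: list, t0: float) -> None:
    dt = time.perf_counter() - t0
    log.append({"stage": name, "seconds": round(dt, 3)})
    logger.info("stage %s finished in %.2fs", name, dt)


def run_study(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the report dict (also written to disk).

    Stages: cohort simulation; depth simulation on a subsample; depth
    normalisation, SVD region scoring and GMM copy-number calling; per-base
    correlation track and HMM breakpoint estimation; copy-number dosage
    association (plus SNP-conditional test); EM haplotype-specific linear
    regression with ANOVA explained variance and the LR test.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    save_config(cfg, out / "config.yaml")
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    stage_log: list[dict] = []
    report: dict = {"config_hash": chash, "seed": cfg.seed}

    # --- cohort ------------------------------------------------------------
    t0 = time.perf_counter()
    model = cfg.haplotype_model()
    cov_spec = CovariateSpec() if cfg.use_covariates else None
    cohort = simulate_cohort(
        model, cfg.n, sigma_e=cfg.sigma_e, seed=int(seeds[0]), covariate_spec=cov_spec
    )
    cohort_df = cohort.to_frame()
    cohort_df.insert(0, "config_hash", chash)
    io.write_cohort(cohort_df, out / "cohort.tsv")
    _stage("simulate_cohort", stage_log, t0)

    # --- depth + copy-number calls -----------------------------------------
    t0 = time.perf_counter()
    depth_cfg = cfg.depth_config()
    depth_idx = np.arange(min(cfg.depth_n, cohort.n))
    sub = cohort.subset(depth_idx)
    dm = simulate_depth(sub.total_cn, depth_cfg, seed=int(seeds[1]))
    nd = depthcn.normalize_depth(dm.depth, dm.chrom_mean, dm.positions)
    region = nd.region(depth_cfg.del_start, depth_cfg.del_end)
    scores = depthcn.region_score(region)
    calls = depthcn.call_cn_gmm(scores, seed=int(seeds[2]))
    cn_acc = float(np.mean(calls.cn == sub.total_cn))
    calls_df = pd.DataFrame(
        {
            "config_hash": chash,
            "sample_id": cohort_df["sample_id"].iloc[depth_idx].to_numpy(),
            "score": calls.scores,
            "cn_map": calls.cn,
            "true_cn": sub.total_cn,
        }
    )
    for k in range(calls.posteriors.shape[1]):
        calls_df[f"posterior_{k}"] = calls.posteriors[:, k]
    calls_df.to_csv(out / "cn_calls.tsv", sep="\t", index=False, float_format="%.6g")
    report["cn_call_accuracy"] = cn_acc
    report["cn_mixture"] = {
        "k": calls.mixture.k,
        "means": calls.mixture.means.tolist(),
        "weights": calls.mixture.weights.tolist(),
        "component_cn": calls.component_cn.tolist(),
    }
    _stage("depth_call", stage_log, t0)

    # --- breakpoints --------------------------------------------------------
    t0 = time.perf_counter()
    track = correlation_statistic(nd.values, calls.cn, nd.positions)
    hmm = fit_breakpoint_hmm(track, tau=cfg.tau)
    bp = call_breakpoints(hmm, track, n_boot=cfg.n_boot, seed=int(seeds[3]))
    bp_payload = bp.to_dict()
    bp_payload["true_deletion_1based"] = [depth_cfg.del_start + 1, depth_cfg.del_end]
    bp_payload["config_hash"] = chash
    io.write_json_report(out / "breakpoints.json", bp_payload)
    report["breakpoints"] = bp_payload
    _stage("breakpoints", stage_log, t0)

    # --- dosage association -------------------------------------------------
    t0 = time.perf_counter()
    covariates = cohort.covariates if cfg.use_covariates else None
    cnp = MarkerDosage(cohort.total_cn.astype(float), kind="cnp", marker_id="cnp")
    snp = MarkerDosage(cohort.snp_gt.astype(float), kind="snp", marker_id="snp")
    res_cnp = dosage_regression(cohort.phenotype, cnp, covariates)
    res_snp = dosage_regression(cohort.phenotype, snp, covariates)
    res_snp_cond = conditional_regression(cohort.phenotype, snp, [cnp], covariates)
    assoc_df = pd.DataFrame(
        [
            {"marker": r.marker_id, "test": t, "beta": r.beta, "se": r.se, "p": r.p, "n": r.n}
            for r, t in [
                (res_cnp, "marginal"),
                (res_snp, "marginal"),
                (res_snp_cond, "conditional_on_cnp"),
            ]
        ]
    )
    assoc_df.insert(0, "config_hash", chash)
    assoc_df.to_csv(out / "association.tsv", sep="\t", index=False, float_format="%.6g")
    report["association"] = assoc_df.drop(columns="config_hash").to_dict("records")
    _stage("association", stage_log, t0)

    # --- haplotype regression ----------------------------------------------
    t0 = time.perf_counter()
    fit = haploreg.fit_haplo_linear(
        cohort.phenotype,
        cohort.snp_gt,
        cohort.total_cn,
        covariates=covariates,
        reference=cfg.reference,
    )
    table1 = fit.summary_table()
    table1.insert(0, "config_hash", chash)
    table1.to_csv(out / "haplotype_linear.tsv", sep="\t", index=False, float_format="%.6g")
    anova = haploreg.anova_explained(fit, cohort.phenotype, covariates)
    null_fit = haploreg.fit_haplo_linear(
        cohort.phenotype,
        cohort.snp_gt,
        cohort.total_cn,
        covariates=covariates,
        reference=cfg.reference,
        null_model=True,
        compute_se=False,
    )
    df_test = int(np.sum(~np.isnan(fit.effects)) - 1)
    lr_stat, lr_p = haploreg.lr_test(fit.log_likelihood, null_fit.log_likelihood, df_test)
    report["haplotype_linear"] = {
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "sigma": float(np.sqrt(fit.sigma2)),
        "frequencies_pct": fit.frequency_percent(),
        "effects": {h.label: (None if np.isnan(e) else float(e)) for h, e in zip(fit.universe, fit.effects)},
        "explained_variance_pct": 100.0 * anova.explained_fraction,
        "anova_f": anova.f_stat,
        "anova_p": anova.p,
        "lr_stat": lr_stat,
        "lr_p": lr_p,
    }
    _stage("haploreg", stage_log, t0)

    # timings and versions go to the run log, never the (deterministic) report
    io.write_json_report(
        out / "run_log.json",
        {
            "config_hash": chash,
            "seed": cfg.seed,
            "package_version": __import__("cnphap").__version__,
            "stages": stage_log,
        },
    )
    io.write_json_report(out / "report.json", report)
    return report
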