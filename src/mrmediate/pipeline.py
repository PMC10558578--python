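"""Config-driven orchestration of the full sex-stratified analysis graph.

For each stratum x exposure the pipeline assembles instruments, runs the
univariable total-effect estimators with their sensitivity diagnostics,
the multivariable direct-effect estimators with conditional F / Q_A
(Q-het is always computed; the weak-instrument / heterogeneity trigger
only decides which estimate is labelled primary), and the difference-
method mediation decomposition, then writes one JSON + TSV report bundle
with full provenance (thresholds, seeds, package version).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import PhenotypeCorrelation
from .mediation import ObservationalMediation, difference_method, prepare_phenotypes
from .mvmr import MultivariableMR
from .sumstats import (assemble_mvmr_instruments, clump, harmonize,
                       read_ld_matrix, read_sumstats, summary_f_stat)
from .unimr import UnivariableMR, bh_confounder_filter


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    exposures: list[str]
    mediator: str
    outcome: str
    strata: list[str]
    #: trait -> stratum -> summary-statistics TSV path
    sumstats: dict[str, dict[str, str]]
    ld_path: str
    #: stratum -> exposure-mediator phenotypic correlation (Q-het weights)
    rho: dict[str, float] = field(default_factory=dict)
    #: exposure -> stratum -> SNP x confounder p-value TSV (optional)
    confounder_pvals: dict[str, dict[str, str]] = field(default_factory=dict)
    #: column-name mapping for the summary-statistics files (canonical ->
    #: file column), applied to every trait
    dialect: dict[str, str] = field(default_factory=dict)
    #: optional individual-level phenotype table for the observational arm
    phenotypes_path: str | None = None
    covariates: list[str] = field(default_factory=list)
    p_thr: float = 5e-8
    r2_thr: float = 0.001
    window_kb: int = 250
    proxy_r2_min: float = 0.8
    fdr: float = 0.05
    cooks_multiplier: float = 4.0
    n_boot: int = 2000
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed: the master seed combined with a CRC32
    of the stage label through a SeedSequence, folded below 2^31 so every
    stage is independently reproducible."""
    ss = np.random.SeedSequence([master, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def sensitivity_rerun(panel, flagged: list[str], which: str,
                      n_boot: int = 2000, seed: int = 0) -> dict:
    """Re-run the univariable estimators after excluding flagged SNPs.

    ``which`` labels the flag source ("confounder-associated" or
    "high-influence"). Estimators whose minimum SNP count is no longer
    met are reported as not estimable; the run continues. Returns a
    paired before/after table with deltas.
    """
    unknown = set(flagged) - set(panel.rsids)
    if unknown:
        raise ValueError(f"flagged rsids not in panel: {sorted(unknown)[:5]}")
    reduced = panel.drop(flagged)
    rows = []
    for method, min_k in (("ivw", 1), ("egger", 3), ("wme", 3)):
        before = UnivariableMR(panel).fit(method, n_boot=n_boot, seed=seed)
        row = {"method": before.method, "which": which,
               "beta_before": before.beta, "se_before": before.se,
               "k_before": before.k}
        if len(reduced) >= min_k and len(reduced) > 0:
            after = UnivariableMR(reduced).fit(method, n_boot=n_boot, seed=seed)
            row.update(beta_after=after.beta, se_after=after.se, k_after=after.k,
                       delta=after.beta - before.beta, estimable=True)
        else:
            row.update(beta_after=None, se_after=None, k_after=len(reduced),
                       delta=None, estimable=False)
        rows.append(row)
    return {"which": which, "flagged": list(flagged), "table": rows}


def _analyse_stratum_exposure(config: AnalysisConfig, stratum: str,
                              exposure: str, ld) -> dict:
    out: dict = {"stratum": stratum, "exposure": exposure}
    dialect = config.dialect or None
    exp_ss, _ = read_sumstats(config.sumstats[exposure][stratum], exposure,
                              stratum, dialect=dialect)
    med_ss, _ = read_sumstats(config.sumstats[config.mediator][stratum],
                              config.mediator, stratum, dialect=dialect)
    out_ss, _ = read_sumstats(config.sumstats[config.outcome][stratum],
                              config.outcome, stratum, dialect=dialect)

    # ---- univariable arm: the exposure's own clumped instrument
    exp_instr = clump(exp_ss, ld, p_thr=config.p_thr, r2_thr=config.r2_thr,
                      window_kb=config.window_kb)
    uni_panel, uni_report = harmonize([exp_instr, out_ss.subset(exp_instr.rsids)],
                                      exposure=exposure, outcome=config.outcome)
    uni = UnivariableMR(uni_panel)
    wme_seed = stage_seed(config.seed, f"{stratum}:{exposure}:wme")
    estimates = {
        "ivw": uni.fit("ivw"),
        "egger": uni.fit("egger"),
        "wme": uni.fit("wme", n_boot=config.n_boot, seed=wme_seed),
    }
    out["univariable"] = {k: v.to_row() for k, v in estimates.items()}
    out["univariable"]["instrument"] = {
        "k": len(uni_panel),
        "mean_f": summary_f_stat(uni_panel, exposure)[1],
        "r2": summary_f_stat(uni_panel, exposure)[2],
        "harmonization_dropped": uni_report.dropped,
    }
    out["leave_one_out"] = [
        {"omitted": rsid, "beta": est.beta, "se": est.se}
        for rsid, est in uni.leave_one_out()
    ]
    out["single_snp"] = uni.single_snp_table().to_dict(orient="records")
    cooks_flagged, cooks_table = uni.cooks_influence(
        threshold=config.cooks_multiplier / len(uni_panel))
    out["cooks"] = {"flagged": cooks_flagged,
                    "table": cooks_table.to_dict(orient="records")}

    conf_flagged: list[str] = []
    conf_cfg = config.confounder_pvals.get(exposure, {})
    if stratum in conf_cfg:
        pvals = pd.read_csv(conf_cfg[stratum], sep="\t", index_col=0)
        conf_flagged = bh_confounder_filter(pvals, fdr=config.fdr)
    out["confounder_flagged"] = conf_flagged

    # ---- sensitivity reruns on the univariable panel
    out["sensitivity"] = []
    for which, flagged in (("confounder-associated", conf_flagged),
                           ("high-influence", cooks_flagged)):
        present = [r for r in flagged if r in uni_panel.rsids]
        out["sensitivity"].append(
            sensitivity_rerun(uni_panel, present, which,
                              n_boot=config.n_boot, seed=wme_seed))

    # ---- multivariable arm
    lookups = {exposure: exp_ss, config.mediator: med_ss, config.outcome: out_ss}
    panel, assembly = assemble_mvmr_instruments(
        exp_ss, med_ss, ld, lookups, outcome=config.outcome,
        p_thr=config.p_thr, r2_thr=config.r2_thr, window_kb=config.window_kb,
        proxy_r2_min=config.proxy_r2_min)
    out["assembly"] = assembly.to_dict()
    model = MultivariableMR(panel)
    mvmr_ivw_res = model.fit("ivw")
    mvmr_egger_res = model.fit("egger")
    rho_val = config.rho.get(stratum, 0.0)
    rho = PhenotypeCorrelation([exposure, config.mediator],
                               np.array([[1.0, rho_val], [rho_val, 1.0]]),
                               stratum=stratum)
    qhet_res = model.fit("qhet", rho=rho, n_boot=config.n_boot,
                         seed=stage_seed(config.seed, f"{stratum}:{exposure}:qhet"))
    cond_f = mvmr_ivw_res.cond_f[exposure]
    weak = cond_f < 10 or mvmr_ivw_res.q_a > len(panel)
    out["mvmr"] = {
        "ivw": mvmr_ivw_res.to_rows(),
        "egger": mvmr_egger_res.to_rows(),
        "qhet": qhet_res.to_rows(),
        "conditional_f": mvmr_ivw_res.cond_f,
        "q_a": mvmr_ivw_res.q_a,
        "weak_instrument_trigger": bool(weak),
        "primary": "qhet" if weak else "ivw",
    }

    # ---- MR-arm mediation decomposition (primary direct-effect estimator)
    direct_res = qhet_res if weak else mvmr_ivw_res
    decomp = difference_method(estimates["ivw"], direct_res, exposure=exposure)
    out["mediation_mr"] = decomp.to_rows()
    return out


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stratum x exposure analysis; a hard error in one stratum
    is recorded as a structured error record and the others continue.
    Returns (and writes) the report bundle."""
    ld = read_ld_matrix(config.ld_path)
    bundle: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "thresholds": {
                "p_thr": config.p_thr, "r2_thr": config.r2_thr,
                "window_kb": config.window_kb,
                "proxy_r2_min": config.proxy_r2_min,
                "fdr": config.fdr, "cooks_multiplier": config.cooks_multiplier,
            },
        },
        "results": [],
        "errors": [],
    }

    pheno = None
    if config.phenotypes_path:
        pheno = pd.read_csv(config.phenotypes_path, sep="\t")

    for stratum in config.strata:
        for exposure in config.exposures:
            try:
                res = _analyse_stratum_exposure(config, stratum, exposure, ld)
            except Exception as exc:  # keep other strata running
                bundle["errors"].append({
                    "stratum": stratum, "exposure": exposure,
                    "stage": "analysis", "error": f"{type(exc).__name__}: {exc}",
                })
                continue
            if pheno is not None:
                try:
                    res["mediation_observational"] = _observational_arm(
                        config, pheno, stratum, exposure)
                except Exception as exc:
                    bundle["errors"].append({
                        "stratum": stratum, "exposure": exposure,
                        "stage": "observational", "error": f"{type(exc).__name__}: {exc}",
                    })
            bundle["results"].append(res)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2, sort_keys=True)
    _write_tidy_tsv(bundle, outdir / "estimates.tsv")
    return bundle


def _observational_arm(config: AnalysisConfig, pheno: pd.DataFrame,
                       stratum: str, exposure: str) -> list[dict]:
    sub = pheno[pheno["stratum"] == stratum] if "stratum" in pheno.columns else pheno
    table, _ = prepare_phenotypes(sub, exposure=exposure, mediator=config.mediator,
                                  covariates=config.covariates)
    model = ObservationalMediation.from_dataframe(
        table, exposure=f"{exposure}_std", mediator=f"log_{config.mediator}",
        outcome="grip", covariates=config.covariates, stratum=stratum)
    decomp, _ = model.fit()
    return decomp.to_rows()


def _write_tidy_tsv(bundle: dict, path) -> None:
    rows = []
    for res in bundle["results"]:
        for key in ("univariable",):
            for method in ("ivw", "egger", "wme"):
                rows.append(res[key][method])
        for method in ("ivw", "egger", "qhet"):
            rows.extend(res["mvmr"][method])
        rows.extend(res.get("mediation_mr", []))
        rows.extend(res.get("mediation_observational", []))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
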