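"""Synthetic cohorts and two-sample summary statistics under a known
exposure -> mediator -> outcome causal structure.

The generator emulates the study design this package analyses: a
standardised adiposity exposure (SD units) instrumented by ~76 SNPs, a
natural-log inflammation mediator instrumented by ~88 SNPs, and a
muscle-strength outcome in kg, with association estimates drawn in
non-overlapping samples so cross-trait sampling covariance is zero.
Genotypes are simulated in Hardy-Weinberg equilibrium and LD-free;
LD enters only through the block-diagonal fixtures of
:func:`simulate_ld`. The generative truth satisfies
``theta_total = theta_dir + theta_xm * theta_my`` exactly and is carried
alongside every simulated object so estimators can be tested by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import HarmonizedPanel, LDMatrix, SummaryStats

_ALLELES = ("A", "G")  # non-palindromic pair; strand games are tested separately


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic exposure/mediator/outcome DAG.

    Effect-size scales default to the study this package mirrors: the
    exposure-SNP set explains ~2% of a standardised exposure, the
    mediator-SNP set ~2% of the log-scale mediator, and the outcome has
    residual SD ~8 kg around causal effects of order 0.5 kg per exposure
    SD. Two-sample estimation sample sizes default to GWAS-scale n.
    """

    k_exposure: int = 76
    k_mediator: int = 88
    maf_low: float = 0.05
    maf_high: float = 0.5
    #: variance in the exposure explained jointly by exposure SNPs
    h2_exposure: float = 0.02
    #: variance in the mediator explained jointly by its own SNPs
    h2_mediator: float = 0.02
    #: exposure -> mediator effect (log-mediator units per exposure SD)
    theta_xm: float = 0.4
    #: exposure -> outcome direct effect (kg per exposure SD)
    theta_dir: float = 0.5
    #: mediator -> outcome effect (kg per log-mediator unit)
    theta_my: float = -0.5
    #: SNP -> outcome horizontal pleiotropy: "none", "balanced", "directional"
    pleiotropy: str = "none"
    mu_alpha: float = 0.0
    sd_alpha: float = 0.0
    sd_x: float = 0.99
    sd_m: float = 1.0
    sd_y: float = 8.0
    #: per-trait estimation sample size (two-sample, non-overlapping)
    n_exposure: int = 230_000
    n_mediator: int = 200_000
    n_outcome: int = 170_000
    #: shared-confounder loadings on X, M, Y (observational-arm testing)
    confounding: tuple[float, float, float] = (0.0, 0.0, 0.0)
    stratum: str = "combined"

    def __post_init__(self) -> None:
        if self.k_exposure < 1 or self.k_mediator < 0:
            raise ValueError("SNP counts must be positive")
        if not (0.01 <= self.maf_low < self.maf_high <= 0.5):
            raise ValueError("MAF bounds must satisfy 0.01 <= low < high <= 0.5")
        if min(self.sd_x, self.sd_m, self.sd_y) < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none|balanced|directional")

    @property
    def theta_indirect(self) -> float:
        return self.theta_xm * self.theta_my

    @property
    def theta_total(self) -> float:
        return self.theta_dir + self.theta_indirect


@dataclass
class Truth:
    """Generative parameters realised for one simulation."""

    maf: np.ndarray
    gamma: np.ndarray   # SNP -> exposure
    kappa: np.ndarray   # SNP -> mediator (direct)
    alpha: np.ndarray   # SNP -> outcome (horizontal pleiotropy)
    theta_xm: float
    theta_dir: float
    theta_my: float

    @property
    def theta_indirect(self) -> float:
        return self.theta_xm * self.theta_my

    @property
    def theta_total(self) -> float:
        return self.theta_dir + self.theta_indirect

    @property
    def beta_x(self) -> np.ndarray:
        """True per-SNP effects on the exposure."""
        return self.gamma

    @property
    def beta_m(self) -> np.ndarray:
        """True per-SNP effects on the mediator (via X plus direct)."""
        return self.theta_xm * self.gamma + self.kappa

    @property
    def beta_y(self) -> np.ndarray:
        """True per-SNP effects on the outcome (all paths)."""
        return self.theta_dir * self.gamma + self.theta_my * self.beta_m + self.alpha


@dataclass
class Cohort:
    genotypes: np.ndarray  # individuals x SNPs, dosages 0/1/2
    x: np.ndarray
    m: np.ndarray
    y: np.ndarray
    covariates: np.ndarray  # individuals x c (may have 0 columns)
    truth: Truth
    config: SimulationConfig

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (self.genotypes.shape[0] == len(self.m) == len(self.y) == n
                == self.covariates.shape[0]):
            raise ValueError("cohort dimensions inconsistent")
        assert self.truth.theta_total == self.truth.theta_dir + self.truth.theta_indirect

    @property
    def n(self) -> int:
        return len(self.x)


def _draw_effects(rng: np.random.Generator, config: SimulationConfig):
    k = config.k_exposure + config.k_mediator
    maf = rng.uniform(config.maf_low, config.maf_high, size=k)
    var_g = 2 * maf * (1 - maf)

    gamma = np.zeros(k)
    # Effect magnitudes are uniform on [0.5, 1.5] x scale: instruments are
    # genome-wide-significant hits, so per-SNP effects are bounded away
    # from zero. Exposure SNPs are coded to the exposure-increasing allele
    # (positive gamma), the same convention harmonization enforces, so
    # directional pleiotropy keeps a well-defined sign relative to the
    # instrument coding.
    raw = rng.uniform(0.5, 1.5, size=config.k_exposure)
    # rescale so the exposure-SNP set explains exactly h2_exposure
    sl = slice(0, config.k_exposure)
    gamma[sl] = raw * np.sqrt(config.h2_exposure / np.sum(var_g[sl] * raw**2))

    kappa = np.zeros(k)
    if config.k_mediator:
        sl = slice(config.k_exposure, k)
        raw = rng.uniform(0.5, 1.5, size=config.k_mediator) * rng.choice(
            [-1.0, 1.0], size=config.k_mediator)
        kappa[sl] = raw * np.sqrt(config.h2_mediator / np.sum(var_g[sl] * raw**2))

    alpha = np.zeros(k)
    if config.pleiotropy == "balanced":
        alpha = rng.normal(0.0, config.sd_alpha, size=k)
    elif config.pleiotropy == "directional":
        alpha = rng.normal(config.mu_alpha, config.sd_alpha, size=k)
    return maf, gamma, kappa, alpha


def simulate_cohort(config: SimulationConfig, seed: int, n: int | None = None,
                    n_covariates: int = 0) -> Cohort:
    """Simulate an individual-level cohort under the linear DAG
    ``X = G*gamma + c_x'C + e_x``, ``M = theta_xm*X + G*kappa + c_m'C + e_m``,
    ``Y = theta_dir*X + theta_my*M + G*alpha + c_y'C + e_y``.

    ``n`` defaults to ``config.n_outcome``. Covariates are standard-normal
    with the confounding loadings from the config applied to the first one.
    """
    rng = np.random.default_rng(seed)
    k = config.k_exposure + config.k_mediator
    n = int(n if n is not None else config.n_outcome)
    if n < k + 10:
        raise ValueError(f"n={n} too small for {k} SNPs (need >= k+10)")
    maf, gamma, kappa, alpha = _draw_effects(rng, config)
    g = rng.binomial(2, maf, size=(n, k)).astype(np.float64)
    c = rng.normal(size=(n, max(n_covariates, 1 if any(config.confounding) else 0)))
    cx, cm, cy = config.confounding
    load = c[:, 0] if c.shape[1] else 0.0

    x = g @ gamma + cx * load + rng.normal(0, config.sd_x, n)
    m = config.theta_xm * x + g @ kappa + cm * load + rng.normal(0, config.sd_m, n)
    y = (config.theta_dir * x + config.theta_my * m + g @ alpha
         + cy * load + rng.normal(0, config.sd_y, n))
    truth = Truth(maf, gamma, kappa, alpha,
                  config.theta_xm, config.theta_dir, config.theta_my)
    return Cohort(g, x, m, y, c, truth, config)


def _per_snp_regression(g: np.ndarray, trait: np.ndarray,
                        covars: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regression of trait on dosage, optionally
    covariate-adjusted by prior residualisation (Frisch-Waugh-Lovell)."""
    n, k = g.shape
    ncov = 1  # intercept
    if covars is not None and covars.shape[1]:
        z = np.column_stack([np.ones(n), covars])
        ncov = z.shape[1]
        coef, *_ = np.linalg.lstsq(z, np.column_stack([trait[:, None], g]), rcond=None)
        resid = np.column_stack([trait[:, None], g]) - z @ coef
        t, gq = resid[:, 0], resid[:, 1:]
    else:
        t = trait - trait.mean()
        gq = g - g.mean(axis=0)
    ssg = np.sum(gq**2, axis=0)
    beta = (gq.T @ t) / ssg
    resid_var = (np.sum(t**2) - beta**2 * ssg) / (n - ncov - 1)
    se = np.sqrt(np.maximum(resid_var, 0.0) / ssg)
    return beta, se, ssg


def cohort_to_sumstats(
    cohort: Cohort,
    split: dict[str, np.ndarray] | None = None,
    seed: int | None = None,
    adjust_covariates: bool = False,
    allow_overlap: bool = False,
) -> dict[str, SummaryStats]:
    """Estimate per-SNP association summary statistics for X, M and Y in
    (by default disjoint) subsamples, mirroring a two-sample design.

    ``split`` maps trait labels ``x``, ``m``, ``y`` to index arrays; when
    omitted, the cohort is partitioned into thirds at random (``seed``
    required). Overlapping splits raise unless ``allow_overlap``.
    """
    from scipy import stats

    n = cohort.n
    if split is None:
        if seed is None:
            raise ValueError("seed required when split is not given")
        perm = np.random.default_rng(seed).permutation(n)
        thirds = np.array_split(perm, 3)
        split = {"x": thirds[0], "m": thirds[1], "y": thirds[2]}
    idx_sets = [set(v.tolist()) for v in split.values()]
    for i in range(len(idx_sets)):
        for j in range(i + 1, len(idx_sets)):
            if idx_sets[i] & idx_sets[j] and not allow_overlap:
                raise ValueError("estimation samples overlap; pass allow_overlap=True "
                                 "to permit sample overlap deliberately")

    traits = {"x": cohort.x, "m": cohort.m, "y": cohort.y}
    out: dict[str, SummaryStats] = {}
    k = cohort.genotypes.shape[1]
    for name, idx in split.items():
        g = cohort.genotypes[idx]
        covars = cohort.covariates[idx] if adjust_covariates else None
        beta, se, _ = _per_snp_regression(g, traits[name][idx], covars)
        with np.errstate(divide="ignore"):
            z = beta / se
        pval = 2 * stats.norm.sf(np.abs(z))
        table = pd.DataFrame({
            "rsid": [f"rs{j + 1}" for j in range(k)],
            "chrom": [str(1 + j // 50) for j in range(k)],
            "pos": [100_000 + 1_000_000 * j for j in range(k)],
            "ea": _ALLELES[0], "oa": _ALLELES[1],
            "eaf": cohort.truth.maf,
            "beta": beta, "se": se,
            "pval": np.clip(pval, np.nextafter(0, 1), 1.0),
            "n": len(idx),
        })
        out[name] = SummaryStats(name, cohort.config.stratum, table)
    return out


def _analytic_se(config: SimulationConfig, maf: np.ndarray) -> dict[str, np.ndarray]:
    """First-order per-SNP regression SEs implied by the config's
    two-sample sizes: se ~ sd(trait) / sqrt(n * 2*maf*(1-maf))."""
    var_g = 2 * maf * (1 - maf)
    sd_m_total = np.sqrt(config.theta_xm**2 + config.sd_m**2)  # X has unit SD
    return {
        "x": 1.0 / np.sqrt(config.n_exposure * var_g),
        "m": sd_m_total / np.sqrt(config.n_mediator * var_g),
        "y": config.sd_y / np.sqrt(config.n_outcome * var_g),
    }


def simulate_sumstats(
    config: SimulationConfig, seed: int,
    se_x: np.ndarray | float | None = None,
    se_m: np.ndarray | float | None = None,
    se_y: np.ndarray | float | None = None,
) -> tuple[HarmonizedPanel, Truth]:
    """Fast path: draw observed per-SNP betas directly around the composed
    truth with independent normal errors per trait (the two-sample,
    non-overlapping-samples regime), skipping individual-level data.

    SEs default to the values implied by the config's estimation sample
    sizes; pass scalars or arrays to override. Zero SEs are permitted and
    reproduce the truth exactly; negative SEs raise.
    """
    rng = np.random.default_rng(seed)
    maf, gamma, kappa, alpha = _draw_effects(rng, config)
    truth = Truth(maf, gamma, kappa, alpha,
                  config.theta_xm, config.theta_dir, config.theta_my)
    k = len(maf)
    defaults = _analytic_se(config, maf)
    ses = {}
    for name, override in (("x", se_x), ("m", se_m), ("y", se_y)):
        s = defaults[name] if override is None else np.broadcast_to(
            np.asarray(override, dtype=float), (k,)).copy()
        if (s < 0).any():
            raise ValueError("standard errors must be non-negative")
        ses[name] = s

    obs = {
        "x": truth.beta_x + rng.normal(size=k) * ses["x"],
        "m": truth.beta_m + rng.normal(size=k) * ses["m"],
        "y": truth.beta_y + rng.normal(size=k) * ses["y"],
    }
    idx = pd.Index([f"rs{j + 1}" for j in range(k)], name="rsid")
    # panels require strictly positive SEs; floor exact zeros at a nominal tiny value
    se_floor = {n: np.maximum(s, 1e-100) for n, s in ses.items()}
    panel = HarmonizedPanel(
        beta=pd.DataFrame(obs, index=idx),
        se=pd.DataFrame(se_floor, index=idx),
        exposure="x", outcome="y", mediator="m",
        eaf=pd.DataFrame({n: maf for n in ("x", "m", "y")}, index=idx),
        stratum=config.stratum,
    )
    return panel, truth


def simulate_ld(block_sizes: list[int], within_r2: float | list[float] = 0.9,
                start_pos: int = 1_000_000, spacing: int = 10_000,
                chrom_of=None, rsid_prefix: str = "rs") -> LDMatrix:
    """Block-diagonal LD fixture: unit diagonal, ``within_r2`` inside each
    block, zero between blocks. SNPs are laid out ``spacing`` bp apart so
    blocks sit inside a standard clumping window."""
    if isinstance(within_r2, (int, float)):
        within_r2 = [float(within_r2)] * len(block_sizes)
    if any(not (0 <= r <= 1) for r in within_r2):
        raise ValueError("within-block r2 must lie in [0, 1]")
    k = sum(block_sizes)
    mat = np.zeros((k, k))
    i = 0
    for size, r2 in zip(block_sizes, within_r2):
        mat[i:i + size, i:i + size] = r2
        i += size
    np.fill_diagonal(mat, 1.0)
    rsids = [f"{rsid_prefix}{j + 1}" for j in range(k)]
    pos = {rs: start_pos + j * spacing for j, rs in enumerate(rsids)}
    return LDMatrix(rsids, mat, pos)


def simulate_gwas_tables(
    config: SimulationConfig, seed: int,
    missing_mediator_in_exposure: int = 0,
    proxies_for_missing: int = 0,
    proxy_r2: float = 0.9,
    trait_names: tuple[str, str, str] = ("x", "m", "y"),
) -> dict:
    """Deterministically structured per-trait GWAS tables for instrument
    assembly: every exposure SNP is genome-wide significant in the
    exposure GWAS and every mediator SNP in the mediator GWAS, all SNPs
    are mutually LD-independent, and the last
    ``missing_mediator_in_exposure`` mediator SNPs are absent from the
    exposure-side table. For the first ``proxies_for_missing`` of those, a
    proxy SNP in LD ``proxy_r2`` is present in the exposure table instead.

    Returns a dict with per-trait ``SummaryStats`` (keys =
    ``trait_names``), the ``LDMatrix``, and the realised ``Truth`` —
    everything :func:`mrmediate.sumstats.assemble_mvmr_instruments` needs.
    """
    rng = np.random.default_rng(seed)
    maf, gamma, kappa, alpha = _draw_effects(rng, config)
    truth = Truth(maf, gamma, kappa, alpha,
                  config.theta_xm, config.theta_dir, config.theta_my)
    k = len(maf)
    kx = config.k_exposure
    ses = _analytic_se(config, maf)
    betas = {
        trait_names[0]: truth.beta_x + rng.normal(size=k) * ses["x"],
        trait_names[1]: truth.beta_m + rng.normal(size=k) * ses["m"],
        trait_names[2]: truth.beta_y + rng.normal(size=k) * ses["y"],
    }
    se_map = dict(zip(trait_names, (ses["x"], ses["m"], ses["y"])))
    rsids = [f"rs{j + 1}" for j in range(k)]
    chrom = [str(1 + j // 50) for j in range(k)]
    pos = [100_000 + 1_000_000 * j for j in range(k)]

    # significance is structural, not sampled: exposure SNPs are
    # genome-wide significant for the exposure, mediator SNPs for the mediator
    pvals = {
        trait_names[0]: np.where(np.arange(k) < kx, 1e-12, 0.5),
        trait_names[1]: np.where(np.arange(k) >= kx, 1e-12, 0.5),
        trait_names[2]: np.full(k, 0.5),
    }

    missing = rsids[k - missing_mediator_in_exposure:] if missing_mediator_in_exposure else []
    proxied = missing[:proxies_for_missing]
    proxy_rsids = [f"{rs}_proxy" for rs in proxied]

    tables = {}
    for i, name in enumerate(trait_names):
        df = pd.DataFrame({
            "rsid": rsids, "chrom": chrom, "pos": pos,
            "ea": _ALLELES[0], "oa": _ALLELES[1], "eaf": maf,
            "beta": betas[name], "se": se_map[name], "pval": pvals[name],
            "n": (config.n_exposure, config.n_mediator, config.n_outcome)[i],
        })
        if name == trait_names[0] and missing:
            keep = ~df["rsid"].isin(missing)
            proxy_rows = df[df["rsid"].isin(proxied)].copy()
            df = df[keep]
            if not proxy_rows.empty:
                # proxies carry the (near-identical) signal of the SNPs they tag
                proxy_rows["rsid"] = [f"{rs}_proxy" for rs in proxy_rows["rsid"]]
                proxy_rows["pos"] = proxy_rows["pos"] + 5_000
                df = pd.concat([df, proxy_rows], ignore_index=True)
        tables[name] = SummaryStats(name, config.stratum, df.reset_index(drop=True))

    all_rsids = rsids + proxy_rsids
    mat = np.eye(len(all_rsids))
    idx = {rs: i for i, rs in enumerate(all_rsids)}
    for rs, prs in zip(proxied, proxy_rsids):
        mat[idx[rs], idx[prs]] = mat[idx[prs], idx[rs]] = proxy_r2
    ld_pos = {rs: 100_000 + 1_000_000 * j for j, rs in enumerate(rsids)}
    ld_pos.update({prs: ld_pos[rs] + 5_000 for rs, prs in zip(proxied, proxy_rsids)})
    ld = LDMatrix(all_rsids, mat, ld_pos)
    return {"tables": tables, "ld": ld, "truth": truth}


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if "confounding" in payload:
        payload["confounding"] = tuple(payload["confounding"])
    return SimulationConfig(**payload)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["confounding"] = list(d["confounding"])
    return d
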