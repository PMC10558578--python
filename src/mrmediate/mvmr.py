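"""Multivariable MR: direct effects of an exposure conditional on a
mediator, with the weak-instrument and heterogeneity machinery the
two-sample setting requires.

Estimators
----------
* MVMR-IVW: weighted regression of outcome betas on the exposure and
  mediator beta columns without intercept, multiplicative random effects.
* MVMR-Egger: the same fit plus an intercept after orienting the exposure
  of interest, whose p-value tests directional pleiotropy.
* Q-het: direct effects estimated by minimising the generalised Cochran
  heterogeneity statistic Q_A, robust to weak instruments, with
  parametric-bootstrap percentile confidence intervals.

Diagnostics are the conditional F-statistic (instrument strength of one
exposure given the other; rule-of-thumb adequacy above 10) and Q_A
(residual heterogeneity; values above roughly the number of SNPs indicate
pleiotropy or weak instruments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import HarmonizedPanel, PhenotypeCorrelation
from .unimr import Z95, _norm_p


@dataclass
class MVMRResult:
    """Direct-effect estimates per exposure from a multivariable MR fit."""

    method: str
    exposures: list[str]
    theta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    k: int
    cond_f: dict[str, float]
    q_a: float
    q_a_df: int
    q_a_pvalue: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    outcome: str = ""
    stratum: str = "combined"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.theta) == len(self.se) == len(self.exposures)):
            raise ValueError("one theta/se per exposure required")

    def effect(self, exposure: str):
        """(theta, se, lcl, ucl, p) for one exposure."""
        i = self.exposures.index(exposure)
        return (float(self.theta[i]), float(self.se[i]),
                float(self.ci_low[i]), float(self.ci_high[i]),
                float(self.pvalue[i]))

    def to_rows(self) -> list[dict]:
        rows = []
        for i, exp in enumerate(self.exposures):
            rows.append({
                "method": self.method, "stratum": self.stratum,
                "exposure": exp, "outcome": self.outcome,
                "beta": float(self.theta[i]), "se": float(self.se[i]),
                "lcl": float(self.ci_low[i]), "ucl": float(self.ci_high[i]),
                "p": float(self.pvalue[i]), "k": self.k,
                "cond_F": self.cond_f.get(exp), "Q_A": self.q_a,
                "intercept": self.intercept,
                "intercept_p": self.intercept_pvalue,
                "n_boot": self.n_boot, "seed": self.seed,
            })
        return rows

    def summary(self) -> str:
        lines = [f"{self.method} direct effects on {self.outcome or 'outcome'} "
                 f"({self.stratum}), k = {self.k} SNPs"]
        for i, exp in enumerate(self.exposures):
            lines.append(
                f"  {exp}: theta = {self.theta[i]:+.4f}  se = {self.se[i]:.4f}  "
                f"95% CI [{self.ci_low[i]:+.4f}, {self.ci_high[i]:+.4f}]  "
                f"p = {self.pvalue[i]:.3g}  cond. F = {self.cond_f.get(exp, float('nan')):.2f}"
            )
        lines.append(f"  Q_A = {self.q_a:.2f} on {self.q_a_df} df "
                     f"(rule-of-thumb critical value ~ k = {self.k}); "
                     f"chi-square p = {self.q_a_pvalue:.3g}")
        if self.intercept is not None:
            lines.append(f"  intercept = {self.intercept:+.4f} "
                         f"(se {self.intercept_se:.4f}, p = {self.intercept_pvalue:.3g})")
        return "\n".join(lines)


def _require_mediator(panel: HarmonizedPanel) -> None:
    if panel.mediator is None:
        raise ValueError("MVMR requires a panel with exposure and mediator columns")


def conditional_f(panel: HarmonizedPanel, exposure_of_interest: str | None = None) -> float:
    """Conditional F-statistic for one exposure given the other.

    Uses the two-sample Q-based formulation with zero cross-trait
    covariance (non-overlapping estimation samples):
    ``F = min_delta sum_j (b1j - delta*b2j)^2 / (se1j^2 + delta^2 se2j^2)
    / (k - 1)``, minimised numerically with a dense-grid fallback.
    """
    _require_mediator(panel)
    exposure_of_interest = exposure_of_interest or panel.exposure
    if exposure_of_interest == panel.exposure:
        b1, s1, b2, s2 = panel.bx, panel.sx, panel.bm, panel.sm
    elif exposure_of_interest == panel.mediator:
        b1, s1, b2, s2 = panel.bm, panel.sm, panel.bx, panel.sx
    else:
        raise ValueError(f"unknown exposure {exposure_of_interest!r}")
    k = len(b1)
    if k < 3:
        raise ValueError("conditional F needs at least 3 SNPs")

    if not np.any(b2):
        # the other exposure carries no signal: delta is unidentified and
        # the statistic reduces to the univariable instrument strength
        return float(np.sum((b1 / s1) ** 2)) / (k - 1)

    def q_x(delta: float) -> float:
        return float(np.sum((b1 - delta * b2) ** 2 / (s1**2 + delta**2 * s2**2)))

    # The objective has a spurious asymptote: as |delta| -> inf it tends to
    # sum((b2/s2)^2), so a global search can run away from the meaningful
    # solution. The statistic uses the interior minimum near the weighted
    # regression of b1 on b2, located by iteratively reweighted least
    # squares and polished by bounded 1-D minimisation (grid fallback on
    # the same neighbourhood).
    delta = 0.0
    for _ in range(100):
        w = 1.0 / (s1**2 + delta**2 * s2**2)
        new = float(np.sum(w * b1 * b2) / np.sum(w * b2**2))
        if abs(new - delta) < 1e-12:
            delta = new
            break
        delta = new
    span = 0.5 * (1.0 + abs(delta))
    res = optimize.minimize_scalar(q_x, bounds=(delta - span, delta + span),
                                   method="bounded", options={"xatol": 1e-10})
    if not res.success:
        grid = np.linspace(delta - span, delta + span, 4001)
        vals = [q_x(d) for d in grid]
        return min(min(vals), q_x(delta)) / (k - 1)
    at_boundary = min(abs(res.x - (delta - span)), abs(res.x - (delta + span))) < 1e-6
    qmin = q_x(delta) if at_boundary else min(float(res.fun), q_x(delta))
    return qmin / (k - 1)


def q_a(panel: HarmonizedPanel, thetas, rho: PhenotypeCorrelation | float | None = None) -> float:
    """Generalised Cochran's Q at direct-effect values ``thetas`` =
    (theta_exposure, theta_mediator).

    Each SNP's squared residual ``(b_Y - tx*b_X - tm*b_M)^2`` is scaled by
    its variance ``se_Y^2 + tx^2 se_X^2 + tm^2 se_M^2 +
    2 tx tm rho se_X se_M``, where rho is the phenotypic correlation
    between exposure and mediator (zero when omitted).
    """
    _require_mediator(panel)
    tx, tm = (float(t) for t in thetas)
    if not (np.isfinite(tx) and np.isfinite(tm)):
        raise ValueError("thetas must be finite")
    if rho is None:
        r = 0.0
    elif isinstance(rho, PhenotypeCorrelation):
        r = rho.get(panel.exposure, panel.mediator)
    else:
        r = float(rho)
    denom = (panel.sy**2 + tx**2 * panel.sx**2 + tm**2 * panel.sm**2
             + 2 * tx * tm * r * panel.sx * panel.sm)
    if (denom <= 0).any():
        raise ValueError("non-positive Q_A weight denominator; invalid correlation")
    resid = panel.by - tx * panel.bx - tm * panel.bm
    return float(np.sum(resid**2 / denom))


class MultivariableMR:
    """Multivariable MR model for a two-exposure (exposure + mediator) panel.

    >>> model = MultivariableMR(panel)
    >>> res = model.fit()                      # MVMR-IVW
    >>> res_egger = model.fit(method="egger")
    >>> res_qhet = model.fit(method="qhet", rho=rho, seed=7)
    """

    def __init__(self, panel: HarmonizedPanel):
        _require_mediator(panel)
        if len(panel) < 3:
            raise ValueError("MVMR needs at least 3 SNPs")
        self.panel = panel
        self.exposures = [panel.exposure, panel.mediator]
        self._cond_f: dict[str, float] | None = None

    @property
    def cond_f(self) -> dict[str, float]:
        """Conditional F per exposure (computed once per model)."""
        if self._cond_f is None:
            self._cond_f = {e: conditional_f(self.panel, e) for e in self.exposures}
        return self._cond_f

    def fit(self, method: str = "ivw", rho: PhenotypeCorrelation | float | None = None,
            n_boot: int = 2000, seed: int | None = None) -> MVMRResult:
        method = method.lower()
        if method == "ivw":
            return self._fit_wls(intercept=False)
        if method == "egger":
            return self._fit_wls(intercept=True)
        if method in ("qhet", "q-het", "q_het"):
            if seed is None:
                raise ValueError("Q-het requires a bootstrap seed")
            return self._fit_qhet(rho=rho, n_boot=n_boot, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    def _design(self, orient: bool):
        bx, bm, by = self.panel.bx.copy(), self.panel.bm.copy(), self.panel.by.copy()
        if orient:
            sign = np.where(bx < 0, -1.0, 1.0)
            bx, bm, by = bx * sign, bm * sign, by * sign
        return bx, bm, by

    def _fit_wls(self, intercept: bool) -> MVMRResult:
        k = len(self.panel)
        if intercept and k < 4:
            raise ValueError("MVMR-Egger needs at least 4 SNPs")
        bx, bm, by = self._design(orient=intercept)
        w = 1.0 / self.panel.sy**2
        # an identically-zero mediator column is a nested univariable model,
        # not a user error: drop it so the fit reduces to univariable IVW
        zero_mediator = not np.any(bm)
        cols = [bx] if zero_mediator else [bx, bm]
        if intercept:
            cols = [np.ones(k)] + cols
        design = np.column_stack(cols)
        rank = np.linalg.matrix_rank(design * np.sqrt(w)[:, None])
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient exposure matrix: exposure and mediator beta "
                "columns are collinear")
        xtwx = design.T @ (design * w[:, None])
        coef = np.linalg.solve(xtwx, design.T @ (w * by))
        resid = by - design @ coef
        rss_w = float(np.sum(w * resid**2))
        df = k - design.shape[1]
        scale = max(1.0, np.sqrt(rss_w / df)) if df > 0 else 1.0
        se = np.sqrt(np.diag(np.linalg.inv(xtwx))) * scale

        off = 1 if intercept else 0
        theta, th_se = coef[off:], se[off:]
        if zero_mediator:
            theta = np.append(theta, 0.0)
            th_se = np.append(th_se, np.inf)
        qa = q_a(self.panel, (theta[0], theta[1]))
        cond = self.cond_f
        qa_df = k - 2
        return MVMRResult(
            method="MVMR-Egger" if intercept else "MVMR-IVW",
            exposures=self.exposures,
            theta=theta, se=th_se,
            ci_low=theta - Z95 * th_se, ci_high=theta + Z95 * th_se,
            pvalue=np.array([_norm_p(t / s) for t, s in zip(theta, th_se)]),
            k=k, cond_f=cond,
            q_a=qa, q_a_df=qa_df, q_a_pvalue=float(stats.chi2.sf(qa, qa_df)),
            intercept=float(coef[0]) if intercept else None,
            intercept_se=float(se[0]) if intercept else None,
            intercept_pvalue=_norm_p(coef[0] / se[0]) if intercept else None,
            outcome=self.panel.outcome, stratum=self.panel.stratum,
            meta={"re_scale": scale, "df": df},
        )

    # -- Q-het ----------------------------------------------------------

    def _minimise_qa(self, bx, sx, bm, sm, by, sy, r: float,
                     start: np.ndarray, grid_fallback: bool = True
                     ) -> tuple[np.ndarray, float, bool]:
        def objective(t):
            tx, tm = t
            denom = (sy**2 + tx**2 * sx**2 + tm**2 * sm**2
                     + 2 * tx * tm * r * sx * sm)
            resid = by - tx * bx - tm * bm
            return float(np.sum(resid**2 / denom))

        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-8,
                                         "maxiter": 2000})
        best, fbest, ok = res.x, float(res.fun), bool(res.success)
        if not grid_fallback:
            return np.asarray(best, dtype=float), fbest, ok
        # coarse 11x11 grid fallback spanning +/- 5 start-scale units
        span = 5.0 * np.maximum(np.abs(start), 0.2)
        g1 = np.linspace(start[0] - span[0], start[0] + span[0], 11)
        g2 = np.linspace(start[1] - span[1], start[1] + span[1], 11)
        for a in g1:
            for b in g2:
                f = objective((a, b))
                if f < fbest - 1e-10:
                    res2 = optimize.minimize(objective, (a, b), method="Nelder-Mead",
                                             options={"xatol": 1e-8, "fatol": 1e-8,
                                                      "maxiter": 2000})
                    if float(res2.fun) < fbest:
                        best, fbest, ok = res2.x, float(res2.fun), bool(res2.success)
        return np.asarray(best, dtype=float), fbest, ok

    def _fit_qhet(self, rho, n_boot: int, seed: int) -> MVMRResult:
        p = self.panel
        if rho is None:
            r = 0.0
        elif isinstance(rho, PhenotypeCorrelation):
            r = rho.get(p.exposure, p.mediator)
        else:
            r = float(rho)
        ivw = self._fit_wls(intercept=False)
        start = np.asarray(ivw.theta, dtype=float)
        theta, qmin, ok = self._minimise_qa(p.bx, p.sx, p.bm, p.sm, p.by, p.sy,
                                            r, start)
        if not ok:
            raise RuntimeError("Q_A minimisation did not converge from the IVW start")

        k = len(p)
        if n_boot == 0:
            nan2 = np.full(2, np.nan)
            return MVMRResult(
                method="Q-het", exposures=self.exposures,
                theta=theta, se=nan2, ci_low=nan2, ci_high=nan2,
                pvalue=nan2, k=k, cond_f=self.cond_f,
                q_a=qmin, q_a_df=k - 2, q_a_pvalue=float(stats.chi2.sf(qmin, k - 2)),
                n_boot=0, seed=seed,
                outcome=p.outcome, stratum=p.stratum,
                meta={"rho": r, "ci_method": "none (n_boot=0)"},
            )

        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, 2))
        failures = 0
        for b in range(n_boot):
            bxs = p.bx + rng.normal(size=k) * p.sx
            bms = p.bm + rng.normal(size=k) * p.sm
            bys = p.by + rng.normal(size=k) * p.sy
            tb, _, okb = self._minimise_qa(bxs, p.sx, bms, p.sm, bys, p.sy,
                                           r, theta, grid_fallback=False)
            if not okb:
                failures += 1
            boots[b] = tb
        if failures > 0.01 * n_boot:
            raise RuntimeError(
                f"{failures}/{n_boot} bootstrap replicates failed to converge; "
                "inspect the panel for pathological weights")
        ci = np.percentile(boots, [2.5, 97.5], axis=0)
        se = np.std(boots, axis=0, ddof=1)
        return MVMRResult(
            method="Q-het", exposures=self.exposures,
            theta=theta, se=se, ci_low=ci[0], ci_high=ci[1],
            pvalue=np.array([_norm_p(t / s) for t, s in zip(theta, se)]),
            k=k,
            cond_f=self.cond_f,
            q_a=qmin, q_a_df=k - 2, q_a_pvalue=float(stats.chi2.sf(qmin, k - 2)),
            n_boot=n_boot, seed=seed,
            outcome=p.outcome, stratum=p.stratum,
            meta={"rho": r, "ci_method": "percentile bootstrap",
                  "rho_weight_form": "2*tx*tm*rho*se_x*se_m cross-term",
                  "bootstrap_failures": failures},
        )


# -- module-level functional surface -----------------------------------

def mvmr_ivw(panel: HarmonizedPanel) -> MVMRResult:
    """MVMR-IVW direct effects (multiplicative random effects)."""
    return MultivariableMR(panel).fit("ivw")


def mvmr_egger(panel: HarmonizedPanel) -> MVMRResult:
    """MVMR-Egger direct effects with pleiotropy-intercept test."""
    return MultivariableMR(panel).fit("egger")


def qhet_estimate(panel: HarmonizedPanel, rho=None, n_boot: int = 2000,
                  seed: int = 0) -> MVMRResult:
    """Direct effects by Q_A minimisation with bootstrap percentile CIs."""
    return MultivariableMR(panel).fit("qhet", rho=rho, n_boot=n_boot, seed=seed)
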