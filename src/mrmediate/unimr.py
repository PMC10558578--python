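"""Univariable two-sample MR: total effects and sensitivity diagnostics.

The primary estimator is the inverse-variance-weighted (IVW) average of
per-SNP Wald ratios under a multiplicative random-effects model; MR-Egger
and the weighted median estimator probe robustness to horizontal
pleiotropy, and the remaining operations (leave-one-out, single-SNP
forest/funnel tables, Cook's distance, confounder-association filtering)
supply the standard instrument-validity diagnostics.

The module exposes a statsmodels-style :class:`UnivariableMR` model whose
``fit`` returns an :class:`MREstimate`; the module-level functions are thin
wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import HarmonizedPanel

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class WaldRatios:
    """Per-SNP ratio estimates beta_Y / beta_X with first-order SEs
    se_Y / |beta_X| and inverse-variance weights."""

    rsids: list[str]
    ratio: np.ndarray
    se: np.ndarray
    weight: np.ndarray

    @classmethod
    def from_panel(cls, panel: HarmonizedPanel) -> "WaldRatios":
        bx, by, sy = panel.bx, panel.by, panel.sy
        nonzero = bx != 0
        if not nonzero.all():
            dropped = [r for r, ok in zip(panel.rsids, nonzero) if not ok]
            warnings.warn(f"dropping {len(dropped)} SNPs with zero exposure beta: "
                          f"{dropped[:5]}", stacklevel=2)
        if not nonzero.any():
            raise ValueError("no SNPs with non-zero exposure beta")
        bx, by, sy = bx[nonzero], by[nonzero], sy[nonzero]
        ratio = by / bx
        se = sy / np.abs(bx)
        return cls(
            rsids=[r for r, ok in zip(panel.rsids, nonzero) if ok],
            ratio=ratio, se=se, weight=1.0 / se**2,
        )

    @property
    def k(self) -> int:
        return len(self.ratio)


@dataclass
class MREstimate:
    """A single causal-effect estimate with heterogeneity diagnostics.

    ``beta`` is in outcome units per unit (typically SD) of exposure; the
    95% CI is ``beta +/- 1.96 se``. ``q``/``i2`` quantify between-SNP
    heterogeneity of the Wald ratios; the Egger intercept fields are
    populated only for the Egger fit.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    k: int
    q: float | None = None
    q_pvalue: float | None = None
    i2: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    exposure: str = ""
    outcome: str = ""
    stratum: str = "combined"
    meta: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    def to_row(self) -> dict:
        return {
            "method": self.method, "stratum": self.stratum,
            "exposure": self.exposure, "outcome": self.outcome,
            "beta": self.beta, "se": self.se,
            "lcl": self.ci_low, "ucl": self.ci_high, "p": self.pvalue,
            "k": self.k, "Q": self.q, "I2": self.i2,
            "intercept": self.intercept, "intercept_p": self.intercept_pvalue,
        }

    def summary(self) -> str:
        lines = [
            f"{self.method} estimate ({self.exposure or 'exposure'} -> "
            f"{self.outcome or 'outcome'}, {self.stratum})",
            f"  beta = {self.beta:+.4f}  se = {self.se:.4f}  "
            f"95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  p = {self.pvalue:.3g}",
            f"  k = {self.k}",
        ]
        if self.q is not None:
            lines.append(f"  Cochran Q = {self.q:.3f} (p = {self.q_pvalue:.3g}), "
                         f"I2 = {self.i2:.1f}%")
        if self.intercept is not None:
            lines.append(f"  intercept = {self.intercept:+.4f} "
                         f"(se {self.intercept_se:.4f}, p = {self.intercept_pvalue:.3g})")
        return "\n".join(lines)


def _norm_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def cochran_q(ratios: WaldRatios, pooled: float) -> tuple[float | None, float | None, float | None]:
    """Cochran's Q about a pooled estimate, with I2 (%) and the chi-square
    p-value on k-1 df. Returns ``(None, None, None)`` for k < 2, where
    heterogeneity is undefined."""
    k = ratios.k
    if k < 2:
        return None, None, None
    q = float(np.sum(ratios.weight * (ratios.ratio - pooled) ** 2))
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    p = float(stats.chi2.sf(q, k - 1))
    return q, i2, p


class UnivariableMR:
    """Univariable two-sample MR model on a harmonized panel.

    Parameters
    ----------
    panel : HarmonizedPanel
        SNP-aligned exposure and outcome estimates.

    Examples
    --------
    >>> model = UnivariableMR(panel)
    >>> res = model.fit()            # IVW, multiplicative random effects
    >>> res_egger = model.fit(method="egger")
    """

    def __init__(self, panel: HarmonizedPanel):
        if len(panel) == 0:
            raise ValueError("empty panel")
        self.panel = panel

    # -- estimators -----------------------------------------------------

    def fit(self, method: str = "ivw", n_boot: int = 2000,
            seed: int | None = None) -> MREstimate:
        method = method.lower()
        if method == "ivw":
            return self._fit_ivw()
        if method == "egger":
            return self._fit_egger()
        if method in ("wme", "weighted_median"):
            if seed is None:
                raise ValueError("weighted median requires a bootstrap seed")
            return self._fit_wme(n_boot=n_boot, seed=seed)
        raise ValueError(f"unknown method {method!r}")

    def _fit_ivw(self) -> MREstimate:
        r = WaldRatios.from_panel(self.panel)
        w = r.weight
        beta = float(np.sum(w * r.ratio) / np.sum(w))
        q, i2, qp = cochran_q(r, beta)
        se_fixed = float(1.0 / np.sqrt(np.sum(w)))
        scale = 1.0
        if r.k >= 2:
            scale = max(1.0, np.sqrt(q / (r.k - 1)))
        se = se_fixed * scale
        return MREstimate(
            method="IVW", beta=beta, se=se, pvalue=_norm_p(beta / se), k=r.k,
            q=q, q_pvalue=qp, i2=i2,
            exposure=self.panel.exposure, outcome=self.panel.outcome,
            stratum=self.panel.stratum,
            meta={"model": "multiplicative random effects", "re_scale": scale},
        )

    def _oriented(self):
        """Exposure betas oriented non-negative with joint outcome flips."""
        bx, by, sy = self.panel.bx.copy(), self.panel.by.copy(), self.panel.sy
        sign = np.where(bx < 0, -1.0, 1.0)
        return bx * sign, by * sign, sy

    def _fit_egger(self) -> MREstimate:
        k = len(self.panel)
        if k < 3:
            raise ValueError("MR-Egger needs at least 3 SNPs")
        bx, by, sy = self._oriented()
        if np.allclose(bx, bx[0]):
            raise np.linalg.LinAlgError("all exposure betas equal: Egger design singular")
        w = 1.0 / sy**2
        design = np.column_stack([np.ones(k), bx])
        xtwx = design.T @ (design * w[:, None])
        coef = np.linalg.solve(xtwx, design.T @ (w * by))
        resid = by - design @ coef
        rss_w = float(np.sum(w * resid**2))
        scale = max(1.0, np.sqrt(rss_w / (k - 2)))
        cov_fixed = np.linalg.inv(xtwx)
        se = np.sqrt(np.diag(cov_fixed)) * scale
        qp = float(stats.chi2.sf(rss_w, k - 2))
        i2 = max(0.0, (rss_w - (k - 2)) / rss_w) * 100 if rss_w > 0 else 0.0
        return MREstimate(
            method="MR-Egger", beta=float(coef[1]), se=float(se[1]),
            pvalue=_norm_p(coef[1] / se[1]), k=k,
            q=rss_w, q_pvalue=qp, i2=i2,
            intercept=float(coef[0]), intercept_se=float(se[0]),
            intercept_pvalue=_norm_p(coef[0] / se[0]),
            exposure=self.panel.exposure, outcome=self.panel.outcome,
            stratum=self.panel.stratum, meta={"re_scale": scale},
        )

    @staticmethod
    def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
        order = np.argsort(ratio, kind="mergesort")
        r, w = ratio[order], weight[order]
        s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
        return float(np.interp(0.5, s, r))

    def _fit_wme(self, n_boot: int, seed: int) -> MREstimate:
        k = len(self.panel)
        if k < 3:
            raise ValueError("weighted median needs at least 3 SNPs")
        r = WaldRatios.from_panel(self.panel)
        beta = self._weighted_median(r.ratio, r.weight)
        rng = np.random.default_rng(seed)
        bx, sx = self.panel.bx, self.panel.sx
        by, sy = self.panel.by, self.panel.sy
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bxs = bx + rng.normal(size=k) * sx
            bys = by + rng.normal(size=k) * sy
            ok = bxs != 0
            ratio = bys[ok] / bxs[ok]
            wt = (bxs[ok] / sy[ok]) ** 2
            boots[b] = self._weighted_median(ratio, wt)
        se = float(np.std(boots, ddof=1))
        return MREstimate(
            method="WME", beta=beta, se=se, pvalue=_norm_p(beta / se), k=k,
            exposure=self.panel.exposure, outcome=self.panel.outcome,
            stratum=self.panel.stratum,
            meta={"n_boot": n_boot, "seed": seed,
                  "se_method": "parametric bootstrap SD, normal approximation"},
        )

    # -- diagnostics ----------------------------------------------------

    def leave_one_out(self) -> list[tuple[str, MREstimate]]:
        """IVW re-estimated k times, each omitting one SNP."""
        if len(self.panel) < 2:
            raise ValueError("leave-one-out needs at least 2 SNPs")
        out = []
        for rsid in self.panel.rsids:
            sub = UnivariableMR(self.panel.drop([rsid]))
            out.append((rsid, sub.fit("ivw")))
        return out

    def single_snp_table(self) -> pd.DataFrame:
        """Per-SNP Wald ratios with CIs (forest-plot data) and precision
        1/se (funnel-plot data)."""
        r = WaldRatios.from_panel(self.panel)
        return pd.DataFrame({
            "rsid": r.rsids, "ratio": r.ratio, "se": r.se,
            "lcl": r.ratio - Z95 * r.se, "ucl": r.ratio + Z95 * r.se,
            "precision": 1.0 / r.se,
        })

    def cooks_influence(self, threshold: float | None = None
                        ) -> tuple[list[str], pd.DataFrame]:
        """Cook's distances from the weighted through-origin IVW regression
        of outcome betas on exposure betas; SNPs with D above ``threshold``
        (default 4/k) are flagged."""
        k = len(self.panel)
        if k < 3:
            raise ValueError("Cook's distance needs at least 3 SNPs")
        if threshold is None:
            threshold = 4.0 / k
        bx, by, sy = self.panel.bx, self.panel.by, self.panel.sy
        w = 1.0 / sy**2
        # transform to homoskedastic form: y* = sqrt(w) y, x* = sqrt(w) x
        xs, ys = np.sqrt(w) * bx, np.sqrt(w) * by
        sxx = float(np.sum(xs**2))
        slope = float(np.sum(xs * ys) / sxx)
        resid = ys - slope * xs
        h = xs**2 / sxx
        p = 1
        s2 = float(np.sum(resid**2) / (k - p))
        d = resid**2 * h / (p * s2 * (1 - h) ** 2)
        table = pd.DataFrame({"rsid": self.panel.rsids, "cooks_d": d,
                              "flagged": d > threshold})
        return table.loc[table["flagged"], "rsid"].tolist(), table


# -- module-level functional surface -----------------------------------

def ivw(panel: HarmonizedPanel) -> MREstimate:
    """IVW total effect under multiplicative random effects."""
    return UnivariableMR(panel).fit("ivw")


def mr_egger(panel: HarmonizedPanel) -> MREstimate:
    """MR-Egger slope and pleiotropy-intercept test."""
    return UnivariableMR(panel).fit("egger")


def weighted_median(panel: HarmonizedPanel, n_boot: int = 2000,
                    seed: int = 0) -> MREstimate:
    """Weighted median estimator with parametric-bootstrap SE."""
    return UnivariableMR(panel).fit("wme", n_boot=n_boot, seed=seed)


def leave_one_out(panel: HarmonizedPanel) -> list[tuple[str, MREstimate]]:
    return UnivariableMR(panel).leave_one_out()


def single_snp_and_funnel(panel: HarmonizedPanel) -> pd.DataFrame:
    return UnivariableMR(panel).single_snp_table()


def cooks_influence(panel: HarmonizedPanel, threshold: float | None = None):
    return UnivariableMR(panel).cooks_influence(threshold)


def bh_confounder_filter(assoc_pvals: pd.DataFrame, fdr: float = 0.05) -> list[str]:
    """Flag SNPs associated with any measured confounder.

    ``assoc_pvals`` is a SNP (rows) x confounder (columns) table of
    association p-values. Benjamini-Hochberg step-up is applied jointly
    over all SNP x confounder tests; a SNP is flagged when any of its
    tests is rejected at the given FDR. The caller decides whether to
    re-run MR without the flagged SNPs.
    """
    from statsmodels.stats.multitest import multipletests

    if assoc_pvals.size == 0:
        return []
    flat = assoc_pvals.to_numpy(dtype=float).ravel()
    if np.isnan(flat).any() or (flat <= 0).any() or (flat > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(flat, alpha=fdr, method="fdr_bh")
    reject = reject.reshape(assoc_pvals.shape)
    flagged = reject.any(axis=1)
    return [str(r) for r, f in zip(assoc_pvals.index, flagged) if f]
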