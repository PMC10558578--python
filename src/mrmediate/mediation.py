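"""Mediation decompositions: total = direct + indirect.

Two arms share the difference method (indirect effect = total effect
minus direct effect):

* the MR arm subtracts the multivariable-MR direct effect from the
  univariable-MR total effect, with the indirect SE from zero-covariance
  propagation of errors, sqrt(se_total^2 + se_direct^2);
* the observational arm fits the classic two-regression system
  (mediator on exposure; outcome on exposure + mediator) plus a
  total-effect regression, all with identical covariate sets, where the
  difference equals the product a1*b2 exactly and the indirect SE comes
  from the delta method on that product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .unimr import Z95, MREstimate, _norm_p


@dataclass
class Effect:
    beta: float
    se: float
    method: str = ""

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def pvalue(self) -> float:
        return _norm_p(self.beta / self.se) if self.se > 0 else 0.0


@dataclass
class MediationDecomposition:
    """Total/direct/indirect effect triplet for one exposure-mediator-outcome
    triple; the identity ``indirect = total - direct`` holds exactly by
    construction."""

    total: Effect
    direct: Effect
    indirect: Effect
    arm: str  # "observational" | "MR"
    exposure: str = ""
    mediator: str = ""
    outcome: str = ""
    stratum: str = "combined"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gap = abs(self.indirect.beta - (self.total.beta - self.direct.beta))
        if gap > 1e-10 * max(1.0, abs(self.total.beta)):
            raise ValueError("decomposition identity indirect = total - direct violated")

    @property
    def proportion_mediated(self) -> float | None:
        """indirect/total, reported only when the total effect is
        distinguishable from zero (|total| > 2 se)."""
        if abs(self.total.beta) > 2 * self.total.se:
            return self.indirect.beta / self.total.beta
        return None

    def to_rows(self) -> list[dict]:
        rows = []
        for name, eff in (("total", self.total), ("direct", self.direct),
                          ("indirect", self.indirect)):
            rows.append({
                "arm": self.arm, "stratum": self.stratum,
                "exposure": self.exposure, "mediator": self.mediator,
                "outcome": self.outcome, "component": name,
                "beta": eff.beta, "se": eff.se,
                "lcl": eff.ci_low, "ucl": eff.ci_high, "p": eff.pvalue,
                "method": eff.method,
            })
        return rows

    def summary(self) -> str:
        lines = [f"Mediation decomposition ({self.arm} arm), "
                 f"{self.exposure} -> {self.mediator} -> {self.outcome} "
                 f"({self.stratum})"]
        for name, eff in (("total", self.total), ("direct", self.direct),
                          ("indirect", self.indirect)):
            lines.append(f"  {name:<9}{eff.beta:+.4f}  "
                         f"[{eff.ci_low:+.4f}, {eff.ci_high:+.4f}]  ({eff.method})")
        pm = self.proportion_mediated
        lines.append("  proportion mediated: "
                     + (f"{pm:.3f}" if pm is not None else
                        "not reported (total effect indistinguishable from zero)"))
        return "\n".join(lines)


def propagation_se(se_total: float, se_direct: float) -> float:
    """SE of a difference of two independent estimates:
    sqrt(se_total^2 + se_direct^2)."""
    if se_total < 0 or se_direct < 0:
        raise ValueError("standard errors must be non-negative")
    return math.hypot(se_total, se_direct)


def difference_method(total: MREstimate, direct, exposure: str | None = None
                      ) -> MediationDecomposition:
    """MR-arm decomposition: subtract the MVMR direct effect from the
    univariable total effect; indirect SE by propagation of errors.

    ``direct`` is an :class:`~mrmediate.mvmr.MVMRResult`; the exposure
    component defaults to the total estimate's exposure. Total and direct
    must refer to the same exposure, stratum and outcome.
    """
    exposure = exposure or total.exposure
    if exposure not in direct.exposures:
        raise ValueError(f"exposure {exposure!r} not in MVMR result {direct.exposures}")
    if total.stratum != direct.stratum:
        raise ValueError(f"stratum mismatch: {total.stratum!r} vs {direct.stratum!r}")
    if total.outcome and direct.outcome and total.outcome != direct.outcome:
        raise ValueError(f"outcome mismatch: {total.outcome!r} vs {direct.outcome!r}")
    if total.exposure and total.exposure != exposure:
        raise ValueError(f"exposure mismatch: {total.exposure!r} vs {exposure!r}")
    d_beta, d_se, *_ = direct.effect(exposure)
    ind_beta = total.beta - d_beta
    ind_se = propagation_se(total.se, d_se)
    mediator = next(e for e in direct.exposures if e != exposure)
    return MediationDecomposition(
        total=Effect(total.beta, total.se, total.method),
        direct=Effect(d_beta, d_se, direct.method),
        indirect=Effect(ind_beta, ind_se, "difference + propagation of errors"),
        arm="MR", exposure=exposure, mediator=mediator,
        outcome=total.outcome or direct.outcome, stratum=total.stratum,
    )


# -- observational arm --------------------------------------------------

@dataclass
class ObservationalFit:
    """Coefficients and covariances from the three least-squares fits:
    model i (mediator ~ exposure + covariates), model ii (outcome ~
    exposure + mediator + covariates) and the total-effect model
    (outcome ~ exposure + covariates)."""

    a1: float          # exposure -> mediator
    a1_se: float
    b2: float          # mediator -> outcome given exposure
    b2_se: float
    direct: float      # exposure -> outcome given mediator
    direct_se: float
    total: float       # exposure -> outcome
    total_se: float
    n: int
    covariates: list[str]


def prepare_phenotypes(raw: pd.DataFrame, exposure: str, mediator: str,
                       grip_left: str = "grip_left", grip_right: str = "grip_right",
                       stratum_col: str | None = None,
                       covariates: list[str] | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """Build the analysis table from raw phenotype measurements.

    The outcome is the maximum recorded grip value (> 0) from either
    hand, with zeros treated as missing; the exposure is z-scored within
    stratum; the mediator is natural-logged (rows with non-positive
    mediator values are dropped). Rows missing any analysis variable are
    dropped; a per-reason accounting dict is returned.
    """
    covariates = covariates or []
    df = raw.copy()
    report: dict[str, int] = {"n_in": len(df)}

    left = pd.to_numeric(df[grip_left], errors="coerce")
    right = pd.to_numeric(df[grip_right], errors="coerce")
    if (left.dropna() < 0).any() or (right.dropna() < 0).any():
        raise ValueError("grip columns must be non-negative")
    grip = pd.concat([left.replace(0, np.nan), right.replace(0, np.nan)],
                     axis=1).max(axis=1)
    df["grip"] = grip

    med = pd.to_numeric(df[mediator], errors="coerce")
    bad_med = med.notna() & (med <= 0)
    report["dropped_nonpositive_mediator"] = int(bad_med.sum())
    med[bad_med] = np.nan
    df[f"log_{mediator}"] = np.log(med)

    cols = [exposure, f"log_{mediator}", "grip"] + covariates
    if stratum_col:
        cols.append(stratum_col)
    df = df[cols]
    complete = df.dropna()
    report["dropped_missing"] = len(df) - len(complete) - report["dropped_nonpositive_mediator"]
    df = complete.copy()

    def zscore(s: pd.Series) -> pd.Series:
        return (s - s.mean()) / s.std(ddof=1)

    if stratum_col:
        df[f"{exposure}_std"] = df.groupby(stratum_col, group_keys=False)[exposure].apply(zscore)
    else:
        df[f"{exposure}_std"] = zscore(df[exposure])
    report["n_out"] = len(df)
    return df.reset_index(drop=True), report


class ObservationalMediation:
    """Observational two-regression mediation model.

    Equation-wise least squares on a recursive linear system (which
    coincides with the joint-ML structural-equation estimates when all
    three equations share one covariate set). The indirect effect is the
    difference total - direct, identical to the product a1*b2; its SE is
    obtained by the delta method on the product form.

    >>> model = ObservationalMediation.from_dataframe(
    ...     df, exposure="bmi_std", mediator="log_crp", outcome="grip",
    ...     covariates=["age"])
    >>> decomp, fit = model.fit()
    """

    def __init__(self, data: pd.DataFrame, exposure: str, mediator: str,
                 outcome: str, covariates: list[str] | None = None,
                 stratum: str = "combined"):
        self.data = data
        self.exposure, self.mediator, self.outcome = exposure, mediator, outcome
        self.covariates = list(covariates or [])
        self.stratum = stratum
        needed = [exposure, mediator, outcome] + self.covariates
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        if len(data) <= len(self.covariates) + 3:
            raise ValueError("too few rows for the requested model")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, exposure: str, mediator: str,
                       outcome: str, covariates: list[str] | None = None,
                       stratum: str = "combined") -> "ObservationalMediation":
        return cls(data, exposure, mediator, outcome, covariates, stratum)

    def _ols(self, y: str, xs: list[str]):
        import statsmodels.api as sm

        design = sm.add_constant(self.data[xs])
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            corr = design.drop(columns="const").corr().abs()
            np.fill_diagonal(corr.values, 0)
            pair = corr.stack().idxmax()
            raise np.linalg.LinAlgError(
                f"rank-deficient design for {y} ~ {xs}; aliased columns near {pair}")
        return sm.OLS(self.data[y], design).fit()

    def fit(self) -> tuple[MediationDecomposition, ObservationalFit]:
        x, m, y, c = self.exposure, self.mediator, self.outcome, self.covariates
        model_i = self._ols(m, [x] + c)
        model_ii = self._ols(y, [x, m] + c)
        model_total = self._ols(y, [x] + c)

        a1, a1_se = model_i.params[x], model_i.bse[x]
        b2, b2_se = model_ii.params[m], model_ii.bse[m]
        direct, direct_se = model_ii.params[x], model_ii.bse[x]
        total, total_se = model_total.params[x], model_total.bse[x]

        indirect = total - direct
        # OLS identity: with identical covariate sets, total - direct = a1*b2
        assert abs(indirect - a1 * b2) < 1e-8 * max(1.0, abs(total)), \
            "product-difference identity violated; covariate sets differ?"
        # delta method on the product form (fits use disjoint residual
        # spaces, so cross-equation covariance of a1 and b2 is zero)
        indirect_se = math.sqrt(b2**2 * a1_se**2 + a1**2 * b2_se**2)

        fitres = ObservationalFit(
            a1=float(a1), a1_se=float(a1_se), b2=float(b2), b2_se=float(b2_se),
            direct=float(direct), direct_se=float(direct_se),
            total=float(total), total_se=float(total_se),
            n=len(self.data), covariates=c,
        )
        decomp = MediationDecomposition(
            total=Effect(float(total), float(total_se), "OLS"),
            direct=Effect(float(direct), float(direct_se), "OLS (mediator-adjusted)"),
            indirect=Effect(float(total - direct), float(indirect_se),
                            "difference (= product a1*b2), delta-method SE"),
            arm="observational", exposure=x, mediator=m, outcome=y,
            stratum=self.stratum,
            meta={"indirect_se_method": "delta method on product form"},
        )
        return decomp, fitres


def observational_mediation(data: pd.DataFrame, exposure: str, mediator: str,
                            outcome: str, covariates: list[str] | None = None,
                            stratum: str = "combined"
                            ) -> tuple[MediationDecomposition, ObservationalFit]:
    """Functional wrapper over :class:`ObservationalMediation`."""
    return ObservationalMediation(data, exposure, mediator, outcome,
                                  covariates, stratum).fit()
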