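"""Core containers for summary-statistic MR analyses.

Per-SNP association estimates are stored vectorised in pandas DataFrames;
``SNPRecord`` is the per-row view. All joins between traits are keyed on
rsid, never on genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics tables
SUMSTATS_COLUMNS = ["rsid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]


class SNPRecord(NamedTuple):
    """One SNP-trait association estimate."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # NaN when unavailable
    beta: float
    se: float
    pval: float
    n: float  # NaN when unavailable

    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryStats:
    """One trait's validated per-SNP association estimates.

    Parameters
    ----------
    trait : str
        Trait label (e.g. ``"bmi"``).
    stratum : str
        One of ``male``, ``female``, ``combined``.
    table : pandas.DataFrame
        Canonical columns :data:`SUMSTATS_COLUMNS`, one row per SNP,
        unique rsids.
    """

    trait: str
    stratum: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary-statistics table missing columns {missing}")
        if self.table["rsid"].duplicated().any():
            dupes = self.table.loc[self.table["rsid"].duplicated(), "rsid"].tolist()
            raise ValueError(f"duplicate rsids in {self.trait}: {dupes[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    def record(self, rsid: str) -> SNPRecord:
        row = self.table.loc[self.table["rsid"] == rsid]
        if row.empty:
            raise KeyError(rsid)
        r = row.iloc[0]
        return SNPRecord(
            rsid=r["rsid"], chrom=str(r["chrom"]), pos=int(r["pos"]),
            effect_allele=r["ea"], other_allele=r["oa"], eaf=float(r["eaf"]),
            beta=float(r["beta"]), se=float(r["se"]), pval=float(r["pval"]),
            n=float(r["n"]),
        )

    def subset(self, rsids) -> "SummaryStats":
        keep = self.table[self.table["rsid"].isin(set(rsids))].copy()
        return SummaryStats(self.trait, self.stratum, keep)


@dataclass
class LDMatrix:
    """Square symmetric matrix of squared LD correlations keyed by rsid."""

    rsids: list[str]
    r2: np.ndarray
    pos: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ValueError("LD matrix shape does not match rsid count")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r2 values must lie in [0, 1]")
        self._index = {rs: i for i, rs in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, a: str, b: str) -> float:
        """r2 between two SNPs; 0 when either is absent or the pair untyped."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


@dataclass
class PhenotypeCorrelation:
    """Symmetric phenotype correlation matrix for one stratum."""

    traits: list[str]
    matrix: np.ndarray
    stratum: str = "combined"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(self.traits)
        if self.matrix.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.abs(self.matrix).max() > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")
        eig = np.linalg.eigvalsh(self.matrix)
        if eig.min() < -1e-8:
            raise ValueError("correlation matrix must be positive semi-definite")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.traits.index(a), self.traits.index(b)])


@dataclass
class HarmonizedPanel:
    """SNP-aligned effect estimates across traits, allele-harmonized.

    ``beta`` and ``se`` are DataFrames indexed by rsid with one column per
    trait; ``eaf`` may be missing per entry. ``flags`` records per-SNP
    harmonization provenance (flipped traits, palindromic resolution,
    proxy substitutions).
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    exposure: str
    outcome: str
    mediator: str | None = None
    eaf: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    stratum: str = "combined"

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.se.index):
            raise ValueError("beta and se must share one rsid index")
        if list(self.beta.columns) != list(self.se.columns):
            raise ValueError("beta and se must share trait columns")
        if self.beta.isna().any().any() or self.se.isna().any().any():
            raise ValueError("harmonized panel must have no missing entries")
        if (self.se.to_numpy() <= 0).any():
            raise ValueError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.beta)

    @property
    def k(self) -> int:
        return len(self.beta)

    @property
    def rsids(self) -> list[str]:
        return self.beta.index.tolist()

    @property
    def traits(self) -> list[str]:
        return list(self.beta.columns)

    def b(self, trait: str) -> np.ndarray:
        return self.beta[trait].to_numpy(dtype=float)

    def s(self, trait: str) -> np.ndarray:
        return self.se[trait].to_numpy(dtype=float)

    # convenience accessors for the standard exposure/mediator/outcome roles
    @property
    def bx(self) -> np.ndarray:
        return self.b(self.exposure)

    @property
    def sx(self) -> np.ndarray:
        return self.s(self.exposure)

    @property
    def bm(self) -> np.ndarray:
        if self.mediator is None:
            raise ValueError("panel has no mediator trait")
        return self.b(self.mediator)

    @property
    def sm(self) -> np.ndarray:
        if self.mediator is None:
            raise ValueError("panel has no mediator trait")
        return self.s(self.mediator)

    @property
    def by(self) -> np.ndarray:
        return self.b(self.outcome)

    @property
    def sy(self) -> np.ndarray:
        return self.s(self.outcome)

    def subset(self, rsids) -> "HarmonizedPanel":
        keep = [r for r in self.beta.index if r in set(rsids)]
        return HarmonizedPanel(
            beta=self.beta.loc[keep].copy(),
            se=self.se.loc[keep].copy(),
            exposure=self.exposure,
            outcome=self.outcome,
            mediator=self.mediator,
            eaf=None if self.eaf is None else self.eaf.loc[keep].copy(),
            flags=None if self.flags is None else self.flags.loc[keep].copy(),
            stratum=self.stratum,
        )

    def drop(self, rsids) -> "HarmonizedPanel":
        omit = set(rsids)
        return self.subset([r for r in self.rsids if r not in omit])
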