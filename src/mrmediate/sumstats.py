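"""Reading, filtering, clumping, proxy substitution and harmonization of
GWAS summary statistics.

The operations here turn raw per-trait association tables into a
:class:`~mrmediate.data.HarmonizedPanel`: a SNP-aligned beta/SE matrix across
exposure(s), mediator and outcome, oriented to the effect-increasing allele
of the designated exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    COMPLEMENT,
    SUMSTATS_COLUMNS,
    VALID_ALLELES,
    HarmonizedPanel,
    LDMatrix,
    SNPRecord,
    SummaryStats,
)

logger = logging.getLogger(__name__)

#: default column-name mapping for :func:`read_sumstats`
DEFAULT_DIALECT = {
    "rsid": "rsid", "chrom": "chr", "pos": "pos", "ea": "ea", "oa": "oa",
    "eaf": "eaf", "beta": "beta", "se": "se", "pval": "pval", "n": "n",
}

#: ambiguity band for palindromic allele-frequency resolution
PALINDROMIC_EAF_BAND = (0.42, 0.58)


@dataclass
class ReadReport:
    """Row-level accounting from :func:`read_sumstats`."""

    n_read: int = 0
    n_valid: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def total_dropped(self) -> int:
        return sum(self.dropped.values())


def read_sumstats(path, trait: str, stratum: str = "combined",
                  dialect: dict[str, str] | None = None,
                  sep: str = "\t") -> tuple[SummaryStats, ReadReport]:
    """Read a delimited summary-statistics file into a validated table.

    Rows violating per-SNP invariants (se <= 0, eaf outside (0,1),
    identical or non-ACGT alleles, p outside (0,1]) are dropped and
    counted per reason in the returned :class:`ReadReport`. Alleles are
    upper-cased before validation.

    Raises
    ------
    ValueError
        If a mapped mandatory column is absent, or no valid rows remain.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, sep=sep)
    optional = {"eaf", "n"}
    for canon, col in mapping.items():
        if col not in raw.columns and canon not in optional:
            raise ValueError(f"missing mandatory column {col!r} ({canon}) in {path}")

    df = pd.DataFrame({
        canon: raw[col] if col in raw.columns else np.nan
        for canon, col in mapping.items()
    })
    report = ReadReport(n_read=len(df))

    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)
    df["rsid"] = df["rsid"].astype(str)

    checks = {
        "non_numeric_estimate": df["beta"].notna() & df["se"].notna() & df["pval"].notna(),
        "nonpositive_se": df["se"] > 0,
        "invalid_pval": (df["pval"] > 0) & (df["pval"] <= 1),
        "invalid_allele": df["ea"].isin(VALID_ALLELES) & df["oa"].isin(VALID_ALLELES),
        "identical_alleles": df["ea"] != df["oa"],
        "invalid_eaf": df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)),
        "duplicate_rsid": ~df["rsid"].duplicated(keep="first"),
    }
    keep = pd.Series(True, index=df.index)
    for reason, ok in checks.items():
        newly = keep & ~ok.fillna(False)
        if newly.any():
            report.dropped[reason] = int(newly.sum())
        keep &= ok.fillna(False)

    df = df.loc[keep, SUMSTATS_COLUMNS].reset_index(drop=True)
    report.n_valid = len(df)
    if report.n_valid == 0:
        raise ValueError(f"no valid summary-statistics rows in {path}")
    return SummaryStats(trait, stratum, df), report


def write_sumstats(ss: SummaryStats, path, sep: str = "\t") -> None:
    """Write a summary-statistics table in the canonical TSV dialect."""
    out = ss.table.rename(columns={"chrom": "chr"})
    out.to_csv(path, sep=sep, index=False)


def read_ld_matrix(path, sep: str = "\t") -> LDMatrix:
    """Read an LD r2 matrix: square with rsid header row/column, or long
    triplets (rsid1, rsid2, r2)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 2:  # long format
        long = df.reset_index()
        long.columns = ["rsid1", "rsid2", "r2"]
        rsids = sorted(set(long["rsid1"]) | set(long["rsid2"]))
        idx = {r: i for i, r in enumerate(rsids)}
        mat = np.eye(len(rsids))
        for _, row in long.iterrows():
            i, j = idx[row["rsid1"]], idx[row["rsid2"]]
            mat[i, j] = mat[j, i] = float(row["r2"])
        return LDMatrix(rsids, mat)
    return LDMatrix(df.index.astype(str).tolist(), df.to_numpy(dtype=float))


def clump(ss: SummaryStats, ld: LDMatrix, p_thr: float = 5e-8,
          r2_thr: float = 0.001, window_kb: int = 250,
          missing_ld: str = "drop") -> SummaryStats:
    """Greedy p-value-ordered LD clumping.

    SNPs passing the significance filter are visited in ascending p-value
    order (ties broken lexicographically by rsid); a SNP is accepted iff
    its r2 with every already-accepted SNP on the same chromosome within
    ``window_kb`` kb is below ``r2_thr``. Output order follows the input
    table, so the result is invariant to input row order.

    Parameters
    ----------
    missing_ld : {"drop", "error"}
        What to do with a significant SNP absent from the LD matrix.
    """
    if missing_ld not in ("drop", "error"):
        raise ValueError("missing_ld must be 'drop' or 'error'")
    sig = ss.table[ss.table["pval"] < p_thr].copy()
    absent = [r for r in sig["rsid"] if r not in ld]
    if absent:
        if missing_ld == "error":
            raise KeyError(f"rsids absent from LD matrix: {absent[:5]}")
        logger.warning("dropping %d SNPs absent from LD matrix", len(absent))
        sig = sig[~sig["rsid"].isin(absent)]

    sig = sig.sort_values(["pval", "rsid"], kind="mergesort")
    window = window_kb * 1000
    accepted: list[tuple[str, str, int]] = []  # (rsid, chrom, pos)
    for row in sig.itertuples():
        ok = True
        for a_rsid, a_chrom, a_pos in accepted:
            if a_chrom != row.chrom:
                continue
            if abs(a_pos - row.pos) > window:
                continue
            if ld.get(row.rsid, a_rsid) >= r2_thr:
                ok = False
                break
        if ok:
            accepted.append((row.rsid, row.chrom, int(row.pos)))
    kept = {r for r, _, _ in accepted}
    out = ss.table[ss.table["rsid"].isin(kept)].reset_index(drop=True)
    return SummaryStats(ss.trait, ss.stratum, out)


def find_proxies(missing: list[str], ld: LDMatrix, donor: SummaryStats,
                 r2_min: float = 0.8) -> dict[str, SNPRecord | None]:
    """For each missing SNP, the donor SNP in highest LD strictly above
    ``r2_min``; ties broken by smaller p then lexicographic rsid. ``None``
    when no candidate qualifies."""
    donor_p = dict(zip(donor.table["rsid"], donor.table["pval"]))
    out: dict[str, SNPRecord | None] = {}
    for rsid in missing:
        best: tuple[float, float, str] | None = None  # (-r2, p, rsid)
        for cand in donor.rsids:
            if cand == rsid:
                continue
            r2 = ld.get(rsid, cand)
            if r2 > r2_min:
                key = (-r2, donor_p[cand], cand)
                if best is None or key < best:
                    best = key
        out[rsid] = donor.record(best[2]) if best is not None else None
    return out


def _classify_pair(ref_ea: str, ref_oa: str, ea: str, oa: str) -> str:
    """Relation of a trait's allele pair to the reference pair."""
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swap"
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return "strand"
    if (cea, coa) == (ref_oa, ref_ea):
        return "strand_swap"
    return "irreconcilable"


@dataclass
class HarmonizeReport:
    n_in: int = 0
    n_out: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # rsid -> reason
    flipped: dict[str, list[str]] = field(default_factory=dict)  # rsid -> traits
    palindromic_resolved: list[str] = field(default_factory=list)


def harmonize(traits: list[SummaryStats], exposure: str, outcome: str,
              mediator: str | None = None,
              proxy_donors: dict[str, dict[str, str]] | None = None,
              stratum: str | None = None) -> tuple[HarmonizedPanel, HarmonizeReport]:
    """Align alleles across traits and orient to the exposure-increasing allele.

    The first trait acts as allele reference. For each shared SNP, a
    non-reference trait whose alleles are swapped (optionally on the
    opposite strand) has its beta negated and eaf complemented. Palindromic
    (A/T, C/G) SNPs are resolved by allele-frequency concordance when both
    frequencies fall outside the ambiguity band, and dropped otherwise.
    Finally every SNP is jointly sign-flipped so the designated exposure
    beta is non-negative.

    Parameters
    ----------
    proxy_donors : mapping trait -> {rsid: donor rsid}, optional
        Provenance of proxy substitutions, recorded in the panel flags.
    """
    if len(traits) < 2:
        raise ValueError("harmonize needs at least two traits")
    names = [t.trait for t in traits]
    for role in [exposure, outcome] + ([mediator] if mediator else []):
        if role not in names:
            raise ValueError(f"trait {role!r} not among {names}")
    ref = traits[0]
    shared = set(ref.rsids)
    for t in traits[1:]:
        shared &= set(t.rsids)
    order = [r for r in ref.rsids if r in shared]

    report = HarmonizeReport(n_in=len(order))
    tables = {t.trait: t.table.set_index("rsid") for t in traits}
    lo, hi = PALINDROMIC_EAF_BAND

    beta_rows, se_rows, eaf_rows, flag_rows, keep_rsids = [], [], [], [], []
    for rsid in order:
        ref_row = tables[ref.trait].loc[rsid]
        ref_ea, ref_oa = ref_row["ea"], ref_row["oa"]
        palindromic = COMPLEMENT[ref_ea] == ref_oa
        betas, ses, eafs = {}, {}, {}
        flipped_traits: list[str] = []
        drop_reason = None
        for t in traits:
            row = tables[t.trait].loc[rsid]
            b, s, f = float(row["beta"]), float(row["se"]), float(row["eaf"])
            if t.trait == ref.trait:
                betas[t.trait], ses[t.trait], eafs[t.trait] = b, s, f
                continue
            if palindromic:
                # alleles carry no strand information: use eaf concordance
                ref_f = float(ref_row["eaf"])
                if np.isnan(ref_f) or np.isnan(f):
                    drop_reason = "palindromic_missing_eaf"
                    break
                if not (lo > ref_f or ref_f > hi) or not (lo > f or f > hi):
                    drop_reason = "palindromic_ambiguous_eaf"
                    break
                if (ref_f < 0.5) != (f < 0.5):
                    b, f = -b, 1.0 - f
                    flipped_traits.append(t.trait)
                report.palindromic_resolved.append(rsid)
            else:
                rel = _classify_pair(ref_ea, ref_oa, row["ea"], row["oa"])
                if rel == "irreconcilable":
                    drop_reason = "irreconcilable_alleles"
                    break
                if rel in ("swap", "strand_swap"):
                    b, f = -b, 1.0 - f
                    flipped_traits.append(t.trait)
            betas[t.trait], ses[t.trait], eafs[t.trait] = b, s, f
        if drop_reason:
            report.dropped[rsid] = drop_reason
            continue
        # orient to the exposure-increasing allele
        if betas[exposure] < 0:
            for name in names:
                betas[name] = -betas[name]
                eafs[name] = 1.0 - eafs[name]
        keep_rsids.append(rsid)
        beta_rows.append(betas)
        se_rows.append(ses)
        eaf_rows.append(eafs)
        if flipped_traits:
            report.flipped[rsid] = flipped_traits
        donors = proxy_donors or {}
        flag_rows.append({
            "flipped": ";".join(flipped_traits),
            "palindromic_resolved": palindromic,
            "proxy_donor": ";".join(
                f"{name}:{donors[name][rsid]}" for name in donors if rsid in donors[name]
            ),
        })

    if not keep_rsids:
        raise ValueError("no SNPs survived harmonization")
    idx = pd.Index(keep_rsids, name="rsid")
    panel = HarmonizedPanel(
        beta=pd.DataFrame(beta_rows, index=idx)[names],
        se=pd.DataFrame(se_rows, index=idx)[names],
        exposure=exposure, outcome=outcome, mediator=mediator,
        eaf=pd.DataFrame(eaf_rows, index=idx)[names],
        flags=pd.DataFrame(flag_rows, index=idx),
        stratum=stratum or ref.stratum,
    )
    report.n_out = len(panel)
    return panel, report


@dataclass
class AssemblyReport:
    """Accounting for MVMR instrument assembly; the identity
    ``n_final == n_union - dropped_clump - dropped_unavailable -
    dropped_harmonization`` holds exactly."""

    n_exposure_significant: int = 0
    n_mediator_significant: int = 0
    n_union: int = 0
    dropped_clump: int = 0
    dropped_unavailable: int = 0
    dropped_harmonization: int = 0
    n_proxied: int = 0
    n_final: int = 0
    unavailable_rsids: list[str] = field(default_factory=list)
    proxy_map: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_exposure_significant": self.n_exposure_significant,
            "n_mediator_significant": self.n_mediator_significant,
            "n_union": self.n_union,
            "dropped_clump": self.dropped_clump,
            "dropped_unavailable": self.dropped_unavailable,
            "dropped_harmonization": self.dropped_harmonization,
            "n_proxied": self.n_proxied,
            "n_final": self.n_final,
            "unavailable_rsids": self.unavailable_rsids,
            "proxy_map": self.proxy_map,
        }


def assemble_mvmr_instruments(
    exposure: SummaryStats,
    mediator: SummaryStats,
    ld: LDMatrix,
    lookups: dict[str, SummaryStats],
    outcome: str,
    p_thr: float = 5e-8,
    r2_thr: float = 0.001,
    window_kb: int = 250,
    proxy_r2_min: float = 0.8,
) -> tuple[HarmonizedPanel, AssemblyReport]:
    """Build the MVMR instrument panel: union of genome-wide-significant
    exposure and mediator SNPs, cross-trait clumped, looked up in every
    trait with proxy fallback, then allele-harmonized.

    ``lookups`` maps each trait label (exposure, mediator and outcome) to
    the full summary statistics used for per-SNP lookup; SNPs unavailable
    in any trait after proxy search are removed and accounted for.
    """
    report = AssemblyReport()
    exp_sig = exposure.table[exposure.table["pval"] < p_thr]
    med_sig = mediator.table[mediator.table["pval"] < p_thr]
    report.n_exposure_significant = len(exp_sig)
    report.n_mediator_significant = len(med_sig)

    # union keyed by rsid, keeping the smaller p where a SNP is significant
    # for both traits (drives the clumping order only)
    union = (
        pd.concat([exp_sig, med_sig])
        .sort_values(["pval", "rsid"], kind="mergesort")
        .drop_duplicates("rsid", keep="first")
        .reset_index(drop=True)
    )
    report.n_union = len(union)
    union_ss = SummaryStats("union", exposure.stratum, union)
    clumped = clump(union_ss, ld, p_thr=p_thr, r2_thr=r2_thr, window_kb=window_kb)
    report.dropped_clump = report.n_union - len(clumped)

    trait_names = list(lookups)
    if outcome not in trait_names:
        raise ValueError(f"outcome {outcome!r} missing from lookups")
    # per-trait lookup with proxy fallback
    per_trait_tables: dict[str, list[pd.Series]] = {t: [] for t in trait_names}
    proxy_map: dict[str, dict[str, str]] = {t: {} for t in trait_names}
    kept_rsids: list[str] = []
    for rsid in clumped.rsids:
        rows, ok = {}, True
        for tname in trait_names:
            tab = lookups[tname].table
            hit = tab[tab["rsid"] == rsid]
            if not hit.empty:
                rows[tname] = hit.iloc[0]
                continue
            proxy = find_proxies([rsid], ld, lookups[tname], r2_min=proxy_r2_min)[rsid]
            if proxy is None:
                ok = False
                break
            row = tab[tab["rsid"] == proxy.rsid].iloc[0].copy()
            proxy_map[tname][rsid] = proxy.rsid
            row["rsid"] = rsid  # re-keyed to the index SNP it stands in for
            rows[tname] = row
        if not ok:
            report.dropped_unavailable += 1
            report.unavailable_rsids.append(rsid)
            continue
        kept_rsids.append(rsid)
        for tname in trait_names:
            per_trait_tables[tname].append(rows[tname])

    if not kept_rsids:
        raise ValueError("instrument assembly produced an empty panel")
    report.n_proxied = sum(len(m) for m in proxy_map.values())
    report.proxy_map = {t: m for t, m in proxy_map.items() if m}

    trait_ss = []
    for tname in trait_names:
        tab = pd.DataFrame(per_trait_tables[tname]).reset_index(drop=True)
        trait_ss.append(SummaryStats(tname, lookups[tname].stratum, tab))
    mediator_name = mediator.trait if mediator.trait in trait_names else None
    panel, hreport = harmonize(
        trait_ss, exposure=exposure.trait, outcome=outcome,
        mediator=mediator_name, proxy_donors=report.proxy_map,
        stratum=exposure.stratum,
    )
    report.dropped_harmonization = len(hreport.dropped)
    report.n_final = len(panel)
    assert report.n_final == (report.n_union - report.dropped_clump
                              - report.dropped_unavailable
                              - report.dropped_harmonization)
    return panel, report


def summary_f_stat(panel: HarmonizedPanel, trait: str) -> tuple[np.ndarray, float, float]:
    """Summary-based instrument strength for one trait.

    Returns per-SNP F_j = (beta_j / se_j)^2, their mean (the usual proxy
    for the instrument F-statistic when only summary data are available),
    and an approximate variance explained R^2 = sum_j beta_j^2 * 2 *
    eaf_j * (1 - eaf_j) on a standardised trait scale (NaN when allele
    frequencies are unavailable).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    b, s = panel.b(trait), panel.s(trait)
    f = (b / s) ** 2
    r2 = np.nan
    if panel.eaf is not None and trait in panel.eaf.columns:
        eaf = panel.eaf[trait].to_numpy(dtype=float)
        if not np.isnan(eaf).any():
            r2 = float(np.sum(b**2 * 2 * eaf * (1 - eaf)))
    return f, float(f.mean()), r2
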