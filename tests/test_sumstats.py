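"""Reading, clumping, proxy search and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.data import LDMatrix, SummaryStats
from mrmediate.simulate import SimulationConfig, simulate_gwas_tables, simulate_ld
from mrmediate.sumstats import (assemble_mvmr_instruments, clump, find_proxies,
                                harmonize, read_sumstats, summary_f_stat)
from mrmediate.unimr import ivw

from .conftest import make_sumstats


def write_tsv(path, rows, columns=("rsid", "chr", "pos", "ea", "oa", "eaf",
                                   "beta", "se", "pval", "n")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
    return path


class TestReadSumstats:
    def test_well_formed_rows_read_verbatim(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv", [
            ["rs1", "1", 100, "A", "G", 0.2, 0.1, 0.01, 1e-9, 1000],
            ["rs2", "1", 200, "C", "T", 0.4, -0.2, 0.02, 1e-10, 1000],
            ["rs3", "2", 300, "G", "A", 0.5, 0.05, 0.01, 0.5, 1000],
        ])
        ss, report = read_sumstats(p, "bmi", "male")
        assert len(ss) == 3
        assert report.total_dropped() == 0
        rec = ss.record("rs2")
        assert rec.beta == -0.2 and rec.effect_allele == "C"

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv", [
            ["rs1", "1", 100, "A", "G", 0.2, 0.1, 0.0, 1e-9, 1000],   # se=0
            ["rs2", "1", 200, "C", "T", 0.4, 0.2, 0.02, 1e-10, 1000],
            ["rs3", "1", 300, "A", "A", 0.4, 0.2, 0.02, 1e-10, 1000],  # ea==oa
            ["rs4", "1", 400, "A", "G", 1.4, 0.2, 0.02, 0.0, 1000],    # eaf, p
        ])
        ss, report = read_sumstats(p, "bmi")
        assert ss.rsids == ["rs2"]
        assert report.dropped["nonpositive_se"] == 1
        assert report.dropped["identical_alleles"] == 1
        assert report.total_dropped() == 3

    def test_lowercase_alleles_normalised(self, tmp_path):
        # oracle: hand-normalised expected pairs for six fixture rows
        rows = [["rs%d" % i, "1", i * 100, ea, oa, 0.2, 0.1, 0.01, 1e-9, 1000]
                for i, (ea, oa) in enumerate(
                    [("a", "g"), ("A", "g"), ("c", "T"), ("t", "c"),
                     ("G", "A"), ("g", "c")], start=1)]
        expected = [("A", "G"), ("A", "G"), ("C", "T"), ("T", "C"),
                    ("G", "A"), ("G", "C")]
        ss, _ = read_sumstats(write_tsv(tmp_path / "a.tsv", rows), "t")
        got = list(zip(ss.table["ea"], ss.table["oa"]))
        assert got == expected

    def test_missing_mandatory_column_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"rsid": ["rs1"], "beta": [0.1]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing mandatory column"):
            read_sumstats(p, "t")

    def test_zero_valid_rows_raises(self, tmp_path):
        p = write_tsv(tmp_path / "a.tsv",
                      [["rs1", "1", 100, "A", "G", 0.2, 0.1, 0.0, 1e-9, 1000]])
        with pytest.raises(ValueError, match="no valid"):
            read_sumstats(p, "t")

    def test_custom_dialect_mapping(self, tmp_path):
        p = tmp_path / "a.tsv"
        pd.DataFrame({"SNP": ["rs1"], "CHR": ["1"], "BP": [100], "A1": ["A"],
                      "A2": ["G"], "FRQ": [0.2], "B": [0.1], "SE": [0.01],
                      "P": [1e-9], "N": [5]}).to_csv(p, sep="\t", index=False)
        ss, _ = read_sumstats(p, "t", dialect={
            "rsid": "SNP", "chrom": "CHR", "pos": "BP", "ea": "A1", "oa": "A2",
            "eaf": "FRQ", "beta": "B", "se": "SE", "pval": "P", "n": "N"})
        assert ss.rsids == ["rs1"]


class TestClump:
    @pytest.fixture
    def blocks(self):
        # blocks {rs1,rs2} and {rs3,rs4}; rs5 independent, all within window
        mat = np.eye(5)
        mat[0, 1] = mat[1, 0] = 0.9
        mat[2, 3] = mat[3, 2] = 0.9
        rsids = [f"rs{i}" for i in range(1, 6)]
        return LDMatrix(rsids, mat)

    @pytest.fixture
    def five_snps(self):
        ps = [1e-10, 1e-9, 1e-12, 1e-8, 0.01]
        return make_sumstats("t", [
            {"rsid": f"rs{i+1}", "pos": 1000 + 10_000 * i, "pval": p}
            for i, p in enumerate(ps)])

    def test_greedy_selection_hand_enumerated(self, five_snps, blocks):
        # visit order by p: rs3, rs1, rs2 (blocked by rs1), rs4 (blocked by
        # rs3); rs5 fails the significance filter
        out = clump(five_snps, blocks)
        assert set(out.rsids) == {"rs3", "rs1"}

    def test_no_ld_all_significant_retained(self, five_snps):
        out = clump(five_snps, LDMatrix([f"rs{i}" for i in range(1, 6)], np.eye(5)))
        assert set(out.rsids) == {"rs1", "rs2", "rs3", "rs4"}

    def test_nothing_significant_returns_empty(self, five_snps, blocks):
        out = clump(five_snps, blocks, p_thr=1e-20)
        assert len(out) == 0

    def test_outside_window_not_clumped(self, blocks):
        ss = make_sumstats("t", [
            {"rsid": "rs1", "pos": 1000, "pval": 1e-10},
            {"rsid": "rs2", "pos": 1000 + 251_000, "pval": 1e-9},
        ])
        assert set(clump(ss, blocks).rsids) == {"rs1", "rs2"}

    def test_cross_chromosome_never_clumps(self, blocks):
        ss = make_sumstats("t", [
            {"rsid": "rs1", "chrom": "1", "pos": 1000, "pval": 1e-10},
            {"rsid": "rs2", "chrom": "2", "pos": 2000, "pval": 1e-9},
        ])
        assert set(clump(ss, blocks).rsids) == {"rs1", "rs2"}

    @pytest.mark.parametrize("perm_seed", [0, 1, 2])
    def test_row_order_invariance(self, five_snps, blocks, perm_seed):
        rng = np.random.default_rng(perm_seed)
        shuffled = SummaryStats(
            "t", "combined",
            five_snps.table.sample(frac=1, random_state=rng.integers(2**31)))
        assert set(clump(shuffled, blocks).rsids) == set(clump(five_snps, blocks).rsids)

    def test_missing_ld_snp_dropped_or_raises(self, five_snps):
        tiny = LDMatrix(["rs1", "rs2"], np.eye(2))
        out = clump(five_snps, tiny)
        assert set(out.rsids) == {"rs1", "rs2"}
        with pytest.raises(KeyError):
            clump(five_snps, tiny, missing_ld="error")


class TestFindProxies:
    def make_ld(self, entries, rsids):
        mat = np.eye(len(rsids))
        idx = {r: i for i, r in enumerate(rsids)}
        for a, b, r2 in entries:
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r2
        return LDMatrix(rsids, mat)

    def test_highest_r2_candidate_returned(self):
        donor = make_sumstats("d", [{"rsid": "rsA"}, {"rsid": "rsB"}])
        ld = self.make_ld([("rs1", "rsA", 0.95), ("rs1", "rsB", 0.85)],
                          ["rs1", "rsA", "rsB"])
        assert find_proxies(["rs1"], ld, donor)["rs1"].rsid == "rsA"

    def test_boundary_r2_strictly_above(self):
        donor = make_sumstats("d", [{"rsid": "rsA"}])
        ld = self.make_ld([("rs1", "rsA", 0.80)], ["rs1", "rsA"])
        assert find_proxies(["rs1"], ld, donor)["rs1"] is None

    def test_tie_broken_by_smaller_p(self):
        donor = make_sumstats("d", [{"rsid": "rsA", "pval": 1e-6},
                                    {"rsid": "rsB", "pval": 1e-9}])
        ld = self.make_ld([("rs1", "rsA", 0.9), ("rs1", "rsB", 0.9)],
                          ["rs1", "rsA", "rsB"])
        assert find_proxies(["rs1"], ld, donor)["rs1"].rsid == "rsB"


class TestHarmonize:
    def pair(self, exp_row, out_row):
        exp = make_sumstats("x", [exp_row])
        out = make_sumstats("y", [out_row])
        return harmonize([exp, out], exposure="x", outcome="y")

    def test_swapped_alleles_flip_beta_and_eaf(self):
        panel, rep = self.pair(
            {"rsid": "rs1", "ea": "A", "oa": "G", "beta": 0.1, "eaf": 0.2},
            {"rsid": "rs1", "ea": "G", "oa": "A", "beta": 0.3, "eaf": 0.8})
        assert panel.by[0] == pytest.approx(-0.3)
        assert panel.eaf["y"].iloc[0] == pytest.approx(0.2)
        assert rep.flipped == {"rs1": ["y"]}

    def test_identical_alleles_unchanged(self):
        panel, rep = self.pair(
            {"rsid": "rs1", "ea": "A", "oa": "G", "beta": 0.1, "eaf": 0.2},
            {"rsid": "rs1", "ea": "A", "oa": "G", "beta": 0.3, "eaf": 0.2})
        assert panel.by[0] == 0.3 and not rep.flipped

    def test_strand_complement_resolved(self):
        panel, _ = self.pair(
            {"rsid": "rs1", "ea": "A", "oa": "G", "beta": 0.1, "eaf": 0.2},
            {"rsid": "rs1", "ea": "T", "oa": "C", "beta": 0.3, "eaf": 0.2})
        assert panel.by[0] == 0.3

    def test_palindromic_discordant_frequency_flipped(self):
        panel, _ = self.pair(
            {"rsid": "rs1", "ea": "A", "oa": "T", "beta": 0.1, "eaf": 0.20},
            {"rsid": "rs1", "ea": "A", "oa": "T", "beta": 0.3, "eaf": 0.81})
        assert panel.by[0] == pytest.approx(-0.3)

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = make_sumstats("x", [
            {"rsid": "rs1", "ea": "A", "oa": "T", "eaf": 0.50},
            {"rsid": "rs2", "ea": "A", "oa": "G", "eaf": 0.2}])
        out = make_sumstats("y", [
            {"rsid": "rs1", "ea": "A", "oa": "T", "eaf": 0.50},
            {"rsid": "rs2", "ea": "A", "oa": "G", "eaf": 0.2}])
        panel, rep = harmonize([exp, out], exposure="x", outcome="y")
        assert panel.rsids == ["rs2"]
        assert rep.dropped["rs1"] == "palindromic_ambiguous_eaf"

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = make_sumstats("x", [{"rsid": "rs1", "ea": "A", "oa": "G"},
                                  {"rsid": "rs2", "ea": "A", "oa": "G"}])
        out = make_sumstats("y", [{"rsid": "rs1", "ea": "A", "oa": "C"},
                                  {"rsid": "rs2", "ea": "A", "oa": "G"}])
        panel, rep = harmonize([exp, out], exposure="x", outcome="y")
        assert panel.rsids == ["rs2"]
        assert rep.dropped["rs1"] == "irreconcilable_alleles"

    def test_exposure_oriented_nonnegative(self):
        exp = make_sumstats("x", [{"rsid": "rs1", "beta": -0.1, "eaf": 0.2}])
        out = make_sumstats("y", [{"rsid": "rs1", "beta": 0.3, "eaf": 0.2}])
        panel, _ = harmonize([exp, out], exposure="x", outcome="y")
        assert panel.bx[0] == pytest.approx(0.1)
        assert panel.by[0] == pytest.approx(-0.3)
        assert panel.eaf["x"].iloc[0] == pytest.approx(0.8)

    def test_harmonizing_harmonized_panel_is_noop(self):
        exp = make_sumstats("x", [
            {"rsid": "rs1", "ea": "A", "oa": "G", "beta": -0.1, "eaf": 0.2},
            {"rsid": "rs2", "ea": "C", "oa": "T", "beta": 0.2, "eaf": 0.7}])
        out = make_sumstats("y", [
            {"rsid": "rs1", "ea": "G", "oa": "A", "beta": 0.3, "eaf": 0.8},
            {"rsid": "rs2", "ea": "C", "oa": "T", "beta": -0.1, "eaf": 0.7}])
        panel, _ = harmonize([exp, out], exposure="x", outcome="y")
        # rebuild per-trait tables from the harmonized panel (shared alleles)
        rows = {t: [] for t in panel.traits}
        for i, rsid in enumerate(panel.rsids):
            for t in panel.traits:
                rows[t].append({"rsid": rsid, "ea": "A", "oa": "G",
                                "beta": panel.b(t)[i], "se": panel.s(t)[i],
                                "eaf": panel.eaf[t].iloc[i]})
        again, rep = harmonize([make_sumstats(t, rows[t]) for t in panel.traits],
                               exposure="x", outcome="y")
        assert not rep.flipped and not rep.dropped
        np.testing.assert_allclose(again.beta.to_numpy(), panel.beta.to_numpy())

    def test_allele_flip_leaves_causal_estimate_invariant(self):
        """Recoding any input SNP to the other allele must not change MR
        estimates downstream (end-to-end sign invariance)."""
        exp_rows = [{"rsid": f"rs{i+1}", "pos": 1000 + 10**6 * i, "beta": b,
                     "eaf": 0.3, "se": 0.01}
                    for i, b in enumerate([0.1, 0.2, 0.3])]
        out_rows = [{"rsid": f"rs{i+1}", "pos": 1000 + 10**6 * i, "beta": b,
                     "eaf": 0.3, "se": 0.01}
                    for i, b in enumerate([0.02, 0.05, 0.09])]
        panel, _ = harmonize([make_sumstats("x", exp_rows),
                              make_sumstats("y", out_rows)],
                             exposure="x", outcome="y")
        base = ivw(panel)
        flipped = [dict(r) for r in exp_rows]
        flipped[1].update(ea="G", oa="A", beta=-flipped[1]["beta"],
                          eaf=1 - flipped[1]["eaf"])
        panel2, _ = harmonize([make_sumstats("x", flipped),
                               make_sumstats("y", out_rows)],
                              exposure="x", outcome="y")
        est = ivw(panel2)
        assert est.beta == pytest.approx(base.beta, abs=1e-12)
        assert est.se == pytest.approx(base.se, abs=1e-12)


class TestAssembly:
    def test_accounting_identity_with_proxies_and_missing(self):
        cfg = SimulationConfig(k_exposure=10, k_mediator=12)
        fx = simulate_gwas_tables(cfg, seed=3, missing_mediator_in_exposure=3,
                                  proxies_for_missing=1)
        panel, rep = assemble_mvmr_instruments(
            fx["tables"]["x"], fx["tables"]["m"], fx["ld"], fx["tables"],
            outcome="y")
        d = rep.to_dict()
        assert d["n_final"] == (d["n_union"] - d["dropped_clump"]
                                - d["dropped_unavailable"]
                                - d["dropped_harmonization"])
        assert d["dropped_unavailable"] == 2 and d["n_proxied"] == 1
        assert len(panel) == 20
        assert panel.flags["proxy_donor"].str.contains("x:").sum() == 1

    def test_empty_panel_raises(self):
        cfg = SimulationConfig(k_exposure=2, k_mediator=1)
        fx = simulate_gwas_tables(cfg, seed=4)
        with pytest.raises(ValueError, match="empty panel"):
            assemble_mvmr_instruments(
                fx["tables"]["x"], fx["tables"]["m"], fx["ld"], fx["tables"],
                outcome="y", p_thr=1e-300)


class TestSummaryFStat:
    def test_single_snp_f(self):
        from .conftest import make_panel
        panel = make_panel(bx=[0.1], by=[0.0], sy=[0.01], sx=[0.02])
        f, mean_f, _ = summary_f_stat(panel, "x")
        assert f[0] == pytest.approx(25.0)

    def test_mean_of_two(self):
        from .conftest import make_panel
        panel = make_panel(bx=[0.04, 0.06], by=[0, 0], sy=[1, 1], sx=[0.01, 0.01])
        _, mean_f, _ = summary_f_stat(panel, "x")
        assert mean_f == pytest.approx((16 + 36) / 2)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_scale_invariance(self, c):
        from .conftest import make_panel
        p1 = make_panel(bx=[0.1, 0.2], by=[0, 0], sy=[1, 1], sx=[0.02, 0.05])
        p2 = make_panel(bx=[0.1 * c, 0.2 * c], by=[0, 0], sy=[1, 1],
                        sx=[0.02 * c, 0.05 * c])
        assert summary_f_stat(p1, "x")[1] == pytest.approx(
            summary_f_stat(p2, "x")[1])


def test_simulated_ld_blocks_and_psd():
    ld = simulate_ld([3, 2], within_r2=[0.9, 0.5])
    assert ld.r2[0, 1] == 0.9 and ld.r2[3, 4] == 0.5 and ld.r2[0, 3] == 0.0
    assert np.allclose(np.diag(ld.r2), 1.0)
    ident = simulate_ld([1] * 4)
    assert np.array_equal(ident.r2, np.eye(4))
    rng = np.random.default_rng(0)
    for _ in range(20):
        sizes = rng.integers(1, 5, size=rng.integers(1, 5)).tolist()
        r2s = rng.uniform(0, 1, size=len(sizes)).tolist()
        mat = simulate_ld(sizes, r2s).r2
        assert np.allclose(mat, mat.T)
        assert np.linalg.eigvalsh(mat).min() > -1e-10
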