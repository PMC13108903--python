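"""Instrument-selection filters, LD clumping and the full selection cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest

from omicmr.instruments import (
    SelectionConfig, compute_f, filter_cis, filter_confounders, filter_f,
    filter_mhc, filter_palindromic, filter_significant, ld_clump,
    select_instruments,
)
from omicmr.sumstats import GeneAnnotation, LDMatrix


def _records(rows):
    df = pd.DataFrame(rows)
    df["POS"] = df["POS"].astype(np.int64)
    return df


def _row(snp, pos, chrom="1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
         p=1e-10):
    return dict(SNP=snp, CHR=chrom, POS=pos, EA=ea, OA=oa, EAF=eaf,
                BETA=beta, SE=se, P=p, N=10000)


GENE = GeneAnnotation("G1", "G1", "1", 10_000_000)


class TestSingleFilters:
    @pytest.mark.parametrize("p, kept", [(4.9e-8, True), (5e-8, False), (1e-3, False)])
    def test_significance_strict_threshold(self, p, kept):
        out = filter_significant(_records([_row("rs1", 100, p=p)]))
        assert (len(out) == 1) == kept

    def test_significance_empty_input(self):
        out = filter_significant(_records([_row("rs1", 1)]).iloc[:0])
        assert len(out) == 0

    @pytest.mark.parametrize("pos, chrom, kept", [
        (11_000_000, "1", True),     # closed boundary at TSS + 1 Mb
        (11_000_001, "1", False),
        (9_000_000, "1", True),
        (10_500_000, "2", False),    # right distance, wrong chromosome
    ])
    def test_cis_window(self, pos, chrom, kept):
        out = filter_cis(_records([_row("rs1", pos, chrom=chrom)]), GENE)
        assert (len(out) == 1) == kept

    @pytest.mark.parametrize("pos, chrom, kept", [
        (27_000_000, "6", False),
        (26_000_000, "6", False),    # closed lower edge
        (34_000_000, "6", False),    # closed upper edge
        (25_999_999, "6", True),
        (34_000_001, "6", True),
        (27_000_000, "7", True),
    ])
    def test_mhc_exclusion(self, pos, chrom, kept):
        out = filter_mhc(_records([_row("rs1", pos, chrom=chrom)]))
        assert (len(out) == 1) == kept

    def test_f_statistic_and_threshold(self):
        assert compute_f(0.1, 0.01) == pytest.approx(100.0)
        recs = _records([
            _row("rs_strong", 100, beta=0.1, se=0.01),   # F = 100
            _row("rs_weak", 200, beta=0.03, se=0.01),    # F = 9
        ])
        out = filter_f(recs, 10.0)
        assert list(out["SNP"]) == ["rs_strong"]
        # an instrument exactly at the threshold is dropped (strict >)
        edge = _records([_row("rs_edge", 300, beta=0.05, se=0.01)])  # F = 25
        f_edge = compute_f(0.05, 0.01)
        assert len(filter_f(edge, f_edge)) == 0
        assert len(filter_f(edge, np.nextafter(f_edge, 0.0))) == 1

    def test_mean_f_of_retained_set(self):
        # instruments with F = 100 and F = 16 average to 58
        f = np.array([compute_f(0.1, 0.01), compute_f(0.04, 0.01)])
        assert f.mean() == pytest.approx(58.0)

    @pytest.mark.parametrize("ea, oa, eaf, kept", [
        ("A", "T", 0.50, False),   # maximally ambiguous palindrome
        ("T", "A", 0.58, False),
        ("C", "G", 0.45, False),
        ("A", "T", 0.10, True),    # skewed frequency disambiguates
        ("A", "G", 0.50, True),    # not palindromic
    ])
    def test_palindrome_rule(self, ea, oa, eaf, kept):
        out, dropped = filter_palindromic(
            _records([_row("rs1", 100, ea=ea, oa=oa, eaf=eaf)]))
        assert (len(out) == 1) == kept
        if not kept:
            assert dropped["rs1"] == "palindromic_ambiguous"

    def test_palindrome_missing_eaf_dropped(self):
        out, dropped = filter_palindromic(
            _records([_row("rs1", 100, ea="A", oa="T", eaf=None)]))
        assert len(out) == 0
        assert dropped["rs1"] == "palindromic_no_eaf"

    def test_palindrome_exclude_all_switch(self):
        out, _ = filter_palindromic(
            _records([_row("rs1", 100, ea="A", oa="T", eaf=0.1)]),
            exclude_all=True)
        assert len(out) == 0

    @pytest.mark.parametrize("p_conf, kept", [(5e-6, False), (2e-5, True)])
    def test_confounder_threshold(self, p_conf, kept):
        conf = pd.DataFrame({"SNP": ["rs1"], "TRAIT": ["smoking"], "P": [p_conf]})
        out = filter_confounders(_records([_row("rs1", 100)]), conf)
        assert (len(out) == 1) == kept

    def test_confounder_absent_snp_passes(self):
        conf = pd.DataFrame({"SNP": ["rs_other"], "TRAIT": ["bp"], "P": [1e-9]})
        out = filter_confounders(_records([_row("rs1", 100)]), conf)
        assert len(out) == 1


def _ld_from_corr(ids, pairs):
    r = np.eye(len(ids))
    idx = {s: i for i, s in enumerate(ids)}
    for a, b, v in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = v
    return LDMatrix(ids, r)


class TestLDClump:
    def test_stronger_snp_dominates_within_window(self):
        recs = _records([_row("rs1", 100_000, p=1e-10),
                         _row("rs2", 101_000, p=1e-9)])
        ld = _ld_from_corr(["rs1", "rs2"], [("rs1", "rs2", np.sqrt(0.9))])
        out, dropped = ld_clump(recs, ld)
        assert list(out["SNP"]) == ["rs1"]
        assert dropped["rs2"] == "ld_clumped"

    def test_below_r2_threshold_both_kept(self):
        recs = _records([_row("rs1", 100_000), _row("rs2", 101_000, p=1e-9)])
        ld = _ld_from_corr(["rs1", "rs2"], [("rs1", "rs2", np.sqrt(0.0005))])
        out, _ = ld_clump(recs, ld)
        assert len(out) == 2

    def test_r2_exactly_at_threshold_both_kept(self):
        recs = _records([_row("rs1", 100_000), _row("rs2", 101_000, p=1e-9)])
        ld = _ld_from_corr(["rs1", "rs2"], [("rs1", "rs2", np.sqrt(0.001))])
        out, _ = ld_clump(recs, ld)
        assert len(out) == 2

    def test_outside_window_both_kept(self):
        recs = _records([_row("rs1", 1), _row("rs2", 10_000_002, p=1e-9)])
        ld = _ld_from_corr(["rs1", "rs2"], [("rs1", "rs2", np.sqrt(0.9))])
        out, _ = ld_clump(recs, ld)
        assert len(out) == 2

    def test_snp_missing_from_panel_dropped_first(self):
        recs = _records([_row("rs1", 100), _row("rs_nold", 200)])
        ld = _ld_from_corr(["rs1"], [])
        out, dropped = ld_clump(recs, ld)
        assert list(out["SNP"]) == ["rs1"]
        assert dropped["rs_nold"] == "no_ld_info"

    @staticmethod
    def _greedy_oracle(recs, ld, r2_max, window):
        """Lexicographically-first maximal independent set over (p, snp_id) order.

        Enumerates every maximal conflict-free subset and returns the one whose
        sorted member sequence is smallest in the (p, id) order — which is the
        greedy-by-p solution.
        """
        rows = list(recs.itertuples())
        key = {r.SNP: (r.P, r.SNP) for r in rows}

        def conflict(a, b):
            return (a.CHR == b.CHR and abs(a.POS - b.POS) <= window
                    and ld.r2(a.SNP, b.SNP) > r2_max)

        ids = [r.SNP for r in rows]
        by_id = {r.SNP: r for r in rows}
        valid_sets = []
        for size in range(len(ids), 0, -1):
            for combo in itertools.combinations(ids, size):
                if any(conflict(by_id[a], by_id[b])
                       for a, b in itertools.combinations(combo, 2)):
                    continue
                # maximal: no outside SNP can be added
                rest = [s for s in ids if s not in combo]
                if any(all(not conflict(by_id[s], by_id[c]) for c in combo)
                       for s in rest):
                    continue
                valid_sets.append(sorted(combo, key=key.get))
        return set(min(valid_sets, key=lambda s: [key[x] for x in s]))

    def test_matches_exhaustive_oracle_on_random_panels(self, rng):
        for trial in range(25):
            k = int(rng.integers(3, 11))
            pos = np.sort(rng.choice(np.arange(1, 30) * 1_000_000, k, replace=False))
            recs = _records([
                _row(f"rs{i}", int(pos[i]), p=float(rng.uniform(1e-12, 1e-8)))
                for i in range(k)])
            r = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.uniform() < 0.4:
                        r[i, j] = r[j, i] = rng.uniform(0.05, 0.99)
            ld = LDMatrix([f"rs{i}" for i in range(k)], r)
            out, _ = ld_clump(recs, ld, 0.001, 10_000_000)
            expected = self._greedy_oracle(recs, ld, 0.001, 10_000_000)
            assert set(out["SNP"]) == expected

    def test_result_is_independent_set(self, rng):
        for trial in range(10):
            k = 12
            recs = _records([
                _row(f"rs{i}", 100_000 + i * 1000, p=float(rng.uniform(1e-12, 1e-8)))
                for i in range(k)])
            r = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    if rng.uniform() < 0.5:
                        r[i, j] = r[j, i] = rng.uniform(0, 1)
            ld = LDMatrix([f"rs{i}" for i in range(k)], r)
            out, _ = ld_clump(recs, ld, 0.001, 10_000_000)
            kept = list(out["SNP"])
            for a, b in itertools.combinations(kept, 2):
                assert ld.r2(a, b) <= 0.001


class TestSelectionPipeline:
    def test_each_stage_removes_designed_victim(self, selection_region):
        fx = selection_region
        table, audit = select_instruments(fx["exposure"], fx["outcome"],
                                          fx["gene"], fx["ld"], fx["confounders"])
        drops = {s.stage: s.dropped for s in audit.stages}
        assert set(drops["significance"]) == {"rs_sig"}
        assert set(drops["cis"]) == {"rs_cis"}
        assert set(drops["mhc"]) == {"rs_mhc"}
        assert set(drops["ld_clump"]) == {"rs_clump"}
        assert set(drops["f_stat"]) == {"rs_weakf"}
        assert set(drops["palindrome"]) == {"rs_palin"}
        assert set(drops["confounder"]) == {"rs_conf"}
        assert set(drops["harmonize"]) == {"rs_noout"}
        assert sorted(table["snp_id"]) == ["rs_keep1", "rs_keep2"]
        # the allele-swapped survivor arrives sign-flipped
        k2 = table.set_index("snp_id").loc["rs_keep2"]
        assert k2["beta_out"] == pytest.approx(0.02)
        assert k2["eaf_out"] == pytest.approx(0.3)

    def test_audit_counts_telescope(self, selection_region):
        fx = selection_region
        _, audit = select_instruments(fx["exposure"], fx["outcome"],
                                      fx["gene"], fx["ld"], fx["confounders"])
        for prev, nxt in zip(audit.stages, audit.stages[1:]):
            assert prev.n_out == nxt.n_in
            assert prev.n_in - prev.n_out == len(prev.dropped)

    def test_all_pass_region_has_zero_drops(self, selection_region):
        fx = selection_region
        keep = ["rs_keep1", "rs_keep2"]
        exposure = fx["exposure"][fx["exposure"]["SNP"].isin(keep)].reset_index(drop=True)
        table, audit = select_instruments(exposure, fx["outcome"], fx["gene"],
                                          fx["ld"], fx["confounders"])
        assert len(table) == len(exposure)
        assert all(len(s.dropped) == 0 for s in audit.stages)

    def test_no_significant_snps_yields_empty_with_notice(self, selection_region):
        fx = selection_region
        exposure = fx["exposure"].copy()
        exposure["P"] = 0.5
        table, audit = select_instruments(exposure, fx["outcome"], fx["gene"],
                                          fx["ld"], fx["confounders"])
        assert len(table) == 0
        assert audit.notes

    def test_mhc_and_palindrome_stages_commute(self, selection_region):
        fx = selection_region
        recs = fx["exposure"]
        a, da = filter_palindromic(filter_mhc(recs))
        b = filter_mhc(filter_palindromic(recs)[0])
        assert sorted(a["SNP"]) == sorted(b["SNP"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(mhc_start_bp=5, mhc_end_bp=4)
        with pytest.raises(ValueError):
            SelectionConfig(p_threshold=0.0)
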