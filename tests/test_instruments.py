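import numpy as np
import pytest
from scipy import stats

from mrshape.exceptions import DomainError, LDLookupError
from mrshape.instruments import (
    ClumpConfig,
    IV_A_PRESET,
    IV_B_PRESET,
    f_statistic,
    high_cadd_analogue,
    independent_significant,
    is_weak_instrument,
    lead_snps,
    merge_loci,
)
from mrshape.summary_io import LDMatrix, SummaryRecord
from mrshape.synthetic_data import simulate_clump_panel


def _rec(rsid, p, pos=1000, chrom="1", cadd=None):
    return SummaryRecord(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele="A", other_allele="G",
        beta=0.05, se=0.01, eaf=0.2, pvalue=p, cadd=cadd,
    )


def _greedy_oracle(records, ld, p_thr, r2_thr):
    """Independent re-statement of the greedy clump for cross-checking."""
    sig = [r for r in records if r.pvalue is not None and r.pvalue < p_thr]
    sig = sorted(sig, key=lambda r: (r.pvalue, r.pos, r.rsid))
    kept = []
    for rec in sig:
        if all(ld.r2_between(rec.rsid, k.rsid) < r2_thr for k in kept):
            kept.append(rec)
    return [r.rsid for r in kept]


class TestClumpConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ClumpConfig(p_lead=0.1, p_candidate=0.05)
        with pytest.raises(ValueError):
            ClumpConfig(r2_indep=0.05, r2_lead=0.6)

    def test_presets(self):
        assert IV_A_PRESET.p_lead == 5e-6 and IV_A_PRESET.r2_lead == 0.05
        assert IV_B_PRESET.p_lead == 5e-8 and IV_B_PRESET.r2_lead == 0.3


class TestIndependentSignificant:
    def test_correlated_pair_keeps_smaller_p(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = independent_significant([_rec("a", 1e-7), _rec("b", 1e-6)], ld, ClumpConfig())
        assert [r.rsid for r in kept] == ["a"]

    def test_uncorrelated_pair_keeps_both(self):
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.1], [0.1, 1.0]]))
        kept = independent_significant([_rec("a", 1e-7), _rec("b", 1e-6)], ld, ClumpConfig())
        assert {r.rsid for r in kept} == {"a", "b"}

    def test_missing_record_raises(self):
        ld = LDMatrix.identity(["a"])
        with pytest.raises(LDLookupError):
            independent_significant([_rec("zz", 1e-7)], ld, ClumpConfig())

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_greedy_oracle_on_block_panels(self, seed):
        records, ld = simulate_clump_panel(50, 5, seed=seed)
        cfg = ClumpConfig()
        kept = independent_significant(records, ld, cfg)
        assert [r.rsid for r in kept] == _greedy_oracle(records, ld, cfg.p_lead, cfg.r2_indep)

    def test_permutation_invariance(self):
        records, ld = simulate_clump_panel(50, 5, seed=11)
        cfg = ClumpConfig()
        reference = {r.rsid for r in independent_significant(records, ld, cfg)}
        rng = np.random.default_rng(0)
        for _ in range(3):
            shuffled = list(records)
            rng.shuffle(shuffled)
            assert {r.rsid for r in independent_significant(shuffled, ld, cfg)} == reference


class TestLeadSnps:
    def test_two_step_selection_properties(self):
        cfg = ClumpConfig()
        for seed in range(10):
            records, ld = simulate_clump_panel(50, 5, seed=seed)
            indep = independent_significant(records, ld, cfg)
            instruments = lead_snps(indep, ld, cfg, candidates=records)
            leads = [inst.lead for inst in instruments]
            assert all(l.pvalue < cfg.p_lead for l in leads)
            for i, a in enumerate(leads):
                for b in leads[i + 1:]:
                    assert ld.r2_between(a.rsid, b.rsid) < cfg.r2_lead
            oracle = _greedy_oracle(indep, ld, cfg.p_lead, cfg.r2_lead)
            assert sorted(l.rsid for l in leads) == sorted(oracle)

    def test_degenerate_r2_lead_keeps_all_independents(self):
        records, ld = simulate_clump_panel(50, 5, seed=3)
        cfg = ClumpConfig(r2_lead=1.0, r2_indep=1.0)
        indep = independent_significant(records, ld, cfg)
        instruments = lead_snps(indep, ld, cfg)
        assert sorted(i.lead.rsid for i in instruments) == sorted(r.rsid for r in indep)

    def test_singleton(self):
        ld = LDMatrix.identity(["a"])
        cfg = ClumpConfig()
        indep = independent_significant([_rec("a", 1e-7)], ld, cfg)
        instruments = lead_snps(indep, ld, cfg)
        assert len(instruments) == 1
        assert instruments[0].block == [instruments[0].lead]

    def test_three_subblock_cluster_gives_three_leads(self):
        # three tightly linked sub-blocks (within r^2 0.9) that are mutually
        # near-independent (r^2 0.01): mirrors a single-locus gene cluster
        # contributing three lead SNPs
        rsids = [f"s{i}" for i in range(9)]
        mat = np.full((9, 9), 0.01)
        for b in range(3):
            sl = slice(3 * b, 3 * b + 3)
            mat[sl, sl] = 0.9
        np.fill_diagonal(mat, 1.0)
        ld = LDMatrix(rsids, mat)
        records = [_rec(r, 10 ** -(7 + i % 3), pos=94_000_000 + 10_000 * i, chrom="14")
                   for i, r in enumerate(rsids)]
        cfg = ClumpConfig()
        instruments = lead_snps(independent_significant(records, ld, cfg), ld, cfg,
                                candidates=records)
        assert len(instruments) == 3
        # each lead's block spans its whole sub-block
        for inst in instruments:
            assert len(inst.block) == 3


class TestMergeLoci:
    def _inst(self, records, ld, cfg=ClumpConfig()):
        return lead_snps(independent_significant(records, ld, cfg), ld, cfg)

    def test_gap_below_threshold_merges(self):
        ld = LDMatrix.identity(["a", "b"])
        instruments = self._inst([_rec("a", 1e-7, pos=1_000_000), _rec("b", 1e-7, pos=1_100_000)], ld)
        assert merge_loci(instruments, gap_bp=250_000) == [0, 0]

    def test_gap_above_threshold_separates(self):
        ld = LDMatrix.identity(["a", "b"])
        instruments = self._inst([_rec("a", 1e-7, pos=1_000_000), _rec("b", 1e-7, pos=1_300_000)], ld)
        assert merge_loci(instruments, gap_bp=250_000) == [0, 1]

    def test_transitive_chain(self):
        ld = LDMatrix.identity(["a", "b", "c"])
        instruments = self._inst(
            [_rec("a", 1e-7, pos=1_000_000), _rec("b", 1e-7, pos=1_200_000),
             _rec("c", 1e-7, pos=1_400_000)], ld)
        # a-b and b-c are 200 kb apart, a-c 400 kb: transitivity joins all three
        assert merge_loci(instruments, gap_bp=250_000) == [0, 0, 0]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        chroms = rng.choice(["1", "2"], n)
        starts = rng.integers(0, 5_000_000, n)
        widths = rng.integers(10_000, 400_000, n)
        ranges = [(chroms[i], int(starts[i]), int(starts[i] + widths[i])) for i in range(n)]
        ld = LDMatrix.identity([f"r{i}" for i in range(n)])
        records = [_rec(f"r{i}", 1e-7, pos=int(starts[i]) + 1, chrom=chroms[i]) for i in range(n)]
        instruments = self._inst(records, ld)
        order = {inst.lead.rsid: k for k, inst in enumerate(instruments)}
        ordered_ranges = [None] * n
        for i in range(n):
            ordered_ranges[order[f"r{i}"]] = ranges[i]
        got = merge_loci(instruments, ordered_ranges, gap_bp=250_000)

        # oracle: explicit union-find over pairwise closeness
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                ci, si, ei = ordered_ranges[i]
                cj, sj, ej = ordered_ranges[j]
                if i < j and ci == cj and max(0, max(si, sj) - min(ei, ej)) < 250_000:
                    parent[find(i)] = find(j)
        groups = [find(i) for i in range(n)]
        # same partition (ids may differ)
        for i in range(n):
            for j in range(n):
                assert (got[i] == got[j]) == (groups[i] == groups[j])


class TestHighCadd:
    def _instrument(self, block):
        from mrshape.instruments import Instrument

        return Instrument(lead=block[0], block=list(block), f_stat=25.0)

    def test_highest_qualifying_cadd_wins(self):
        lead = _rec("lead", 1e-7)
        lo = _rec("lo", 1e-6, cadd=13.0)
        hi = _rec("hi", 1e-6, cadd=19.0)
        ld = LDMatrix(["lead", "lo", "hi"],
                      np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.8], [0.9, 0.8, 1.0]]))
        inst = self._instrument([lead, lo, hi])
        assert high_cadd_analogue(inst, ld).rsid == "hi"
        assert inst.high_cadd.rsid == "hi"

    def test_absent_when_no_cadd_above_cutoff(self):
        # the published lead blocks topped out at CADD 7.24 -> no analogue
        lead = _rec("lead", 1e-7, cadd=2.9)
        other = _rec("other", 1e-6, cadd=7.24)
        ld = LDMatrix(["lead", "other"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert high_cadd_analogue(self._instrument([lead, other]), ld) is None

    def test_low_ld_or_weak_p_disqualify(self):
        lead = _rec("lead", 1e-7)
        weak_ld = _rec("weak_ld", 1e-6, cadd=20.0)
        weak_p = _rec("weak_p", 2e-4, cadd=20.0)
        ld = LDMatrix(["lead", "weak_ld", "weak_p"],
                      np.array([[1.0, 0.2, 0.9], [0.2, 1.0, 0.1], [0.9, 0.1, 1.0]]))
        assert high_cadd_analogue(self._instrument([lead, weak_ld, weak_p]), ld) is None


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,expected",
        [(0.0567, 0.0113, 25.2), (0.0857, 0.0095, 81.4), (0.0, 0.01, 0.0)],
    )
    def test_published_spot_values(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected, abs=0.051)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            f_statistic(0.05, 0.0)

    def test_weak_instrument_predicate(self):
        assert is_weak_instrument(9.9) and not is_weak_instrument(10.1)

    def test_consistent_with_chi2_quantile_on_fixture(self, table1):
        # F = (beta/se)^2 should match the chi-square(1) quantile implied by
        # the reported p-value, up to table rounding
        for rec in table1.records:
            implied = stats.chi2.isf(rec.pvalue, 1)
            assert f_statistic(rec.beta, rec.se) == pytest.approx(implied, rel=0.05)
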