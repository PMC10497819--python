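"""Instrument selection, clumping oracle, proxies, harmonization, F stats."""

import numpy as np
import pytest

from mrmediate.instruments import (HarmonizedRecord, InstrumentSet,
                                   composite_instrument_weights, find_proxy,
                                   harmonize, mean_f_statistic,
                                   select_instruments)
from mrmediate.mr import ivw
from mrmediate.simulate import SimulationConfig, simulate_ld_block, \
    simulate_two_sample
from mrmediate.summstats import LdPanel, SummaryStats, pairwise_r2
from tests.conftest import make_assoc


def greedy_oracle(snps, panel, r2_threshold, window_kb):
    """Reference clumping: identical greedy rule, independently coded."""
    window = window_kb * 1000
    kept = []
    for cand in sorted(snps, key=lambda r: (r.pval, r.snp_id)):
        if cand.snp_id not in panel:
            continue
        cc, cp = panel.positions[cand.snp_id]
        clash = False
        for k in kept:
            kc, kp = panel.positions[k.snp_id]
            if kc == cc and abs(kp - cp) <= window:
                if pairwise_r2(panel, cand.snp_id, k.snp_id) >= r2_threshold:
                    clash = True
                    break
        if not clash:
            kept.append(cand)
    return [k.snp_id for k in kept]


class TestSelectInstruments:
    def test_independent_significant_snps_all_retained(self, tiny_panel,
                                                       simple_stats):
        # rsA/rsB are in perfect LD; rsC, rsD independent
        inst = select_instruments(simple_stats, tiny_panel, p_threshold=1e-7,
                                  r2_threshold=0.01, window_kb=10)
        assert set(inst.snp_ids()) == {"rsA", "rsC", "rsD"}

    def test_perfect_ld_pair_keeps_smaller_p(self, tiny_panel):
        ss = SummaryStats(trait="toy")
        ss.add(make_assoc(snp_id="rsA", pos=1_000_000, pval=1e-9))
        ss.add(make_assoc(snp_id="rsB", pos=1_001_000, pval=1e-12))
        inst = select_instruments(ss, tiny_panel, r2_threshold=0.5, window_kb=10)
        assert inst.snp_ids() == ["rsB"]

    def test_nonsignificant_and_uncovered_snps_dropped(self, tiny_panel):
        ss = SummaryStats(trait="toy")
        ss.add(make_assoc(snp_id="rsC", pval=1e-9))
        ss.add(make_assoc(snp_id="rsD", pval=1e-4))        # not significant
        ss.add(make_assoc(snp_id="rsZ", pval=1e-20))       # not in panel
        inst = select_instruments(ss, tiny_panel)
        assert inst.snp_ids() == ["rsC"]

    def test_empty_set_errors(self, tiny_panel):
        ss = SummaryStats(trait="toy")
        ss.add(make_assoc(snp_id="rsC", pval=0.5))
        with pytest.raises(ValueError, match="no valid instruments"):
            select_instruments(ss, tiny_panel)

    def test_clump_matches_greedy_oracle_on_ld_block(self):
        panel = simulate_ld_block(800, 10, target_r2=0.9, seed=13)
        rng = np.random.default_rng(13)
        for i in range(10):
            panel.add_variant(f"ind{i}", rng.binomial(2, 0.3, 800).astype(float),
                              chrom="2", pos=1_000_000 + 1000 * i)
        ss = SummaryStats(trait="toy")
        pvals = rng.uniform(1e-30, 1e-9, 20)
        for i, snp in enumerate(list(panel.genotypes)):
            ss.add(make_assoc(snp_id=snp, pval=float(pvals[i])))
        inst = select_instruments(ss, panel, r2_threshold=0.1, window_kb=100)
        assert inst.snp_ids() == greedy_oracle(list(ss.records.values()),
                                               panel, 0.1, 100)

    def test_row_order_invariance(self, tiny_panel, simple_stats):
        reversed_stats = SummaryStats(trait="toy")
        for rec in reversed(list(simple_stats.records.values())):
            reversed_stats.add(rec)
        a = select_instruments(simple_stats, tiny_panel, p_threshold=1e-7,
                               r2_threshold=0.01, window_kb=10)
        b = select_instruments(reversed_stats, tiny_panel, p_threshold=1e-7,
                               r2_threshold=0.01, window_kb=10)
        assert a.snp_ids() == b.snp_ids()


class TestFindProxy:
    def test_perfect_duplicate_found(self, tiny_panel):
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="rsB"))
        match = find_proxy("rsA", outcome, tiny_panel)
        assert match is not None and match.snp_id == "rsB"
        assert match.r2 == pytest.approx(1.0) and match.sign == 1

    def test_below_threshold_returns_none(self, tiny_panel):
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="rsC"))
        assert find_proxy("rsA", outcome, tiny_panel, r2_min=0.8) is None

    def test_distance_tie_break(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.3, 400).astype(float)
        panel = LdPanel(samples=[f"S{i}" for i in range(400)])
        panel.add_variant("idx", base, chrom="1", pos=100_000)
        panel.add_variant("far", base.copy(), chrom="1", pos=110_000)
        panel.add_variant("near", base.copy(), chrom="1", pos=105_000)
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="far"))
        outcome.add(make_assoc(snp_id="near"))
        match = find_proxy("idx", outcome, panel)
        assert match.snp_id == "near"

    def test_negative_correlation_sign_transferred(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.4, 300).astype(float)
        panel = LdPanel(samples=[f"S{i}" for i in range(300)])
        panel.add_variant("idx", base, chrom="1", pos=1000)
        panel.add_variant("anti", 2 - base, chrom="1", pos=2000)
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="anti"))
        match = find_proxy("idx", outcome, panel)
        assert match.sign == -1


def _instrument_set(*assocs):
    return InstrumentSet(exposure_trait="exp", snps=list(assocs),
                         per_snp_f=[(a.beta / a.se) ** 2 for a in assocs],
                         mean_f=float(np.mean([(a.beta / a.se) ** 2
                                               for a in assocs])))


class TestHarmonize:
    def test_swapped_alleles_negate_outcome(self):
        exp = _instrument_set(make_assoc(ea="A", oa="G", beta=0.1))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(ea="G", oa="A", beta=0.2, eaf=0.7))
        rec = harmonize(exp, outcome)[0]
        assert rec.Gamma == pytest.approx(-0.2)
        assert rec.aligned_effect_allele == "A"

    def test_strand_flip_same_orientation_kept(self):
        exp = _instrument_set(make_assoc(ea="A", oa="G", beta=0.1))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(ea="T", oa="C", beta=0.2))
        rec = harmonize(exp, outcome)[0]
        assert rec.Gamma == pytest.approx(0.2)

    def test_strand_flip_swapped_orientation_negated(self):
        exp = _instrument_set(make_assoc(ea="A", oa="G", beta=0.1))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(ea="C", oa="T", beta=0.2))
        rec = harmonize(exp, outcome)[0]
        assert rec.Gamma == pytest.approx(-0.2)

    def test_ambiguous_palindromic_dropped(self):
        exp = _instrument_set(make_assoc(snp_id="rsP", ea="A", oa="T", eaf=0.50),
                              make_assoc(snp_id="rsK", ea="A", oa="G"))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="rsP", ea="A", oa="T", eaf=0.50, beta=0.2))
        outcome.add(make_assoc(snp_id="rsK", ea="A", oa="G", beta=0.2))
        recs = harmonize(exp, outcome)
        assert [r.snp_id for r in recs] == ["rsK"]

    def test_palindromic_frequency_orientation(self):
        exp = _instrument_set(make_assoc(snp_id="rsP", ea="A", oa="T", eaf=0.2))
        outcome = SummaryStats(trait="out")
        # outcome reports the complementary strand: EAF on the other side
        outcome.add(make_assoc(snp_id="rsP", ea="A", oa="T", eaf=0.8, beta=0.2))
        rec = harmonize(exp, outcome)[0]
        assert rec.Gamma == pytest.approx(-0.2)
        assert rec.palindromic_flag

    def test_unresolvable_alleles_dropped(self):
        exp = _instrument_set(make_assoc(snp_id="rs1", ea="A", oa="G"),
                              make_assoc(snp_id="rs2", ea="A", oa="C"))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="rs1", ea="A", oa="C", beta=0.2))
        outcome.add(make_assoc(snp_id="rs2", ea="A", oa="C", beta=0.2))
        recs = harmonize(exp, outcome)
        assert [r.snp_id for r in recs] == ["rs2"]

    def test_double_flip_identity(self):
        exp = _instrument_set(make_assoc(ea="A", oa="G", beta=0.1, eaf=0.3))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(ea="A", oa="G", beta=0.2, eaf=0.3))
        flipped = SummaryStats(trait="out")
        flipped.add(make_assoc(ea="G", oa="A", beta=-0.2, eaf=0.7))
        a = harmonize(exp, outcome)[0]
        b = harmonize(exp, flipped)[0]
        assert (a.gamma, a.Gamma, a.aligned_effect_allele) == \
               (b.gamma, b.Gamma, b.aligned_effect_allele)

    def test_harmonization_idempotent(self):
        exp = _instrument_set(make_assoc(ea="A", oa="G", beta=0.1, eaf=0.3))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(ea="G", oa="A", beta=0.2, eaf=0.7))
        once = harmonize(exp, outcome)[0]
        # re-express the harmonized record as an outcome table and re-harmonize
        re_outcome = SummaryStats(trait="out")
        re_outcome.add(make_assoc(ea=once.aligned_effect_allele, oa="G",
                                  beta=once.Gamma, eaf=0.3))
        twice = harmonize(exp, re_outcome)[0]
        assert twice.Gamma == pytest.approx(once.Gamma, abs=0)

    def test_missing_snp_uses_proxy(self, tiny_panel):
        exp = _instrument_set(make_assoc(snp_id="rsA", beta=0.1, pval=1e-10))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="rsB", beta=0.25))
        rec = harmonize(exp, outcome, panel=tiny_panel)[0]
        assert rec.proxy_of == "rsA"
        assert rec.snp_id == "rsB"
        assert rec.Gamma == pytest.approx(0.25)

    def test_empty_harmonized_set_errors(self):
        exp = _instrument_set(make_assoc(snp_id="rs1"))
        outcome = SummaryStats(trait="out")
        outcome.add(make_assoc(snp_id="rs9"))
        with pytest.raises(ValueError, match="empty"):
            harmonize(exp, outcome)

    def test_swapped_allele_simulation_ivw_invariant(self):
        base = SimulationConfig(seed=21, n_snps=60, n_snps_mediator=0,
                                swap_allele_frac=0.0)
        swapped = SimulationConfig(seed=21, n_snps=60, n_snps_mediator=0,
                                   swap_allele_frac=0.4)
        est = {}
        for name, cfg in [("plain", base), ("swapped", swapped)]:
            exposure, _, outcome, panel, _ = simulate_two_sample(cfg)
            inst = select_instruments(exposure, panel)
            est[name] = ivw(harmonize(inst, outcome), mode="fixed")
        assert est["swapped"].beta == pytest.approx(est["plain"].beta,
                                                    rel=1e-12)
        assert est["swapped"].se == pytest.approx(est["plain"].se, rel=1e-12)


class TestCompositeWeights:
    def test_equal_components_pool_to_mean(self):
        eff = composite_instrument_weights([[0.1, 0.1, 0.1]],
                                           [[0.02, 0.02, 0.02]],
                                           [1, 1, 1])[0]
        assert eff.point == pytest.approx(0.1)
        assert eff.se == pytest.approx(0.02 / np.sqrt(3))

    def test_hand_computed_weighted_mean(self):
        b, s = [0.1, 0.3, 0.2], [0.01, 0.03, 0.02]
        w = [1 / x ** 2 for x in s]
        expected = sum(wi * bi for wi, bi in zip(w, b)) / sum(w)
        eff = composite_instrument_weights([b], [s], [1, 1, 1])[0]
        assert eff.point == pytest.approx(expected, rel=1e-12)
        assert eff.se == pytest.approx((sum(w)) ** -0.5, rel=1e-12)

    def test_orientation_invariance(self):
        a = composite_instrument_weights([[0.1, -0.3, 0.2]], [[0.01, 0.03, 0.02]],
                                         [1, -1, 1])[0]
        b = composite_instrument_weights([[0.1, 0.3, 0.2]], [[0.01, 0.03, 0.02]],
                                         [1, 1, 1])[0]
        assert a.point == pytest.approx(b.point, rel=1e-12)

    def test_single_usable_component_errors(self):
        with pytest.raises(ValueError, match="rs77"):
            composite_instrument_weights([[0.1, np.nan, np.nan]],
                                         [[0.01, 0.02, 0.03]], [1, 1, 1],
                                         snp_ids=["rs77"])


class TestMeanF:
    def test_single_snp_f(self):
        inst = _instrument_set(make_assoc(beta=0.1, se=0.01))
        assert mean_f_statistic(inst) == pytest.approx(100.0)

    def test_mean_of_two(self):
        inst = _instrument_set(make_assoc(snp_id="a", beta=0.1, se=0.01),
                               make_assoc(snp_id="b", beta=0.04, se=0.01))
        assert mean_f_statistic(inst) == pytest.approx(58.0)

    def test_weak_instrument_warning(self):
        inst = _instrument_set(make_assoc(beta=0.03, se=0.01))
        with pytest.warns(UserWarning, match="weak"):
            f = mean_f_statistic(inst)
        assert f == pytest.approx(9.0)
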