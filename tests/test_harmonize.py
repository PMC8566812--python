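import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtools.errors import ConfigurationError, EmptyHarmonizedSetError
from mrtools.harmonize import (
    FLAG_FLIPPED,
    FLAG_PALINDROMIC,
    FLAG_PROXY,
    FLAG_UNCHANGED,
    Dropped,
    HarmonizedSnp,
    LdInfo,
    build_harmonized_set,
    clump,
    harmonize_pair,
    select_instruments,
    substitute_proxies,
)

from conftest import make_record


class TestSelectInstruments:
    def test_all_nonsignificant_gives_empty(self):
        recs = [make_record(snp_id=f"rs{i}", pvalue=0.5) for i in range(4)]
        assert select_instruments(recs) == []

    def test_strict_inequality_at_threshold(self):
        # p = {1e-9, 1e-7, 4.9e-8, 5e-8, 1e-10} at 5e-8 -> 3 kept
        ps = [1e-9, 1e-7, 4.9e-8, 5e-8, 1e-10]
        recs = [make_record(snp_id=f"rs{i}", pvalue=p) for i, p in enumerate(ps)]
        kept = select_instruments(recs, 5e-8)
        assert [r.snp_id for r in kept] == ["rs0", "rs2", "rs4"]

    def test_order_preserved(self):
        recs = [make_record(snp_id=s, pvalue=1e-10) for s in ("rsZ", "rsA", "rsM")]
        assert [r.snp_id for r in select_instruments(recs)] == ["rsZ", "rsA", "rsM"]

    def test_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            select_instruments([], p_threshold=0.0)


def _positioned(snp_id, chrom, pos, p):
    return make_record(snp_id=snp_id, chrom=chrom, pos=pos, pvalue=p)


class TestClump:
    def test_outside_window_both_kept(self):
        a = _positioned("rs1", "1", 1_000_000, 1e-20)
        b = _positioned("rs2", "1", 3_000_000, 1e-9)  # 2 Mb apart
        ld = LdInfo({("rs1", "rs2"): 0.9})
        assert len(clump([a, b], ld)) == 2

    def test_in_window_high_r2_keeps_lower_p(self):
        a = _positioned("rs1", "1", 1_000_000, 1e-20)
        b = _positioned("rs2", "1", 1_010_000, 1e-9)
        ld = LdInfo({("rs1", "rs2"): 0.5})
        kept = clump([a, b], ld)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_r2_at_cutoff_is_kept(self):
        # strict inequality: 0.009 <= 0.01 keeps both; so does exactly 0.01
        a = _positioned("rs1", "1", 1_000_000, 1e-20)
        b = _positioned("rs2", "1", 1_010_000, 1e-9)
        for r2 in (0.009, 0.01):
            assert len(clump([a, b], LdInfo({("rs1", "rs2"): r2}))) == 2

    def test_different_chromosomes_ignored(self):
        a = _positioned("rs1", "1", 1_000_000, 1e-20)
        b = _positioned("rs2", "2", 1_000_500, 1e-9)
        assert len(clump([a, b], LdInfo({("rs1", "rs2"): 0.99}))) == 2

    def test_missing_r2_strict_raises_lenient_removes(self):
        a = _positioned("rs1", "1", 1_000_000, 1e-20)
        b = _positioned("rs2", "1", 1_010_000, 1e-9)
        with pytest.raises(ConfigurationError):
            clump([a, b], LdInfo())
        kept = clump([a, b], LdInfo(), strict=False)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_missing_position_raises(self):
        with pytest.raises(ConfigurationError):
            clump([make_record()], LdInfo())

    def test_positions_from_ldinfo(self):
        recs = [make_record(snp_id="rs1", pvalue=1e-9), make_record(snp_id="rs2", pvalue=1e-10)]
        ld = LdInfo({("rs1", "rs2"): 0.9},
                    positions={"rs1": ("1", 100), "rs2": ("1", 200)})
        assert [r.snp_id for r in clump(recs, ld)] == ["rs2"]

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_checker(self, data):
        k = data.draw(st.integers(2, 20))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        recs = [
            _positioned(
                f"rs{i}",
                str(rng.integers(1, 3)),
                int(rng.integers(1, 4_000_000)),
                float(rng.uniform(1e-30, 1e-8)),
            )
            for i in range(k)
        ]
        pairs = {}
        for i in range(k):
            for j in range(i + 1, k):
                pairs[(f"rs{i}", f"rs{j}")] = float(rng.uniform(0, 1))
        ld = LdInfo(pairs)
        kept = clump(recs, ld)
        kept_ids = {r.snp_id for r in kept}
        assert kept_ids <= {r.snp_id for r in recs}
        # pairwise constraint: no kept pair in-window with r2 > cutoff
        pos = {r.snp_id: (r.chrom, r.pos) for r in recs}
        for a in kept:
            for b in kept:
                if a.snp_id >= b.snp_id:
                    continue
                same = pos[a.snp_id][0] == pos[b.snp_id][0]
                near = abs(pos[a.snp_id][1] - pos[b.snp_id][1]) <= 1_000_000
                if same and near:
                    assert ld.r2(a.snp_id, b.snp_id) <= 0.01
        # maximality of the greedy rule: every removed SNP conflicts with a
        # kept SNP of smaller or equal p-value
        for r in recs:
            if r.snp_id in kept_ids:
                continue
            conflicts = [
                a for a in kept
                if pos[a.snp_id][0] == pos[r.snp_id][0]
                and abs(pos[a.snp_id][1] - pos[r.snp_id][1]) <= 1_000_000
                and ld.r2(a.snp_id, r.snp_id) > 0.01
            ]
            assert conflicts
            assert min(a.pvalue for a in conflicts) <= r.pvalue


class TestSubstituteProxies:
    def test_below_threshold_dropped(self):
        outcome = {"rsP": make_record(snp_id="rsP")}
        chosen, dropped = substitute_proxies(["rs1"], {"rs1": [("rsP", 0.79)]}, outcome)
        assert chosen == {}
        assert dropped == [Dropped("rs1", "no_proxy")]

    def test_highest_r2_wins(self):
        outcome = {"rsA": make_record(snp_id="rsA"), "rsB": make_record(snp_id="rsB")}
        chosen, dropped = substitute_proxies(
            ["rs1"], {"rs1": [("rsA", 0.8), ("rsB", 0.95)]}, outcome
        )
        assert chosen["rs1"].record.snp_id == "rsB"
        assert not dropped

    def test_tie_broken_lexicographically(self):
        outcome = {"rsA": make_record(snp_id="rsA"), "rsB": make_record(snp_id="rsB")}
        chosen, _ = substitute_proxies(["rs1"], {"rs1": [("rsB", 0.9), ("rsA", 0.9)]}, outcome)
        assert chosen["rs1"].record.snp_id == "rsA"

    def test_empty_table_drops_all(self):
        chosen, dropped = substitute_proxies(["rs1", "rs2"], {}, {})
        assert chosen == {}
        assert {d.snp_id for d in dropped} == {"rs1", "rs2"}

    def test_proxy_absent_from_outcome_ignored(self):
        chosen, dropped = substitute_proxies(["rs1"], {"rs1": [("rsX", 0.99)]}, {})
        assert chosen == {}
        assert dropped == [Dropped("rs1", "no_proxy")]


class TestHarmonizePair:
    def test_identical_alleles_unchanged(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.1)
        out = make_record(effect_allele="A", other_allele="G", beta=-0.2)
        h = harmonize_pair(exp, out)
        assert isinstance(h, HarmonizedSnp)
        assert h.Y == -0.2
        assert h.flag == FLAG_UNCHANGED

    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.1)
        out = make_record(effect_allele="G", other_allele="A", beta=-0.2, eaf=0.3)
        h = harmonize_pair(exp, out)
        assert h.Y == pytest.approx(0.2)
        assert h.outcome_eaf == pytest.approx(0.7)
        assert h.flag == FLAG_FLIPPED

    def test_strand_complement_match(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.1)
        out = make_record(effect_allele="T", other_allele="C", beta=-0.2)
        h = harmonize_pair(exp, out)
        assert h.Y == -0.2
        assert h.flag == FLAG_UNCHANGED

    def test_strand_complement_swapped(self):
        exp = make_record(effect_allele="A", other_allele="G", beta=0.1)
        out = make_record(effect_allele="C", other_allele="T", beta=-0.2)
        h = harmonize_pair(exp, out)
        assert h.Y == pytest.approx(0.2)
        assert h.flag == FLAG_FLIPPED

    def test_palindromic_keep_mode(self):
        exp = make_record(effect_allele="A", other_allele="T", beta=0.1)
        out = make_record(effect_allele="A", other_allele="T", beta=-0.2)
        h = harmonize_pair(exp, out, palindromic_mode="keep")
        assert isinstance(h, HarmonizedSnp)
        assert h.Y == -0.2
        assert h.flag == FLAG_PALINDROMIC

    def test_palindromic_keep_swapped_coding_flips(self):
        exp = make_record(effect_allele="A", other_allele="T", beta=0.1)
        out = make_record(effect_allele="T", other_allele="A", beta=-0.2)
        h = harmonize_pair(exp, out, palindromic_mode="keep")
        assert h.Y == pytest.approx(0.2)
        assert h.flag == FLAG_PALINDROMIC

    def test_palindromic_drop_mode(self):
        exp = make_record(effect_allele="C", other_allele="G", beta=0.1)
        out = make_record(effect_allele="C", other_allele="G", beta=-0.2)
        d = harmonize_pair(exp, out, palindromic_mode="drop")
        assert d == Dropped("rs1", "palindromic")

    def test_palindromic_frequency_mode_concordant_kept(self):
        exp = make_record(effect_allele="A", other_allele="T", beta=0.1, eaf=0.2)
        out = make_record(effect_allele="A", other_allele="T", beta=-0.2, eaf=0.25)
        h = harmonize_pair(exp, out, palindromic_mode="frequency")
        assert isinstance(h, HarmonizedSnp)
        assert h.flag == FLAG_PALINDROMIC

    @pytest.mark.parametrize(
        "exp_eaf,out_eaf,reason",
        [
            (0.5, 0.2, "palindromic_ambiguous_frequency"),
            (0.45, 0.2, "palindromic_ambiguous_frequency"),
            (0.2, 0.55, "palindromic_ambiguous_frequency"),
            (0.2, 0.8, "palindromic_frequency_discordant"),
            (None, 0.2, "palindromic_no_frequency"),
        ],
    )
    def test_palindromic_frequency_mode_drops(self, exp_eaf, out_eaf, reason):
        exp = make_record(effect_allele="A", other_allele="T", beta=0.1, eaf=exp_eaf)
        out = make_record(effect_allele="A", other_allele="T", beta=-0.2, eaf=out_eaf)
        d = harmonize_pair(exp, out, palindromic_mode="frequency")
        assert d == Dropped("rs1", reason)

    def test_incompatible_alleles_dropped(self):
        exp = make_record(effect_allele="A", other_allele="G")
        out = make_record(effect_allele="A", other_allele="C")
        assert harmonize_pair(exp, out) == Dropped("rs1", "incompatible_alleles")

    def test_palindromic_vs_nonpalindromic_dropped(self):
        exp = make_record(effect_allele="A", other_allele="T")
        out = make_record(effect_allele="A", other_allele="G")
        assert harmonize_pair(exp, out) == Dropped("rs1", "incompatible_alleles")

    @given(
        beta=st.floats(-2, 2, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_double_flip_idempotence(self, beta, eaf):
        """Swapping outcome alleles twice returns the original effect."""
        exp = make_record(effect_allele="A", other_allele="G", beta=0.1)
        out = make_record(effect_allele="G", other_allele="A", beta=beta, eaf=eaf)
        once = harmonize_pair(exp, out)
        # re-swap: re-encode the flipped record with exposure coding
        reswapped = make_record(
            effect_allele="A", other_allele="G", beta=once.Y,
            eaf=once.outcome_eaf,
        )
        twice = harmonize_pair(exp, reswapped)
        assert twice.Y == pytest.approx(once.Y)
        assert twice.flag == FLAG_UNCHANGED

    @given(x=st.floats(0.01, 1), y=st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_joint_negation_preserves_wald_ratio(self, x, y):
        assert (-y) / (-x) == pytest.approx(y / x, rel=1e-12)


class TestBuildHarmonizedSet:
    def test_disjoint_sets_raise(self):
        exp = [make_record(snp_id="rs1")]
        out = [make_record(snp_id="rs2")]
        with pytest.raises(EmptyHarmonizedSetError, match="exp_name"):
            build_harmonized_set(exp, out, exposure_name="exp_name")

    def test_three_pairs_one_flipped(self):
        exp = [
            make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.1),
            make_record(snp_id="rs2", effect_allele="C", other_allele="T", beta=0.2),
            make_record(snp_id="rs3", effect_allele="G", other_allele="A", beta=0.3),
        ]
        out = [
            make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.01),
            make_record(snp_id="rs2", effect_allele="T", other_allele="C", beta=0.02),
            make_record(snp_id="rs3", effect_allele="G", other_allele="A", beta=0.03),
        ]
        h = build_harmonized_set(exp, out)
        assert h.n_snp == 3
        assert h.flags.count(FLAG_FLIPPED) == 1
        assert h.Y[1] == pytest.approx(-0.02)

    def test_proxy_substitution_flagged_and_phase_applied(self):
        exp = [
            make_record(snp_id="rs1", beta=0.1),
            make_record(snp_id="rs2", beta=0.2),
        ]
        out = [
            make_record(snp_id="rs1", beta=0.01),
            make_record(snp_id="rsP", effect_allele="C", other_allele="T", beta=0.05),
        ]
        h = build_harmonized_set(
            exp, out, proxy_table={"rs2": [("rsP", 0.9, "swap")]}
        )
        assert h.n_snp == 2
        i = h.snp_ids.index("rs2")
        assert h.flags[i] == FLAG_PROXY
        assert h.Y[i] == pytest.approx(-0.05)

    def test_unproxied_missing_snp_audited(self):
        exp = [make_record(snp_id="rs1"), make_record(snp_id="rs2")]
        out = [make_record(snp_id="rs1", beta=0.01)]
        h = build_harmonized_set(exp, out)
        assert h.n_snp == 1
        assert Dropped("rs2", "no_proxy") in h.audit

    def test_drop_reasons_collected(self):
        exp = [
            make_record(snp_id="rs1", effect_allele="A", other_allele="G"),
            make_record(snp_id="rs2", effect_allele="A", other_allele="C"),
        ]
        out = [
            make_record(snp_id="rs1", effect_allele="A", other_allele="G", beta=0.01),
            make_record(snp_id="rs2", effect_allele="A", other_allele="G", beta=0.02),
        ]
        h = build_harmonized_set(exp, out)
        assert h.n_snp == 1
        assert h.audit == [Dropped("rs2", "incompatible_alleles")]
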