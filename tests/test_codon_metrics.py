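import math

import numpy as np
import pytest

from hiddenstops.codon_metrics import (
    CodonUsageTable,
    cai,
    codon_usage,
    read_usage_tsv,
    relative_adaptiveness,
    rscu,
    usage_metrics_table,
    write_usage_tsv,
)
from hiddenstops.genetic_codes import synonymous_families
from hiddenstops.sequence_io import coding_sequence


class TestCodonUsage:
    def test_direct_counting(self, std_code):
        t = codon_usage([coding_sequence("ATGATGAAA", "a")], std_code)
        assert t.counts == {"ATG": 2, "AAA": 1}
        assert t.frequencies["ATG"] == pytest.approx(2 / 3)
        assert t.frequencies["AAA"] == pytest.approx(1 / 3)

    def test_terminal_stop_excluded_by_default(self, std_code):
        t = codon_usage([coding_sequence("ATGTGA", "a")], std_code)
        assert t.counts == {"ATG": 1}

    def test_terminal_stop_kept_on_request(self, std_code):
        t = codon_usage(
            [coding_sequence("ATGTGA", "a")], std_code, exclude_terminal_stop=False
        )
        assert t.counts == {"ATG": 1, "TGA": 1}

    def test_internal_stop_is_counted(self, std_code):
        # only the TERMINAL stop is special-cased
        t = codon_usage([coding_sequence("ATGTGATGA", "a")], std_code)
        assert t.counts == {"ATG": 1, "TGA": 1}

    def test_pooling_is_additive(self, std_code):
        a = coding_sequence("ATGAAA", "a")
        b = coding_sequence("ATGCCC", "b")
        pooled = codon_usage([a, b], std_code).counts
        single = {}
        for s in (a, b):
            for c, n in codon_usage([s], std_code).counts.items():
                single[c] = single.get(c, 0) + n
        assert pooled == single

    def test_masked_codons_not_counted(self, std_code):
        t = codon_usage([coding_sequence("ATGNNNAAA", "a")], std_code)
        assert t.counts == {"ATG": 1, "AAA": 1}

    def test_no_countable_codons_errors(self, std_code):
        with pytest.raises(ValueError, match="no countable codons"):
            codon_usage([coding_sequence("NNN", "a")], std_code)

    def test_frequencies_sum_to_one(self, std_code):
        t = codon_usage([coding_sequence("ATGAAACCCGGGTTT", "a")], std_code)
        assert sum(t.frequencies.values()) == pytest.approx(1.0, abs=1e-9)


class TestRscu:
    def test_two_codon_family(self, std_code):
        t = CodonUsageTable(counts={"AAA": 3, "AAG": 1})
        r = rscu(t, std_code)
        assert r["AAA"] == pytest.approx(1.5)
        assert r["AAG"] == pytest.approx(0.5)

    def test_uniform_family_is_one(self, std_code):
        fams = synonymous_families(std_code)
        t = CodonUsageTable(counts={c: 7 for c in fams["L"]})
        r = rscu(t, std_code)
        assert all(r[c] == pytest.approx(1.0) for c in fams["L"])

    def test_single_codon_family_is_one(self, std_code):
        r = rscu(CodonUsageTable(counts={"ATG": 123}), std_code)
        assert r["ATG"] == pytest.approx(1.0)

    def test_uncounted_families_absent(self, std_code):
        r = rscu(CodonUsageTable(counts={"ATG": 1}), std_code)
        assert set(r) == {"ATG"}

    def test_family_means_are_one(self, std_code, rng):
        counts = {c: int(n) for c, n in
                  zip(std_code.codon_map, rng.integers(1, 50, size=64))}
        r = rscu(CodonUsageTable(counts=counts), std_code)
        for fam in synonymous_families(std_code).values():
            vals = [r[c] for c in fam if c in r]
            if vals:
                assert np.mean(vals) == pytest.approx(1.0)


class TestRelativeAdaptiveness:
    def test_ratio_to_family_max(self, std_code):
        w = relative_adaptiveness(
            CodonUsageTable(counts={"AAA": 4, "AAG": 2, "ATG": 1}), std_code
        )
        assert w["AAA"] == 1.0
        assert w["AAG"] == 0.5

    def test_family_max_is_one_everywhere(self, std_code, rng):
        counts = {c: int(n) for c, n in
                  zip(std_code.codon_map, rng.integers(1, 100, size=64))}
        w = relative_adaptiveness(CodonUsageTable(counts=counts), std_code)
        for aa, fam in synonymous_families(std_code).items():
            if aa == "*":
                assert not set(fam) & set(w)  # stops excluded
            else:
                assert max(w[c] for c in fam) == 1.0

    def test_zero_count_gets_floor(self, std_code):
        w = relative_adaptiveness(
            CodonUsageTable(counts={"AAA": 4}), std_code, floor=0.01
        )
        assert w["AAG"] == 0.01

    def test_empty_family_warns_and_floors(self, std_code):
        with pytest.warns(UserWarning, match="zero total count"):
            w = relative_adaptiveness(CodonUsageTable(counts={"AAA": 1}), std_code)
        assert w["ATG"] == 0.01


class TestCai:
    def _ref(self, std_code):
        t = CodonUsageTable(counts={"AAA": 2, "AAG": 4, "GCT": 1, "GCC": 1})
        with pytest.warns(UserWarning):
            return t.with_w(std_code)

    def test_family_maximal_gene_scores_one(self, std_code):
        ref = self._ref(std_code)
        assert cai(coding_sequence("AAGAAGGCT", "g"), ref, std_code) == \
            pytest.approx(1.0)

    def test_direct_geometric_mean(self, std_code):
        ref = self._ref(std_code)
        got = cai(coding_sequence("AAAAAG", "g"), ref, std_code)
        assert got == pytest.approx(math.sqrt(0.5))

    def test_single_codon_gene(self, std_code):
        ref = self._ref(std_code)
        assert cai(coding_sequence("AAA", "g"), ref, std_code) == pytest.approx(0.5)

    def test_stop_and_singleton_codons_excluded(self, std_code):
        ref = self._ref(std_code)
        # ATG (Met, singleton family) and terminal TGA must not contribute
        assert cai(coding_sequence("ATGAAATGA", "g"), ref, std_code) == \
            pytest.approx(0.5)

    def test_no_eligible_codons_errors(self, std_code):
        ref = self._ref(std_code)
        with pytest.raises(ValueError, match="no eligible codons"):
            cai(coding_sequence("ATGTGA", "g"), ref, std_code)

    def test_order_permutation_invariance(self, std_code):
        ref = self._ref(std_code)
        a = cai(coding_sequence("AAAAAGGCTGCC", "g"), ref, std_code)
        b = cai(coding_sequence("GCCGCTAAGAAA", "g"), ref, std_code)
        assert a == pytest.approx(b)

    def test_strictly_decreases_with_suboptimal_synonym(self, std_code):
        ref = self._ref(std_code)
        high = cai(coding_sequence("AAGAAGGCT", "g"), ref, std_code)
        low = cai(coding_sequence("AAGAAAGCT", "g"), ref, std_code)
        assert low < high

    def test_long_gene_no_underflow(self, std_code):
        ref = self._ref(std_code)
        got = cai(coding_sequence("AAA" * 2000, "g"), ref, std_code)
        assert got == pytest.approx(0.5)  # plain product would underflow

    def test_bounds(self, std_code, rng):
        ref = self._ref(std_code)
        gene = coding_sequence(
            "".join(rng.choice(["AAA", "AAG", "GCT", "GCC"], size=100)), "g"
        )
        assert 0 < cai(gene, ref, std_code) <= 1


class TestUsageTsv:
    def test_round_trip(self, tmp_path, std_code):
        t = CodonUsageTable(counts={"AAA": 5, "ATG": 2})
        path = tmp_path / "usage.tsv"
        write_usage_tsv(t, path)
        back = read_usage_tsv(path)
        assert back.counts["AAA"] == 5 and back.counts["ATG"] == 2

    def test_rna_letters_accepted(self, tmp_path):
        p = tmp_path / "u.tsv"
        p.write_text("codon\tcount\nAUG\t3\nUUU\t1\n")
        t = read_usage_tsv(p)
        assert t.counts == {"ATG": 3.0, "TTT": 1.0}

    def test_bad_codon_errors(self, tmp_path):
        p = tmp_path / "u.tsv"
        p.write_text("AAA\t1\nQQQ\t2\n")
        with pytest.raises(ValueError, match="not a codon"):
            read_usage_tsv(p)


def test_usage_metrics_table_shape(std_code):
    t = codon_usage([coding_sequence("ATGAAACCC", "a")], std_code)
    with pytest.warns(UserWarning):
        df = usage_metrics_table(t, std_code)
    assert len(df) == 64
    assert df["frequency"].sum() == pytest.approx(1.0)
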