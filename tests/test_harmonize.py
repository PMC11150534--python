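"""Instrument selection: p-filtering, clumping, harmonization, F-filter."""

import numpy as np
import pytest

from mrmediate.harmonize import (
    LDInfo,
    SelectionConfig,
    SelectionError,
    clump,
    compute_f_stat,
    filter_by_pvalue,
    harmonize,
    select_instruments,
)

from conftest import make_table, make_variant


class TestFilterByPvalue:
    def test_strict_inequality_at_the_threshold(self):
        table = make_table(
            [
                make_variant("a", pos=1, pvalue=4e-8),
                make_variant("b", pos=2, pvalue=5e-8),
                make_variant("c", pos=3, pvalue=6e-8),
            ]
        )
        assert filter_by_pvalue(table, 5e-8).variant_ids == ("a",)

    def test_threshold_one_keeps_everything(self):
        table = make_table([make_variant(f"v{i}", pos=i + 1, pvalue=0.99) for i in range(4)])
        assert filter_by_pvalue(table, 1.0).variant_ids == table.variant_ids

    def test_count_matches_brute_force_scan(self, rng):
        pvals = 10.0 ** rng.uniform(-12, 0, size=1000)
        table = make_table(
            [make_variant(f"v{i}", pos=i + 1, pvalue=p) for i, p in enumerate(pvals)]
        )
        expected = int(np.sum(pvals < 5e-6))  # independent brute-force count
        assert len(filter_by_pvalue(table, 5e-6)) == expected


class TestComputeFStat:
    @pytest.mark.parametrize(
        "beta,se,expected", [(0.1, 0.02, 25.0), (0.0, 0.5, 0.0), (-0.3, 0.1, 9.0)]
    )
    def test_hand_arithmetic(self, beta, se, expected):
        assert compute_f_stat(beta, se) == pytest.approx(expected)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            compute_f_stat(0.1, 0.0)


class TestClump:
    def test_smaller_p_variant_dominates_linked_neighbour(self):
        table = make_table(
            [
                make_variant("lead", pos=100_000, pvalue=1e-12),
                make_variant("tag", pos=105_000, pvalue=1e-9),
            ]
        )
        ld = LDInfo({("lead", "tag"): 0.9})
        assert clump(table, ld).variant_ids == ("lead",)

    def test_different_chromosomes_both_survive(self):
        table = make_table(
            [
                make_variant("a", chrom="1", pos=100, pvalue=1e-12),
                make_variant("b", chrom="2", pos=100, pvalue=1e-9),
            ]
        )
        ld = LDInfo({("a", "b"): 0.99})
        assert len(clump(table, ld)) == 2

    def test_absent_ld_pair_means_independent(self):
        table = make_table(
            [
                make_variant("a", pos=100, pvalue=1e-12),
                make_variant("b", pos=200, pvalue=1e-9),
            ]
        )
        assert len(clump(table, LDInfo())) == 2

    @staticmethod
    def _greedy_oracle(records, ld, r2_threshold, window_bp):
        """Independent re-implementation: set-based greedy index selection."""
        alive = {r.variant_id: r for r in records}
        chosen = []
        while alive:
            idx = min(alive.values(), key=lambda r: (r.pvalue, r.variant_id))
            chosen.append(idx.variant_id)
            for other in list(alive.values()):
                if other.variant_id == idx.variant_id:
                    continue
                if (
                    other.chrom == idx.chrom
                    and abs(other.pos - idx.pos) <= window_bp
                    and ld.get(idx.variant_id, other.variant_id) >= r2_threshold
                ):
                    del alive[other.variant_id]
            del alive[idx.variant_id]
        return chosen

    def test_five_blocks_give_five_block_minimum_survivors(self, rng):
        records, ld = [], LDInfo()
        for block in range(5):
            ids = [f"b{block}s{i}" for i in range(10)]
            for i, vid in enumerate(ids):
                records.append(
                    make_variant(
                        vid,
                        chrom=str(block + 1),
                        pos=1_000_000 + 5_000 * i,
                        pvalue=float(rng.uniform(1e-12, 1e-6)),
                    )
                )
            for i in range(10):
                for j in range(i + 1, 10):
                    ld.set(ids[i], ids[j], 0.8)
        table = make_table(records)
        result = clump(table, ld)
        assert len(result) == 5
        # each survivor is its block's p-minimum
        for block in range(5):
            block_recs = [r for r in records if r.variant_id.startswith(f"b{block}")]
            best = min(block_recs, key=lambda r: r.pvalue)
            assert best.variant_id in result.variant_ids
        assert list(result.variant_ids) == self._greedy_oracle(records, ld, 0.001, 1e7)

    def test_matches_independent_greedy_on_random_ld(self, rng):
        records = [
            make_variant(
                f"v{i}",
                chrom=str(1 + i % 3),
                pos=int(rng.integers(1, 3_000_000)),
                pvalue=float(rng.uniform(0, 1)),
            )
            for i in range(40)
        ]
        ld = LDInfo()
        for _ in range(120):
            i, j = rng.integers(0, 40, size=2)
            if i != j:
                ld.set(f"v{i}", f"v{j}", float(rng.uniform(0, 1)))
        result = clump(make_table(records), ld, r2_threshold=0.2, window_kb=1000)
        assert list(result.variant_ids) == self._greedy_oracle(records, ld, 0.2, 1_000_000)

    def test_output_p_sorted_and_pairwise_unlinked(self, rng):
        records = [
            make_variant(
                f"v{i}", chrom="1", pos=1_000_000 + 1000 * i, pvalue=float(rng.uniform(0, 1))
            )
            for i in range(30)
        ]
        ld = LDInfo()
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.3:
                    ld.set(f"v{i}", f"v{j}", float(rng.uniform(0, 1)))
        result = clump(make_table(records), ld, r2_threshold=0.1, window_kb=10000)
        pvals = [r.pvalue for r in result.records]
        assert pvals == sorted(pvals)
        for a in result.records:
            for b in result.records:
                if a.variant_id < b.variant_id and abs(a.pos - b.pos) <= 1e7:
                    assert ld.get(a.variant_id, b.variant_id) < 0.1


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exposure = make_table([make_variant("rs1", ea="A", oa="G", beta=0.1)])
        outcome = make_table([make_variant("rs1", ea="G", oa="A", beta=0.05, eaf=0.7)])
        result = harmonize(exposure, outcome)
        (inst,) = result.instruments
        assert inst.beta_out == pytest.approx(-0.05)
        assert inst.eaf_out == pytest.approx(0.3)

    def test_palindrome_at_half_frequency_dropped(self):
        exposure = make_table([make_variant("rs1", ea="A", oa="T", eaf=0.50)])
        outcome = make_table([make_variant("rs1", ea="A", oa="T", eaf=0.50, beta=0.05)])
        result = harmonize(exposure, outcome)
        assert not result.instruments
        assert result.dropped == (("rs1", "ambiguous palindrome"),)

    def test_palindrome_drop_reason_recorded(self):
        exposure = make_table(
            [
                make_variant("rs1", ea="A", oa="T", eaf=0.50),
                make_variant("rs2", pos=2_000_000, ea="A", oa="G", beta=0.2),
            ]
        )
        outcome = make_table(
            [
                make_variant("rs1", ea="A", oa="T", eaf=0.50, beta=0.05),
                make_variant("rs2", pos=2_000_000, ea="A", oa="G", beta=0.1),
            ]
        )
        result = harmonize(exposure, outcome)
        assert dict(result.dropped)["rs1"] == "ambiguous palindrome"
        assert len(result.instruments) == 1

    def test_resolvable_palindrome_uses_frequency(self):
        exposure = make_table([make_variant("rs1", ea="A", oa="T", eaf=0.10, beta=0.1)])
        aligned = make_table([make_variant("rs1", ea="A", oa="T", eaf=0.12, beta=0.05)])
        flipped = make_table([make_variant("rs1", ea="A", oa="T", eaf=0.88, beta=0.05)])
        assert harmonize(exposure, aligned).instruments[0].beta_out == pytest.approx(0.05)
        inst = harmonize(exposure, flipped).instruments[0]
        assert inst.beta_out == pytest.approx(-0.05)
        assert inst.eaf_out == pytest.approx(0.12)

    def test_twelve_snp_truth_table(self):
        """6 direct, 3 swapped, 2 strand-flipped, 1 ambiguous palindrome."""
        spec = []
        # (id, exp alleles, out alleles, expected sign or None for drop)
        for i in range(6):
            spec.append((f"d{i}", ("A", "G"), ("A", "G"), +1.0))
        for i in range(3):
            spec.append((f"s{i}", ("A", "G"), ("G", "A"), -1.0))
        spec.append(("f0", ("A", "G"), ("T", "C"), +1.0))  # strand flip
        spec.append(("f1", ("C", "A"), ("T", "G"), -1.0))  # strand flip + swap
        spec.append(("p0", ("A", "T"), ("A", "T"), None))  # ambiguous palindrome

        exp_records, out_records = [], []
        for k, (vid, (eea, eoa), (oea, ooa), _) in enumerate(spec):
            exp_records.append(
                make_variant(vid, pos=(k + 1) * 10**6, ea=eea, oa=eoa, beta=0.1, eaf=0.5)
            )
            out_records.append(
                make_variant(vid, pos=(k + 1) * 10**6, ea=oea, oa=ooa, beta=0.05, eaf=0.5)
            )
        result = harmonize(make_table(exp_records), make_table(out_records))
        assert len(result.instruments) == 11
        by_id = {i.variant_id: i for i in result.instruments}
        for vid, _, _, sign in spec:
            if sign is None:
                assert vid not in by_id
            else:
                assert by_id[vid].beta_out == pytest.approx(sign * 0.05), vid

    def test_incompatible_alleles_dropped_with_reason(self):
        exposure = make_table(
            [
                make_variant("rs1", ea="A", oa="G"),
                make_variant("rs2", pos=2_000_000, ea="A", oa="G"),
            ]
        )
        outcome = make_table(
            [
                make_variant("rs1", ea="A", oa="C", beta=0.05),
                make_variant("rs2", pos=2_000_000, ea="A", oa="G", beta=0.1),
            ]
        )
        result = harmonize(exposure, outcome)
        assert dict(result.dropped)["rs1"] == "incompatible alleles"

    def test_empty_intersection_raises(self):
        exposure = make_table([make_variant("rs1")])
        outcome = make_table([make_variant("rs2")])
        with pytest.raises(SelectionError, match="no shared instruments"):
            harmonize(exposure, outcome)

    def test_self_harmonization_gives_unit_ratios(self):
        table = make_table(
            [
                make_variant(f"v{i}", pos=(i + 1) * 10**6, ea="A", oa="G", beta=0.1 * (i + 1))
                for i in range(5)
            ]
        )
        result = harmonize(table, table)
        assert all(inst.ratio == pytest.approx(1.0) for inst in result.instruments)


class TestSelectInstruments:
    def _exposure_outcome(self, n=12):
        exp = [
            make_variant(
                f"v{i}", chrom=str(1 + i % 22), pos=10**6 * (1 + i), beta=0.1, se=0.01, pvalue=1e-10
            )
            for i in range(n)
        ]
        out = [
            make_variant(
                f"v{i}", chrom=str(1 + i % 22), pos=10**6 * (1 + i), beta=0.02, se=0.01, pvalue=0.05
            )
            for i in range(n)
        ]
        return make_table(exp, trait_id="exp"), make_table(out, trait_id="out")

    def test_twelve_strong_independent_snps_all_survive(self):
        exposure, outcome = self._exposure_outcome(12)
        result = select_instruments(exposure, outcome)
        assert len(result) == 12

    def test_no_significant_snp_fails_at_p_filter(self):
        exposure, outcome = self._exposure_outcome(5)
        weak = make_table(
            [make_variant(f"v{i}", pos=10**6 * (1 + i), pvalue=0.5) for i in range(5)],
            trait_id="exp",
        )
        with pytest.raises(SelectionError, match="p_filter"):
            select_instruments(weak, outcome)

    def test_attrition_log_on_mixed_fixture(self):
        """40 candidates -> 9 significant -> 8 clumped -> 8 harmonized -> 7 strong."""
        exp_records, out_records = [], []
        for i in range(40):
            significant = i < 9
            exp_records.append(
                make_variant(
                    f"v{i}",
                    chrom="1" if i in (0, 1) else str(2 + i % 20),
                    pos=1_000_000 + (5_000 if i == 1 else 10**7 * i),
                    beta=0.03 if i == 2 else 0.1,  # v2: reported p and z disagree -> F = 9
                    se=0.01,
                    pvalue=1e-10 * (i + 1) if significant else 0.5,
                )
            )
            out_records.append(
                make_variant(
                    f"v{i}",
                    chrom="1" if i in (0, 1) else str(2 + i % 20),
                    pos=1_000_000 + (5_000 if i == 1 else 10**7 * i),
                    beta=0.02,
                    se=0.01,
                    pvalue=0.05,
                )
            )
        ld = LDInfo({("v0", "v1"): 0.9})  # v1 clumped away by v0
        result = select_instruments(
            make_table(exp_records, trait_id="exp"), make_table(out_records, trait_id="out"), ld
        )
        steps = [(a.step, a.n_in, a.n_out) for a in result.attrition]
        assert steps == [
            ("p_filter", 40, 9),
            ("clump", 9, 8),
            ("harmonize", 8, 8),
            ("f_filter", 8, 7),
        ]
        assert len(result) == 7
        # counts chain: each step's output feeds the next step's input
        for first, second in zip(result.attrition, result.attrition[1:]):
            assert first.n_out == second.n_in

    def test_f_filter_strictness(self):
        # F exactly 10 is retained ("less than 10 removed")
        exposure = make_table(
            [make_variant("v0", beta=0.1 * 10**0.5, se=0.1, pvalue=1e-10)], trait_id="exp"
        )
        outcome = make_table([make_variant("v0", beta=0.02)], trait_id="out")
        result = select_instruments(exposure, outcome)
        assert len(result) == 1
        assert result.instruments[0].f_stat == pytest.approx(10.0)
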