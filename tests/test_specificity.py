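"""Top-pMHC calls, exact Wilcoxon, expected binders, concordance, accuracy."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tcrpair import (
    Clonotype,
    Dataset,
    GemRecord,
    annotation_accuracy,
    binding_concordance,
    expected_binder,
    gem_top_pmhc,
    wilcoxon_signed_rank_greater,
)


def pgem(gid, counts, clonotype=None):
    return GemRecord(gem_id=gid, pmhc_counts=dict(counts), clonotype_id=clonotype)


def make_clonotype(cid, gems):
    return Clonotype(clonotype_id=cid, cdr3a="CAAF", cdr3b="CASSF",
                     member_gems=[g.gem_id for g in gems])


def enumeration_pvalue(diffs):
    """Exact one-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.array([x for x in diffs if x != 0], dtype=float)
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= observed - 1e-9:
            count += 1
    return count / 2**n


class TestTopPmhc:
    def test_argmax_and_runner_up(self):
        s = gem_top_pmhc(pgem("g", {"A": 5, "B": 2}))
        assert (s.top_feature, s.umi_max, s.umi_sec, s.tie_flag) == ("A", 5, 2, False)

    def test_tie_has_no_unique_top(self):
        s = gem_top_pmhc(pgem("g", {"A": 3, "B": 3}))
        assert s.tie_flag and s.top_feature is None

    def test_singleton(self):
        s = gem_top_pmhc(pgem("g", {"A": 4}))
        assert (s.top_feature, s.umi_sec) == ("A", 0)

    def test_no_counts_returns_none(self):
        assert gem_top_pmhc(pgem("g", {})) is None


class TestWilcoxon:
    def test_all_positive_ten_differences(self):
        assert wilcoxon_signed_rank_greater([5, 5, 7, 5, 5, 7, 5, 6, 6, 6]) == (
            pytest.approx(1 / 1024)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        diffs = rng.integers(-4, 6, size=int(rng.integers(3, 12))).tolist()
        if all(d == 0 for d in diffs):
            diffs[0] = 1
        assert wilcoxon_signed_rank_greater(diffs) == pytest.approx(
            enumeration_pvalue(diffs)
        )

    def test_matches_scipy_on_tie_free_input(self):
        rng = np.random.default_rng(3)
        diffs = rng.permutation(np.arange(1, 13) * np.resize([1, -1, 1], 12))
        ours = wilcoxon_signed_rank_greater(diffs)
        ref = stats.wilcoxon(diffs, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(float(ref))

    def test_all_zero_differences_undefined(self):
        assert wilcoxon_signed_rank_greater([0, 0, 0]) is None

    def test_large_sample_normal_tail(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(1.0, 1.0, size=60)
        p = wilcoxon_signed_rank_greater(diffs)
        assert 0 < p < 1e-4


class TestExpectedBinder:
    def test_small_clonotypes_untested(self):
        gems = [pgem(f"g{i}", {"A": 5, "B": 1}) for i in range(9)]
        eb = expected_binder(make_clonotype("c", gems), {g.gem_id: g for g in gems})
        assert not eb.tested and eb.pmhc_id is None

    def test_clear_winner_assigned_with_exact_p(self):
        xs = [5, 6, 7, 5, 6, 7, 5, 6, 7, 6]
        ys = [0, 1, 0, 0, 1, 0, 0, 0, 1, 0]
        gems = [
            pgem(f"g{i}", {"X": x, **({"Y": y} if y else {})})
            for i, (x, y) in enumerate(zip(xs, ys))
        ]
        eb = expected_binder(make_clonotype("c", gems), {g.gem_id: g for g in gems})
        assert eb.tested and eb.pmhc_id == "X"
        assert eb.p_value == pytest.approx(1 / 1024)

    def test_absent_pmhc_counts_as_zero(self):
        """Missing entries enter the paired test as 0 UMI."""
        gems = [pgem(f"g{i}", {"X": 4}) for i in range(5)]
        gems += [pgem(f"h{i}", {"X": 4, "Y": 1}) for i in range(5)]
        eb = expected_binder(make_clonotype("c", gems), {g.gem_id: g for g in gems})
        # diffs are 4,4,4,4,4,3,3,3,3,3 -> all positive, p = 1/1024
        assert eb.p_value == pytest.approx(1 / 1024)
        assert eb.pmhc_id == "X"

    def test_single_pmhc_degenerate_assignment(self):
        gems = [pgem(f"g{i}", {"A": 3}) for i in range(12)]
        eb = expected_binder(make_clonotype("c", gems), {g.gem_id: g for g in gems})
        assert eb.degenerate and eb.pmhc_id == "A" and eb.p_value is None

    def test_exactness_against_enumeration_for_small_clonotypes(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(10, 13))
            top = rng.integers(0, 8, size=n)
            sec = rng.integers(0, 8, size=n)
            gems = [
                pgem(f"g{i}", {k: v for k, v in (("X", 10 + t), ("Y", s)) if v})
                for i, (t, s) in enumerate(zip(top, sec))
            ]
            eb = expected_binder(
                make_clonotype("c", gems), {g.gem_id: g for g in gems}
            )
            diffs = (top + 10) - sec
            assert eb.p_value == pytest.approx(enumeration_pvalue(diffs))

    def test_recovers_planted_targets_without_noise(self, clean_sim):
        from conftest import annotate
        from tcrpair.specificity import expected_binders_for_dataset

        ds = annotate(clean_sim[0])
        truth = clean_sim[1].set_index("gem_id")
        expected = expected_binders_for_dataset(ds)
        for cid, ct in ds.clonotypes.items():
            if len(ct.member_gems) < 10:
                continue
            planted = truth.loc[ct.member_gems[0], "target_pmhc"]
            assert expected[cid].pmhc_id == planted


class TestConcordance:
    def test_direct_count_oracle(self):
        gems = [pgem("g0", {"A": 5}), pgem("g1", {"A": 2}),
                pgem("g2", {"A": 9, "B": 1}), pgem("g3", {"B": 7})]
        entries, n_tied = binding_concordance(
            make_clonotype("c", gems), {g.gem_id: g for g in gems}
        )
        fracs = {e.pmhc_id: e.fraction for e in entries}
        assert fracs == {"A": 0.75, "B": 0.25} and n_tied == 0

    def test_single_gem_clonotype_has_concordance_one(self):
        gems = [pgem("g0", {"A": 2})]
        entries, _ = binding_concordance(
            make_clonotype("c", gems), {g.gem_id: g for g in gems}
        )
        assert entries[0].fraction == 1.0

    def test_tied_gems_excluded_from_both_sides(self):
        gems = [pgem("g0", {"A": 5}), pgem("g1", {"A": 3}),
                pgem("g2", {"A": 2, "B": 2})]
        entries, n_tied = binding_concordance(
            make_clonotype("c", gems), {g.gem_id: g for g in gems}
        )
        assert n_tied == 1
        assert {e.pmhc_id: e.fraction for e in entries} == {"A": 1.0}

    def test_fractions_sum_to_one(self, small_sim):
        from conftest import annotate

        ds = annotate(small_sim[0])
        for ct in ds.clonotypes.values():
            entries, _ = binding_concordance(ct, ds.gems)
            if entries:
                assert sum(e.fraction for e in entries) == pytest.approx(1.0, abs=1e-12)


class TestAccuracy:
    def _dataset(self, tops, target="A"):
        gems = [pgem(f"g{i}", {t: 5} if t else {}, clonotype="c") for i, t in enumerate(tops)]
        ds = Dataset.from_parts(gems)
        ds.clonotypes = {"c": make_clonotype("c", gems)}
        return ds

    def test_ratio_of_matches(self):
        from tcrpair.specificity import ExpectedBinder

        ds = self._dataset(["A"] * 7 + ["B"] * 3)
        expected = {"c": ExpectedBinder("c", pmhc_id="A", tested=True, n_gems=10)}
        assert annotation_accuracy(ds, expected) == pytest.approx(0.7)

    def test_all_match_gives_one(self):
        from tcrpair.specificity import ExpectedBinder

        ds = self._dataset(["A"] * 5)
        expected = {"c": ExpectedBinder("c", pmhc_id="A", tested=True, n_gems=5)}
        assert annotation_accuracy(ds, expected) == 1.0

    def test_undefined_without_targets(self):
        from tcrpair.specificity import ExpectedBinder

        ds = self._dataset(["A"] * 5)
        assert annotation_accuracy(ds, {"c": ExpectedBinder("c")}) is None

    def test_adding_matching_gem_never_decreases(self):
        from tcrpair.specificity import ExpectedBinder

        expected = {"c": ExpectedBinder("c", pmhc_id="A", tested=True, n_gems=4)}
        ds = self._dataset(["A", "B", "A"])
        before = annotation_accuracy(ds, expected)
        ds2 = self._dataset(["A", "B", "A", "A"])
        assert annotation_accuracy(ds2, expected) >= before
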