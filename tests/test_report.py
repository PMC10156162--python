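"""Stage reports, adjusted multimer cell counts, and the capture comparison."""

import numpy as np
import pytest

from tcrpair import (
    Clonotype,
    Dataset,
    GemRecord,
    MultimerResponse,
    adjusted_cell_counts,
    compare_with_multimer,
    compute_report,
)
from tcrpair.specificity import ExpectedBinder

from conftest import annotate


def pgem(gid, counts, clonotype="c"):
    return GemRecord(gem_id=gid, pmhc_counts=dict(counts), clonotype_id=clonotype)


class TestComputeReport:
    def test_noise_free_dataset_is_perfect(self, clean_sim):
        from tcrpair.specificity import expected_binders_for_dataset

        ds = annotate(clean_sim[0])
        expected = expected_binders_for_dataset(ds)
        report = compute_report(ds, "total", expected)
        assert report.accuracy == 1.0
        assert report.avg_concordance == 1.0
        assert report.retained_fraction == 1.0

    def test_gem_weighted_average_concordance(self):
        gems = [pgem("g0", {"A": 5}), pgem("g1", {"A": 4}),
                pgem("g2", {"A": 3}), pgem("g3", {"B": 7})]
        ds = Dataset.from_parts(gems)
        ds.clonotypes = {
            "c": Clonotype("c", cdr3a="CAAF", cdr3b="CASSF",
                           member_gems=[g.gem_id for g in gems])
        }
        expected = {"c": ExpectedBinder("c", pmhc_id="A", tested=True, n_gems=4)}
        report = compute_report(ds, "total", expected)
        # three GEMs at concordance 0.75, one at 0.25
        assert report.avg_concordance == pytest.approx((0.75 * 3 + 0.25) / 4)
        assert report.accuracy == pytest.approx(0.75)


def resp(donor, pmhc, freq, events):
    return MultimerResponse(donor, pmhc, freq, events)


class TestAdjustedCounts:
    def test_sole_response_takes_all_sorted_cells(self):
        out = adjusted_cell_counts([resp("d1", "pA", 0.1, 50)])
        assert out[0].adjusted_cells == pytest.approx(1800)

    def test_proportional_allocation(self):
        out = adjusted_cell_counts(
            [resp("d1", "pA", 0.3, 50), resp("d1", "pB", 0.1, 20)]
        )
        assert out[0].adjusted_cells == pytest.approx(1350)
        assert out[1].adjusted_cells == pytest.approx(450)

    def test_conserves_sorted_total_per_donor(self):
        rng = np.random.default_rng(2)
        responses = [
            resp(f"d{i % 3}", f"p{j}", float(rng.uniform(0.01, 1)), 30)
            for i in range(3) for j in range(4)
        ]
        out = adjusted_cell_counts(responses)
        for donor in {"d0", "d1", "d2"}:
            total = sum(r.adjusted_cells for r in out if r.donor_id == donor)
            assert total == pytest.approx(1800, abs=1e-9)

    @pytest.mark.parametrize(
        "freq,events,expect",
        [(0.005, 8, False),   # few events and below the 0.01% floor
         (0.002, 10, True),   # boundary of the many-event rule
         (0.01, 5, True),     # few events but frequent
         (0.001, 100, False)],
    )
    def test_detection_threshold_rule(self, freq, events, expect):
        assert resp("d", "p", freq, events).above_threshold is expect


class TestCompareWithMultimer:
    def test_perfect_agreement(self):
        responses = adjusted_cell_counts(
            [resp("d1", f"p{i}", 0.1 * (i + 1), 50) for i in range(6)]
        )
        gems = {("d1", f"p{i}"): 10 + i for i in range(6)}
        out = compare_with_multimer(responses, gems)
        assert out["recall"] == 1.0 and out["precision"] == 1.0
        # all-positive table has zero margins for the negative class
        assert out["mcc"] is None

    def test_known_2x2_table(self):
        # TP=3, FP=1, FN=0, TN=2
        responses = adjusted_cell_counts(
            [resp("d1", "p0", 0.2, 50), resp("d1", "p1", 0.2, 50),
             resp("d1", "p2", 0.2, 50),
             resp("d1", "p4", 0.0001, 2), resp("d1", "p5", 0.0001, 2)]
        )
        gems = {("d1", "p0"): 5, ("d1", "p1"): 3, ("d1", "p2"): 2,
                ("d1", "p3"): 1}
        out = compare_with_multimer(responses, gems)
        assert out["table"] == {"tp": 3, "fp": 1, "fn": 0, "tn": 2}
        assert out["recall"] == 1.0
        assert out["precision"] == pytest.approx(0.75)
        expect_mcc = (3 * 2 - 1 * 0) / np.sqrt(4 * 3 * 3 * 2)
        assert out["mcc"] == pytest.approx(expect_mcc)

    def test_mcc_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(3)
        for _ in range(10):
            truth = rng.integers(0, 2, size=12)
            query = rng.integers(0, 2, size=12)
            responses = []
            gems = {}
            for i, (t, q) in enumerate(zip(truth, query)):
                key = ("d", f"p{i}")
                responses.append(resp("d", f"p{i}", 0.5 if t else 0.0001, 50 if t else 2))
                if q:
                    gems[key] = 3
            out = compare_with_multimer(adjusted_cell_counts(responses), gems)
            ref = matthews_corrcoef(truth, query)
            if out["mcc"] is None:
                assert ref == 0.0
            else:
                assert out["mcc"] == pytest.approx(ref)

    def test_log_log_regression_recovers_planted_line(self):
        # counts planted on log10(y) = 0.86 log10(x) + 1.18 exactly
        rng = np.random.default_rng(4)
        responses = []
        gems = {}
        for i in range(8):
            freq = float(rng.uniform(0.05, 2.0))
            responses.append(resp("d", f"p{i}", freq, 50))
        adjusted = adjusted_cell_counts(responses)
        for r in adjusted:
            y = 10 ** (0.86 * np.log10(r.adjusted_cells) + 1.18)
            gems[(r.donor_id, r.pmhc_id)] = int(round(y))
        out = compare_with_multimer(adjusted, gems)
        assert out["regression"]["slope"] == pytest.approx(0.86, abs=0.02)
        assert out["regression"]["intercept"] == pytest.approx(1.18, abs=0.05)
        assert out["regression"]["r2"] > 0.99

    def test_printed_regression_line_example(self):
        """The published fit predicts ~100 captured GEMs at 9 adjusted cells."""
        y = 10 ** (0.86 * np.log10(9.0) + 1.18)
        assert y == pytest.approx(100, rel=0.05)
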