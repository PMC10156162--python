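"""The filter cascade: individual rules, composition, monotone removal."""

import pytest

from tcrpair import (
    ChainObservation,
    Dataset,
    FilterConfig,
    GemRecord,
    PanelEntry,
    SampleInfo,
    UmiThresholds,
    apply_filter_chain,
)
from tcrpair.filters import (
    filter_complete_tcr,
    filter_hashing_singlets,
    filter_hla_match,
    filter_specificity_multiplets,
    filter_umi_thresholds,
    filter_viable_cells,
)
from tcrpair.hashing import HashClassification
from tcrpair.specificity import ExpectedBinder, expected_binders_for_dataset

from conftest import annotate


def gem(gid, pmhc, hashes=None, clonotype="c1", **kw):
    return GemRecord(gem_id=gid, pmhc_counts=dict(pmhc),
                     hash_counts=dict(hashes or {}), clonotype_id=clonotype, **kw)


PANEL = [
    PanelEntry("pA", "PEPTIDEA", "A*03:01", "ACGT"),
    PanelEntry("pB", "PEPTIDEB", "B*07:02", "CGTA"),
]
SAMPLES = [
    SampleInfo("h1", "d1", frozenset({"A*03:01"})),
    SampleInfo("h2", "d2", frozenset({"A*01:01", "A*02:01"})),
]


def singlet(gid, hash_id):
    return HashClassification(gid, "singlet", frozenset({hash_id}))


class TestUmiThresholdFilter:
    THR = UmiThresholds(min_umi={"pmhc": 2, "tra": 0, "trb": 0},
                        min_ratio={"pmhc": 1.0, "tra": 0.0, "trb": 0.0})

    @pytest.mark.parametrize(
        "counts,kept",
        [({"pA": 1}, False),        # below the 2-UMI floor
         ({"pA": 3, "pB": 3}, False),  # ratio 3/3.25 <= 1
         ({"pA": 10, "pB": 2}, True)],  # clears both criteria
    )
    def test_count_and_ratio_criteria(self, counts, kept):
        ds = Dataset.from_parts([gem("g", counts)], PANEL, SAMPLES)
        out = filter_umi_thresholds(ds, self.THR)
        assert ("g" in out.gems) == kept


class TestHlaMatch:
    def test_matching_allele_retained(self):
        ds = Dataset.from_parts([gem("g", {"pA": 5})], PANEL, SAMPLES)
        out = filter_hla_match(ds, ds.samples, {"g": singlet("g", "h1")})
        assert "g" in out.gems

    def test_mismatching_allele_removed(self):
        ds = Dataset.from_parts([gem("g", {"pB": 5})], PANEL, SAMPLES)
        out = filter_hla_match(ds, ds.samples, {"g": singlet("g", "h2")})
        assert out.n_gems == 0

    def test_doublet_uses_union_of_haplotypes(self):
        ds = Dataset.from_parts([gem("g", {"pA": 5})], PANEL, SAMPLES)
        call = HashClassification("g", "doublet", frozenset({"h1", "h2"}))
        out = filter_hla_match(ds, ds.samples, {"g": call})
        assert "g" in out.gems

    def test_negative_gems_removed(self):
        ds = Dataset.from_parts([gem("g", {"pA": 5})], PANEL, SAMPLES)
        out = filter_hla_match(
            ds, ds.samples, {"g": HashClassification("g", "negative")}
        )
        assert out.n_gems == 0


class TestHashingSinglets:
    def test_label_based_retention(self):
        ds = Dataset.from_parts(
            [gem("s", {"pA": 1}), gem("d", {"pA": 1}), gem("n", {"pA": 1})],
            PANEL, SAMPLES,
        )
        calls = {
            "s": singlet("s", "h1"),
            "d": HashClassification("d", "doublet", frozenset({"h1", "h2"})),
            "n": HashClassification("n", "negative"),
        }
        out = filter_hashing_singlets(ds, calls)
        assert set(out.gems) == {"s"}


def chain(locus, umi=3, nt="aaa"):
    return ChainObservation(locus, "V", "J", "", "CAAF", nt, umi, True, True)


class TestCompleteTcr:
    def test_exactly_one_pair_retained(self):
        g = gem("g", {"pA": 1})
        g.chains = [chain("TRA"), chain("TRB")]
        g.n_tra_raw, g.n_trb_raw = 1, 1
        out = filter_complete_tcr(Dataset.from_parts([g], PANEL, SAMPLES))
        assert "g" in out.gems

    @pytest.mark.parametrize("n_a,n_b", [(1, 0), (0, 1), (2, 1), (1, 3)])
    def test_missing_or_multiple_chains_removed(self, n_a, n_b):
        g = gem("g", {"pA": 1})
        g.n_tra_raw, g.n_trb_raw = n_a, n_b
        out = filter_complete_tcr(Dataset.from_parts([g], PANEL, SAMPLES))
        assert out.n_gems == 0

    def test_chain_ambiguous_removed(self):
        g = gem("g", {"pA": 1})
        g.n_tra_raw, g.n_trb_raw, g.chain_ambiguous = 1, 1, True
        out = filter_complete_tcr(Dataset.from_parts([g], PANEL, SAMPLES))
        assert out.n_gems == 0


class TestSpecificityMultiplets:
    def _ds(self, specs):
        gems = [gem(f"g{i}", {p: 5}, clonotype=c) for i, (c, p) in enumerate(specs)]
        ds = Dataset.from_parts(gems, PANEL, SAMPLES)
        return ds

    def test_supported_pairs_retained(self):
        ds = self._ds([("c1", "pA")] * 3)
        assert filter_specificity_multiplets(ds).n_gems == 3

    def test_singleton_pair_removed(self):
        ds = self._ds([("c1", "pA"), ("c1", "pB"), ("c1", "pA")])
        out = filter_specificity_multiplets(ds)
        assert out.n_gems == 2

    def test_recounts_on_current_set(self):
        """A pair reduced to one GEM by an earlier step loses its support."""
        ds = self._ds([("c1", "pA"), ("c1", "pA")])
        reduced = ds.subset(["g0"])
        assert filter_specificity_multiplets(reduced).n_gems == 0


class TestViableCells:
    @pytest.mark.parametrize(
        "n_genes,mito,kept",
        [(2600, 0.05, False), (150, 0.05, False), (1000, 0.25, False),
         (1000, 0.05, True), (200, 0.2, True), (2500, 0.0, True)],
    )
    def test_gene_and_mito_bounds(self, n_genes, mito, kept):
        g = gem("g", {"pA": 1}, n_genes=n_genes, mito_fraction=mito)
        out = filter_viable_cells(Dataset.from_parts([g], PANEL, SAMPLES))
        assert ("g" in out.gems) == kept

    def test_skipped_without_gex(self):
        g = gem("g", {"pA": 1})
        out = filter_viable_cells(Dataset.from_parts([g], PANEL, SAMPLES))
        assert "g" in out.gems


class TestFilterChain:
    def test_empty_step_list_is_identity(self, small_sim):
        ds = annotate(small_sim[0])
        expected = expected_binders_for_dataset(ds)
        out, reports = apply_filter_chain(ds, FilterConfig(steps=[]), expected)
        assert out.n_gems == ds.n_gems
        assert len(reports) == 1 and reports[0].step == "total"

    def test_every_step_only_removes(self, default_sim):
        from tcrpair.hashing import demultiplex_hashing

        ds = annotate(default_sim[0])
        expected = expected_binders_for_dataset(ds)
        calls = {
            c.gem_id: c
            for c in demultiplex_hashing(
                {g.gem_id: g.hash_counts for g in ds.iter_gems()},
                n_samples=len(ds.samples),
            )
        }
        config = FilterConfig(
            thresholds=UmiThresholds(
                min_umi={"pmhc": 2, "tra": 0, "trb": 0},
                min_ratio={"pmhc": 1.0, "tra": 0.0, "trb": 0.0},
            )
        )
        _, reports = apply_filter_chain(
            ds, config, expected, hash_calls=calls, mode="cumulative"
        )
        counts = [r.n_gems for r in reports]
        assert counts == sorted(counts, reverse=True)
        clono = [r.n_clonotypes for r in reports]
        assert clono == sorted(clono, reverse=True)

    def test_order_insensitive_steps_commute(self, small_sim):
        from tcrpair.filters import filter_umi_thresholds, filter_viable_cells

        ds = annotate(small_sim[0])
        thr = UmiThresholds(min_umi={"pmhc": 2, "tra": 0, "trb": 0},
                            min_ratio={"pmhc": 0.0, "tra": 0.0, "trb": 0.0})
        ab = filter_viable_cells(filter_umi_thresholds(ds, thr))
        ba = filter_umi_thresholds(filter_viable_cells(ds), thr)
        assert set(ab.gems) == set(ba.gems)

    def test_is_cell_requires_flags(self):
        ds = Dataset.from_parts([gem("g", {"pA": 1})], PANEL, SAMPLES)
        from tcrpair.model import ConfigurationError

        with pytest.raises(ConfigurationError):
            apply_filter_chain(
                ds, FilterConfig(steps=["is_cell"]),
                {"c1": ExpectedBinder("c1")},
            )
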