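"""The composable GEM filter cascade.

Each filter only removes GEMs.  Filters can be evaluated individually on
the raw data or cumulatively in a fixed order; only the
specificity-multiplet step is order-sensitive because it recounts
(clonotype, pMHC) pair support on the current set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

from .gridsearch import UmiThresholds, threshold_mask
from .hashing import HashClassification
from .model import ConfigurationError, Dataset, SampleInfo
from .specificity import ExpectedBinder, annotation_accuracy, average_concordance, gem_top_pmhc

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterStepReport",
    "filter_umi_thresholds",
    "filter_hla_match",
    "filter_hashing_singlets",
    "filter_complete_tcr",
    "filter_specificity_multiplets",
    "filter_is_cell",
    "filter_is_cell_gex",
    "filter_viable_cells",
    "apply_filter_chain",
]

DEFAULT_STEP_ORDER = [
    "umi_thresholds",
    "hla_match",
    "hashing_singlets",
    "complete_tcr",
    "specificity_multiplets",
    "is_cell",
    "is_cell_gex",
    "viable_cell",
]


@dataclass
class FilterConfig:
    steps: list[str] = field(default_factory=lambda: list(DEFAULT_STEP_ORDER))
    thresholds: UmiThresholds = field(default_factory=UmiThresholds)
    min_genes: int = 200
    max_genes: int = 2500
    max_mito: float = 0.2

    def validate(self) -> None:
        unknown = [s for s in self.steps if s not in DEFAULT_STEP_ORDER]
        if unknown:
            raise ConfigurationError(f"unknown filter step(s): {unknown}")


@dataclass
class FilterStepReport:
    step: str
    n_gems: int
    n_clonotypes: int
    accuracy: Optional[float]
    avg_concordance: Optional[float]
    retained_fraction: float


def filter_umi_thresholds(dataset: Dataset, thresholds: UmiThresholds) -> Dataset:
    """Keep GEMs passing every enabled UMI count (>=) and ratio (>) threshold."""
    mask = threshold_mask(dataset, thresholds)
    keep = [g.gem_id for g, m in zip(dataset.iter_gems(), mask) if m]
    return dataset.subset(keep)


def _implicated_donors(
    call: HashClassification, samples: dict[str, SampleInfo]
) -> list[SampleInfo]:
    return [samples[h] for h in call.positive_hashes if h in samples]


def filter_hla_match(
    dataset: Dataset,
    samples: dict[str, SampleInfo],
    hash_calls: dict[str, HashClassification],
) -> Dataset:
    """Keep GEMs whose top pMHC's restricting HLA is in the donor haplotype.

    For hashing doublets the union of the implicated donors' haplotypes is
    used; hashing-negative GEMs and GEMs with a tied top pMHC are removed
    (no defined specificity to match).
    """
    keep = []
    for gem in dataset.iter_gems():
        call = hash_calls.get(gem.gem_id)
        if call is None or call.label == "negative":
            continue
        summary = gem_top_pmhc(gem)
        if summary is None or summary.tie_flag:
            continue
        panel_entry = dataset.panel.get(summary.top_feature)
        if panel_entry is None:
            continue
        donors = _implicated_donors(call, samples)
        haplotype: set[str] = set()
        for d in donors:
            if not d.hla_haplotype:
                raise ConfigurationError(f"donor {d.donor_id} has empty haplotype")
            haplotype |= d.hla_haplotype
        if panel_entry.hla_allele in haplotype:
            keep.append(gem.gem_id)
    return dataset.subset(keep)


def filter_hashing_singlets(
    dataset: Dataset, hash_calls: dict[str, HashClassification]
) -> Dataset:
    keep = [
        g.gem_id
        for g in dataset.iter_gems()
        if hash_calls.get(g.gem_id) is not None
        and hash_calls[g.gem_id].label == "singlet"
    ]
    return dataset.subset(keep)


def filter_complete_tcr(dataset: Dataset) -> Dataset:
    """Keep GEMs with exactly one alpha and one beta chain.

    Pre-selection multiplicity counts when dominant-chain selection has
    been applied; chain-ambiguous GEMs (UMI-tied multiplets) are removed.
    """
    keep = []
    for gem in dataset.iter_gems():
        n_a = gem.n_tra_raw if gem.n_tra_raw is not None else len(gem.chains_of("TRA"))
        n_b = gem.n_trb_raw if gem.n_trb_raw is not None else len(gem.chains_of("TRB"))
        if n_a == 1 and n_b == 1 and not gem.chain_ambiguous:
            keep.append(gem.gem_id)
    return dataset.subset(keep)


def filter_specificity_multiplets(dataset: Dataset) -> Dataset:
    """Keep GEMs whose (clonotype, top pMHC) pair has >=2 GEMs in the
    current set.  Support is recounted on the set this filter receives,
    so the step is order-dependent within a cascade."""
    pair_counts: dict[tuple[str, str], int] = {}
    pairs: dict[str, tuple[str, str]] = {}
    for gem in dataset.iter_gems():
        summary = gem_top_pmhc(gem)
        if gem.clonotype_id is None or summary is None or summary.tie_flag:
            continue
        pair = (gem.clonotype_id, summary.top_feature)
        pairs[gem.gem_id] = pair
        pair_counts[pair] = pair_counts.get(pair, 0) + 1
    keep = [gid for gid, pair in pairs.items() if pair_counts[pair] >= 2]
    return dataset.subset(keep)


def filter_is_cell(dataset: Dataset) -> Dataset:
    if any(g.is_cell_flag is None for g in dataset.iter_gems()):
        raise ConfigurationError("is_cell flags are absent from the input")
    return dataset.subset(
        [g.gem_id for g in dataset.iter_gems() if g.is_cell_flag]
    )


def filter_is_cell_gex(dataset: Dataset) -> Dataset:
    if any(g.is_cell_gex_flag is None for g in dataset.iter_gems()):
        raise ConfigurationError("is_cell (GEX) flags are absent from the input")
    return dataset.subset(
        [g.gem_id for g in dataset.iter_gems() if g.is_cell_gex_flag]
    )


def filter_viable_cells(
    dataset: Dataset,
    min_genes: int = 200,
    max_genes: int = 2500,
    max_mito: float = 0.2,
) -> Dataset:
    """Keep GEMs with min_genes <= n_genes <= max_genes and mito <= max_mito.

    GEMs above the gene ceiling are likely doublets; below the floor or
    with a high mitochondrial load, likely dead cells.  Skipped with a
    warning when gene-expression summaries are absent.
    """
    if all(g.n_genes is None for g in dataset.iter_gems()):
        logger.warning("no gene-expression summaries; viability filter skipped")
        return dataset
    keep = []
    for g in dataset.iter_gems():
        if g.n_genes is None or g.mito_fraction is None:
            continue
        if min_genes <= g.n_genes <= max_genes and g.mito_fraction <= max_mito:
            keep.append(g.gem_id)
    return dataset.subset(keep)


def apply_filter_chain(
    dataset: Dataset,
    config: FilterConfig,
    expected: dict[str, ExpectedBinder],
    samples: Optional[dict[str, SampleInfo]] = None,
    hash_calls: Optional[dict[str, HashClassification]] = None,
    mode: str = "cumulative",
) -> tuple[Dataset, list[FilterStepReport]]:
    """Apply the configured steps, reporting metrics after each.

    ``mode='cumulative'`` chains the steps; ``mode='single'`` evaluates
    each step independently on the input dataset (the returned dataset is
    then the unfiltered input).  Accuracy is always measured against the
    fixed expected-binder labels supplied by the caller.
    """
    config.validate()
    samples = samples or dataset.samples
    hash_calls = hash_calls or {}

    step_fns: dict[str, Callable[[Dataset], Dataset]] = {
        "umi_thresholds": lambda ds: filter_umi_thresholds(ds, config.thresholds),
        "hla_match": lambda ds: filter_hla_match(ds, samples, hash_calls),
        "hashing_singlets": lambda ds: filter_hashing_singlets(ds, hash_calls),
        "complete_tcr": filter_complete_tcr,
        "specificity_multiplets": filter_specificity_multiplets,
        "is_cell": filter_is_cell,
        "is_cell_gex": filter_is_cell_gex,
        "viable_cell": lambda ds: filter_viable_cells(
            ds, config.min_genes, config.max_genes, config.max_mito
        ),
    }

    n_total = dataset.n_gems

    def report(label: str, ds: Dataset) -> FilterStepReport:
        return FilterStepReport(
            step=label,
            n_gems=ds.n_gems,
            n_clonotypes=ds.n_clonotypes,
            accuracy=annotation_accuracy(ds, expected),
            avg_concordance=(
                average_concordance(ds) if ds.clonotypes is not None else None
            ),
            retained_fraction=ds.n_gems / n_total if n_total else 0.0,
        )

    reports = [report("total", dataset)]
    current = dataset
    for step in config.steps:
        filtered = step_fns[step](current if mode == "cumulative" else dataset)
        reports.append(report(step, filtered))
        if mode == "cumulative":
            current = filtered
    return (current if mode == "cumulative" else dataset), reports
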