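"""End-to-end orchestration: ingest -> clonotyping -> demux -> binders ->
grid search -> filter cascade -> evaluation, with per-stage artifacts."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as tio
from .clonotyping import (
    collapse_and_impute_clonotypes,
    filter_dataset_contigs,
    select_dominant_chains_dataset,
)
from .filters import DEFAULT_STEP_ORDER, FilterConfig, apply_filter_chain
from .gridsearch import UmiThresholds, grid_search_thresholds
from .hashing import demultiplex_hashing
from .model import ConfigurationError, Dataset, GemRecord
from .similarity import (
    LabeledClonotype,
    intra_inter_scores,
    intra_vs_inter_test,
    similarity_auc,
)
from .specificity import binding_concordance, expected_binders_for_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "assemble_dataset", "similarity_auc_for_dataset"]


@dataclass
class PipelineConfig:
    contigs: Optional[str] = None
    matrix_dir: Optional[str] = None  # matrix.mtx + features.tsv + barcodes.tsv
    panel: Optional[str] = None
    samples: Optional[str] = None
    out_dir: str = "tcrpair_out"
    seed: int = 0
    steps: list[str] = field(default_factory=lambda: list(DEFAULT_STEP_ORDER))
    filter_mode: str = "cumulative"
    grid_search: bool = True
    wilcoxon_variant: str = "paired"
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("contigs", "panel", "samples"):
            p = getattr(self, name)
            if p is None:
                raise ConfigurationError(f"missing required input path: {name}")
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.matrix_dir is None or not Path(self.matrix_dir).is_dir():
            raise ConfigurationError(f"matrix_dir does not exist: {self.matrix_dir}")


def assemble_dataset(config: PipelineConfig) -> Dataset:
    """Build a Dataset from 10x-style inputs.

    Only GEMs carrying at least one TCR contig and at least one pMHC
    barcode enter the dataset (droplets void of either carry no pairing
    information).
    """
    panel = tio.read_panel_config(config.panel)
    samples = tio.read_sample_config(config.samples)
    contigs = tio.read_contig_annotations(config.contigs)
    mdir = Path(config.matrix_dir)
    counts = tio.read_feature_counts(
        mdir / "matrix.mtx", mdir / "features.tsv", mdir / "barcodes.tsv"
    )
    gems: dict[str, GemRecord] = {}
    for gem_id, obs in contigs.records:
        gem = gems.setdefault(gem_id, GemRecord(gem_id=gem_id))
        gem.chains.append(obs)
    for gem_id, gem in gems.items():
        gem.pmhc_counts = counts.class_counts(gem_id, "pmhc")
        gem.hash_counts = counts.class_counts(gem_id, "hashing")
        gem.clonotype_id = contigs.vendor_clonotypes.get(gem_id)
        if gem_id in contigs.is_cell_flags:
            gem.is_cell_flag = contigs.is_cell_flags[gem_id]
    keep = [g for g in gems.values() if g.chains and g.pmhc_counts]
    ds = Dataset.from_parts(keep, panel, samples)
    ds.validate()
    return ds


def similarity_auc_for_dataset(
    dataset: Dataset,
    expected,
    seed: int = 0,
) -> tuple[Optional[float], Optional[float], list]:
    """Label clonotypes, compute intra/inter records, AUC and test p-value.

    A clonotype's label is its expected target, or its highest-concordance
    pMHC when no target was assigned; only both-chain clonotypes enter.
    """
    labeled = []
    for cid, ct in (dataset.clonotypes or {}).items():
        if ct.cdr3a is None or ct.cdr3b is None:
            continue
        label = None
        eb = expected.get(cid)
        if eb is not None and eb.pmhc_id is not None:
            label = eb.pmhc_id
        else:
            entries, _ = binding_concordance(ct, dataset.gems)
            if entries:
                label = max(entries, key=lambda e: (e.fraction, e.pmhc_id)).pmhc_id
        if label is not None:
            labeled.append(
                LabeledClonotype(cid, ct.cdr3a, ct.cdr3b, label)
            )
    records = intra_inter_scores(labeled, seed=seed)
    return similarity_auc(records), intra_vs_inter_test(records), records


def run_pipeline(config: PipelineConfig, dataset: Optional[Dataset] = None) -> dict:
    """Execute the full pipeline and write per-stage artifacts.

    A pre-assembled dataset (e.g. simulated) may be passed directly,
    bypassing file ingest.  Returns the JSON-serializable manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset is None:
        config.validate_paths()
        dataset = assemble_dataset(config)

    dataset, removed = filter_dataset_contigs(dataset)
    dataset = Dataset.from_parts(
        [g for g in dataset.iter_gems() if g.chains and g.pmhc_counts],
        dataset.panel.values(),
        dataset.samples.values(),
    )
    dataset = collapse_and_impute_clonotypes(dataset)
    dataset = select_dominant_chains_dataset(dataset)
    tio.write_gem_table(dataset, out / "gems_raw.csv", "total")

    hash_calls = {
        c.gem_id: c
        for c in demultiplex_hashing(
            {g.gem_id: g.hash_counts for g in dataset.iter_gems()},
            n_samples=len(dataset.samples) or None,
            seed=config.seed,
        )
    }
    pd.DataFrame(
        {
            "gem_id": [c.gem_id for c in hash_calls.values()],
            "label": [c.label for c in hash_calls.values()],
            "positive_hashes": [
                ";".join(sorted(c.positive_hashes)) for c in hash_calls.values()
            ],
        }
    ).to_csv(out / "hash_calls.csv", index=False)

    expected = expected_binders_for_dataset(dataset, variant=config.wilcoxon_variant)
    pd.DataFrame(
        {
            "clonotype_id": [e.clonotype_id for e in expected.values()],
            "pmhc_id": [e.pmhc_id or "" for e in expected.values()],
            "p_value": [e.p_value for e in expected.values()],
            "n_gems": [e.n_gems for e in expected.values()],
            "tested": [e.tested for e in expected.values()],
        }
    ).to_csv(out / "expected_binders.csv", index=False)

    thresholds = UmiThresholds()
    grid_summary = None
    if config.grid_search:
        result, audit = grid_search_thresholds(dataset, expected, audit=True)
        thresholds = result.thresholds
        if audit is not None:
            audit.to_csv(out / "grid_audit.csv", index=False)
        grid_summary = {
            "min_umi": result.thresholds.min_umi,
            "min_ratio": result.thresholds.min_ratio,
            "acc": result.acc,
            "retained_fraction": result.retained_fraction,
            "objective": result.objective,
        }

    fconfig = FilterConfig(steps=list(config.steps), thresholds=thresholds)
    filtered, reports = apply_filter_chain(
        dataset,
        fconfig,
        expected,
        samples=dataset.samples,
        hash_calls=hash_calls,
        mode=config.filter_mode,
    )
    tio.write_gem_table(filtered, out / "gems_filtered.csv", "filtered")

    auc_raw, p_raw, _ = similarity_auc_for_dataset(dataset, expected, config.seed)
    auc_filt, p_filt, _ = similarity_auc_for_dataset(filtered, expected, config.seed)

    report_rows = [dataclasses.asdict(r) for r in reports]
    pd.DataFrame(report_rows).to_csv(out / "filter_reports.csv", index=False)

    manifest = {
        "seed": config.seed,
        "n_gems_input": dataset.n_gems,
        "n_clonotypes": dataset.n_clonotypes,
        "contig_removals": dict(removed),
        "grid_search": grid_summary,
        "filter_reports": report_rows,
        "similarity_auc_raw": auc_raw,
        "similarity_auc_filtered": auc_filt,
        "similarity_p_raw": p_raw,
        "similarity_p_filtered": p_filt,
        "n_gems_filtered": filtered.n_gems,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
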