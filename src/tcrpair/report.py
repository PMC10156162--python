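"""Aggregate per-stage metrics and the fluorescent-multimer comparison.

A FilterReport row summarizes one filtering configuration: retained GEM
and clonotype counts, annotation accuracy, average binding concordance
and (optionally) the intra/inter similarity AUC.  The multimer comparison
validates the single-cell capture against flow-cytometry multimer
staining: per-donor response frequencies are converted to adjusted sorted
cell counts, detection is compared as binary classes (MCC, recall,
precision), and counts are related by correlation and a log-log linear
regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import Dataset
from .specificity import (
    ExpectedBinder,
    annotation_accuracy,
    average_concordance,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "MultimerResponse",
    "compute_report",
    "adjusted_cell_counts",
    "compare_with_multimer",
]


@dataclass
class FilterReport:
    stage: str
    n_gems: int
    n_clonotypes: int
    accuracy: Optional[float]
    avg_concordance: Optional[float]
    retained_fraction: float
    auc: Optional[float] = None


@dataclass(frozen=True)
class MultimerResponse:
    """One (donor, pMHC) response measured by fluorescent multimer staining.

    ``frequency`` is in percent of total CD8 T cells.  A response counts
    as detected (above threshold) with >=10 events at >=0.002%, or with
    <=10 events at >=0.01%.
    """

    donor_id: str
    pmhc_id: str
    frequency: float
    n_events: int
    adjusted_cells: Optional[float] = None

    @property
    def above_threshold(self) -> bool:
        return (self.n_events >= 10 and self.frequency >= 0.002) or (
            self.n_events <= 10 and self.frequency >= 0.01
        )


def compute_report(
    dataset: Dataset,
    stage: str,
    expected: Mapping[str, ExpectedBinder],
    n_total: Optional[int] = None,
    auc: Optional[float] = None,
) -> FilterReport:
    """Assemble the metric row for one filtering stage."""
    n_total = n_total if n_total is not None else dataset.n_gems
    return FilterReport(
        stage=stage,
        n_gems=dataset.n_gems,
        n_clonotypes=dataset.n_clonotypes,
        accuracy=annotation_accuracy(dataset, dict(expected)),
        avg_concordance=(
            average_concordance(dataset) if dataset.clonotypes is not None else None
        ),
        retained_fraction=dataset.n_gems / n_total if n_total else 0.0,
        auc=auc,
    )


def adjusted_cell_counts(
    responses: Sequence[MultimerResponse],
    n_sorted: int = 1800,
    normalization: str = "donor_share",
) -> list[MultimerResponse]:
    """Allocate each donor's sorted cells across its detected responses.

    With the default ``donor_share`` normalization the n_sorted cells of a
    donor are split proportionally to the response frequencies, so the
    adjusted counts of a donor sum to n_sorted.  ``capacity`` instead
    multiplies each raw frequency (as a fraction) by n_sorted.
    """
    out: list[MultimerResponse] = []
    by_donor: dict[str, float] = {}
    for r in responses:
        by_donor[r.donor_id] = by_donor.get(r.donor_id, 0.0) + r.frequency
    for r in responses:
        if normalization == "donor_share":
            total = by_donor[r.donor_id]
            if total <= 0:
                logger.warning(
                    "donor %s has zero summed frequency; adjusted count undefined",
                    r.donor_id,
                )
                adjusted = None
            else:
                adjusted = n_sorted * r.frequency / total
        elif normalization == "capacity":
            adjusted = n_sorted * r.frequency / 100.0
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        out.append(replace(r, adjusted_cells=adjusted))
    return out


def _mcc(tp: int, fp: int, fn: int, tn: int) -> Optional[float]:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom)


def compare_with_multimer(
    responses: Sequence[MultimerResponse],
    gem_counts: Mapping[tuple[str, str], int],
) -> dict:
    """Compare single-cell capture against multimer-staining responses.

    Truth labels are responses above the detection threshold; a (donor,
    pMHC) pair is query-positive when at least one GEM survived filtering.
    Returns MCC/recall/precision from the 2x2 agreement table, the
    Pearson correlation between adjusted cell counts and GEM counts over
    pairs with at least one adjusted cell or one GEM, and an ordinary
    least-squares fit in log10-log10 space over pairs positive on both
    axes.
    """
    resp_by_key = {(r.donor_id, r.pmhc_id): r for r in responses}
    keys = sorted(set(resp_by_key) | set(gem_counts))
    tp = fp = fn = tn = 0
    xs, ys = [], []
    for key in keys:
        r = resp_by_key.get(key)
        truth = r.above_threshold if r is not None else False
        n_gems = gem_counts.get(key, 0)
        query = n_gems >= 1
        if truth and query:
            tp += 1
        elif truth and not query:
            fn += 1
        elif query:
            fp += 1
        else:
            tn += 1
        adjusted = r.adjusted_cells if r is not None and r.adjusted_cells else 0.0
        if adjusted >= 1 or n_gems >= 1:
            xs.append(adjusted)
            ys.append(n_gems)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    mcc = _mcc(tp, fp, fn, tn)
    if mcc is None:
        logger.warning("degenerate 2x2 agreement table; MCC undefined")
    pearson = (
        float(stats.pearsonr(xs, ys).statistic) if xs.size >= 2 else None
    )
    both = (xs >= 1) & (ys >= 1)
    regression = None
    if both.sum() >= 2 and np.unique(xs[both]).size > 1:
        fit = stats.linregress(np.log10(xs[both]), np.log10(ys[both]))
        regression = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2),
        }
    return {
        "table": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "mcc": mcc,
        "recall": recall,
        "precision": precision,
        "pearson_r": pearson,
        "regression": regression,
    }
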