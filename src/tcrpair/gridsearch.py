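"""UMI-ratio transform, weighted objective, and exhaustive threshold search.

Six filtering features are searched jointly: a minimum UMI count and a
minimum UMI ratio for each of the pMHC, alpha-chain and beta-chain
feature classes.  The UMI ratio of a GEM is

    ratio = umi_max / (umi_sec + 0.25)

(0.25 in the denominator avoids division by zero), and the objective

    o = (2 * acc + f) / 3

trades annotation accuracy against the fraction of GEMs retained.
Accuracy is always evaluated against expected-binder labels fixed on the
unfiltered data; the search itself is exhaustive over the grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Dataset
from .specificity import ExpectedBinder, gem_chain_summary, gem_top_pmhc

logger = logging.getLogger(__name__)

__all__ = [
    "UmiThresholds",
    "GridSearchResult",
    "umi_ratio",
    "objective_score",
    "grid_search_thresholds",
    "threshold_mask",
]

RATIO_EPS = 0.25
FEATURE_CLASSES = ("pmhc", "tra", "trb")


def umi_ratio(umi_max: int, umi_sec: int) -> float:
    """Ratio of the top two UMI counts, stabilized against zero seconds."""
    if umi_max < 0 or umi_sec < 0:
        raise ValueError("UMI counts must be non-negative")
    if umi_max < umi_sec:
        raise ValueError(f"umi_max ({umi_max}) < umi_sec ({umi_sec})")
    return umi_max / (umi_sec + RATIO_EPS)


def objective_score(acc: float, retained_fraction: float) -> float:
    """Weighted average of accuracy and retained-GEM fraction, o = (2*acc+f)/3."""
    if not (0.0 <= acc <= 1.0):
        raise ValueError(f"accuracy out of [0,1]: {acc}")
    if not (0.0 <= retained_fraction <= 1.0):
        raise ValueError(f"retained fraction out of [0,1]: {retained_fraction}")
    return (2.0 * acc + retained_fraction) / 3.0


@dataclass(frozen=True)
class UmiThresholds:
    """Six thresholds; 0 disables a criterion.  Counts compare with >=,
    ratios strictly with >."""

    min_umi: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in FEATURE_CLASSES}
    )
    min_ratio: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in FEATURE_CLASSES}
    )

    def as_tuple(self) -> tuple:
        return tuple(self.min_umi[c] for c in FEATURE_CLASSES) + tuple(
            self.min_ratio[c] for c in FEATURE_CLASSES
        )


@dataclass
class GridSearchResult:
    thresholds: UmiThresholds
    acc: float
    retained_fraction: float
    objective: float
    n_gems_retained: int


def _feature_arrays(dataset: Dataset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per feature class: (umi_max, ratio) arrays over GEMs in dict order."""
    out = {}
    gems = list(dataset.iter_gems())
    for cls in FEATURE_CLASSES:
        umax = np.zeros(len(gems), dtype=np.int64)
        usec = np.zeros(len(gems), dtype=np.int64)
        for i, gem in enumerate(gems):
            if cls == "pmhc":
                s = gem_top_pmhc(gem)
                if s is not None:
                    umax[i], usec[i] = s.umi_max, s.umi_sec
            else:
                s = gem_chain_summary(gem, cls.upper())
                umax[i], usec[i] = s.umi_max, s.umi_sec
        out[cls] = (umax, umax / (usec + RATIO_EPS))
    return out


def threshold_mask(dataset: Dataset, thresholds: UmiThresholds) -> np.ndarray:
    """Boolean retention mask over GEMs (in dataset order) for a threshold set."""
    arrays = _feature_arrays(dataset)
    n = dataset.n_gems
    mask = np.ones(n, dtype=bool)
    for cls in FEATURE_CLASSES:
        umax, ratio = arrays[cls]
        cmin = thresholds.min_umi.get(cls, 0)
        rmin = thresholds.min_ratio.get(cls, 0.0)
        if cmin > 0:
            mask &= umax >= cmin
        if rmin > 0:
            mask &= ratio > rmin
    return mask


def _default_count_grid(umax: np.ndarray, cap: int = 15) -> list[int]:
    """Integers 0..median(per-GEM umi_max), thinned to at most ``cap`` values."""
    med = int(np.median(umax))
    values = list(range(0, med + 1))
    if len(values) > cap:
        step = int(np.ceil((len(values) - 1) / (cap - 1)))
        values = list(range(0, med + 1, step))
        if values[-1] != med:
            values.append(med)
    return values


def _default_ratio_grid(ratio: np.ndarray, cap: int = 12) -> list[float]:
    """Ladder 0, 1, 1.5, 2, 3, 4, 5, ... capped at the median per-GEM ratio.

    Beyond 5 the ladder continues in integer steps, geometrically thinned
    when needed to keep the joint six-feature grid tractable.
    """
    med = float(np.median(ratio))
    ladder = [v for v in (0.0, 1.0, 1.5) if v <= med]
    v = 2.0
    while v <= med:
        ladder.append(v)
        v += 1.0
    if len(ladder) > cap:
        head = ladder[:6]  # always keep 0, 1, 1.5, 2, 3, 4
        tail = ladder[6:]
        step = int(np.ceil(len(tail) / (cap - len(head))))
        ladder = head + tail[::step]
        if ladder[-1] != tail[-1]:
            ladder.append(tail[-1])
    return ladder


def grid_search_thresholds(
    dataset: Dataset,
    expected: dict[str, ExpectedBinder],
    count_grids: Optional[dict[str, Sequence[int]]] = None,
    ratio_grids: Optional[dict[str, Sequence[float]]] = None,
    audit: bool = False,
) -> tuple[GridSearchResult, Optional[pd.DataFrame]]:
    """Exhaustive search over the six-feature threshold grid.

    Training labels (the expected binder per clonotype) are fixed from
    the unfiltered data before the search; at every grid point accuracy
    is recomputed over surviving training GEMs and the retained fraction
    over all GEMs.  Ties in the objective prefer higher retention, then
    component-wise lower thresholds.  With ``audit=True`` the full grid
    evaluation is returned as a DataFrame.
    """
    gems = list(dataset.iter_gems())
    n_total = len(gems)
    arrays = _feature_arrays(dataset)

    targets = {
        cid: eb.pmhc_id for cid, eb in expected.items() if eb.pmhc_id is not None
    }
    train = np.zeros(n_total, dtype=bool)
    match = np.zeros(n_total, dtype=bool)
    for i, gem in enumerate(gems):
        target = targets.get(gem.clonotype_id)
        if target is None:
            continue
        train[i] = True
        s = gem_top_pmhc(gem)
        match[i] = s is not None and not s.tie_flag and s.top_feature == target

    grids_c = {}
    grids_r = {}
    for cls in FEATURE_CLASSES:
        umax, ratio = arrays[cls]
        grids_c[cls] = list(
            (count_grids or {}).get(cls) or _default_count_grid(umax)
        )
        grids_r[cls] = list(
            (ratio_grids or {}).get(cls) or _default_ratio_grid(ratio)
        )

    # per class: all (count, ratio) threshold pairs -> retention masks,
    # split into an all-GEM mask (for f) and a training-slice mask (for acc)
    train_idx = np.flatnonzero(train)
    match_train = match[train_idx]
    pair_info: dict[str, list[tuple[int, float]]] = {}
    pair_masks_all: dict[str, np.ndarray] = {}
    pair_masks_train: dict[str, np.ndarray] = {}
    for cls in FEATURE_CLASSES:
        umax, ratio = arrays[cls]
        pairs = list(itertools.product(grids_c[cls], grids_r[cls]))
        masks = np.ones((len(pairs), n_total), dtype=bool)
        for pi, (cmin, rmin) in enumerate(pairs):
            if cmin > 0:
                masks[pi] &= umax >= cmin
            if rmin > 0:
                masks[pi] &= ratio > rmin
        pair_info[cls] = pairs
        pair_masks_all[cls] = masks
        pair_masks_train[cls] = masks[:, train_idx]

    n_points = int(np.prod([len(pair_info[c]) for c in FEATURE_CLASSES]))
    logger.info("grid search over %d points (%d GEMs)", n_points, n_total)

    best: Optional[tuple[float, float, tuple, GridSearchResult]] = None
    audit_rows = [] if audit else None
    for ia, (ca, ra) in enumerate(pair_info["pmhc"]):
        m_all_a = pair_masks_all["pmhc"][ia]
        m_tr_a = pair_masks_train["pmhc"][ia]
        for ib, (cb, rb) in enumerate(pair_info["tra"]):
            m_all_ab = m_all_a & pair_masks_all["tra"][ib]
            m_tr_ab = m_tr_a & pair_masks_train["tra"][ib]
            for ic, (cc, rc) in enumerate(pair_info["trb"]):
                m_all = m_all_ab & pair_masks_all["trb"][ic]
                m_tr = m_tr_ab & pair_masks_train["trb"][ic]
                n_ret = int(np.count_nonzero(m_all))
                f = n_ret / n_total if n_total else 0.0
                denom = int(np.count_nonzero(m_tr))
                if denom == 0:
                    acc = 0.0  # empty surviving training set; flagged below
                else:
                    acc = int(np.count_nonzero(m_tr & match_train)) / denom
                o = (2.0 * acc + f) / 3.0
                thr_tuple = (ca, cb, cc, ra, rb, rc)
                if audit_rows is not None:
                    audit_rows.append(
                        {
                            "min_umi_pmhc": ca,
                            "min_umi_tra": cb,
                            "min_umi_trb": cc,
                            "min_ratio_pmhc": ra,
                            "min_ratio_tra": rb,
                            "min_ratio_trb": rc,
                            "acc": acc,
                            "f": f,
                            "o": o,
                            "n_retained": n_ret,
                            "empty_training": denom == 0,
                        }
                    )
                key = (o, f)
                if (
                    best is None
                    or key > (best[0], best[1])
                    or (key == (best[0], best[1]) and thr_tuple < best[2])
                ):
                    thresholds = UmiThresholds(
                        min_umi={"pmhc": ca, "tra": cb, "trb": cc},
                        min_ratio={"pmhc": ra, "tra": rb, "trb": rc},
                    )
                    best = (
                        o,
                        f,
                        thr_tuple,
                        GridSearchResult(thresholds, acc, f, o, n_ret),
                    )
    assert best is not None
    df = pd.DataFrame(audit_rows) if audit_rows is not None else None
    return best[3], df
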