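"""Per-GEM specificity calls and per-clonotype expected-binder inference.

A GEM's apparent specificity is the pMHC barcode with the highest UMI
count in that droplet.  Because ambient barcodes contaminate droplets,
the per-clonotype *expected binder* aggregates over member GEMs: the two
pMHCs with the highest mean UMI are compared with a one-sided Wilcoxon
test (paired signed-rank by default), and the top pMHC becomes the
clonotype's expected target when it wins at alpha = 0.05.  Clonotypes
with fewer than 10 GEMs are not tested.  Binding concordance measures,
per clonotype, the fraction of GEMs agreeing on each specificity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .model import Clonotype, Dataset, GemRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GemFeatureSummary",
    "ExpectedBinder",
    "ConcordanceEntry",
    "gem_top_pmhc",
    "gem_chain_summary",
    "wilcoxon_signed_rank_greater",
    "expected_binder",
    "expected_binders_for_dataset",
    "binding_concordance",
    "annotation_accuracy",
    "average_concordance",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GEMS = 10
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class GemFeatureSummary:
    """Most and second-most abundant feature of one class within a GEM."""

    gem_id: str
    feature_class: str  # "pMHC" | "TRA" | "TRB"
    umi_max: int
    umi_sec: int
    top_feature: Optional[str]
    tie_flag: bool


@dataclass
class ExpectedBinder:
    clonotype_id: str
    pmhc_id: Optional[str] = None
    p_value: Optional[float] = None
    n_gems: int = 0
    tested: bool = False
    degenerate: bool = False
    alpha: float = DEFAULT_ALPHA
    min_gems: int = DEFAULT_MIN_GEMS


@dataclass(frozen=True)
class ConcordanceEntry:
    clonotype_id: str
    pmhc_id: str
    fraction: float
    n_support: int


def gem_top_pmhc(gem: GemRecord) -> Optional[GemFeatureSummary]:
    """Summarize the most abundant pMHC of a GEM.

    Returns None for GEMs without any pMHC count (the caller excludes
    them).  When two or more pMHCs share the maximum the GEM is tied and
    carries no unique top feature.
    """
    if not gem.pmhc_counts:
        return None
    items = sorted(gem.pmhc_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    umi_max = items[0][1]
    umi_sec = items[1][1] if len(items) > 1 else 0
    tied = len(items) > 1 and items[1][1] == umi_max
    return GemFeatureSummary(
        gem_id=gem.gem_id,
        feature_class="pMHC",
        umi_max=umi_max,
        umi_sec=umi_sec,
        top_feature=None if tied else items[0][0],
        tie_flag=tied,
    )


def gem_chain_summary(gem: GemRecord, locus: str) -> GemFeatureSummary:
    """UMI max / second-max over a GEM's chains of one locus (0 if absent)."""
    umis = sorted((c.umi_count for c in gem.chains_of(locus)), reverse=True)
    umi_max = umis[0] if umis else 0
    umi_sec = umis[1] if len(umis) > 1 else 0
    return GemFeatureSummary(
        gem_id=gem.gem_id,
        feature_class=locus,
        umi_max=umi_max,
        umi_sec=umi_sec,
        top_feature=None,
        tie_flag=len(umis) > 1 and umis[1] == umi_max,
    )


def wilcoxon_signed_rank_greater(diffs: Iterable[float]) -> Optional[float]:
    """One-sided paired Wilcoxon signed-rank p-value, H1: median diff > 0.

    Zero differences are discarded (classic zero handling).  For n <= 25
    the exact null distribution of the positive-rank sum is computed by a
    generating-function convolution over the midranks (doubled so tied
    midranks stay integral), which remains exact under ties.  Above 25 a
    normal approximation with tie correction and continuity correction is
    used.  Returns None when no nonzero difference remains.
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    if n == 0:
        return None
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= EXACT_WILCOXON_MAX_N:
        r2 = np.rint(2 * ranks).astype(int)
        total = r2.sum()
        # coefficient c[s] = number of sign assignments with 2*W+ == s
        coeffs = np.zeros(total + 1, dtype=float)
        coeffs[0] = 1.0
        for r in r2:
            coeffs[r:] += coeffs[: coeffs.size - r].copy()
        target = int(np.rint(2 * w_plus))
        return float(coeffs[target:].sum() / 2.0**n)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance of the rank sum
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return float(stats.norm.sf(z))


def _clonotype_pmhc_matrix(
    clonotype: Clonotype, gems: dict[str, GemRecord]
) -> tuple[list[str], np.ndarray]:
    """Per-member UMI counts for every pMHC observed in the clonotype.

    A pMHC not detected in a member GEM contributes 0 UMI for that GEM.
    """
    members = [gems[gid] for gid in clonotype.member_gems]
    pmhcs = sorted({p for g in members for p in g.pmhc_counts})
    mat = np.zeros((len(members), len(pmhcs)), dtype=float)
    for i, g in enumerate(members):
        for j, p in enumerate(pmhcs):
            mat[i, j] = g.pmhc_counts.get(p, 0)
    return pmhcs, mat


def expected_binder(
    clonotype: Clonotype,
    gems: dict[str, GemRecord],
    alpha: float = DEFAULT_ALPHA,
    min_gems: int = DEFAULT_MIN_GEMS,
    variant: str = "paired",
) -> ExpectedBinder:
    """Infer a clonotype's expected pMHC target.

    The two pMHCs with the highest mean UMI across member GEMs are
    compared one-sidedly; a significant win assigns the top pMHC as the
    expected target.  ``variant`` selects the paired signed-rank test
    (default; both candidate pMHCs are measured in the same droplets) or
    the unpaired rank-sum test.
    """
    n = len(clonotype.member_gems)
    result = ExpectedBinder(
        clonotype_id=clonotype.clonotype_id,
        n_gems=n,
        alpha=alpha,
        min_gems=min_gems,
    )
    if n < min_gems:
        return result
    pmhcs, mat = _clonotype_pmhc_matrix(clonotype, gems)
    if len(pmhcs) == 0:
        return result
    if len(pmhcs) == 1:
        # degenerate: a single specificity observed across >= min_gems GEMs
        result.degenerate = True
        result.pmhc_id = pmhcs[0]
        logger.info(
            "clonotype %s observes a single pMHC (%s); assigned without test",
            clonotype.clonotype_id,
            pmhcs[0],
        )
        return result
    result.tested = True
    means = mat.mean(axis=0)
    n_obs = (mat > 0).sum(axis=0)
    # top two by mean; ties broken toward more supporting GEMs, then name
    order = sorted(
        range(len(pmhcs)), key=lambda j: (-means[j], -n_obs[j], pmhcs[j])
    )
    top, sec = order[0], order[1]
    if variant == "paired":
        p = wilcoxon_signed_rank_greater(mat[:, top] - mat[:, sec])
        if p is None:  # all member GEMs tie the two candidates exactly
            return result
    elif variant == "ranksum":
        p = float(
            stats.mannwhitneyu(mat[:, top], mat[:, sec], alternative="greater").pvalue
        )
    else:
        raise ValueError(f"unknown Wilcoxon variant {variant!r}")
    result.p_value = p
    if p < alpha:
        result.pmhc_id = pmhcs[top]
    return result


def expected_binders_for_dataset(
    dataset: Dataset,
    alpha: float = DEFAULT_ALPHA,
    min_gems: int = DEFAULT_MIN_GEMS,
    variant: str = "paired",
) -> dict[str, ExpectedBinder]:
    if dataset.clonotypes is None:
        raise ValueError("dataset has no clonotype assignments")
    return {
        cid: expected_binder(ct, dataset.gems, alpha, min_gems, variant)
        for cid, ct in dataset.clonotypes.items()
    }


def binding_concordance(
    clonotype: Clonotype, gems: dict[str, GemRecord]
) -> tuple[list[ConcordanceEntry], int]:
    """Fraction of a clonotype's unambiguous GEMs supporting each pMHC.

    GEMs whose top pMHC is tied are excluded from both numerator and
    denominator and reported via the second return value.
    """
    tops: list[str] = []
    n_tied = 0
    for gid in clonotype.member_gems:
        summary = gem_top_pmhc(gems[gid])
        if summary is None:
            continue
        if summary.tie_flag:
            n_tied += 1
        else:
            tops.append(summary.top_feature)
    if not tops:
        if n_tied:
            logger.warning(
                "clonotype %s: all member GEMs tied; empty concordance",
                clonotype.clonotype_id,
            )
        return [], n_tied
    denom = len(tops)
    counts: dict[str, int] = {}
    for t in tops:
        counts[t] = counts.get(t, 0) + 1
    entries = [
        ConcordanceEntry(clonotype.clonotype_id, p, c / denom, c)
        for p, c in sorted(counts.items())
    ]
    return entries, n_tied


def annotation_accuracy(
    dataset: Dataset, expected: dict[str, ExpectedBinder]
) -> Optional[float]:
    """Fraction of GEMs whose top pMHC matches their clonotype's target.

    Evaluated only over GEMs in clonotypes with an assigned expected
    target; tied GEMs count as mismatches.  None when no clonotype has a
    target.
    """
    targets = {
        cid: eb.pmhc_id for cid, eb in expected.items() if eb.pmhc_id is not None
    }
    n_eligible = 0
    n_match = 0
    for gem in dataset.iter_gems():
        target = targets.get(gem.clonotype_id)
        if target is None:
            continue
        n_eligible += 1
        summary = gem_top_pmhc(gem)
        if summary is not None and not summary.tie_flag and summary.top_feature == target:
            n_match += 1
    if n_eligible == 0:
        return None
    return n_match / n_eligible


def average_concordance(
    dataset: Dataset, weighting: str = "gem"
) -> Optional[float]:
    """Average binding concordance over the dataset.

    GEM-weighted (default): each GEM with an unambiguous top pMHC
    contributes its clonotype's concordance fraction for that pMHC.
    Clonotype-weighted: each clonotype contributes its maximum
    concordance fraction once.
    """
    if dataset.clonotypes is None:
        raise ValueError("dataset has no clonotype assignments")
    values: list[float] = []
    for ct in dataset.clonotypes.values():
        entries, _ = binding_concordance(ct, dataset.gems)
        if not entries:
            continue
        fractions = {e.pmhc_id: e.fraction for e in entries}
        if weighting == "clonotype":
            values.append(max(fractions.values()))
        elif weighting == "gem":
            for gid in ct.member_gems:
                summary = gem_top_pmhc(dataset.gems[gid])
                if summary is None or summary.tie_flag:
                    continue
                values.append(fractions[summary.top_feature])
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    if not values:
        return None
    return float(np.mean(values))
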