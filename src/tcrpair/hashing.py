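"""Cell-hashing demultiplexing: singlet / doublet / negative calls per GEM.

Follows the hashtag-oligo (HTO) demultiplexing scheme of Stoeckius et al.:
the centered-log-ratio normalized count matrix is clustered with k-medoids
into k = n_samples + 1 clusters; for each hashing barcode a negative
binomial background distribution is fitted to the raw counts of all GEMs
outside the cluster with the highest average expression of that barcode,
and a GEM is called positive for the barcode when its raw count exceeds
the background distribution's high quantile (default 0.99).  GEMs positive
for exactly one barcode are singlets, for two or more doublets, for none
negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .model import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["HashClassification", "demultiplex_hashing", "clr_normalize", "pam_kmedoids"]


@dataclass
class HashClassification:
    gem_id: str
    label: str  # "singlet" | "doublet" | "negative"
    positive_hashes: frozenset[str] = frozenset()
    per_hash_threshold: dict[str, float] = field(default_factory=dict)


def clr_normalize(counts: np.ndarray) -> np.ndarray:
    """Centered log-ratio across barcodes within each GEM (rows = GEMs)."""
    log1 = np.log1p(counts.astype(float))
    return log1 - log1.mean(axis=1, keepdims=True)


def pam_kmedoids(
    X: np.ndarray, k: int, max_iter: int = 50
) -> np.ndarray:
    """Partitioning around medoids with the deterministic BUILD start.

    BUILD greedily seeds medoids by maximal cost reduction; SWAP then
    replaces one medoid at a time while the total distance to the nearest
    medoid decreases.  Fully deterministic: ties resolve to the lowest
    index.  Returns per-point cluster labels.
    """
    n = X.shape[0]
    if k > n:
        raise ConfigurationError(f"k={k} exceeds number of points {n}")
    D = np.sqrt(
        np.maximum(
            (X**2).sum(1)[:, None] + (X**2).sum(1)[None, :] - 2 * X @ X.T, 0.0
        )
    )
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        m = int(np.argmax(gains))
        medoids.append(m)
        nearest = np.minimum(nearest, D[m])
    # SWAP
    medoids = list(medoids)
    for _ in range(max_iter):
        Dm = D[medoids]  # k x n
        order = np.argsort(Dm, axis=0)
        cost = Dm[order[0], np.arange(n)].sum()
        best = (0.0, None, None)
        for mi in range(len(medoids)):
            others = [medoids[j] for j in range(len(medoids)) if j != mi]
            d_others = D[others].min(axis=0) if others else np.full(n, np.inf)
            cand_costs = np.minimum(D, d_others[None, :]).sum(axis=1)
            cand_costs[medoids] = np.inf
            h = int(np.argmin(cand_costs))
            delta = cand_costs[h] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
    labels = np.argmin(D[medoids], axis=0)
    return labels


def _fit_negative_binomial(counts: np.ndarray):
    """Profile-ML negative binomial fit; Poisson fallback when the sample
    is under-dispersed (variance <= mean).  Returns a frozen scipy dist."""
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean()
    var = counts.var(ddof=1) if counts.size > 1 else 0.0
    if mean <= 0:
        return None
    if var <= mean:
        return stats.poisson(mean)

    def negloglik(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + mean)
        return -stats.nbinom.logpmf(counts, r, p).sum()

    r0 = mean**2 / (var - mean)  # method-of-moments start
    res = optimize.minimize_scalar(
        negloglik,
        bounds=(np.log(r0) - 6, np.log(r0) + 6),
        method="bounded",
    )
    r = float(np.exp(res.x))
    p = r / (r + mean)
    return stats.nbinom(r, p)


def demultiplex_hashing(
    hash_counts: dict[str, dict[str, int]],
    n_samples: int | None = None,
    quantile: float = 0.99,
    seed: int = 0,
) -> list[HashClassification]:
    """Classify each GEM as hashing singlet, doublet or negative.

    Parameters
    ----------
    hash_counts
        Per-GEM sparse hashing barcode counts (absent barcode = 0).
    n_samples
        Number of hashed samples; defaults to the number of distinct
        barcodes observed.  Clustering uses k = n_samples + 1 clusters.
    quantile
        Background quantile a raw count must strictly exceed to call the
        barcode positive in a GEM.
    seed
        Accepted for interface stability; the PAM implementation is
        deterministic and does not consume randomness.
    """
    gem_ids = list(hash_counts)
    barcodes = sorted({h for v in hash_counts.values() for h in v})
    if n_samples is None:
        n_samples = len(barcodes)
    k = n_samples + 1
    if len(gem_ids) < k:
        raise ConfigurationError(
            f"need at least {k} GEMs for k={k} clusters, got {len(gem_ids)}"
        )
    mat = np.zeros((len(gem_ids), len(barcodes)), dtype=float)
    bidx = {b: j for j, b in enumerate(barcodes)}
    for i, gid in enumerate(gem_ids):
        for b, c in hash_counts[gid].items():
            mat[i, bidx[b]] = c

    clr = clr_normalize(mat)
    labels = pam_kmedoids(clr, k)

    thresholds: dict[str, float] = {}
    positive = np.zeros(mat.shape, dtype=bool)
    for j, bc in enumerate(barcodes):
        col = mat[:, j]
        if col.max() == 0:
            logger.warning("hashing barcode %s has all-zero counts", bc)
            thresholds[bc] = np.inf
            continue
        present = [c for c in range(k) if (labels == c).any()]
        cluster_means = {c: col[labels == c].mean() for c in present}
        top_cluster = max(present, key=lambda c: cluster_means[c])
        # the background pool drops the top cluster and any other cluster
        # enriched for this barcode (positive average CLR); the surplus
        # (k = n_samples + 1)th cluster can split a sample in two when the
        # data lack a negative population, and both halves carry signal
        excluded = {
            c for c in present if clr[labels == c, j].mean() > 0
        } | {top_cluster}
        pool_mask = ~np.isin(labels, list(excluded))
        pool = col[pool_mask]
        dist = _fit_negative_binomial(pool) if pool.size else None
        if dist is None:
            # empty or all-zero background: any nonzero count is signal
            thr = 0.0
        else:
            thr = float(dist.ppf(quantile))
        thresholds[bc] = thr
        positive[:, j] = col > thr

    out: list[HashClassification] = []
    for i, gid in enumerate(gem_ids):
        pos = frozenset(barcodes[j] for j in np.flatnonzero(positive[i]))
        if len(pos) == 1:
            label = "singlet"
        elif len(pos) >= 2:
            label = "doublet"
        else:
            label = "negative"
        out.append(
            HashClassification(
                gem_id=gid,
                label=label,
                positive_hashes=pos,
                per_hash_threshold=dict(thresholds),
            )
        )
    return out
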