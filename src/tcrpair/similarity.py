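"""String-kernel CDR3 similarity and intra- vs inter-specificity evaluation.

Two TCRs binding the same pMHC tend to share CDR3 sequence features, so a
good filter should raise the similarity among same-specificity clonotypes
(intra) relative to different-specificity ones (inter).  The similarity of
two CDR3 strings is a normalized substring kernel: the raw kernel sums,
over every k from 1 to min(|s|, |t|) and every pair of k-mers (one from
each string), the product over aligned positions of an amino-acid
similarity derived from a substitution matrix; normalization by
K(s,s) and K(t,t) maps identical pairs to exactly 1.  A TCR pair's score
is the sum of its alpha- and beta-chain similarities (range [0, 2]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .model import AA_ALPHABET
from .specificity import wilcoxon_signed_rank_greater

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityRecord",
    "cdr3_kernel_similarity",
    "intra_inter_scores",
    "similarity_auc",
    "intra_vs_inter_test",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@lru_cache(maxsize=None)
def _scaled_substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Substitution scores affinely rescaled to (0, 1].

    With BLOSUM62 the scores over the 20 standard residues span [-4, 11];
    the map s -> (s - min + 1) / (max - min + 1) keeps every value
    positive so k-mer products never vanish, and assigns 1 to the single
    best-conserved pair.
    """
    raw = substitution_matrices.load(name)
    mat = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = raw[a][b]
    lo, hi = mat.min(), mat.max()
    return (mat - lo + 1.0) / (hi - lo + 1.0)


def _encode(seq: str) -> np.ndarray:
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)} in {seq!r}")
    if not seq:
        raise ValueError("empty CDR3 sequence")
    return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.intp, count=len(seq))


def _raw_kernel(
    s_idx: np.ndarray, t_idx: np.ndarray, S: np.ndarray, kmax: Optional[int]
) -> float:
    """Sum over all k-mer pairs of position-wise substitution products.

    Dynamic programme over match lengths: M[i, j] holds the product for
    the length-k window starting at (i, j); extending every window by one
    residue multiplies in the next diagonal element.
    """
    M = S[np.ix_(s_idx, t_idx)]
    limit = min(len(s_idx), len(t_idx))
    if kmax is not None:
        limit = min(limit, kmax)
    cur = M
    total = cur.sum()
    for k in range(2, limit + 1):
        cur = cur[:-1, :-1] * M[k - 1 :, k - 1 :]
        total += cur.sum()
    return float(total)


def cdr3_kernel_similarity(
    cdr3_a: str,
    cdr3_b: str,
    matrix: str = "BLOSUM62",
    kmax: Optional[int] = None,
    trim_flanks: bool = False,
) -> float:
    """Normalized string-kernel similarity of two CDR3 sequences in [0, 1].

    ``trim_flanks`` removes the first and last residue of each sequence
    before scoring (off by default).  ``kmax`` bounds the k-mer length;
    by default all lengths up to min(|s|, |t|) contribute.
    """
    if trim_flanks:
        cdr3_a, cdr3_b = cdr3_a[1:-1], cdr3_b[1:-1]
    S = _scaled_substitution_matrix(matrix)
    a, b = _encode(cdr3_a), _encode(cdr3_b)
    k_ab = _raw_kernel(a, b, S, kmax)
    k_aa = _raw_kernel(a, a, S, kmax)
    k_bb = _raw_kernel(b, b, S, kmax)
    return k_ab / np.sqrt(k_aa * k_bb)


@dataclass(frozen=True)
class SimilarityRecord:
    clonotype_id: str
    peptide: str  # the pmhc label of the clonotype
    intra_score: float
    inter_score: float
    n_intra_partners: int
    n_inter_partners: int


@dataclass(frozen=True)
class LabeledClonotype:
    """A both-chain clonotype with its single specificity label."""

    clonotype_id: str
    cdr3a: str
    cdr3b: str
    label: str


def _pair_similarity_matrix(
    clonotypes: Sequence[LabeledClonotype],
    matrix: str,
    kmax: Optional[int],
    trim_flanks: bool,
) -> np.ndarray:
    """Summed alpha+beta similarity for every clonotype pair, with caching
    over unique chain-sequence pairs."""
    n = len(clonotypes)
    cache: dict[tuple[str, str], float] = {}

    def sim(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = cdr3_kernel_similarity(
                key[0], key[1], matrix=matrix, kmax=kmax, trim_flanks=trim_flanks
            )
        return cache[key]

    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = sim(clonotypes[i].cdr3a, clonotypes[j].cdr3a) + sim(
                clonotypes[i].cdr3b, clonotypes[j].cdr3b
            )
            out[i, j] = out[j, i] = v
    return out


def intra_inter_scores(
    clonotypes: Sequence[LabeledClonotype],
    seed: int = 0,
    matrix: str = "BLOSUM62",
    kmax: Optional[int] = None,
    trim_flanks: bool = False,
) -> list[SimilarityRecord]:
    """Per-clonotype maximal intra- and inter-specificity similarities.

    For each clonotype the intra score is the maximum summed alpha+beta
    similarity to the other clonotypes sharing its label; the inter score
    is the maximum over a seeded uniform sample, without replacement, of
    other-label clonotypes of the same size as the intra comparison set
    (all of them when fewer are available).  Clonotypes without a
    same-label partner are excluded.
    """
    if len(clonotypes) < 2:
        logger.warning("fewer than 2 labeled clonotypes; no similarity records")
        return []
    order = sorted(range(len(clonotypes)), key=lambda i: clonotypes[i].clonotype_id)
    clonotypes = [clonotypes[i] for i in order]
    sims = _pair_similarity_matrix(clonotypes, matrix, kmax, trim_flanks)
    labels = np.array([c.label for c in clonotypes])
    rng = np.random.default_rng(seed)
    records: list[SimilarityRecord] = []
    for i, ct in enumerate(clonotypes):
        same = np.flatnonzero((labels == ct.label) & (np.arange(len(labels)) != i))
        if same.size == 0:
            continue
        other = np.flatnonzero(labels != ct.label)
        if other.size == 0:
            continue
        n_sample = min(same.size, other.size)
        sampled = rng.choice(other, size=n_sample, replace=False)
        records.append(
            SimilarityRecord(
                clonotype_id=ct.clonotype_id,
                peptide=ct.label,
                intra_score=float(sims[i, same].max()),
                inter_score=float(sims[i, sampled].max()),
                n_intra_partners=int(same.size),
                n_inter_partners=int(n_sample),
            )
        )
    return records


def similarity_auc(records: Sequence[SimilarityRecord]) -> Optional[float]:
    """Rank AUC: P(random intra score > random inter score), ties half.

    Intra scores act as positives, inter scores as negatives.  None when
    either class is empty.
    """
    intra = np.array([r.intra_score for r in records])
    inter = np.array([r.inter_score for r in records])
    if intra.size == 0 or inter.size == 0:
        return None
    from scipy.stats import rankdata

    pooled = np.concatenate([intra, inter])
    ranks = rankdata(pooled)
    r_intra = ranks[: intra.size].sum()
    u = r_intra - intra.size * (intra.size + 1) / 2.0
    return float(u / (intra.size * inter.size))


def intra_vs_inter_test(records: Sequence[SimilarityRecord]) -> Optional[float]:
    """One-sided paired signed-rank p-value for intra > inter.

    None when every record's intra and inter scores are equal (no nonzero
    difference to rank)."""
    diffs = [r.intra_score - r.inter_score for r in records]
    return wilcoxon_signed_rank_greater(diffs)
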