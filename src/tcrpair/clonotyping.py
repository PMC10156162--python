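"""Contig quality control and clonotype definition.

Clonotypes are sets of GEMs sharing identical V gene, J gene and CDR3 on
both the alpha and the beta chain.  Vendor clonotypes (defined at the
nucleotide level across the full V(D)J-C span) are consumed as input,
merged when functionally identical, and unassigned GEMs are imputed into
the merged set or founded as new clonotypes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import replace
from typing import Iterable, Optional

from .model import ChainObservation, Clonotype, Dataset, GemRecord

logger = logging.getLogger(__name__)

__all__ = [
    "filter_contigs",
    "gem_chain_key",
    "collapse_and_impute_clonotypes",
    "select_dominant_chains",
]


def filter_contigs(
    chains: Iterable[ChainObservation],
) -> tuple[list[ChainObservation], Counter]:
    """Drop incomplete and unproductive contigs.

    A contig is incomplete when it does not span the full V-to-J length and
    unproductive when its junction contains a frameshift or premature stop.
    Returns the retained contigs and per-reason removal counts.
    """
    kept: list[ChainObservation] = []
    removed: Counter = Counter()
    for c in chains:
        if not c.full_length:
            removed["not_full_length"] += 1
        elif not c.productive:
            removed["not_productive"] += 1
        else:
            kept.append(c)
    return kept, removed


def filter_dataset_contigs(dataset: Dataset) -> tuple[Dataset, Counter]:
    """Apply :func:`filter_contigs` GEM-wise, keeping GEM records in place."""
    total: Counter = Counter()
    for gem in dataset.iter_gems():
        kept, removed = filter_contigs(gem.chains)
        gem.chains = kept
        total.update(removed)
    if total:
        logger.info("contig filtering removed: %s", dict(total))
    return dataset, total


def _dominant(chains: list[ChainObservation]) -> Optional[ChainObservation]:
    """Highest-UMI chain; UMI ties broken by smallest cdr3_nt for determinism."""
    if not chains:
        return None
    return min(chains, key=lambda c: (-c.umi_count, c.cdr3_nt))


def gem_chain_key(gem: GemRecord) -> tuple:
    """The (alpha, beta) VJ-CDR3 key of a GEM.

    Each side is the (v_gene, j_gene, cdr3_aa) triple of the locus's
    dominant chain, or None when the locus was not captured.
    """
    a = _dominant(gem.chains_of("TRA"))
    b = _dominant(gem.chains_of("TRB"))
    return (
        a.vj_cdr3 if a is not None else None,
        b.vj_cdr3 if b is not None else None,
    )


def _nt_key(gem: GemRecord) -> tuple:
    a = _dominant(gem.chains_of("TRA"))
    b = _dominant(gem.chains_of("TRB"))
    return (
        (a.v_gene, a.j_gene, a.cdr3_nt) if a is not None else None,
        (b.v_gene, b.j_gene, b.cdr3_nt) if b is not None else None,
    )


def collapse_and_impute_clonotypes(
    dataset: Dataset,
    vendor_clonotypes: Optional[dict[str, str]] = None,
    use_nucleotide_cdr3: bool = False,
) -> Dataset:
    """Merge functionally identical clonotypes and impute unassigned GEMs.

    Three passes:

    1. vendor clonotypes whose members share an identical VJ-CDR3 alpha/beta
       key are merged under one id;
    2. each unassigned GEM whose key matches an existing clonotype joins it
       (a single-chain GEM joins only when exactly one clonotype matches its
       defined chain — the missing chain is a wildcard for imputation only);
    3. remaining unassigned GEMs found new clonotypes, grouped by key.

    Every TCR-bearing GEM ends with exactly one clonotype id.  GEMs whose
    chains contradict their vendor clonotype's modal key are reassigned by
    the matching rule with a warning.
    """
    keyfn = _nt_key if use_nucleotide_cdr3 else gem_chain_key
    if vendor_clonotypes is None:
        vendor_clonotypes = {
            g.gem_id: g.clonotype_id
            for g in dataset.iter_gems()
            if g.clonotype_id is not None
        }

    tcr_gems = [g for g in dataset.iter_gems() if g.chains]
    keys = {g.gem_id: keyfn(g) for g in tcr_gems}

    # pass 1: group assigned GEMs by vendor id, take the modal key as the
    # vendor clonotype's definition, merge identical definitions
    by_vendor: dict[str, list[str]] = {}
    for g in tcr_gems:
        vid = vendor_clonotypes.get(g.gem_id)
        if vid is not None:
            by_vendor.setdefault(vid, []).append(g.gem_id)

    key_to_cid: dict[tuple, str] = {}
    members: dict[str, list[str]] = {}
    unassigned: list[str] = []
    def _consistent(gem_key: tuple, group_key: tuple) -> bool:
        # a missing chain on the GEM side is a wildcard; a chain the group
        # definition lacks is a contradiction
        return all(g is None or g == m for g, m in zip(gem_key, group_key))

    for vid in by_vendor:
        gids = by_vendor[vid]
        modal_key, _ = Counter(keys[g] for g in gids).most_common(1)[0]
        for g in gids:
            if not _consistent(keys[g], modal_key):
                logger.warning(
                    "GEM %s contradicts vendor clonotype %s; reassigning", g, vid
                )
                unassigned.append(g)
                continue
            cid = key_to_cid.setdefault(modal_key, vid)
            members.setdefault(cid, []).append(g)
    unassigned.extend(
        g.gem_id for g in tcr_gems if vendor_clonotypes.get(g.gem_id) is None
    )

    # pass 2: impute unassigned GEMs into the duplicate-reduced set
    new_groups: dict[tuple, list[str]] = {}
    for gid in unassigned:
        key = keys[gid]
        if key in key_to_cid:
            members[key_to_cid[key]].append(gid)
            continue
        alpha, beta = key
        if alpha is None or beta is None:
            # single-chain GEM: join only on a unique defined-chain match
            side = 0 if beta is None else 1
            matches = [
                cid
                for k, cid in key_to_cid.items()
                if k[side] == key[side]
            ]
            if len(matches) == 1:
                members[matches[0]].append(gid)
                continue
        new_groups.setdefault(key, []).append(gid)

    # pass 3: new clonotypes for novel keys (grouped, in first-seen order)
    counter = 0
    for key, gids in new_groups.items():
        counter += 1
        cid = f"ct_new{counter:05d}"
        while cid in members:
            counter += 1
            cid = f"ct_new{counter:05d}"
        key_to_cid[key] = cid
        members[cid] = gids

    cid_of_key = {cid: key for key, cid in key_to_cid.items()}
    clonotypes: dict[str, Clonotype] = {}
    for cid, gids in members.items():
        alpha, beta = cid_of_key[cid]
        clonotypes[cid] = Clonotype(
            clonotype_id=cid,
            va=alpha[0] if alpha else None,
            ja=alpha[1] if alpha else None,
            cdr3a=alpha[2] if alpha else None,
            vb=beta[0] if beta else None,
            jb=beta[1] if beta else None,
            cdr3b=beta[2] if beta else None,
            member_gems=gids,
        )
        for gid in gids:
            dataset.gems[gid].clonotype_id = cid
    dataset.clonotypes = clonotypes
    return dataset


def select_dominant_chains(gem: GemRecord) -> GemRecord:
    """Keep the most abundant chain per locus; record original multiplicity.

    UMI ties are broken toward the lexicographically smallest cdr3_nt, and
    the GEM is flagged chain-ambiguous so the complete-TCR filter can drop
    it.  Applied after clonotype definition.
    """
    out = gem.copy()
    out.n_tra_raw = len(gem.chains_of("TRA"))
    out.n_trb_raw = len(gem.chains_of("TRB"))
    kept: list[ChainObservation] = []
    ambiguous = False
    for locus in ("TRA", "TRB"):
        chains = gem.chains_of(locus)
        if not chains:
            continue
        best = _dominant(chains)
        top = max(c.umi_count for c in chains)
        if sum(1 for c in chains if c.umi_count == top) > 1:
            ambiguous = True
        kept.append(best)
    out.chains = kept
    out.chain_ambiguous = ambiguous
    return out


def select_dominant_chains_dataset(dataset: Dataset) -> Dataset:
    for gid in list(dataset.gems):
        dataset.gems[gid] = select_dominant_chains(dataset.gems[gid])
    return dataset
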