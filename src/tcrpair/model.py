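"""Core domain types for barcoded single-cell TCR-pMHC datasets.

The unit record is the GEM (gel-bead in emulsion): one droplet that ideally
captured a single T cell together with DNA-barcoded pMHC multimers and a
sample-hashing antibody.  Each GEM carries TCR contig observations plus
sparse UMI count vectors for the pMHC and hashing barcode libraries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "TcrPairError",
    "ConfigurationError",
    "FormatError",
    "RecordError",
    "IntegrityError",
    "ChainObservation",
    "GemRecord",
    "PanelEntry",
    "SampleInfo",
    "Clonotype",
    "Dataset",
    "canonicalize_hla",
]


class TcrPairError(Exception):
    """Base class for package errors."""


class ConfigurationError(TcrPairError):
    """Invalid or inconsistent configuration (missing column, bad allele...)."""


class FormatError(TcrPairError):
    """Malformed input file."""


class RecordError(TcrPairError):
    """A single record could not be parsed; carries the row index."""


class IntegrityError(TcrPairError):
    """Referential-integrity violation between dataset components."""


_HLA_COMPACT = re.compile(r"^([A-Z]+)(\d{4})$")
_HLA_FORMAL = re.compile(r"^([A-Z]+\d?)\*(\d{1,3}):(\d{1,3})$")


def canonicalize_hla(allele: str) -> str:
    """Normalize an HLA allele string to two-field star notation.

    "A0301", "HLA-A*03:01" and "A*03:01" all map to "A*03:01", so that
    haplotype matching is independent of the notation used in panel and
    sample tables.
    """
    s = allele.strip().upper()
    if s.startswith("HLA-"):
        s = s[4:]
    m = _HLA_FORMAL.match(s)
    if m:
        locus, f1, f2 = m.groups()
        return f"{locus}*{int(f1):02d}:{int(f2):02d}"
    m = _HLA_COMPACT.match(s)
    if m:
        locus, digits = m.groups()
        return f"{locus}*{int(digits[:2]):02d}:{int(digits[2:]):02d}"
    raise ConfigurationError(f"unparseable HLA allele: {allele!r}")


@dataclass(frozen=True)
class ChainObservation:
    """One TCR contig: a single alpha- or beta-chain observation in a GEM."""

    locus: str  # "TRA" or "TRB"
    v_gene: str
    j_gene: str
    c_gene: str
    cdr3_aa: str
    cdr3_nt: str
    umi_count: int
    full_length: bool
    productive: bool

    def __post_init__(self) -> None:
        if self.locus not in ("TRA", "TRB"):
            raise RecordError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.umi_count < 0:
            raise RecordError(f"negative UMI count: {self.umi_count}")
        allowed = AA_ALPHABET | ({"*"} if not self.productive else set())
        bad = set(self.cdr3_aa) - allowed
        if bad:
            raise RecordError(
                f"invalid CDR3 amino-acid characters {sorted(bad)} in {self.cdr3_aa!r}"
            )

    @property
    def vj_cdr3(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_aa)


@dataclass
class GemRecord:
    """One droplet's full observation.

    ``pmhc_counts`` and ``hash_counts`` are sparse: a feature that is absent
    has an implicit count of 0 and is never materialized.
    """

    gem_id: str
    chains: list[ChainObservation] = field(default_factory=list)
    pmhc_counts: dict[str, int] = field(default_factory=dict)
    hash_counts: dict[str, int] = field(default_factory=dict)
    n_genes: Optional[int] = None
    mito_fraction: Optional[float] = None
    is_cell_flag: Optional[bool] = None
    is_cell_gex_flag: Optional[bool] = None
    clonotype_id: Optional[str] = None
    # multiplicity before dominant-chain selection; set by select_dominant_chains
    n_tra_raw: Optional[int] = None
    n_trb_raw: Optional[int] = None
    chain_ambiguous: bool = False

    def chains_of(self, locus: str) -> list[ChainObservation]:
        return [c for c in self.chains if c.locus == locus]

    def copy(self) -> "GemRecord":
        return replace(
            self,
            chains=list(self.chains),
            pmhc_counts=dict(self.pmhc_counts),
            hash_counts=dict(self.hash_counts),
        )


@dataclass(frozen=True)
class PanelEntry:
    """One pMHC reagent in the barcoded multimer panel."""

    pmhc_id: str
    peptide: str
    hla_allele: str
    barcode_seq: str
    selection_label: str = "sorted"  # "sorted" or "deselected"


@dataclass(frozen=True)
class SampleInfo:
    """One hashed sample: hashing barcode, donor, and donor HLA haplotype."""

    hash_id: str
    donor_id: str
    hla_haplotype: frozenset[str] = frozenset()


@dataclass
class Clonotype:
    """A set of GEMs sharing identical VJ-CDR3 on the alpha and beta chains.

    At least one of the chain triples must be defined; single-chain
    clonotypes arise from chain dropout.
    """

    clonotype_id: str
    va: Optional[str] = None
    ja: Optional[str] = None
    cdr3a: Optional[str] = None
    vb: Optional[str] = None
    jb: Optional[str] = None
    cdr3b: Optional[str] = None
    member_gems: list[str] = field(default_factory=list)

    @property
    def alpha(self) -> Optional[tuple[str, str, str]]:
        if self.cdr3a is None:
            return None
        return (self.va or "", self.ja or "", self.cdr3a)

    @property
    def beta(self) -> Optional[tuple[str, str, str]]:
        if self.cdr3b is None:
            return None
        return (self.vb or "", self.jb or "", self.cdr3b)

    @property
    def key(self) -> tuple:
        return (self.alpha, self.beta)

    def __post_init__(self) -> None:
        if self.cdr3a is None and self.cdr3b is None:
            raise IntegrityError(
                f"clonotype {self.clonotype_id} has neither chain defined"
            )


@dataclass
class Dataset:
    """GEM records plus the panel / sample configuration they refer to."""

    gems: dict[str, GemRecord] = field(default_factory=dict)
    panel: dict[str, PanelEntry] = field(default_factory=dict)
    samples: dict[str, SampleInfo] = field(default_factory=dict)
    clonotypes: Optional[dict[str, Clonotype]] = None

    @classmethod
    def from_parts(
        cls,
        gems: Iterable[GemRecord],
        panel: Iterable[PanelEntry] = (),
        samples: Iterable[SampleInfo] = (),
    ) -> "Dataset":
        ds = cls(
            gems={g.gem_id: g for g in gems},
            panel={p.pmhc_id: p for p in panel},
            samples={s.hash_id: s for s in samples},
        )
        return ds

    @property
    def n_gems(self) -> int:
        return len(self.gems)

    @property
    def n_clonotypes(self) -> int:
        if self.clonotypes is not None:
            return len(self.clonotypes)
        ids = {g.clonotype_id for g in self.gems.values() if g.clonotype_id}
        return len(ids)

    def validate(self) -> None:
        """Check referential integrity between GEMs and panel/sample tables."""
        for gem in self.gems.values():
            if self.panel:
                for pid in gem.pmhc_counts:
                    if pid not in self.panel:
                        raise IntegrityError(
                            f"GEM {gem.gem_id} references unknown pMHC {pid!r}"
                        )
            if self.samples:
                for hid in gem.hash_counts:
                    if hid not in self.samples:
                        raise IntegrityError(
                            f"GEM {gem.gem_id} references unknown hash {hid!r}"
                        )
        if self.clonotypes:
            for ct in self.clonotypes.values():
                for gid in ct.member_gems:
                    if gid not in self.gems:
                        raise IntegrityError(
                            f"clonotype {ct.clonotype_id} references unknown GEM {gid!r}"
                        )

    def subset(self, gem_ids: Iterable[str]) -> "Dataset":
        """Restrict to the given GEMs, trimming clonotype member lists.

        Clonotypes left without members are dropped.  Filters use this so
        that every step returns a self-consistent dataset.
        """
        keep = set(gem_ids)
        gems = {gid: g for gid, g in self.gems.items() if gid in keep}
        clonotypes = None
        if self.clonotypes is not None:
            clonotypes = {}
            for cid, ct in self.clonotypes.items():
                members = [gid for gid in ct.member_gems if gid in keep]
                if members:
                    clonotypes[cid] = replace(ct, member_gems=members)
        return Dataset(
            gems=gems, panel=self.panel, samples=self.samples, clonotypes=clonotypes
        )

    def iter_gems(self) -> Iterable[GemRecord]:
        return self.gems.values()
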