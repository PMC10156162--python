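"""Readers and writers for the standard input/output formats.

Inputs follow the 10x Genomics conventions: the ``all_contig_annotations.csv``
dialect for V(D)J contigs and Matrix Market triplets plus feature/barcode
lists for the feature-barcode count matrices.  Panel and sample
configurations are plain delimited tables.  The pipeline's own flat GEM
table round-trips losslessly through :func:`write_gem_table` /
:func:`read_gem_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .model import (
    ChainObservation,
    ConfigurationError,
    Dataset,
    FormatError,
    GemRecord,
    PanelEntry,
    RecordError,
    SampleInfo,
    canonicalize_hla,
)

logger = logging.getLogger(__name__)

CONTIG_COLUMNS = [
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "umis",
    "full_length",
    "productive",
]

#: default id-prefix rules for classifying features when no type column exists
DEFAULT_PREFIX_RULES = {
    "pmhc": ("pMHC", "PMHC", "pmhc"),
    "hashing": ("hash", "Hash", "HTO", "Hashtag"),
}


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "t", "1"):
        return True
    if s in ("false", "f", "0", "none", "nan", ""):
        return False
    raise RecordError(f"row {row}: unparseable boolean {value!r} in column {column}")


@dataclass
class ContigData:
    """Parsed contig annotations plus the per-GEM vendor metadata."""

    records: list[tuple[str, ChainObservation]]
    vendor_clonotypes: dict[str, str] = field(default_factory=dict)
    is_cell_flags: dict[str, bool] = field(default_factory=dict)
    n_dropped_loci: int = 0


def read_contig_annotations(path, dialect: str = "10x") -> ContigData:
    """Parse a Cellranger-style contig annotation table.

    Rows whose chain is neither TRA nor TRB (e.g. IGH from ambient B cell
    material) are dropped; the count is logged and reported on the result.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"contig file {path} is missing required column(s): {', '.join(missing)}"
        )
    records: list[tuple[str, ChainObservation]] = []
    vendor: dict[str, str] = {}
    is_cell: dict[str, bool] = {}
    dropped = 0
    has_clonotype = "raw_clonotype_id" in df.columns
    has_is_cell = "is_cell" in df.columns
    for row in df.itertuples(index=True):
        locus = row.chain.strip()
        if locus not in ("TRA", "TRB"):
            dropped += 1
            continue
        try:
            umis = int(row.umis)
        except ValueError:
            raise RecordError(
                f"row {row.Index}: unparseable UMI count {row.umis!r}"
            ) from None
        obs = ChainObservation(
            locus=locus,
            v_gene=row.v_gene,
            j_gene=row.j_gene,
            c_gene=getattr(row, "c_gene", ""),
            cdr3_aa=row.cdr3,
            cdr3_nt=row.cdr3_nt,
            umi_count=umis,
            full_length=_parse_bool(row.full_length, row.Index, "full_length"),
            productive=_parse_bool(row.productive, row.Index, "productive"),
        )
        records.append((row.barcode, obs))
        if has_clonotype and row.raw_clonotype_id not in ("", "None"):
            vendor[row.barcode] = row.raw_clonotype_id
        if has_is_cell:
            is_cell[row.barcode] = _parse_bool(row.is_cell, row.Index, "is_cell")
    if dropped:
        logger.info("dropped %d non-TRA/TRB contig rows", dropped)
    return ContigData(records, vendor, is_cell, dropped)


def write_contig_annotations(path, contigs: ContigData) -> None:
    rows = []
    for gem_id, c in contigs.records:
        rows.append(
            {
                "barcode": gem_id,
                "is_cell": contigs.is_cell_flags.get(gem_id, True),
                "chain": c.locus,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "c_gene": c.c_gene,
                "cdr3": c.cdr3_aa,
                "cdr3_nt": c.cdr3_nt,
                "umis": c.umi_count,
                "full_length": c.full_length,
                "productive": c.productive,
                "raw_clonotype_id": contigs.vendor_clonotypes.get(gem_id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def classify_feature(
    feature_id: str,
    feature_type: Optional[str] = None,
    prefix_rules: Optional[Mapping[str, Sequence[str]]] = None,
) -> str:
    """Assign a feature id to {pmhc, hashing, gene}.

    An explicit feature-type column wins; otherwise configurable id-prefix
    rules are applied, defaulting to anything else being gene expression.
    """
    if feature_type:
        t = feature_type.strip().lower()
        if "hash" in t or t == "hto":
            return "hashing"
        if "pmhc" in t or "antigen" in t or "multimer" in t:
            return "pmhc"
        return "gene"
    rules = prefix_rules or DEFAULT_PREFIX_RULES
    for cls in ("hashing", "pmhc"):
        if any(feature_id.startswith(p) for p in rules.get(cls, ())):
            return cls
    return "gene"


@dataclass
class FeatureCounts:
    """Sparse per-GEM feature counts with a feature-class partition."""

    counts: dict[str, dict[str, int]]
    feature_classes: dict[str, str]

    def class_counts(self, gem_id: str, cls: str) -> dict[str, int]:
        return {
            f: c
            for f, c in self.counts.get(gem_id, {}).items()
            if self.feature_classes.get(f) == cls
        }


def read_feature_counts(
    matrix_path,
    features_path,
    barcodes_path,
    prefix_rules: Optional[Mapping[str, Sequence[str]]] = None,
) -> FeatureCounts:
    """Read a Matrix Market triplet matrix with feature/barcode lists.

    Zero entries are never materialized; duplicate triplets for the same
    (feature, GEM) cell are summed with a warning.  Total UMI mass is
    conserved: the sum of returned counts equals the sum of the file's
    value column.
    """
    mat = scipy.io.mmread(str(matrix_path))
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    coo = scipy.sparse.coo_matrix(mat)
    if coo.shape[0] != len(features) or coo.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix is {coo.shape[0]}x{coo.shape[1]} but feature/barcode lists "
            f"have {len(features)}/{len(barcodes)} entries"
        )
    feature_ids = features[0].tolist()
    feature_types = (
        features[2].tolist() if features.shape[1] >= 3 else [None] * len(features)
    )
    barcode_ids = barcodes[0].tolist()
    nnz_before = coo.nnz
    coo.sum_duplicates()
    if coo.nnz < nnz_before:
        logger.warning(
            "summed %d duplicate triplet entries", nnz_before - coo.nnz
        )
    counts: dict[str, dict[str, int]] = {}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        v = int(v)
        if v == 0:
            continue
        counts.setdefault(barcode_ids[j], {})[feature_ids[i]] = v
    classes = {
        fid: classify_feature(fid, ftype, prefix_rules)
        for fid, ftype in zip(feature_ids, feature_types)
    }
    return FeatureCounts(counts, classes)


def write_feature_counts(
    outdir,
    counts: FeatureCounts,
    feature_order: Optional[Sequence[str]] = None,
    barcode_order: Optional[Sequence[str]] = None,
) -> None:
    """Write counts as matrix.mtx + features.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features = list(feature_order or sorted(counts.feature_classes))
    barcodes = list(barcode_order or sorted(counts.counts))
    fidx = {f: i for i, f in enumerate(features)}
    bidx = {b: i for i, b in enumerate(barcodes)}
    rows, cols, vals = [], [], []
    for gem, fc in counts.counts.items():
        for f, v in fc.items():
            rows.append(fidx[f])
            cols.append(bidx[gem])
            vals.append(v)
    mat = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(len(features), len(barcodes)), dtype=np.int64
    )
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat)
    type_names = {"pmhc": "pMHC", "hashing": "Hashing", "gene": "Gene Expression"}
    with open(outdir / "features.tsv", "w") as fh:
        for f in features:
            cls = counts.feature_classes.get(f, "gene")
            fh.write(f"{f}\t{f}\t{type_names[cls]}\n")
    with open(outdir / "barcodes.tsv", "w") as fh:
        for b in barcodes:
            fh.write(b + "\n")


def read_panel_config(path) -> list[PanelEntry]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = ["pmhc_id", "peptide", "hla", "barcode"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"panel config missing column(s): {', '.join(missing)}"
        )
    entries: list[PanelEntry] = []
    seen = set()
    for row in df.itertuples():
        if row.pmhc_id in seen:
            raise ConfigurationError(f"duplicate pmhc_id {row.pmhc_id!r}")
        seen.add(row.pmhc_id)
        entries.append(
            PanelEntry(
                pmhc_id=row.pmhc_id,
                peptide=row.peptide,
                hla_allele=canonicalize_hla(row.hla),
                barcode_seq=row.barcode,
                selection_label=getattr(row, "selection", "sorted") or "sorted",
            )
        )
    return entries


def read_sample_config(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    required = ["hash_id", "donor", "haplotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"sample config missing column(s): {', '.join(missing)}"
        )
    infos: list[SampleInfo] = []
    seen = set()
    for row in df.itertuples():
        if row.hash_id in seen:
            raise ConfigurationError(f"duplicate hash_id {row.hash_id!r}")
        seen.add(row.hash_id)
        alleles = frozenset(
            canonicalize_hla(a) for a in str(row.haplotype).split(";") if a.strip()
        )
        infos.append(
            SampleInfo(hash_id=row.hash_id, donor_id=row.donor, hla_haplotype=alleles)
        )
    return infos


def write_panel_config(path, panel: Sequence[PanelEntry]) -> None:
    pd.DataFrame(
        {
            "pmhc_id": [p.pmhc_id for p in panel],
            "peptide": [p.peptide for p in panel],
            "hla": [p.hla_allele for p in panel],
            "barcode": [p.barcode_seq for p in panel],
            "selection": [p.selection_label for p in panel],
        }
    ).to_csv(path, index=False)


def write_sample_config(path, samples: Sequence[SampleInfo]) -> None:
    pd.DataFrame(
        {
            "hash_id": [s.hash_id for s in samples],
            "donor": [s.donor_id for s in samples],
            "haplotype": [";".join(sorted(s.hla_haplotype)) for s in samples],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flat GEM table
# ---------------------------------------------------------------------------

_OPT = ""  # serialized missing value


def _encode_chain(c: ChainObservation) -> str:
    return "|".join(
        [
            c.locus,
            c.v_gene,
            c.j_gene,
            c.c_gene,
            c.cdr3_aa,
            c.cdr3_nt,
            str(c.umi_count),
            "T" if c.full_length else "F",
            "T" if c.productive else "F",
        ]
    )


def _decode_chain(s: str) -> ChainObservation:
    parts = s.split("|")
    if len(parts) != 9:
        raise FormatError(f"malformed chain encoding: {s!r}")
    return ChainObservation(
        locus=parts[0],
        v_gene=parts[1],
        j_gene=parts[2],
        c_gene=parts[3],
        cdr3_aa=parts[4],
        cdr3_nt=parts[5],
        umi_count=int(parts[6]),
        full_length=parts[7] == "T",
        productive=parts[8] == "T",
    )


def _encode_counts(counts: Mapping[str, int]) -> str:
    return ";".join(f"{k}:{v}" for k, v in sorted(counts.items()))


def _decode_counts(s: str) -> dict[str, int]:
    if not s:
        return {}
    out = {}
    for item in s.split(";"):
        k, v = item.rsplit(":", 1)
        out[k] = int(v)
    return out


def write_gem_table(dataset: Dataset, path, stage_label: str = "total") -> None:
    """Write the flat per-GEM table; the stage label is kept in a comment."""
    from .specificity import gem_top_pmhc  # late import to avoid a cycle

    rows = []
    for gem in dataset.iter_gems():
        tra = gem.chains_of("TRA")
        trb = gem.chains_of("TRB")
        a = max(tra, key=lambda c: c.umi_count) if tra else None
        b = max(trb, key=lambda c: c.umi_count) if trb else None
        summary = gem_top_pmhc(gem) if gem.pmhc_counts else None
        rows.append(
            {
                "gem_id": gem.gem_id,
                "clonotype_id": gem.clonotype_id or _OPT,
                "va": a.v_gene if a else _OPT,
                "ja": a.j_gene if a else _OPT,
                "cdr3a": a.cdr3_aa if a else _OPT,
                "umi_a": a.umi_count if a else _OPT,
                "vb": b.v_gene if b else _OPT,
                "jb": b.j_gene if b else _OPT,
                "cdr3b": b.cdr3_aa if b else _OPT,
                "umi_b": b.umi_count if b else _OPT,
                "top_pmhc": (summary.top_feature or _OPT) if summary else _OPT,
                "umi_pmhc_max": summary.umi_max if summary else _OPT,
                "pmhc_counts": _encode_counts(gem.pmhc_counts),
                "hash_counts": _encode_counts(gem.hash_counts),
                "chains": ";".join(_encode_chain(c) for c in gem.chains),
                "n_genes": gem.n_genes if gem.n_genes is not None else _OPT,
                "mito_fraction": (
                    gem.mito_fraction if gem.mito_fraction is not None else _OPT
                ),
                "is_cell": _flag(gem.is_cell_flag),
                "is_cell_gex": _flag(gem.is_cell_gex_flag),
                "n_tra_raw": gem.n_tra_raw if gem.n_tra_raw is not None else _OPT,
                "n_trb_raw": gem.n_trb_raw if gem.n_trb_raw is not None else _OPT,
                "chain_ambiguous": "T" if gem.chain_ambiguous else "F",
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage_label}\n")
        df.to_csv(fh, index=False)


def _flag(v: Optional[bool]) -> str:
    if v is None:
        return _OPT
    return "T" if v else "F"


def _unflag(s: str) -> Optional[bool]:
    if s == _OPT:
        return None
    return s == "T"


def read_gem_table(
    path,
    panel: Optional[Sequence[PanelEntry]] = None,
    samples: Optional[Sequence[SampleInfo]] = None,
) -> tuple[Dataset, str]:
    """Read a flat GEM table; returns the dataset and the stage label."""
    with open(path) as fh:
        first = fh.readline()
        stage = "unknown"
        if first.startswith("# stage:"):
            stage = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    gems = []
    for row in df.itertuples():
        chains = [
            _decode_chain(s) for s in row.chains.split(";") if s
        ]
        gems.append(
            GemRecord(
                gem_id=row.gem_id,
                chains=chains,
                pmhc_counts=_decode_counts(row.pmhc_counts),
                hash_counts=_decode_counts(row.hash_counts),
                n_genes=int(row.n_genes) if row.n_genes != _OPT else None,
                mito_fraction=(
                    float(row.mito_fraction) if row.mito_fraction != _OPT else None
                ),
                is_cell_flag=_unflag(row.is_cell),
                is_cell_gex_flag=_unflag(row.is_cell_gex),
                clonotype_id=row.clonotype_id or None,
                n_tra_raw=int(row.n_tra_raw) if row.n_tra_raw != _OPT else None,
                n_trb_raw=int(row.n_trb_raw) if row.n_trb_raw != _OPT else None,
                chain_ambiguous=row.chain_ambiguous == "T",
            )
        )
    ds = Dataset.from_parts(gems, panel or (), samples or ())
    return ds, stage
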