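"""Seeded simulation of barcoded single-cell TCR-pMHC datasets.

The generator plants a ground-truth pairing — each clonotype has one
target pMHC consistent with its donor's HLA haplotype — and then layers
on the noise processes that plague real droplet data: ambient barcode
contamination (low Poisson counts on non-target pMHCs), chain dropout,
droplet doublets that merge two cells' contents, and hashing background.
Every pipeline stage can therefore be validated against known truth
without any external download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .hashing import HashClassification
from .model import (
    ChainObservation,
    ConfigurationError,
    Dataset,
    GemRecord,
    PanelEntry,
    SampleInfo,
)
from .specificity import ExpectedBinder, gem_top_pmhc

logger = logging.getLogger(__name__)

__all__ = ["SimulationParams", "simulate_dataset", "score_against_truth"]

_ALLELE_POOL = [
    "A*01:01",
    "A*02:01",
    "A*03:01",
    "B*07:02",
    "B*08:01",
    "A*11:01",
    "A*24:02",
    "B*15:01",
    "B*35:01",
    "B*44:02",
]
_NT = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class NbModel:
    """Negative-binomial signal model parameterized by mean and size."""

    mean: float
    size: float

    def draw(self, rng: np.random.Generator, n: int, min_value: int = 0) -> np.ndarray:
        p = self.size / (self.size + self.mean)
        x = rng.negative_binomial(self.size, p, size=n)
        return np.maximum(x, min_value)


@dataclass
class SimulationParams:
    seed: int = 0
    n_clonotypes: int = 300
    clone_size_alpha: float = 1.5  # power-law exponent of the clone-size law
    clone_size_max: int = 60
    n_pmhc: int = 10
    n_samples: int = 4
    pmhc_signal: NbModel = field(default_factory=lambda: NbModel(8.0, 5.0))
    tra_signal: NbModel = field(default_factory=lambda: NbModel(5.0, 5.0))
    trb_signal: NbModel = field(default_factory=lambda: NbModel(5.0, 5.0))
    hashing_signal: NbModel = field(default_factory=lambda: NbModel(80.0, 10.0))
    hashing_background: NbModel = field(default_factory=lambda: NbModel(2.0, 5.0))
    ambient_rate: float = 0.5  # Poisson mean per non-target pMHC per GEM
    dropout_alpha: float = 0.10
    dropout_beta: float = 0.05
    doublet_rate: float = 0.05
    hla_mismatch_fraction: float = 0.0  # clonotypes planted against haplotype
    vendor_unassigned_rate: float = 0.10
    haplotype_size: int = 6
    gex_summaries: bool = True
    cross_reactive_fraction: float = 0.0  # clonotypes with two planted targets

    def validate(self) -> None:
        if self.n_pmhc < 2:
            raise ConfigurationError("need at least 2 pMHCs")
        for name in ("ambient_rate", "doublet_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("dropout_alpha", "dropout_beta", "hla_mismatch_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1]")


def _random_seq(rng: np.random.Generator, alphabet: np.ndarray, length: int) -> str:
    return "".join(rng.choice(alphabet, size=length))


def _random_cdr3(rng: np.random.Generator, flank5: str, flank3: str) -> str:
    # total length 10-18 with fixed field-typical flanks
    mid = int(rng.integers(10, 19)) - len(flank5) - len(flank3)
    return flank5 + _random_seq(rng, _AA, mid) + flank3


def _make_panel(rng: np.random.Generator, n_pmhc: int) -> list[PanelEntry]:
    entries = []
    for i in range(n_pmhc):
        entries.append(
            PanelEntry(
                pmhc_id=f"pMHC{i:02d}",
                peptide=_random_seq(rng, _AA, 9),
                hla_allele=_ALLELE_POOL[i % len(_ALLELE_POOL)],
                barcode_seq=_random_seq(rng, _NT, 12),
                selection_label="sorted",
            )
        )
    return entries


def _make_samples(
    rng: np.random.Generator,
    n_samples: int,
    panel: list[PanelEntry],
    haplotype_size: int,
) -> list[SampleInfo]:
    alleles = sorted({p.hla_allele for p in panel})
    samples = []
    for i in range(n_samples):
        size = min(haplotype_size, len(alleles))
        hap = rng.choice(alleles, size=size, replace=False)
        samples.append(
            SampleInfo(
                hash_id=f"hash{i:02d}",
                donor_id=f"donor{i:02d}",
                hla_haplotype=frozenset(hap.tolist()),
            )
        )
    return samples


def simulate_dataset(
    params: SimulationParams,
) -> tuple[Dataset, pd.DataFrame]:
    """Generate a dataset with planted ground truth.

    Returns the dataset (GEMs with contigs, pMHC and hashing counts, GEX
    summaries, vendor clonotype ids on a subset) and the truth table with
    one row per GEM: true clonotype, planted target pMHC, donor, and
    whether the GEM is a merged doublet.  Fully reproducible from
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    panel = _make_panel(rng, params.n_pmhc)
    samples = _make_samples(rng, params.n_samples, panel, params.haplotype_size)

    # clonotype identities with unique alpha/beta pairs
    seen_pairs: set[tuple[str, str]] = set()
    clono_meta = []
    sizes_support = np.arange(1, params.clone_size_max + 1)
    size_probs = sizes_support ** (-params.clone_size_alpha)
    size_probs /= size_probs.sum()
    for c in range(params.n_clonotypes):
        while True:
            cdr3a = _random_cdr3(rng, "CA", "F")
            cdr3b = _random_cdr3(rng, "CASS", "F")
            if (cdr3a, cdr3b) not in seen_pairs:
                seen_pairs.add((cdr3a, cdr3b))
                break
        sample = samples[int(rng.integers(len(samples)))]
        compatible = [p for p in panel if p.hla_allele in sample.hla_haplotype]
        incompatible = [p for p in panel if p.hla_allele not in sample.hla_haplotype]
        if not compatible:
            raise ConfigurationError(
                f"donor {sample.donor_id} haplotype matches no panel entry"
            )
        if incompatible and rng.random() < params.hla_mismatch_fraction:
            target = incompatible[int(rng.integers(len(incompatible)))]
        else:
            target = compatible[int(rng.integers(len(compatible)))]
        second_target = None
        if params.cross_reactive_fraction and rng.random() < params.cross_reactive_fraction:
            others = [p for p in compatible if p.pmhc_id != target.pmhc_id]
            if others:
                second_target = others[int(rng.integers(len(others)))]
        clono_meta.append(
            {
                "clonotype": f"sim_ct{c:04d}",
                "va": f"TRAV{int(rng.integers(1, 41))}",
                "ja": f"TRAJ{int(rng.integers(1, 61))}",
                "cdr3a": cdr3a,
                "cdr3a_nt": _random_seq(rng, _NT, 3 * len(cdr3a)),
                "vb": f"TRBV{int(rng.integers(1, 31))}",
                "jb": f"TRBJ{int(rng.integers(1, 3))}-{int(rng.integers(1, 7))}",
                "cdr3b": cdr3b,
                "cdr3b_nt": _random_seq(rng, _NT, 3 * len(cdr3b)),
                "sample": sample,
                "target": target,
                "second_target": second_target,
                "size": int(rng.choice(sizes_support, p=size_probs)),
            }
        )

    gems: list[GemRecord] = []
    truth_rows = []
    vendor: dict[str, str] = {}
    gem_counter = 0
    for meta in clono_meta:
        for _ in range(meta["size"]):
            gem_counter += 1
            gid = _random_seq(rng, _NT, 16) + "-1"
            target: PanelEntry = meta["target"]
            if meta["second_target"] is not None and rng.random() < 0.5:
                target = meta["second_target"]
            pmhc_counts = {}
            signal = int(params.pmhc_signal.draw(rng, 1, min_value=1)[0])
            pmhc_counts[target.pmhc_id] = signal
            ambient = rng.poisson(params.ambient_rate, size=params.n_pmhc)
            for p, a in zip(panel, ambient):
                if a > 0 and p.pmhc_id != target.pmhc_id:
                    pmhc_counts[p.pmhc_id] = pmhc_counts.get(p.pmhc_id, 0) + int(a)
            sample: SampleInfo = meta["sample"]
            hash_counts = {}
            for s in samples:
                if s.hash_id == sample.hash_id:
                    hash_counts[s.hash_id] = int(
                        params.hashing_signal.draw(rng, 1, min_value=1)[0]
                    )
                else:
                    c = int(params.hashing_background.draw(rng, 1)[0])
                    if c > 0:
                        hash_counts[s.hash_id] = c
            chains = []
            if rng.random() >= params.dropout_alpha:
                chains.append(
                    ChainObservation(
                        "TRA",
                        meta["va"],
                        meta["ja"],
                        "TRAC",
                        meta["cdr3a"],
                        meta["cdr3a_nt"],
                        int(params.tra_signal.draw(rng, 1, min_value=1)[0]),
                        True,
                        True,
                    )
                )
            if rng.random() >= params.dropout_beta:
                chains.append(
                    ChainObservation(
                        "TRB",
                        meta["vb"],
                        meta["jb"],
                        "TRBC1",
                        meta["cdr3b"],
                        meta["cdr3b_nt"],
                        int(params.trb_signal.draw(rng, 1, min_value=1)[0]),
                        True,
                        True,
                    )
                )
            n_genes = None
            mito = None
            is_cell = None
            if params.gex_summaries:
                n_genes = int(np.clip(rng.normal(1200, 350), 50, 4000))
                mito = float(np.clip(rng.beta(2, 22), 0, 1))
                is_cell = True
            gems.append(
                GemRecord(
                    gem_id=gid,
                    chains=chains,
                    pmhc_counts=pmhc_counts,
                    hash_counts=hash_counts,
                    n_genes=n_genes,
                    mito_fraction=mito,
                    is_cell_flag=is_cell,
                    is_cell_gex_flag=is_cell,
                )
            )
            if rng.random() >= params.vendor_unassigned_rate:
                vendor[gid] = meta["clonotype"]
            truth_rows.append(
                {
                    "gem_id": gid,
                    "clonotype_true": meta["clonotype"],
                    "target_pmhc": target.pmhc_id,
                    "donor": sample.donor_id,
                    "hash_id": sample.hash_id,
                    "is_doublet": False,
                }
            )

    # droplet doublets: merge pairs of GEMs' contents
    n_doublets = int(round(params.doublet_rate * len(gems) / 2))
    truth = pd.DataFrame(truth_rows).set_index("gem_id")
    if n_doublets > 0 and len(gems) >= 2 * n_doublets:
        idx = rng.choice(len(gems), size=2 * n_doublets, replace=False)
        absorbed = set()
        for a, b in zip(idx[:n_doublets], idx[n_doublets:]):
            ga, gb = gems[a], gems[b]
            ga.chains = ga.chains + gb.chains
            for p, c in gb.pmhc_counts.items():
                ga.pmhc_counts[p] = ga.pmhc_counts.get(p, 0) + c
            for h, c in gb.hash_counts.items():
                ga.hash_counts[h] = ga.hash_counts.get(h, 0) + c
            if ga.n_genes is not None and gb.n_genes is not None:
                ga.n_genes += gb.n_genes
            truth.loc[ga.gem_id, "is_doublet"] = True
            absorbed.add(gb.gem_id)
        gems = [g for g in gems if g.gem_id not in absorbed]
        truth = truth.drop(index=list(absorbed))
        vendor = {k: v for k, v in vendor.items() if k not in absorbed}

    ds = Dataset.from_parts(gems, panel, samples)
    # vendor clonotype ids are observed input (a subset of GEMs arrives
    # pre-annotated); collapse_and_impute_clonotypes reads them from here
    for gid, vid in vendor.items():
        ds.gems[gid].clonotype_id = vid
    truth = truth.reset_index()
    truth["vendor_clonotype_id"] = truth["gem_id"].map(vendor).fillna("")
    ds.validate()
    return ds, truth


def score_against_truth(
    dataset: Dataset,
    truth: pd.DataFrame,
    expected: Optional[dict[str, ExpectedBinder]] = None,
    hash_calls: Optional[dict[str, HashClassification]] = None,
    min_gems: int = 10,
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    * target recovery: fraction of clonotypes with >= ``min_gems`` members
      whose expected binder equals the planted target (the modal true
      target of the members);
    * GEM precision / recall of top-pMHC annotations on the retained set
      (a merged doublet is scored against its primary constituent's target);
    * hashing singlet accuracy over true (non-doublet) singlet GEMs.
    """
    t = truth.set_index("gem_id")
    out: dict = {}

    if expected is not None and dataset.clonotypes is not None:
        n_big = 0
        n_recovered = 0
        for cid, ct in dataset.clonotypes.items():
            if len(ct.member_gems) < min_gems:
                continue
            members = [g for g in ct.member_gems if g in t.index]
            if not members:
                continue
            n_big += 1
            planted = t.loc[members, "target_pmhc"].mode().iloc[0]
            eb = expected.get(cid)
            if eb is not None and eb.pmhc_id == planted:
                n_recovered += 1
        out["n_clonotypes_tested"] = n_big
        out["target_recovery"] = n_recovered / n_big if n_big else None

    tp = 0
    n_retained = 0
    for gem in dataset.iter_gems():
        if gem.gem_id not in t.index:
            continue
        n_retained += 1
        summary = gem_top_pmhc(gem)
        if summary is None or summary.tie_flag:
            continue
        if summary.top_feature == t.loc[gem.gem_id, "target_pmhc"]:
            tp += 1
    out["gem_precision"] = tp / n_retained if n_retained else None
    out["gem_recall"] = tp / len(t) if len(t) else None

    if hash_calls is not None:
        singles = t[~t["is_doublet"]]
        n_ok = 0
        for gid, row in singles.iterrows():
            call = hash_calls.get(gid)
            if (
                call is not None
                and call.label == "singlet"
                and row["hash_id"] in call.positive_hashes
            ):
                n_ok += 1
        out["hashing_singlet_accuracy"] = n_ok / len(singles) if len(singles) else None
    return out
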