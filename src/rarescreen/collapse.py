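"""Gene-based collapsing of qualifying rare variants and CNVs.

Each sample is coded 1 for a gene if it carries at least one qualifying
variant (or qualifying CNV) in that gene under the chosen model, else 0.
Two models are supported:

``coding``
    Damaging coding variants: one of the coding consequence terms, not
    predicted benign by PolyPhen/SIFT, and rare (<0.1% in every gnomAD
    population and locally). CNVs: rare PASS deletions or duplications.
``lof``
    Loss-of-function only: stop gained/lost, start lost, frameshift,
    splice donor/acceptor, same frequency rule. CNVs: rare PASS deletions
    overlapping at least one exon.

Missing PolyPhen/SIFT scores are treated as *not* benign: the predictors do
not score LoF consequences, and discarding unscored variants would empty the
LoF set out of the coding model. A missing gnomAD population frequency is
treated as 0 (absence of evidence of commonness).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    CODING_CONSEQUENCES,
    CONSEQUENCE_VOCABULARY,
    LOF_CONSEQUENCES,
    MODELS,
    ThresholdConfig,
)

__all__ = [
    "AnnotatedVariant",
    "CnvEvent",
    "BurdenMatrix",
    "qualify_variant",
    "qualify_cnv",
    "collapse_burden",
]


@dataclass(frozen=True)
class AnnotatedVariant:
    """One decomposed alternate allele with annotation and carriers.

    Coordinates are 1-based (VCF convention); multi-allelic sites must be
    decomposed to one record per alternate allele upstream.
    """

    variant_id: str  # chrom:pos:ref:alt
    gene_id: str
    consequence: str
    polyphen_score: Optional[float]
    sift_score: Optional[float]
    gnomad_afs: Mapping[str, float]
    local_af: float
    carriers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_VOCABULARY:
            raise ValueError(
                f"unknown consequence {self.consequence!r} for {self.variant_id}"
            )
        for pop, af in self.gnomad_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"gnomAD AF out of range for {pop}: {af}")
        if not (0.0 <= self.local_af <= 1.0):
            raise ValueError(f"local AF out of range: {self.local_af}")


@dataclass(frozen=True)
class CnvEvent:
    """One copy-number event on one gene for one sample.

    ``exon_freq`` is the maximum per-exon cohort frequency of the event's
    exons; ``event_freq`` the event-level cohort frequency. Gene overlap is
    taken as reported by the caller; no re-intersection is performed.
    """

    sample_id: str
    gene_id: str
    cnv_type: str  # "deletion" | "duplication"
    n_exons_overlapped: int
    qc_pass: bool
    exon_freq: float
    event_freq: float

    def __post_init__(self) -> None:
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")
        if self.n_exons_overlapped < 0:
            raise ValueError("n_exons_overlapped must be >= 0")
        for name in ("exon_freq", "event_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of range: {v}")


@dataclass
class BurdenMatrix:
    """Samples x genes binary carrier indicators under one model."""

    model: str
    entries: pd.DataFrame  # index: sample_id, columns: gene_id, values 0/1

    @property
    def carrier_counts(self) -> pd.Series:
        return self.entries.sum(axis=0)

    def carriers_of(self, gene_id: str) -> frozenset[str]:
        col = self.entries[gene_id]
        return frozenset(col.index[col == 1])


def _is_benign(v: AnnotatedVariant, t: ThresholdConfig) -> bool:
    poly_benign = (
        v.polyphen_score is not None and v.polyphen_score < t.polyphen_benign_below
    )
    sift_benign = v.sift_score is not None and v.sift_score > t.sift_benign_above
    if t.benign_rule == "either":
        return poly_benign or sift_benign
    return poly_benign and sift_benign


def qualify_variant(v: AnnotatedVariant, model: str, t: ThresholdConfig) -> bool:
    """Return True iff ``v`` is a qualifying variant under ``model``.

    A variant qualifies when its consequence is in the model's set, it is not
    predicted benign, and its allele frequency is below ``t.maf_max`` in every
    gnomAD population as well as locally. Independent of the carrier list.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    conseq_set = LOF_CONSEQUENCES if model == "lof" else CODING_CONSEQUENCES
    if v.consequence not in conseq_set:
        return False
    if _is_benign(v, t):
        return False
    max_af = max([*v.gnomad_afs.values(), v.local_af], default=v.local_af)
    return max_af < t.maf_max


def qualify_cnv(c: CnvEvent, model: str, t: ThresholdConfig) -> bool:
    """Return True iff CNV event ``c`` qualifies under ``model``.

    Requires the PASS QC flag and exon- and event-level cohort frequencies
    below ``t.cnv_freq_max``. The LoF model admits only deletions overlapping
    at least one exon; the coding model admits deletions and duplications.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if not c.qc_pass:
        return False
    if c.exon_freq >= t.cnv_freq_max or c.event_freq >= t.cnv_freq_max:
        return False
    if model == "lof":
        return c.cnv_type == "deletion" and c.n_exons_overlapped >= 1
    return c.cnv_type in ("deletion", "duplication")


def collapse_burden(
    variants: Iterable[AnnotatedVariant],
    cnvs: Iterable[CnvEvent],
    samples: Sequence[str],
    genes: Sequence[str],
    model: str,
    t: ThresholdConfig,
) -> BurdenMatrix:
    """Collapse qualifying variants and CNVs to a binary burden matrix.

    Genes with zero carriers are retained as all-zero columns so downstream
    stages see the full gene universe. A carrier referenced by a variant or
    CNV but absent from ``samples`` is an error (manifest integrity).
    """
    sample_set = set(samples)
    gene_index = {g: j for j, g in enumerate(genes)}
    sample_index = {s: i for i, s in enumerate(samples)}
    mat = np.zeros((len(samples), len(genes)), dtype=np.int8)

    for v in variants:
        if v.gene_id not in gene_index:
            continue
        if not qualify_variant(v, model, t):
            continue
        unknown = v.carriers - sample_set
        if unknown:
            raise KeyError(
                f"variant {v.variant_id} carriers not in manifest: {sorted(unknown)[:5]}"
            )
        j = gene_index[v.gene_id]
        for s in v.carriers:
            mat[sample_index[s], j] = 1

    for c in cnvs:
        if c.gene_id not in gene_index:
            continue
        if not qualify_cnv(c, model, t):
            continue
        if c.sample_id not in sample_set:
            raise KeyError(f"CNV sample {c.sample_id!r} not in manifest")
        mat[sample_index[c.sample_id], gene_index[c.gene_id]] = 1

    entries = pd.DataFrame(mat, index=list(samples), columns=list(genes))
    entries.index.name = "sample_id"
    return BurdenMatrix(model=model, entries=entries)
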