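"""Synthetic two-cohort genotype/phenotype data with known penetrance.

The generator emulates the statistical structure the screening analysis
assumes: two exome-plus-EHR cohorts of different size, sex ratio and age
range, a set of null genes and a set of causal genes with configured carrier
frequency and lifetime penetrance, decoy variants exercising every clause of
the qualification filters, exon-level CNV events in the cohort that has a
CNV caller, and dated ICD diagnosis streams that resolve through a fixture
phecode map back to the intended phecodes.

Carriers of a causal gene acquire the gene's target phecode with probability
exactly equal to the penetrance; non-carriers with the background prevalence.
That makes the downstream positive predictive value a direct binomial
estimate of penetrance, which the calibration tests rely on.

All randomness flows from numpy Generators keyed by (seed, cohort index,
gene/phecode index), so output is reproducible bit-for-bit for a fixed seed
and extending the gene list does not perturb earlier genes' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phenotype import PhecodeMap

GNOMAD_POPS = ("afr", "amr", "eas", "nfe", "sas")

__all__ = [
    "SimTruth",
    "SimConfig",
    "CohortData",
    "default_truths",
    "build_fixture_phecode_map",
    "sample_carrier_mask",
    "emit_icd_stream",
    "generate_cohorts",
    "simulate_null_arrays",
]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one gene.

    ``penetrance`` is the lifetime probability that a carrier acquires
    ``target_phecode``; ``background_prevalence`` the probability for a
    non-carrier. ``lof_fraction`` of qualifying variants are LoF
    consequences, the rest damaging missense; ``cnv_fraction`` of carriers
    (in CNV-enabled cohorts) owe their status to an exonic deletion.
    """

    gene_id: str
    is_causal: bool
    carrier_freq: float
    penetrance: float
    target_phecode: str
    background_prevalence: float
    lof_fraction: float = 0.5
    cnv_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "carrier_freq",
            "penetrance",
            "background_prevalence",
            "lof_fraction",
            "cnv_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.carrier_freq > 0.01:
            raise ValueError("carrier_freq above 1% is not a rare-variant regime")
        if self.is_causal and self.penetrance < self.background_prevalence:
            raise ValueError("causal gene penetrance below background prevalence")


@dataclass(frozen=True)
class SimConfig:
    """Two-cohort study design at desk scale.

    Defaults emulate the contrast between a large 40-69-year-old cohort that
    is 55% female (no CNV calls, ICD-9 + ICD-10) and a smaller 18-89+ cohort
    that is 68% female (exon-level CNV calls, ICD-9 + ICD-10-CM), at sizes
    that keep a full pipeline run in minutes while preserving rare-variant
    sparsity.
    """

    cohort_sizes: tuple[int, int] = (20000, 5000)
    cohort_names: tuple[str, str] = ("cohort_a", "cohort_b")
    sex_fraction_female: tuple[float, float] = (0.55, 0.68)
    age_range: tuple[tuple[int, int], tuple[int, int]] = ((40, 69), (18, 89))
    icd_dialects: tuple[tuple[str, ...], tuple[str, ...]] = (
        ("icd9", "icd10"),
        ("icd9", "icd10cm"),
    )
    cnv_enabled: tuple[bool, bool] = (False, True)
    n_background_phecodes: int = 5
    background_phecode_prevalence: float = 0.03
    history_ok_fraction: float = 0.9
    extraction_date: str = "2023-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.cohort_sizes):
            raise ValueError("cohort sizes must be positive")
        if self.cohort_sizes[0] == self.cohort_sizes[1]:
            raise ValueError("cohorts must differ in size")
        if not (0.0 <= self.history_ok_fraction <= 1.0):
            raise ValueError("history_ok_fraction must lie in [0,1]")


@dataclass
class CohortData:
    """One simulated cohort, in the same layouts the ingestion module reads."""

    name: str
    samples: pd.DataFrame
    variants: pd.DataFrame
    cnvs: pd.DataFrame
    diagnoses: pd.DataFrame


def default_truths(
    n_null_genes: int = 50,
    n_causal_genes: int = 5,
    causal_penetrance: Sequence[float] = (0.8, 0.7, 0.6, 0.5, 0.4),
    causal_carrier_freq: Sequence[float] = (0.004, 0.0035, 0.003, 0.002, 0.0015),
    target_background_prevalence: float = 0.01,
) -> list[SimTruth]:
    """Default gene set: causal genes spanning the screened effect range.

    Causal penetrances span 0.4-0.8 and carrier frequencies 0.15-0.4%,
    the regime where a dual-cohort screen at desk scale retains power;
    null genes get a ramp of rare carrier frequencies and no phenotype link.
    """
    if n_causal_genes > len(causal_penetrance):
        raise ValueError("not enough penetrance values for requested causal genes")
    truths = []
    for j in range(n_causal_genes):
        truths.append(
            SimTruth(
                gene_id=f"CAUSAL_{j:02d}",
                is_causal=True,
                carrier_freq=causal_carrier_freq[j],
                penetrance=causal_penetrance[j],
                target_phecode=f"{200 + j}.1",
                background_prevalence=target_background_prevalence,
            )
        )
    for j in range(n_null_genes):
        truths.append(
            SimTruth(
                gene_id=f"NULL_{j:02d}",
                is_causal=False,
                carrier_freq=0.0005 + 0.00007 * (j % 50),
                penetrance=target_background_prevalence,
                target_phecode=f"{200 + (j % max(n_causal_genes, 1))}.1",
                background_prevalence=target_background_prevalence,
            )
        )
    return truths


def build_fixture_phecode_map(
    phecodes: Sequence[str],
    dialects: Sequence[str] = ("icd9", "icd10", "icd10cm"),
    codes_per_phecode: int = 2,
) -> PhecodeMap:
    """Synthetic ICD->phecode map covering every phecode in every dialect.

    Codes are synthetic but dialect-shaped (numeric with decimal for ICD-9,
    letter-prefixed for ICD-10/ICD-10-CM). Inverting the map recovers each
    phecode exactly: every generated code maps to a single phecode.
    """
    tables: dict[str, dict[str, frozenset[str]]] = {d: {} for d in dialects}
    for k, phe in enumerate(phecodes):
        for j in range(codes_per_phecode):
            if "icd9" in tables:
                tables["icd9"][f"{100 + k}.{j}"] = frozenset({phe})
            if "icd10" in tables:
                tables["icd10"][f"B{k:02d}.{j}"] = frozenset({phe})
            if "icd10cm" in tables:
                tables["icd10cm"][f"B{k:02d}.{j}1"] = frozenset({phe})
    return PhecodeMap(tables=tables)


def phecode_map_frames(pmap: PhecodeMap) -> dict[str, pd.DataFrame]:
    """Phecode map as per-dialect DataFrames (icd_code, phecode) for CSV export."""
    out = {}
    for system, table in pmap.tables.items():
        rows = [(icd, p) for icd, phes in sorted(table.items()) for p in sorted(phes)]
        out[system] = pd.DataFrame(rows, columns=["icd_code", "phecode"])
    return out


def sample_carrier_mask(rng: np.random.Generator, n: int, freq: float) -> np.ndarray:
    """Bernoulli carrier mask; one draw per sample."""
    return rng.random(n) < freq


def emit_icd_stream(
    rng: np.random.Generator,
    truth_phecodes: Sequence[str],
    pmap: PhecodeMap,
    dialects: Sequence[str],
    first_record: pd.Timestamp,
    extraction: pd.Timestamp,
    history_ok: bool,
) -> list[tuple[str, str, pd.Timestamp]]:
    """Dated ICD events for one sample: (icd_code, icd_system, date) rows.

    Every truth phecode yields one event whose code resolves back to exactly
    that phecode under the fixture map. When ``history_ok`` the event is
    placed at least five years after the first record (where the span
    allows), so the age-at-diagnosis history rule is satisfied; otherwise it
    is placed inside the first five years of record. A sentinel unmapped
    wellness code at the start of the record anchors medical history.
    """
    events: list[tuple[str, str, pd.Timestamp]] = [
        ("Z00.0", dialects[0], first_record)
    ]
    span_days = (extraction - first_record).days
    five_years = int(5 * 365.25)
    for phe in truth_phecodes:
        dialect = dialects[int(rng.integers(0, len(dialects)))]
        codes = sorted(
            icd
            for icd, phes in pmap.tables.get(dialect, {}).items()
            if phe in phes
        )
        if not codes:
            raise KeyError(f"phecode {phe!r} has no {dialect} code in fixture map")
        code = codes[int(rng.integers(0, len(codes)))]
        if history_ok and span_days > five_years:
            offset = five_years + int(rng.integers(0, span_days - five_years + 1))
        else:
            offset = int(rng.integers(0, max(1, min(span_days, five_years - 1))))
        events.append((code, dialect, first_record + pd.Timedelta(days=offset)))
    return events


def _simulate_samples(
    rng: np.random.Generator, cfg: SimConfig, i: int
) -> pd.DataFrame:
    n = cfg.cohort_sizes[i]
    name = cfg.cohort_names[i]
    lo, hi = cfg.age_range[i]
    extraction = pd.Timestamp(cfg.extraction_date)
    age = rng.uniform(lo, hi, size=n)
    sex = (rng.random(n) < cfg.sex_fraction_female[i]).astype(int)  # 1 = female
    record_years = rng.uniform(6.0, 15.0, size=n)
    birth = extraction - pd.to_timedelta((age * 365.25).round(), unit="D")
    first_record = extraction - pd.to_timedelta(
        (record_years * 365.25).round(), unit="D"
    )
    # records cannot predate birth
    first_record = pd.Series(first_record).where(first_record > birth, birth)
    return pd.DataFrame(
        {
            "sample_id": [f"{name}_{k:06d}" for k in range(n)],
            "sex": sex,
            "age": np.round(age, 2),
            "birth_date": pd.Series(birth).dt.strftime("%Y-%m-%d"),
            "first_record_date": pd.Series(first_record).dt.strftime("%Y-%m-%d"),
            "extraction_date": extraction.strftime("%Y-%m-%d"),
        }
    )


def _gene_variants(
    rng: np.random.Generator,
    truth: SimTruth,
    gene_idx: int,
    samples: pd.DataFrame,
    cnv_enabled: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Variant + CNV tables and (carrier mask, lof-carrier mask) for one gene."""
    n = len(samples)
    ids = samples["sample_id"].to_numpy()
    carrier = sample_carrier_mask(rng, n, truth.carrier_freq)
    idx = np.flatnonzero(carrier)

    via_cnv = (
        rng.random(idx.size) < truth.cnv_fraction
        if cnv_enabled
        else np.zeros(idx.size, dtype=bool)
    )
    is_lof = rng.random(idx.size) < truth.lof_fraction

    n_sites = 4  # per consequence class; keeps per-site AF well under 0.1%
    site_of = rng.integers(0, n_sites, size=idx.size)
    chrom = str(1 + gene_idx % 22)
    base_pos = 1_000_000 * (gene_idx + 1)

    lof_mask = np.zeros(n, dtype=bool)
    var_rows = []
    for klass, klass_mask, conseq_pool in (
        ("lof", is_lof & ~via_cnv, ["stop_gained", "frameshift_variant", "splice_donor_variant", "splice_acceptor_variant"]),
        ("mis", ~is_lof & ~via_cnv, ["missense_variant"]),
    ):
        for s in range(n_sites):
            members = idx[klass_mask & (site_of == s)]
            if members.size == 0:
                continue
            conseq = conseq_pool[s % len(conseq_pool)]
            pos = base_pos + (0 if klass == "lof" else 500) + s
            gnomad = rng.uniform(0.0, 0.0005, size=len(GNOMAD_POPS))
            row = {
                "chrom": chrom,
                "pos": pos,
                "ref": "A",
                "alt": "T",
                "gene": truth.gene_id,
                "consequence": conseq,
                "polyphen": "" if conseq != "missense_variant" else round(rng.uniform(0.7, 1.0), 3),
                "sift": "" if conseq != "missense_variant" else round(rng.uniform(0.0, 0.04), 3),
                # generative allele frequency: what annotation against the
                # full source population reports (desk-scale observed counts
                # would overstate frequency for a truly rare allele)
                "local_af": round(truth.carrier_freq / (2 * 2 * n_sites), 8),
                "carriers": ",".join(ids[members]),
            }
            for p, af in zip(GNOMAD_POPS, gnomad):
                row[f"gnomad_af_{p}"] = round(float(af), 8)
            var_rows.append(row)
            if klass == "lof":
                lof_mask[members] = True

    # decoy variants: one per filter clause, never qualifying
    decoy_specs = [
        dict(consequence="synonymous_variant", polyphen="", sift="", local_af=0.0001, common_pop=None),
        dict(consequence="missense_variant", polyphen=0.05, sift=0.6, local_af=0.0001, common_pop=None),
        dict(consequence="missense_variant", polyphen=0.95, sift=0.01, local_af=0.0001, common_pop="afr"),
        dict(consequence="missense_variant", polyphen=0.95, sift=0.01, local_af=0.02, common_pop=None),
    ]
    for dnum, spec in enumerate(decoy_specs):
        members = np.flatnonzero(rng.random(n) < 0.002)
        if members.size == 0:
            continue
        row = {
            "chrom": chrom,
            "pos": base_pos + 900 + dnum,
            "ref": "G",
            "alt": "C",
            "gene": truth.gene_id,
            "consequence": spec["consequence"],
            "polyphen": spec["polyphen"],
            "sift": spec["sift"],
            "local_af": spec["local_af"],
            "carriers": ",".join(ids[members]),
        }
        for p in GNOMAD_POPS:
            row[f"gnomad_af_{p}"] = 0.02 if spec["common_pop"] == p else 0.0001
        var_rows.append(row)

    cnv_rows = []
    cnv_members = idx[via_cnv]
    for s in cnv_members:
        cnv_rows.append(
            {
                "sample_id": ids[s],
                "gene": truth.gene_id,
                "cnv_type": "deletion",
                "n_exons_overlapped": int(rng.integers(1, 6)),
                "qc_filter": "PASS",
                "exon_freq": round(truth.carrier_freq * truth.cnv_fraction / 2, 8),
                "event_freq": round(truth.carrier_freq * truth.cnv_fraction / 2, 8),
            }
        )
    if cnv_enabled:
        # decoy CNVs: QC fail, common event, duplication (coding-only path)
        for dnum, (qc, efreq, ctype) in enumerate(
            [("FAIL", 0.0001, "deletion"), ("PASS", 0.01, "deletion"), ("PASS", 0.0001, "duplication")]
        ):
            members = np.flatnonzero(rng.random(n) < 0.001)
            for s in members:
                cnv_rows.append(
                    {
                        "sample_id": ids[s],
                        "gene": truth.gene_id,
                        "cnv_type": ctype,
                        "n_exons_overlapped": int(rng.integers(1, 4)),
                        "qc_filter": qc,
                        "exon_freq": efreq,
                        "event_freq": efreq,
                    }
                )
                if ctype == "duplication" and qc == "PASS" and efreq < 0.001:
                    carrier[s] = True  # duplication carriers count (coding model)

    variants = pd.DataFrame(var_rows)
    cnvs = pd.DataFrame(
        cnv_rows,
        columns=[
            "sample_id",
            "gene",
            "cnv_type",
            "n_exons_overlapped",
            "qc_filter",
            "exon_freq",
            "event_freq",
        ],
    )
    return variants, cnvs, carrier, lof_mask


def generate_cohorts(
    config: SimConfig,
    truths: Sequence[SimTruth],
    pmap: Optional[PhecodeMap] = None,
) -> tuple[dict[str, CohortData], PhecodeMap, dict[str, pd.DataFrame]]:
    """Simulate both cohorts end to end.

    Returns ``(cohorts, phecode_map, truth_tables)`` where ``truth_tables``
    holds per-cohort DataFrames of hidden truth (carrier and case status per
    gene) for calibration tests.
    """
    if not truths:
        raise ValueError("gene set is empty")
    target_phecodes = sorted({t.target_phecode for t in truths})
    background_phecodes = [
        f"{800 + j}.2" for j in range(config.n_background_phecodes)
    ]
    all_phecodes = target_phecodes + background_phecodes
    if pmap is None:
        pmap = build_fixture_phecode_map(all_phecodes)

    cohorts: dict[str, CohortData] = {}
    truth_tables: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(config.cohort_names):
        rng_s = np.random.default_rng([config.seed, i, 1])
        samples = _simulate_samples(rng_s, config, i)
        n = len(samples)

        var_frames, cnv_frames = [], []
        carrier_masks: dict[str, np.ndarray] = {}
        for j, truth in enumerate(truths):
            rng_g = np.random.default_rng([config.seed, i, 100 + j])
            v, c, carrier, _ = _gene_variants(
                rng_g, truth, j, samples, config.cnv_enabled[i]
            )
            var_frames.append(v)
            cnv_frames.append(c)
            carrier_masks[truth.gene_id] = carrier

        # phenotype truth: causal-gene carriers w.p. penetrance, everyone
        # else w.p. the phecode's background prevalence
        case_masks: dict[str, np.ndarray] = {}
        for k, phe in enumerate(target_phecodes):
            rng_p = np.random.default_rng([config.seed, i, 5000 + k])
            causal_here = [
                t for t in truths if t.is_causal and t.target_phecode == phe
            ]
            bg = max(
                [t.background_prevalence for t in truths if t.target_phecode == phe],
                default=0.01,
            )
            u = rng_p.random(n)
            case = u < bg
            for t in causal_here:
                m = carrier_masks[t.gene_id]
                case[m] = u[m] < t.penetrance
            case_masks[phe] = case
        for k, phe in enumerate(background_phecodes):
            rng_p = np.random.default_rng([config.seed, i, 9000 + k])
            case_masks[phe] = rng_p.random(n) < config.background_phecode_prevalence

        rng_d = np.random.default_rng([config.seed, i, 3])
        first_record = pd.to_datetime(samples["first_record_date"])
        extraction = pd.Timestamp(config.extraction_date)
        diag_rows: list[tuple[str, str, str, str]] = []
        case_lists: list[list[str]] = [[] for _ in range(n)]
        for phe in all_phecodes:
            for s in np.flatnonzero(case_masks[phe]):
                case_lists[s].append(phe)
        for s in range(n):
            history_ok = rng_d.random() < config.history_ok_fraction
            events = emit_icd_stream(
                rng_d,
                case_lists[s],
                pmap,
                config.icd_dialects[i],
                first_record.iloc[s],
                extraction,
                history_ok,
            )
            sid = samples["sample_id"].iloc[s]
            for code, system, date in events:
                diag_rows.append((sid, code, system, date.strftime("%Y-%m-%d")))

        diagnoses = pd.DataFrame(
            diag_rows, columns=["sample_id", "icd_code", "icd_system", "date"]
        )
        variants = pd.concat(var_frames, ignore_index=True)
        nonempty_cnv = [f for f in cnv_frames if len(f)]
        cnvs = (
            pd.concat(nonempty_cnv, ignore_index=True)
            if config.cnv_enabled[i] and nonempty_cnv
            else cnv_frames[0].iloc[0:0]
        )
        cohorts[name] = CohortData(
            name=name,
            samples=samples,
            variants=variants,
            cnvs=cnvs,
            diagnoses=diagnoses,
        )
        tt = pd.DataFrame({"sample_id": samples["sample_id"]})
        for t in truths:
            tt[f"carrier_{t.gene_id}"] = carrier_masks[t.gene_id].astype(int)
        for phe in all_phecodes:
            tt[f"case_{phe}"] = case_masks[phe].astype(int)
        truth_tables[name] = tt

    return cohorts, pmap, truth_tables


def simulate_null_arrays(
    rng: np.random.Generator,
    n_samples: int,
    n_genes: int,
    n_phecodes: int,
    carrier_freq: float = 0.003,
    prevalence: float = 0.05,
    age_range: tuple[float, float] = (40, 69),
    sex_fraction_female: float = 0.55,
) -> dict[str, np.ndarray]:
    """Matrix-level null draws: burden and phenotype fully independent.

    A lightweight path for calibration studies (type-I error, p-value
    uniformity) that skips ICD emission and file round-trips; the burden and
    phenotype marginals match what the full generator would produce under
    the null.
    """
    burden = (rng.random((n_samples, n_genes)) < carrier_freq).astype(np.int8)
    pheno = (rng.random((n_samples, n_phecodes)) < prevalence).astype(np.int8)
    age = rng.uniform(*age_range, size=n_samples)
    sex = (rng.random(n_samples) < sex_fraction_female).astype(int)
    return {"burden": burden, "pheno": pheno, "age": age, "sex": sex}
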