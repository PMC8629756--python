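"""File ingestion and serialization.

All tabular artifacts are TSV (tab-separated, UTF-8, header row); phecode
maps are CSV. ICD codes and phecodes are always read and written as strings.
Loaders validate schema and cross-file referential integrity (every carrier
and every diagnosis must reference a manifest sample) and fail with
file/line context.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .collapse import AnnotatedVariant, BurdenMatrix, CnvEvent
from .config import CohortPaths
from .phenotype import ICD_SYSTEMS, DiagnosisEvent, PhecodeMap, load_phecode_map
from .simulate import GNOMAD_POPS, CohortData, phecode_map_frames

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = [
    "sample_id",
    "sex",
    "age",
    "birth_date",
    "first_record_date",
    "extraction_date",
]
DIAGNOSIS_COLUMNS = ["sample_id", "icd_code", "icd_system", "date"]
CNV_COLUMNS = [
    "sample_id",
    "gene",
    "cnv_type",
    "n_exons_overlapped",
    "qc_filter",
    "exon_freq",
    "event_freq",
]


@dataclass
class CohortDataset:
    """Validated in-memory inputs for one cohort."""

    name: str
    samples: pd.DataFrame
    variants: list[AnnotatedVariant]
    cnvs: list[CnvEvent]
    diagnoses: list[DiagnosisEvent]
    phecode_map: PhecodeMap
    genes: list[str]


def _require_columns(df: pd.DataFrame, needed: list[str], path: Path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_samples(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, SAMPLE_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return df


def read_variants(path: Path) -> tuple[list[AnnotatedVariant], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "carriers": str})
    _require_columns(
        df, ["chrom", "pos", "ref", "alt", "gene", "consequence", "local_af", "carriers"], path
    )
    return variants_from_frame(df, source=str(path))


def variants_from_frame(
    df: pd.DataFrame, source: str = "<frame>"
) -> tuple[list[AnnotatedVariant], list[str]]:
    """Annotated-variant records and first-seen gene order from a table."""
    path = source
    af_cols = [c for c in df.columns if c.startswith("gnomad_af_")]
    variants: list[AnnotatedVariant] = []
    genes: list[str] = []
    seen = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            carriers = frozenset(
                s for s in str(rec["carriers"]).split(",") if s and s != "nan"
            )
            variants.append(
                AnnotatedVariant(
                    variant_id=f"{rec['chrom']}:{rec['pos']}:{rec['ref']}:{rec['alt']}",
                    gene_id=str(rec["gene"]),
                    consequence=str(rec["consequence"]),
                    polyphen_score=_opt_float(rec.get("polyphen")),
                    sift_score=_opt_float(rec.get("sift")),
                    gnomad_afs={
                        c.removeprefix("gnomad_af_"): float(rec[c]) for c in af_cols
                    },
                    local_af=float(rec["local_af"]),
                    carriers=carriers,
                )
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"{path}:{line_no}: {err}") from err
        if rec["gene"] not in seen:
            seen.add(rec["gene"])
            genes.append(str(rec["gene"]))
    return variants, genes


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def read_cnvs(path: Path) -> list[CnvEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, CNV_COLUMNS, path)
    return cnvs_from_frame(df, source=str(path))


def cnvs_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[CnvEvent]:
    path = source
    events = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        try:
            events.append(
                CnvEvent(
                    sample_id=str(rec["sample_id"]),
                    gene_id=str(rec["gene"]),
                    cnv_type=str(rec["cnv_type"]),
                    n_exons_overlapped=int(rec["n_exons_overlapped"]),
                    qc_pass=str(rec["qc_filter"]) == "PASS",
                    exon_freq=float(rec["exon_freq"]),
                    event_freq=float(rec["event_freq"]),
                )
            )
        except ValueError as err:
            raise ValueError(f"{path}:{line_no}: {err}") from err
    return events


def read_diagnoses(path: Path) -> list[DiagnosisEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, DIAGNOSIS_COLUMNS, path)
    return diagnoses_from_frame(df, source=str(path))


def diagnoses_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[DiagnosisEvent]:
    path = source
    events = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        if rec["icd_system"] not in ICD_SYSTEMS:
            raise ValueError(
                f"{path}:{line_no}: unknown icd_system {rec['icd_system']!r}"
            )
        try:
            date = pd.Timestamp(rec["date"])
        except ValueError as err:
            raise ValueError(f"{path}:{line_no}: unparseable date {rec['date']!r}") from err
        events.append(
            DiagnosisEvent(
                sample_id=rec["sample_id"],
                icd_code=rec["icd_code"],
                icd_system=rec["icd_system"],
                date=date,
            )
        )
    return events


def load_cohort(name: str, paths: CohortPaths) -> CohortDataset:
    """Load and cross-validate one cohort's inputs."""
    samples = read_samples(paths.samples)
    sample_set = set(samples["sample_id"])
    variants, genes = read_variants(paths.variants)
    for v in variants:
        unknown = v.carriers - sample_set
        if unknown:
            raise ValueError(
                f"{paths.variants}: variant {v.variant_id} carrier(s) not in manifest: "
                f"{sorted(unknown)[:3]}"
            )
    cnvs = read_cnvs(paths.cnvs) if paths.cnvs else []
    for c in cnvs:
        if c.sample_id not in sample_set:
            raise ValueError(f"{paths.cnvs}: CNV sample {c.sample_id!r} not in manifest")
    diagnoses = read_diagnoses(paths.diagnoses)
    bad = {e.sample_id for e in diagnoses} - sample_set
    if bad:
        raise ValueError(
            f"{paths.diagnoses}: diagnoses reference unknown sample(s): {sorted(bad)[:3]}"
        )
    pmap = load_phecode_map(paths.phecode_maps)
    logger.info(
        "cohort %s: %d samples, %d variants, %d CNVs, %d diagnoses",
        name, len(samples), len(variants), len(cnvs), len(diagnoses),
    )
    return CohortDataset(
        name=name,
        samples=samples,
        variants=variants,
        cnvs=cnvs,
        diagnoses=diagnoses,
        phecode_map=pmap,
        genes=genes,
    )


def write_cohort(data: CohortData, out_dir: Path, pmap: PhecodeMap) -> dict[str, Path]:
    """Write a simulated cohort in the layouts the loaders read."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out_dir / "samples.tsv",
        "variants": out_dir / "variants.tsv",
        "diagnoses": out_dir / "diagnoses.tsv",
    }
    data.samples.to_csv(paths["samples"], sep="\t", index=False)
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "consequence", "polyphen", "sift",
        *[f"gnomad_af_{p}" for p in GNOMAD_POPS], "local_af", "carriers",
    ]
    data.variants.reindex(columns=cols).to_csv(paths["variants"], sep="\t", index=False)
    data.diagnoses.to_csv(paths["diagnoses"], sep="\t", index=False)
    if len(data.cnvs):
        paths["cnvs"] = out_dir / "cnvs.tsv"
        data.cnvs.to_csv(paths["cnvs"], sep="\t", index=False)
    map_dir = out_dir / "phecode_maps"
    map_dir.mkdir(exist_ok=True)
    for system, frame in phecode_map_frames(pmap).items():
        frame.to_csv(map_dir / f"{system}.csv", index=False)
    return paths


def write_burden(matrix: BurdenMatrix, out_dir: Path, stem: str) -> None:
    """Burden matrix as dense TSV plus sparse triplets (sample, gene, 1)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix.entries.to_csv(out_dir / f"{stem}.tsv", sep="\t")
    stacked = matrix.entries.stack()
    trip = stacked[stacked == 1].reset_index()
    trip.columns = ["sample_id", "gene", "value"]
    trip.to_csv(out_dir / f"{stem}.triplets.tsv", sep="\t", index=False)


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(out_dir: Path, payload: dict) -> Path:
    """Sidecar recording config hash, seed and package versions."""
    import rarescreen

    out = Path(out_dir) / "provenance.json"
    record = {
        "package": "rarescreen",
        "version": getattr(rarescreen, "__version__", "unknown"),
        **payload,
    }
    record["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    out.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return out
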