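"""Phecode phenotype construction from dated ICD diagnosis streams.

Billing codes (ICD-9, ICD-10 or ICD-10-CM, depending on the health system)
are mapped to phecodes; an individual is a case for a phecode if it appears
at least once anywhere in their record. Case status uses *all* events; the
five-year-history rule gates only the age-at-first-diagnosis value used for
age-stratified summaries, never case membership.

ICD codes and phecodes are strings throughout — decimal points and leading
zeros are significant and must never be coerced to numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ThresholdConfig

logger = logging.getLogger(__name__)

ICD_SYSTEMS = ("icd9", "icd10", "icd10cm")

__all__ = [
    "DiagnosisEvent",
    "PhecodeMap",
    "PhenotypeMatrix",
    "load_phecode_map",
    "map_diagnoses",
    "filter_phenotypes",
    "age_at_first_valid_diagnosis",
]


@dataclass(frozen=True)
class DiagnosisEvent:
    sample_id: str
    icd_code: str
    icd_system: str
    date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.icd_system not in ICD_SYSTEMS:
            raise ValueError(f"unknown icd_system {self.icd_system!r}")


@dataclass
class PhecodeMap:
    """Per-dialect ICD -> {phecodes} lookup. Dialects are kept separate."""

    tables: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def lookup(self, icd_system: str, icd_code: str) -> frozenset[str]:
        if icd_system not in self.tables:
            raise KeyError(f"no map loaded for icd_system {icd_system!r}")
        return self.tables[icd_system].get(icd_code, frozenset())

    def phecodes(self) -> frozenset[str]:
        out: set[str] = set()
        for table in self.tables.values():
            for codes in table.values():
                out |= codes
        return frozenset(out)


def load_phecode_map(paths: Mapping[str, str | Path]) -> PhecodeMap:
    """Read phecode map CSVs, one per ICD dialect.

    Each CSV has columns ``icd_code,phecode`` (extra columns ignored); the
    dialect is implied by the file, keyed by the mapping argument. Codes are
    read as strings verbatim.
    """
    tables: dict[str, dict[str, frozenset[str]]] = {}
    for system, path in paths.items():
        if system not in ICD_SYSTEMS:
            raise ValueError(f"unknown icd_system {system!r}")
        df = pd.read_csv(path, dtype=str)
        if not {"icd_code", "phecode"} <= set(df.columns):
            raise ValueError(f"{path}: phecode map needs icd_code,phecode columns")
        table: dict[str, set[str]] = {}
        for icd, phe in zip(df["icd_code"], df["phecode"]):
            table.setdefault(icd, set()).add(phe)
        tables[system] = {k: frozenset(v) for k, v in table.items()}
    return PhecodeMap(tables=tables)


@dataclass
class PhenotypeMatrix:
    """Samples x phecodes binary case matrix with per-pair first-diagnosis ages."""

    entries: pd.DataFrame  # index sample_id, columns phecode, values 0/1
    age_at_first_diagnosis: pd.DataFrame  # same shape, float years, NaN = missing

    @property
    def case_counts(self) -> pd.Series:
        return self.entries.sum(axis=0)


def _events_frame(events: Iterable[DiagnosisEvent]) -> pd.DataFrame:
    rows = [(e.sample_id, e.icd_code, e.icd_system, e.date) for e in events]
    return pd.DataFrame(rows, columns=["sample_id", "icd_code", "icd_system", "date"])


def map_diagnoses(
    events: Iterable[DiagnosisEvent],
    phecode_map: PhecodeMap,
    samples: Sequence[str],
    birth_dates: Optional[Mapping[str, pd.Timestamp]] = None,
    phecodes: Optional[Sequence[str]] = None,
) -> PhenotypeMatrix:
    """Build the binary phenotype matrix from a diagnosis stream.

    ``entry(s, p) = 1`` iff at least one event of sample ``s`` maps to phecode
    ``p``. A single ICD code mapping to several phecodes sets all of them.
    Unmapped ICD codes are counted and logged, never fatal. When
    ``birth_dates`` is given, ``age_at_first_diagnosis`` applies the
    five-year-history rule via :func:`age_at_first_valid_diagnosis`.
    """
    ev = _events_frame(events)
    unknown_systems = set(ev["icd_system"]) - set(ICD_SYSTEMS) if len(ev) else set()
    if unknown_systems:
        raise ValueError(f"unknown icd_system values: {sorted(unknown_systems)}")
    missing_map = set(ev["icd_system"]) - set(phecode_map.tables) if len(ev) else set()
    if missing_map:
        raise ValueError(f"no phecode map for icd_system: {sorted(missing_map)}")

    # explode events to (sample, phecode, date)
    mapped_rows: list[tuple[str, str, pd.Timestamp]] = []
    n_unmapped = 0
    for s, icd, system, date in ev.itertuples(index=False):
        targets = phecode_map.lookup(system, icd)
        if not targets:
            n_unmapped += 1
            continue
        for p in targets:
            mapped_rows.append((s, p, date))
    if n_unmapped:
        logger.info("map_diagnoses: %d events had no phecode mapping", n_unmapped)

    mapped = pd.DataFrame(mapped_rows, columns=["sample_id", "phecode", "date"])
    universe = (
        list(phecodes)
        if phecodes is not None
        else sorted(set(mapped["phecode"])) or sorted(phecode_map.phecodes())
    )
    entries = pd.DataFrame(0, index=list(samples), columns=universe, dtype=np.int8)
    entries.index.name = "sample_id"
    ages = pd.DataFrame(np.nan, index=list(samples), columns=universe, dtype=float)
    ages.index.name = "sample_id"

    if len(mapped):
        known = mapped[mapped["sample_id"].isin(set(samples))]
        dropped = len(mapped) - len(known)
        if dropped:
            raise KeyError(
                "diagnosis events reference samples absent from manifest: "
                f"{sorted(set(mapped['sample_id']) - set(samples))[:5]}"
            )
        for (s, p), grp in known.groupby(["sample_id", "phecode"], sort=False):
            if p not in entries.columns:
                continue
            entries.at[s, p] = 1

        if birth_dates is not None:
            first_any = ev.groupby("sample_id")["date"].min()
            for (s, p), grp in known.groupby(["sample_id", "phecode"], sort=False):
                if p not in ages.columns:
                    continue
                age = _age_valid(
                    birth=birth_dates[s],
                    first_any=first_any[s],
                    first_target=grp["date"].min(),
                )
                if age is not None:
                    ages.at[s, p] = age

    return PhenotypeMatrix(entries=entries, age_at_first_diagnosis=ages)


def _age_valid(
    birth: pd.Timestamp, first_any: pd.Timestamp, first_target: pd.Timestamp
) -> Optional[float]:
    if first_target < birth:
        raise ValueError("diagnosis date precedes birth")
    age = (first_target - birth).days / 365.25
    five_years_history = first_any <= first_target - pd.DateOffset(years=5)
    if five_years_history or age < 5.0:
        return age
    return None


def age_at_first_valid_diagnosis(
    events: Sequence[DiagnosisEvent],
    phecode: str,
    phecode_map: PhecodeMap,
    birth_date: pd.Timestamp,
) -> Optional[float]:
    """Age (years) at the earliest event mapping to ``phecode``, or None.

    The age is returned only when the record shows at least five years of
    medical history before that event — the first diagnosis of *any*
    condition must fall at least five years earlier — or when the diagnosis
    occurred within the first five years of life.
    """
    if not events:
        raise ValueError("sample has no events")
    dates_any = [e.date for e in events]
    dates_target = [
        e.date for e in events if phecode in phecode_map.lookup(e.icd_system, e.icd_code)
    ]
    if not dates_target:
        return None
    return _age_valid(birth_date, min(dates_any), min(dates_target))


def filter_phenotypes(
    matrix_large: PhenotypeMatrix,
    matrix_small: PhenotypeMatrix,
    t: ThresholdConfig,
) -> list[str]:
    """Phecodes analyzable in both cohorts.

    Retains phecodes with at least one case in the larger cohort and at least
    ``t.min_cases_small_cohort`` cases in the smaller cohort.
    """
    shared = [p for p in matrix_large.entries.columns if p in matrix_small.entries.columns]
    counts_large = matrix_large.case_counts
    counts_small = matrix_small.case_counts
    return [
        p
        for p in shared
        if counts_large[p] >= 1 and counts_small[p] >= t.min_cases_small_cohort
    ]
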