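"""Threshold and run configuration.

All tunable cutoffs of the screening procedure live in :class:`ThresholdConfig`
so that every rule clause (frequency filters, deleteriousness cutoffs,
significance and PPV gates) is applied from a single validated source.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: Consequence terms that count as "coding" for the damaging/coding model.
CODING_CONSEQUENCES = frozenset(
    {
        "stop_lost",
        "missense_variant",
        "start_lost",
        "splice_donor_variant",
        "inframe_deletion",
        "frameshift_variant",
        "splice_acceptor_variant",
        "stop_gained",
        "inframe_insertion",
    }
)

#: Consequence terms that count as loss-of-function (LoF model).
LOF_CONSEQUENCES = frozenset(
    {
        "stop_lost",
        "start_lost",
        "splice_donor_variant",
        "frameshift_variant",
        "splice_acceptor_variant",
        "stop_gained",
    }
)

#: Full controlled vocabulary accepted on input. Non-qualifying terms are kept
#: so that decoy/benign records parse cleanly and are rejected by the rule,
#: not by the parser.
CONSEQUENCE_VOCABULARY = CODING_CONSEQUENCES | {
    "synonymous_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "splice_region_variant",
}

MODELS = ("coding", "lof")


@dataclass(frozen=True)
class ThresholdConfig:
    """Cutoffs used across qualification, phenotype filtering, and screening.

    Parameters
    ----------
    maf_max:
        Qualifying variants must have allele frequency strictly below this in
        every gnomAD population and locally (default 0.1%).
    polyphen_benign_below:
        PolyPhen scores below this are benign (default 0.15).
    sift_benign_above:
        SIFT scores above this are benign (default 0.05).
    benign_rule:
        ``"either"`` drops a variant if either predictor calls it benign
        (default, conservative); ``"both"`` requires both predictors to agree.
    cnv_freq_max:
        Exon- and event-level CNV cohort frequencies must be below this.
    bonferroni_alpha:
        Meta-analysis significance cutoff (default 1e-9).
    ppv_min:
        Positive-predictive-value threshold for screening candidacy.
    min_cases_small_cohort:
        Phenotypes must have at least this many cases in the smaller cohort.
    min_carrier_cases_display:
        Strata with fewer carrier cases than this are flagged non-displayable.
    age_stratum_cut:
        Age (years, at data extraction) defining the lifetime-risk stratum.
    strict_stratum_policy:
        If True, an undefined/under-sized 60+ stratum never counts as passing;
        if False (default) it counts as passing when that cohort's all-ages
        PPV clears ``ppv_min`` (flagged for manual review).
    """

    maf_max: float = 0.001
    polyphen_benign_below: float = 0.15
    sift_benign_above: float = 0.05
    benign_rule: str = "either"
    cnv_freq_max: float = 0.001
    bonferroni_alpha: float = 1e-9
    ppv_min: float = 0.3
    min_cases_small_cohort: int = 30
    min_carrier_cases_display: int = 5
    age_stratum_cut: float = 60.0

    strict_stratum_policy: bool = False
    meta_weighting: str = "effective"  # or "raw"
    p_method: str = "lrt"  # or "wald"

    def __post_init__(self) -> None:
        for name in (
            "maf_max",
            "polyphen_benign_below",
            "sift_benign_above",
            "cnv_freq_max",
            "bonferroni_alpha",
            "age_stratum_cut",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.ppv_min < 1.0):
            raise ValueError("ppv_min must lie in (0, 1)")
        if self.min_cases_small_cohort < 1 or self.min_carrier_cases_display < 1:
            raise ValueError("case-count thresholds must be positive")
        if self.benign_rule not in ("either", "both"):
            raise ValueError("benign_rule must be 'either' or 'both'")
        if self.meta_weighting not in ("effective", "raw"):
            raise ValueError("meta_weighting must be 'effective' or 'raw'")
        if self.p_method not in ("lrt", "wald"):
            raise ValueError("p_method must be 'lrt' or 'wald'")


@dataclass
class CohortPaths:
    """Input file locations for one cohort."""

    samples: Path
    variants: Path
    diagnoses: Path
    cnvs: Optional[Path] = None
    phecode_maps: dict[str, Path] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs, thresholds, models, seed."""

    cohorts: dict[str, CohortPaths]
    out_dir: Path
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    models: tuple[str, ...] = MODELS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cohorts) != 2:
            raise ValueError("exactly two cohorts are required")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration.

    Layout::

        seed: 7
        out_dir: out/
        models: [coding, lof]
        thresholds: {maf_max: 0.001, ...}       # optional overrides
        cohorts:
          ukb_like:
            samples: a/samples.tsv
            variants: a/variants.tsv
            diagnoses: a/diagnoses.tsv
            phecode_maps: {icd9: maps/icd9.csv, icd10: maps/icd10.csv}
          hnp_like:
            samples: b/samples.tsv
            ...
            cnvs: b/cnvs.tsv
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else base / p

    cohorts = {}
    for name, spec in raw["cohorts"].items():
        cohorts[name] = CohortPaths(
            samples=_p(spec["samples"]),
            variants=_p(spec["variants"]),
            diagnoses=_p(spec["diagnoses"]),
            cnvs=_p(spec["cnvs"]) if spec.get("cnvs") else None,
            phecode_maps={k: _p(v) for k, v in spec.get("phecode_maps", {}).items()},
        )
    thresholds = ThresholdConfig(**raw.get("thresholds", {}))
    known = {f.name for f in dataclasses.fields(ThresholdConfig)}
    extra = set(raw.get("thresholds", {})) - known
    if extra:
        raise ValueError(f"unknown threshold keys: {sorted(extra)}")
    return RunConfig(
        cohorts=cohorts,
        out_dir=_p(raw.get("out_dir", "out")),
        thresholds=thresholds,
        models=tuple(raw.get("models", MODELS)),
        seed=int(raw.get("seed", 0)),
    )
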