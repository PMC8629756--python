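"""End-to-end orchestration: collapse -> phenotype -> associate -> meta -> screen.

The pipeline is deterministic given its inputs: no stage draws random
numbers, artifact orders are fixed by input order, and a rerun with the same
configuration produces byte-identical files (verified by checksum in the
test suite). Each run writes a provenance sidecar with the config hash and
seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import (
    CohortAssocResult,
    ConstantPhenotypeError,
    _design,
    build_covariates,
    compute_ppv,
    contingency_stats,
    firth_logistic,
)
from .collapse import BurdenMatrix, collapse_burden
from .config import RunConfig, ThresholdConfig
from .io import (
    CohortDataset,
    file_checksum,
    load_cohort,
    write_burden,
    write_provenance,
)
from .meta import (
    MetaResult,
    ScreenDecision,
    build_report,
    ppv_screen,
    significance_gate,
    weighted_z_meta,
)
from .phenotype import PhenotypeMatrix, filter_phenotypes, map_diagnoses
from scipy import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "analyze_cohort_data",
    "associate_cohort",
    "build_phenotypes",
]


@dataclass
class PipelineResult:
    cohort_names: tuple[str, str]  # (larger, smaller)
    burden: dict[tuple[str, str], BurdenMatrix]  # (cohort, model) -> matrix
    phenotypes: dict[str, PhenotypeMatrix]
    analysis_phecodes: list[str]
    assoc: dict[str, dict[tuple[str, str, str], CohortAssocResult]]
    metas: list[MetaResult]
    decisions: list[ScreenDecision]
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    full_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_phenotypes(dataset: CohortDataset) -> PhenotypeMatrix:
    """Phenotype matrix over the cohort's phecode-map universe."""
    birth = {
        s: pd.Timestamp(b)
        for s, b in zip(dataset.samples["sample_id"], dataset.samples["birth_date"])
    }
    return map_diagnoses(
        dataset.diagnoses,
        dataset.phecode_map,
        list(dataset.samples["sample_id"]),
        birth_dates=birth,
        phecodes=sorted(dataset.phecode_map.phecodes()),
    )


def associate_cohort(
    burden_matrices: dict[str, BurdenMatrix],
    pheno: PhenotypeMatrix,
    samples: pd.DataFrame,
    phecodes: Sequence[str],
    t: ThresholdConfig,
    genes: Optional[Sequence[str]] = None,
) -> dict[tuple[str, str, str], CohortAssocResult]:
    """All (gene, phecode, model) tests for one cohort.

    Covariate-only Firth fits are cached per phecode and used to warm-start
    each gene's constrained and full fits; results are identical to calling
    :func:`rarescreen.association.fit_burden_test` pair by pair.
    """
    age = samples["age"].to_numpy(dtype=float)
    sex = samples["sex"].to_numpy(dtype=int)
    covs = build_covariates(age, sex)
    n = len(samples)
    X = _design(np.zeros(n, dtype=np.int8), covs)
    k = X.shape[1] - 1

    results: dict[tuple[str, str, str], CohortAssocResult] = {}
    for phe in phecodes:
        y = pheno.entries[phe].to_numpy(dtype=float)
        if y.min() == y.max():
            logger.warning("phecode %s constant in cohort; skipped", phe)
            continue
        fit_cov = firth_logistic(X[:, :k], y)
        start = np.append(fit_cov.beta, 0.0)
        for model, bm in burden_matrices.items():
            cols = genes if genes is not None else bm.entries.columns
            for gene in cols:
                b = bm.entries[gene].to_numpy(dtype=np.int8)
                if b.sum() < 1:
                    continue
                X[:, k] = b
                fit0 = firth_logistic(X, y, fixed_zero=[k], start=start)
                fit1 = firth_logistic(X, y, start=fit0.beta)
                beta = float(fit1.beta[k])
                if t.p_method == "wald":
                    se = float(fit1.se[k])
                    z = beta / se if se > 0 else 0.0
                    p = float(2.0 * _stats.norm.sf(abs(z)))
                else:
                    stat = max(0.0, 2.0 * (fit1.pen_loglik - fit0.pen_loglik))
                    z = float(np.sign(beta) * np.sqrt(stat))
                    p = float(_stats.chi2.sf(stat, df=1))
                a, bb, c, d, oddsr = contingency_stats(b, y)
                ppv_all, _ = compute_ppv(b, y, age, "all", t.age_stratum_cut)
                ppv_60, cc60 = compute_ppv(b, y, age, "sixty_plus", t.age_stratum_cut)
                results[(gene, phe, model)] = CohortAssocResult(
                    gene_id=gene,
                    phecode=phe,
                    model=model,
                    n_samples=n,
                    a=a,
                    b=bb,
                    c=c,
                    d=d,
                    beta=beta,
                    se=float(fit1.se[k]),
                    z=z,
                    p=max(p, np.nextafter(0, 1)),
                    odds_ratio=oddsr,
                    ppv_all_ages=ppv_all,
                    ppv_60plus=ppv_60,
                    carrier_cases_60plus=cc60,
                )
        X[:, k] = 0
    return results


def _assoc_frame(results: dict[tuple[str, str, str], CohortAssocResult]) -> pd.DataFrame:
    rows = []
    for (gene, phe, model), r in sorted(results.items()):
        rows.append(
            {
                "gene": gene,
                "phecode": phe,
                "model": model,
                "n": r.n_samples,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "beta": r.beta,
                "se": r.se,
                "z": r.z,
                "p": r.p,
                "or": r.odds_ratio,
                "ppv_all": r.ppv_all_ages,
                "ppv_60plus": r.ppv_60plus,
                "carrier_cases_60plus": r.carrier_cases_60plus,
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort_data(
    cohorts: dict,
    pmap,
    t: Optional[ThresholdConfig] = None,
    models: Sequence[str] = ("coding", "lof"),
) -> PipelineResult:
    """Run collapse -> phenotype -> associate -> meta -> screen in memory.

    ``cohorts`` maps names to :class:`rarescreen.simulate.CohortData`
    (or any object with the same DataFrames); no files are read or written.
    """
    from .io import cnvs_from_frame, diagnoses_from_frame, variants_from_frame

    t = t or ThresholdConfig()
    datasets: dict[str, CohortDataset] = {}
    for name, data in cohorts.items():
        variants, genes = variants_from_frame(data.variants)
        cnvs = cnvs_from_frame(data.cnvs) if len(data.cnvs) else []
        diagnoses = diagnoses_from_frame(data.diagnoses)
        datasets[name] = CohortDataset(
            name=name,
            samples=data.samples,
            variants=variants,
            cnvs=cnvs,
            diagnoses=diagnoses,
            phecode_map=pmap,
            genes=genes,
        )
    names = sorted(datasets, key=lambda n: -len(datasets[n].samples))
    larger, smaller = names[0], names[1]

    burden: dict[tuple[str, str], BurdenMatrix] = {}
    for name, ds in datasets.items():
        gene_universe = sorted(set(ds.genes) | {c.gene_id for c in ds.cnvs})
        for model in models:
            burden[(name, model)] = collapse_burden(
                ds.variants, ds.cnvs, list(ds.samples["sample_id"]),
                gene_universe, model, t,
            )

    phenos = {name: build_phenotypes(ds) for name, ds in datasets.items()}
    analysis_phecodes = filter_phenotypes(phenos[larger], phenos[smaller], t)

    assoc: dict[str, dict[tuple[str, str, str], CohortAssocResult]] = {}
    for name, ds in datasets.items():
        bms = {m: burden[(name, m)] for m in models}
        assoc[name] = associate_cohort(bms, phenos[name], ds.samples, analysis_phecodes, t)

    metas: list[MetaResult] = []
    for key in sorted(set(assoc[larger]) & set(assoc[smaller])):
        ra, rb = assoc[larger][key], assoc[smaller][key]
        if min(ra.n_cases, ra.n_controls, rb.n_cases, rb.n_controls) == 0:
            continue
        m = weighted_z_meta(ra, rb, t)
        significance_gate(m, t)
        metas.append(m)

    decisions = [
        ppv_screen(m, assoc[larger][(m.gene_id, m.phecode, m.model)],
                   assoc[smaller][(m.gene_id, m.phecode, m.model)], t)
        for m in metas
        if m.significant
    ]
    candidates, full = build_report(metas, decisions, assoc[larger], assoc[smaller])
    return PipelineResult(
        cohort_names=(larger, smaller),
        burden=burden,
        phenotypes=phenos,
        analysis_phecodes=analysis_phecodes,
        assoc=assoc,
        metas=metas,
        decisions=decisions,
        candidates=candidates,
        full_table=full,
    )


_STAGE_ORDER = ("collapse", "phenotype", "associate", "meta", "screen")


def run_pipeline(config: RunConfig, stop_after: Optional[str] = None) -> PipelineResult:
    """Execute the stages in order and write all artifacts.

    Stage order: load -> collapse (per cohort, per model) -> phenotype ->
    associate per cohort -> weighted-Z meta -> significance gates -> PPV
    screen -> report. ``stop_after`` truncates the run after the named stage
    so intermediate artifacts can be inspected. Any stage failure halts with
    the stage name.
    """
    if stop_after is not None and stop_after not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {stop_after!r}")
    last = _STAGE_ORDER.index(stop_after) if stop_after else len(_STAGE_ORDER) - 1
    t = config.thresholds
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    phenos: dict[str, PhenotypeMatrix] = {}
    analysis_phecodes: list[str] = []
    assoc: dict[str, dict[tuple[str, str, str], CohortAssocResult]] = {}
    metas: list[MetaResult] = []
    decisions: list[ScreenDecision] = []
    candidates = pd.DataFrame()
    full = pd.DataFrame()

    stage = "load"
    try:
        datasets = {
            name: load_cohort(name, paths) for name, paths in config.cohorts.items()
        }
        names = sorted(datasets, key=lambda n: -len(datasets[n].samples))
        larger, smaller = names[0], names[1]

        stage = "collapse"
        burden: dict[tuple[str, str], BurdenMatrix] = {}
        for name, ds in datasets.items():
            gene_universe = sorted(
                set(ds.genes)
                | {c.gene_id for c in ds.cnvs}
            )
            for model in config.models:
                bm = collapse_burden(
                    ds.variants,
                    ds.cnvs,
                    list(ds.samples["sample_id"]),
                    gene_universe,
                    model,
                    t,
                )
                burden[(name, model)] = bm
                write_burden(bm, out / name, f"burden_{model}")

        if last >= _STAGE_ORDER.index("phenotype"):
            stage = "phenotype"
            phenos = {name: build_phenotypes(ds) for name, ds in datasets.items()}
            for name, pm in phenos.items():
                (out / name).mkdir(parents=True, exist_ok=True)
                pm.entries.to_csv(out / name / "phenotypes.tsv", sep="\t")
            analysis_phecodes = filter_phenotypes(phenos[larger], phenos[smaller], t)

        if last >= _STAGE_ORDER.index("associate"):
            stage = "associate"
            for name, ds in datasets.items():
                bms = {m: burden[(name, m)] for m in config.models}
                assoc[name] = associate_cohort(
                    bms, phenos[name], ds.samples, analysis_phecodes, t
                )
                _assoc_frame(assoc[name]).to_csv(
                    out / name / "associations.tsv", sep="\t", index=False
                )

        if last >= _STAGE_ORDER.index("meta"):
            stage = "meta"
            shared = sorted(set(assoc[larger]) & set(assoc[smaller]))
            for key in shared:
                ra, rb = assoc[larger][key], assoc[smaller][key]
                if min(ra.n_cases, ra.n_controls, rb.n_cases, rb.n_controls) == 0:
                    continue
                m = weighted_z_meta(ra, rb, t)
                significance_gate(m, t)
                metas.append(m)

        if last >= _STAGE_ORDER.index("screen"):
            stage = "screen"
            decisions = [
                ppv_screen(m, assoc[larger][(m.gene_id, m.phecode, m.model)],
                           assoc[smaller][(m.gene_id, m.phecode, m.model)], t)
                for m in metas
                if m.significant
            ]
            candidates, full = build_report(
                metas, decisions, assoc[larger], assoc[smaller]
            )
            candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
            full.to_csv(out / "associations_meta.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    write_provenance(
        out,
        {
            "seed": config.seed,
            "models": list(config.models),
            "thresholds": vars(t),
            "cohorts": {
                n: {
                    "samples_sha256": file_checksum(p.samples),
                    "variants_sha256": file_checksum(p.variants),
                    "diagnoses_sha256": file_checksum(p.diagnoses),
                }
                for n, p in config.cohorts.items()
            },
            "larger_cohort": larger,
            "stop_after": stop_after,
            "n_analysis_phecodes": len(analysis_phecodes),
            "n_meta_triples": len(metas),
            "n_candidates": int(candidates.shape[0]),
        },
    )
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return PipelineResult(
        cohort_names=(larger, smaller),
        burden=burden,
        phenotypes=phenos,
        analysis_phecodes=analysis_phecodes,
        assoc=assoc,
        metas=metas,
        decisions=decisions,
        candidates=candidates,
        full_table=full,
    )
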