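"""Two-cohort weighted-Z meta-analysis and the PPV screening verdict.

Cohort-level signed Z statistics are combined with sample-size weights
(METAL scheme): z_meta = (w_a z_a + w_b z_b) / sqrt(w_a^2 + w_b^2), with
w_i = sqrt(n_eff,i) and effective sample size n_eff = 4/(1/cases + 1/controls)
for a binary trait (raw-n weighting is a config option).

A triple is *significant* when all three gates hold: at least one carrier in
both cohorts, meta p strictly better than either cohort's p, and meta
p < 1e-9 (Bonferroni). A significant triple becomes a screening *candidate*
when its positive predictive value reaches the threshold (default 0.3) in
BOTH cohorts, in the all-ages stratum or in the 60+ (lifetime-risk) stratum;
a 60+ pass counts even when the all-ages PPV is lower. Only risk-increasing
(z_meta > 0) associations are screened; protective hits stay in the full
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from scipy import stats

from .association import CohortAssocResult
from .config import ThresholdConfig

__all__ = [
    "MetaResult",
    "ScreenDecision",
    "weighted_z_meta",
    "significance_gate",
    "ppv_screen",
    "build_report",
]


@dataclass
class MetaResult:
    gene_id: str
    phecode: str
    model: str
    z_meta: float
    p_meta: float
    weights: tuple[float, float]
    carriers_per_cohort: tuple[int, int]
    p_per_cohort: tuple[float, float]
    gates: dict[str, bool] = field(default_factory=dict)
    significant: bool = False


def _effective_n(res: CohortAssocResult) -> float:
    if res.n_cases == 0 or res.n_controls == 0:
        raise ValueError(
            f"cohort has zero cases or controls for {res.gene_id}/{res.phecode}"
        )
    return 4.0 / (1.0 / res.n_cases + 1.0 / res.n_controls)


def weighted_z_meta(
    res_a: CohortAssocResult,
    res_b: CohortAssocResult,
    t: Optional[ThresholdConfig] = None,
) -> MetaResult:
    """Combine two cohorts' signed Z statistics by sample-size weighting."""
    t = t or ThresholdConfig()
    if (res_a.gene_id, res_a.phecode, res_a.model) != (
        res_b.gene_id,
        res_b.phecode,
        res_b.model,
    ):
        raise ValueError("cohort results refer to different triples")
    if t.meta_weighting == "raw":
        w_a, w_b = math.sqrt(res_a.n_samples), math.sqrt(res_b.n_samples)
    else:
        w_a, w_b = math.sqrt(_effective_n(res_a)), math.sqrt(_effective_n(res_b))
    z_meta = (w_a * res_a.z + w_b * res_b.z) / math.sqrt(w_a**2 + w_b**2)
    p_meta = float(min(1.0, 2.0 * stats.norm.sf(abs(z_meta))))
    return MetaResult(
        gene_id=res_a.gene_id,
        phecode=res_a.phecode,
        model=res_a.model,
        z_meta=float(z_meta),
        p_meta=max(p_meta, 5e-324),
        weights=(w_a, w_b),
        carriers_per_cohort=(res_a.n_carriers, res_b.n_carriers),
        p_per_cohort=(res_a.p, res_b.p),
    )


def significance_gate(meta: MetaResult, t: Optional[ThresholdConfig] = None) -> bool:
    """Apply the three significance gates; records them on ``meta``.

    Gates: >=1 carrier in both cohorts; meta p strictly lower (better) than
    each cohort's own p; meta p below the Bonferroni cutoff.
    """
    t = t or ThresholdConfig()
    carriers_both = min(meta.carriers_per_cohort) >= 1
    meta_better = meta.p_meta < min(meta.p_per_cohort)
    bonferroni = meta.p_meta < t.bonferroni_alpha
    meta.gates = {
        "carriers_both": carriers_both,
        "meta_better_than_both": meta_better,
        "bonferroni": bonferroni,
    }
    meta.significant = carriers_both and meta_better and bonferroni
    return meta.significant


@dataclass
class ScreenDecision:
    """Dual-cohort PPV verdict for one significant triple."""

    gene_id: str
    phecode: str
    model: str
    # per cohort-stratum: "pass" | "fail" | "undefined"
    ppv_flags: dict[str, str]
    displayable: dict[str, bool]  # >= min_carrier_cases_display carrier cases
    manual_review: bool
    candidate: bool
    rationale: str


def _stratum_flag(ppv: Optional[float], t: ThresholdConfig) -> str:
    if ppv is None:
        return "undefined"
    return "pass" if ppv >= t.ppv_min else "fail"


def ppv_screen(
    meta: MetaResult,
    res_a: CohortAssocResult,
    res_b: CohortAssocResult,
    t: Optional[ThresholdConfig] = None,
) -> ScreenDecision:
    """Issue the screening verdict for one significant triple.

    Candidate iff PPV >= ``t.ppv_min`` in BOTH cohorts for the all-ages
    stratum or for the 60+ stratum, and the association is risk-increasing.
    Default stratum policy: a cohort whose 60+ stratum is undefined or has
    fewer than ``t.min_carrier_cases_display`` carrier cases is counted as
    passing the 60+ stratum when that same cohort's all-ages PPV clears the
    threshold; such triples are flagged for manual review. With
    ``strict_stratum_policy`` the 60+ stratum must pass on its own numbers.
    """
    t = t or ThresholdConfig()
    if not meta.significant:
        raise ValueError("ppv_screen expects a significant triple")

    flags = {
        "a_all": _stratum_flag(res_a.ppv_all_ages, t),
        "b_all": _stratum_flag(res_b.ppv_all_ages, t),
        "a_60": _stratum_flag(res_a.ppv_60plus, t),
        "b_60": _stratum_flag(res_b.ppv_60plus, t),
    }
    displayable = {
        "a_all": res_a.a >= t.min_carrier_cases_display,
        "b_all": res_b.a >= t.min_carrier_cases_display,
        "a_60": res_a.carrier_cases_60plus >= t.min_carrier_cases_display,
        "b_60": res_b.carrier_cases_60plus >= t.min_carrier_cases_display,
    }

    pass_all = flags["a_all"] == "pass" and flags["b_all"] == "pass"

    def _60_ok(key60: str, key_all: str, other60: str) -> tuple[bool, bool]:
        """(passes, needed_rescue) for one cohort's 60+ stratum."""
        if flags[key60] == "pass" and displayable[key60]:
            return True, False
        undersized = flags[key60] == "undefined" or not displayable[key60]
        if (
            not t.strict_stratum_policy
            and undersized
            and flags[other60] == "pass"
            and flags[key_all] == "pass"
        ):
            return True, True
        return (flags[key60] == "pass"), False

    a60, a_rescue = _60_ok("a_60", "a_all", "b_60")
    b60, b_rescue = _60_ok("b_60", "b_all", "a_60")
    pass_60 = a60 and b60
    manual_review = pass_60 and (a_rescue or b_rescue)

    risk_increasing = meta.z_meta > 0
    candidate = risk_increasing and (pass_all or pass_60)
    if not risk_increasing:
        rationale = "protective association excluded from PPV screening"
    elif pass_all and pass_60:
        rationale = "PPV threshold met in both cohorts for all-ages and 60+ strata"
    elif pass_all:
        rationale = "PPV threshold met in both cohorts for all-ages stratum"
    elif pass_60:
        rationale = "PPV threshold met in both cohorts for 60+ stratum" + (
            " (under-sized stratum backed by all-ages PPV; manual review)"
            if manual_review
            else ""
        )
    else:
        rationale = "PPV below threshold in at least one cohort in every stratum"
    return ScreenDecision(
        gene_id=meta.gene_id,
        phecode=meta.phecode,
        model=meta.model,
        ppv_flags=flags,
        displayable=displayable,
        manual_review=manual_review,
        candidate=candidate,
        rationale=rationale,
    )


def build_report(
    metas: list[MetaResult],
    decisions: list[ScreenDecision],
    results_a: dict[tuple[str, str, str], CohortAssocResult],
    results_b: dict[tuple[str, str, str], CohortAssocResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble (candidate table, full association table).

    The full table holds every meta-analyzed triple, sorted by candidacy,
    then meta p ascending. The candidate table keeps, per gene, the
    significant association with the best (highest) minimum-across-cohorts
    PPV, mirroring a per-gene headline reporting style.
    """
    dec_by_key = {(d.gene_id, d.phecode, d.model): d for d in decisions}
    rows = []
    for m in metas:
        key = (m.gene_id, m.phecode, m.model)
        ra, rb = results_a.get(key), results_b.get(key)
        d = dec_by_key.get(key)
        best_min_ppv = None
        if ra is not None and rb is not None:
            for pa, pb in (
                (ra.ppv_all_ages, rb.ppv_all_ages),
                (ra.ppv_60plus, rb.ppv_60plus),
            ):
                if pa is not None and pb is not None:
                    v = min(pa, pb)
                    if best_min_ppv is None or v > best_min_ppv:
                        best_min_ppv = v
        rows.append(
            {
                "gene": m.gene_id,
                "phecode": m.phecode,
                "model": m.model,
                "z_meta": m.z_meta,
                "p_meta": m.p_meta,
                "carriers_a": m.carriers_per_cohort[0],
                "carriers_b": m.carriers_per_cohort[1],
                "gate_carriers_both": m.gates.get("carriers_both"),
                "gate_meta_better": m.gates.get("meta_better_than_both"),
                "gate_bonferroni": m.gates.get("bonferroni"),
                "significant": m.significant,
                "min_ppv_best_stratum": best_min_ppv,
                "ppv_all_a": None if ra is None else ra.ppv_all_ages,
                "ppv_all_b": None if rb is None else rb.ppv_all_ages,
                "ppv_60_a": None if ra is None else ra.ppv_60plus,
                "ppv_60_b": None if rb is None else rb.ppv_60plus,
                "or_a": None if ra is None else ra.odds_ratio,
                "or_b": None if rb is None else rb.odds_ratio,
                "displayable_60_a": None if d is None else d.displayable["a_60"],
                "displayable_60_b": None if d is None else d.displayable["b_60"],
                "manual_review": False if d is None else d.manual_review,
                "candidate": False if d is None else d.candidate,
                "rationale": "" if d is None else d.rationale,
            }
        )
    full = pd.DataFrame(rows)
    if len(full):
        full = full.sort_values(
            ["candidate", "p_meta"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)

    cand_rows = full[full["candidate"] == True] if len(full) else full  # noqa: E712
    best = []
    if len(cand_rows):
        for gene, grp in cand_rows.groupby("gene", sort=True):
            grp = grp.sort_values(
                ["min_ppv_best_stratum", "p_meta"],
                ascending=[False, True],
                kind="mergesort",
            )
            best.append(grp.iloc[0])
    candidates = (
        pd.DataFrame(best).reset_index(drop=True)
        if best
        else full.iloc[0:0].reset_index(drop=True)
    )
    return candidates, full
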