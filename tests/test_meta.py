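"""Weighted-Z meta-analysis, significance gates, and the PPV screen."""

import math

import numpy as np
import pytest

from rarescreen.association import CohortAssocResult
from rarescreen.config import ThresholdConfig
from rarescreen.meta import (
    build_report,
    ppv_screen,
    significance_gate,
    weighted_z_meta,
)


def make_result(
    z=3.0,
    p=1e-3,
    n_cases=500,
    n_controls=9500,
    carriers=10,
    carrier_cases=6,
    ppv_all=0.6,
    ppv_60=0.6,
    cc60=6,
    gene="G1",
    phecode="P1",
    model="coding",
):
    a = carrier_cases
    b = carriers - carrier_cases
    c = n_cases - a
    d = n_controls - b
    return CohortAssocResult(
        gene_id=gene, phecode=phecode, model=model,
        n_samples=n_cases + n_controls,
        a=a, b=b, c=c, d=d,
        beta=np.sign(z) * 1.0, se=0.3, z=z, p=p,
        odds_ratio=math.exp(np.sign(z)),
        ppv_all_ages=ppv_all, ppv_60plus=ppv_60, carrier_cases_60plus=cc60,
    )


class TestWeightedZ:
    def test_equal_weights_closed_form(self):
        ra = make_result(z=3.0)
        rb = make_result(z=3.0)
        m = weighted_z_meta(ra, rb)
        assert m.z_meta == pytest.approx(3.0 * math.sqrt(2), abs=1e-12)

    def test_equal_weights_cancellation(self):
        m = weighted_z_meta(make_result(z=2.0), make_result(z=-2.0))
        assert m.z_meta == pytest.approx(0.0, abs=1e-12)
        assert m.p_meta == pytest.approx(1.0)

    def test_two_to_one_weights_hand_evaluation(self):
        # w_a = 2 w_b requires n_eff,a = 4 n_eff,b
        ra = make_result(z=4.0, n_cases=2000, n_controls=2000)   # n_eff 4000
        rb = make_result(z=0.0, n_cases=500, n_controls=500)     # n_eff 1000
        m = weighted_z_meta(ra, rb)
        assert m.weights[0] == pytest.approx(2 * m.weights[1], rel=1e-12)
        assert m.z_meta == pytest.approx(8 / math.sqrt(5), abs=1e-12)

    def test_effective_sample_size_formula(self):
        ra = make_result(n_cases=400, n_controls=19600)
        m = weighted_z_meta(ra, make_result())
        assert m.weights[0] == pytest.approx(
            math.sqrt(4 / (1 / 400 + 1 / 19600)), rel=1e-12
        )

    def test_zero_case_cohort_ineligible(self):
        ra = make_result(n_cases=0, n_controls=1000, carrier_cases=0)
        with pytest.raises(ValueError, match="zero cases"):
            weighted_z_meta(ra, make_result())

    def test_continuity_as_one_weight_vanishes(self):
        """z_meta -> z_a when cohort B's relative weight shrinks to ~1e-6.

        Effective-sample-size weights are bounded below (n_eff >= 2), so the
        vanishing-weight limit is exercised through raw-n weighting.
        """
        t = ThresholdConfig(meta_weighting="raw")
        ra = make_result(z=3.3, n_cases=10**12, n_controls=10**12)
        rb = make_result(z=-1.0, n_cases=1, n_controls=1)
        m = weighted_z_meta(ra, rb, t)
        assert m.weights[1] / m.weights[0] == pytest.approx(1e-6, rel=0.01)
        assert m.z_meta == pytest.approx(3.3, abs=1e-5)

    def test_raw_weighting_option(self):
        t = ThresholdConfig(meta_weighting="raw")
        ra = make_result(z=2.0, n_cases=100, n_controls=900)
        rb = make_result(z=2.0, n_cases=50, n_controls=950)
        m = weighted_z_meta(ra, rb, t)
        assert m.weights[0] == pytest.approx(math.sqrt(1000))


class TestSignificanceGate:
    def test_carrier_gate(self):
        m = weighted_z_meta(make_result(p=1e-20, carriers=10),
                            make_result(p=1e-20, carriers=0, carrier_cases=0))
        assert significance_gate(m) is False
        assert m.gates["carriers_both"] is False

    def test_meta_must_beat_both_cohorts(self):
        ra = make_result(z=7.0, p=1e-12)
        rb = make_result(z=0.5, p=0.6)
        m = weighted_z_meta(ra, rb)
        m.p_meta = 5e-10  # worse than cohort A's 1e-12
        assert significance_gate(m) is False
        assert m.gates["meta_better_than_both"] is False

    def test_all_gates_pass(self):
        ra = make_result(z=6.0, p=1e-8)
        rb = make_result(z=4.0, p=1e-4, carriers=3, carrier_cases=2)
        m = weighted_z_meta(ra, rb)
        m.p_meta = 1e-12
        assert significance_gate(m) is True

    def test_bonferroni_boundary_strict(self):
        m = weighted_z_meta(make_result(p=1e-4), make_result(p=1e-4))
        m.p_meta = 1e-9
        assert significance_gate(m) is False  # strict <


def significant_meta(ra, rb):
    m = weighted_z_meta(ra, rb)
    m.p_meta = 1e-15
    assert significance_gate(m)
    return m


class TestPpvScreen:
    def test_candidate_via_all_ages(self):
        ra = make_result(ppv_all=0.35, ppv_60=0.2)
        rb = make_result(ppv_all=0.32, ppv_60=0.2)
        d = ppv_screen(significant_meta(ra, rb), ra, rb)
        assert d.candidate is True
        assert "all-ages" in d.rationale

    def test_both_cohorts_required(self):
        ra = make_result(ppv_all=0.5, ppv_60=0.55)
        rb = make_result(ppv_all=0.2, ppv_60=0.2)
        d = ppv_screen(significant_meta(ra, rb), ra, rb)
        assert d.candidate is False

    def test_candidate_via_sixty_plus_despite_low_all_ages(self):
        ra = make_result(ppv_all=0.2, ppv_60=0.4)
        rb = make_result(ppv_all=0.22, ppv_60=0.31)
        d = ppv_screen(significant_meta(ra, rb), ra, rb)
        assert d.candidate is True
        assert "60+" in d.rationale

    def test_undersized_stratum_backed_by_all_ages(self):
        """One cohort's 60+ carrier cases all younger than 60: still passes
        when that cohort's all-ages PPV clears the threshold."""
        ra = make_result(ppv_all=0.5, ppv_60=0.45)
        rb = make_result(ppv_all=0.44, ppv_60=None, cc60=0)
        d = ppv_screen(significant_meta(ra, rb), ra, rb)
        assert d.candidate is True
        assert d.manual_review is True

    def test_strict_policy_blocks_undersized_stratum(self):
        t = ThresholdConfig(strict_stratum_policy=True)
        ra = make_result(ppv_all=0.2, ppv_60=0.45)
        rb = make_result(ppv_all=0.44, ppv_60=None, cc60=0)
        d = ppv_screen(significant_meta(ra, rb), ra, rb, t)
        assert d.candidate is False

    def test_protective_association_excluded(self):
        ra = make_result(z=-6.0, ppv_all=0.5)
        rb = make_result(z=-5.0, ppv_all=0.5)
        m = weighted_z_meta(ra, rb)
        m.p_meta = 1e-15
        significance_gate(m)
        d = ppv_screen(m, ra, rb)
        assert d.candidate is False
        assert "protective" in d.rationale

    def test_raising_threshold_never_adds_candidates(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            ppvs = rng.uniform(0, 1, size=4)
            ra = make_result(ppv_all=ppvs[0], ppv_60=ppvs[1])
            rb = make_result(ppv_all=ppvs[2], ppv_60=ppvs[3])
            m = significant_meta(ra, rb)
            low = ppv_screen(m, ra, rb, ThresholdConfig(ppv_min=0.3))
            high = ppv_screen(m, ra, rb, ThresholdConfig(ppv_min=0.5))
            assert low.candidate or not high.candidate


class TestBuildReport:
    def test_best_ppv_phecode_reported_per_gene(self):
        ra1 = make_result(phecode="P1", ppv_all=0.4, ppv_60=0.4)
        rb1 = make_result(phecode="P1", ppv_all=0.4, ppv_60=0.4)
        ra2 = make_result(phecode="P2", ppv_all=0.6, ppv_60=0.6)
        rb2 = make_result(phecode="P2", ppv_all=0.6, ppv_60=0.6)
        m1, m2 = significant_meta(ra1, rb1), significant_meta(ra2, rb2)
        d1 = ppv_screen(m1, ra1, rb1)
        d2 = ppv_screen(m2, ra2, rb2)
        candidates, full = build_report(
            [m1, m2], [d1, d2],
            {("G1", "P1", "coding"): ra1, ("G1", "P2", "coding"): ra2},
            {("G1", "P1", "coding"): rb1, ("G1", "P2", "coding"): rb2},
        )
        assert len(candidates) == 1
        assert candidates.iloc[0]["phecode"] == "P2"
        assert len(full) == 2

    def test_no_significant_triples_empty_candidates(self):
        ra = make_result(p=0.5, z=0.3)
        rb = make_result(p=0.5, z=0.3)
        m = weighted_z_meta(ra, rb)
        significance_gate(m)
        candidates, full = build_report(
            [m], [], {("G1", "P1", "coding"): ra}, {("G1", "P1", "coding"): rb}
        )
        assert len(candidates) == 0
        assert len(full) == 1 and not full.iloc[0]["candidate"]
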