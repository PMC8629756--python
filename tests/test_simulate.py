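"""Synthetic-data generator: determinism, degenerate probabilities,
binomial consistency, and the diagnosis round trip."""

import numpy as np
import pandas as pd
import pytest

from rarescreen.collapse import collapse_burden
from rarescreen.config import ThresholdConfig
from rarescreen.phenotype import map_diagnoses
from rarescreen.io import diagnoses_from_frame, variants_from_frame, cnvs_from_frame
from rarescreen.simulate import (
    SimConfig,
    SimTruth,
    build_fixture_phecode_map,
    default_truths,
    emit_icd_stream,
    generate_cohorts,
    sample_carrier_mask,
)


def small_config(seed=1, sizes=(1200, 500)):
    return SimConfig(seed=seed, cohort_sizes=sizes)


def small_truths(penetrance=0.7, background=0.02, carrier_freq=0.008):
    # carrier_freq at the top of the rare band so small cohorts have carriers
    return [
        SimTruth("CAUSAL_00", True, carrier_freq, penetrance, "200.1", background),
        SimTruth("NULL_00", False, carrier_freq, background, "200.1", background),
    ]


class TestDeterminism:
    def test_same_seed_identical_serialized_output(self):
        frames = []
        for _ in range(2):
            cohorts, _, _ = generate_cohorts(small_config(), small_truths())
            frames.append(cohorts)
        for name in frames[0]:
            for attr in ("samples", "variants", "cnvs", "diagnoses"):
                a = getattr(frames[0][name], attr)
                b = getattr(frames[1][name], attr)
                assert a.to_csv() == b.to_csv()

    def test_different_seed_differs(self):
        c1, _, _ = generate_cohorts(small_config(seed=1), small_truths())
        c2, _, _ = generate_cohorts(small_config(seed=2), small_truths())
        name = list(c1)[0]
        assert c1[name].diagnoses.to_csv() != c2[name].diagnoses.to_csv()

    def test_appending_genes_preserves_earlier_draws(self):
        t2 = small_truths()
        t3 = t2 + [SimTruth("NULL_01", False, 0.004, 0.02, "200.1", 0.02)]
        c2, _, tt2 = generate_cohorts(small_config(), t2)
        c3, _, tt3 = generate_cohorts(small_config(), t3)
        name = list(c2)[0]
        for g in ("CAUSAL_00", "NULL_00"):
            assert (
                tt2[name][f"carrier_{g}"] == tt3[name][f"carrier_{g}"]
            ).all()


class TestDegenerateProbabilities:
    def test_full_penetrance_zero_background(self):
        truths = [SimTruth("CAUSAL_00", True, 0.01, 1.0, "200.1", 0.0)]
        cfg = small_config()
        cohorts, pmap, tt = generate_cohorts(cfg, truths)
        for name, data in cohorts.items():
            carriers = tt[name]["carrier_CAUSAL_00"].astype(bool)
            cases = tt[name]["case_200.1"].astype(bool)
            assert (carriers == cases).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            SimTruth("G", True, 0.005, 1.5, "200.1", 0.0)
        with pytest.raises(ValueError):
            SimTruth("G", True, 0.05, 0.5, "200.1", 0.0)  # not rare
        with pytest.raises(ValueError):
            SimConfig(cohort_sizes=(0, 10))
        with pytest.raises(ValueError):
            SimConfig(cohort_sizes=(500, 500))  # cohorts must differ


def test_carrier_counts_binomially_consistent():
    """Mean observed carrier count over replicates near n*f (3 SE band)."""
    n, freq, reps = 20000, 0.004, 200
    counts = [
        sample_carrier_mask(np.random.default_rng([s, 0]), n, freq).sum()
        for s in range(reps)
    ]
    expected = n * freq
    se_mean = np.sqrt(n * freq * (1 - freq) / reps)
    assert abs(np.mean(counts) - expected) <= 3 * se_mean


def test_carrier_frequency_ci_coverage():
    """95% binomial CI around observed count covers the true frequency in
    at least 90% of seeds."""
    from scipy.stats import binom

    n, freq, reps = 5000, 0.004, 120
    hits = 0
    for s in range(reps):
        k = sample_carrier_mask(np.random.default_rng([s, 1]), n, freq).sum()
        lo, hi = binom.ppf(0.025, n, freq), binom.ppf(0.975, n, freq)
        hits += lo <= k <= hi
    assert hits / reps >= 0.90


class TestIcdStream:
    def test_round_trip_single_phecode(self):
        pmap = build_fixture_phecode_map(["250.2"])
        rng = np.random.default_rng(0)
        events = emit_icd_stream(
            rng, ["250.2"], pmap, ("icd9", "icd10"),
            pd.Timestamp("2010-01-01"), pd.Timestamp("2023-01-01"), True,
        )
        mapped = {
            p
            for code, system, _ in events
            for p in pmap.lookup(system, code)
        }
        assert mapped == {"250.2"}

    def test_empty_truth_stream_has_no_target_codes(self):
        pmap = build_fixture_phecode_map(["250.2"])
        rng = np.random.default_rng(0)
        events = emit_icd_stream(
            rng, [], pmap, ("icd9",),
            pd.Timestamp("2010-01-01"), pd.Timestamp("2023-01-01"), True,
        )
        assert all(not pmap.lookup(s, c) for c, s, _ in events)

    def test_missing_phecode_in_map_fatal(self):
        pmap = build_fixture_phecode_map(["250.2"])
        rng = np.random.default_rng(0)
        with pytest.raises(KeyError, match="999.9"):
            emit_icd_stream(
                rng, ["999.9"], pmap, ("icd9",),
                pd.Timestamp("2010-01-01"), pd.Timestamp("2023-01-01"), True,
            )


class TestRoundTrip:
    def test_phenotype_module_recovers_truth_cases_exactly(self):
        """Mapping the emitted streams back through the fixture map gives
        precisely the simulated case labels."""
        cfg = small_config()
        cohorts, pmap, tt = generate_cohorts(cfg, small_truths())
        for name, data in cohorts.items():
            events = diagnoses_from_frame(data.diagnoses)
            samples = list(data.samples["sample_id"])
            m = map_diagnoses(events, pmap, samples,
                              phecodes=sorted(pmap.phecodes()))
            truth = tt[name].set_index("sample_id")
            got = m.entries["200.1"]
            want = truth["case_200.1"]
            assert (got.to_numpy() == want.to_numpy()).all()

    def test_collapse_recovers_truth_carriers(self):
        """Burden matrix under the coding model equals the simulated carrier
        mask: decoys never qualify, qualifying events always do."""
        cfg = small_config()
        cohorts, pmap, tt = generate_cohorts(cfg, small_truths())
        t = ThresholdConfig()
        for name, data in cohorts.items():
            variants, genes = variants_from_frame(data.variants)
            cnvs = cnvs_from_frame(data.cnvs) if len(data.cnvs) else []
            samples = list(data.samples["sample_id"])
            bm = collapse_burden(variants, cnvs, samples, sorted(set(genes)), "coding", t)
            truth = tt[name].set_index("sample_id")
            for g in ("CAUSAL_00", "NULL_00"):
                got = bm.entries[g].to_numpy()
                want = truth[f"carrier_{g}"].to_numpy()
                assert (got == want).all()


def test_default_truths_structure():
    truths = default_truths()
    causal = [t for t in truths if t.is_causal]
    assert len(causal) == 5 and len(truths) == 55
    assert all(t.penetrance >= 0.4 for t in causal)
    assert all(0.001 <= t.carrier_freq <= 0.004 for t in causal)
    assert len({t.target_phecode for t in causal}) == 5
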