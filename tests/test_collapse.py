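"""Qualification rules and gene-based collapsing.

The brute-force oracle re-evaluates the qualification rule text clause by
clause with independent code, so the burden matrix can be checked against a
second reading of the same rules.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarescreen.collapse import (
    AnnotatedVariant,
    CnvEvent,
    collapse_burden,
    qualify_cnv,
    qualify_variant,
)
from rarescreen.config import (
    CODING_CONSEQUENCES,
    LOF_CONSEQUENCES,
    CONSEQUENCE_VOCABULARY,
    ThresholdConfig,
)


def make_variant(**kw):
    base = dict(
        variant_id="1:100:A:T",
        gene_id="GENE_A",
        consequence="missense_variant",
        polyphen_score=0.9,
        sift_score=0.01,
        gnomad_afs={"afr": 0.0001, "nfe": 0.0001},
        local_af=0.0001,
        carriers=frozenset({"s1"}),
    )
    base.update(kw)
    return AnnotatedVariant(**base)


class TestQualifyVariant:
    @pytest.mark.parametrize(
        "kw,coding_ok,lof_ok",
        [
            # damaging missense: coding only
            (dict(), True, False),
            # LoF with no scores qualifies under both (missing scores not benign)
            (dict(consequence="stop_gained", polyphen_score=None, sift_score=None,
                  gnomad_afs={"afr": 0.0002}, local_af=0.0002), True, True),
            # one gnomAD population too common -> excluded everywhere
            (dict(gnomad_afs={"afr": 0.002, "nfe": 0.0001}), False, False),
            # PolyPhen-benign missense excluded from coding
            (dict(polyphen_score=0.10), False, False),
            # PolyPhen exactly at 0.15 is NOT benign (benign is < 0.15)
            (dict(polyphen_score=0.15, sift_score=0.01), True, False),
            # SIFT exactly at 0.05 is NOT benign (benign is > 0.05)
            (dict(sift_score=0.05), True, False),
            # SIFT just above threshold is benign
            (dict(sift_score=0.051), False, False),
            # local AF exactly at 0.1% fails the strict < rule
            (dict(local_af=0.001), False, False),
            (dict(local_af=0.000999), True, False),
            # synonymous never qualifies
            (dict(consequence="synonymous_variant", polyphen_score=None,
                  sift_score=None), False, False),
        ],
    )
    def test_rule_clauses(self, kw, coding_ok, lof_ok, thresholds):
        v = make_variant(**kw)
        assert qualify_variant(v, "coding", thresholds) is coding_ok
        assert qualify_variant(v, "lof", thresholds) is lof_ok

    def test_lof_set_is_subset_of_coding_set(self):
        assert LOF_CONSEQUENCES < CODING_CONSEQUENCES

    def test_unknown_consequence_rejected(self):
        with pytest.raises(ValueError, match="unknown consequence"):
            make_variant(consequence="upstream_gene_variant")

    def test_malformed_frequency_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            make_variant(local_af=1.5)

    def test_both_benign_rule_is_laxer(self):
        t_or = ThresholdConfig(benign_rule="either")
        t_and = ThresholdConfig(benign_rule="both")
        v = make_variant(polyphen_score=0.05, sift_score=0.01)  # PolyPhen-only benign
        assert not qualify_variant(v, "coding", t_or)
        assert qualify_variant(v, "coding", t_and)


class TestQualifyCnv:
    def make(self, **kw):
        base = dict(
            sample_id="s1",
            gene_id="GENE_B",
            cnv_type="deletion",
            n_exons_overlapped=3,
            qc_pass=True,
            exon_freq=0.0004,
            event_freq=0.0004,
        )
        base.update(kw)
        return CnvEvent(**base)

    @pytest.mark.parametrize(
        "kw,coding_ok,lof_ok",
        [
            (dict(), True, True),
            (dict(cnv_type="duplication"), True, False),
            (dict(event_freq=0.005), False, False),
            (dict(exon_freq=0.001), False, False),  # boundary: < is strict
            (dict(qc_pass=False), False, False),
            (dict(n_exons_overlapped=0), True, False),
        ],
    )
    def test_rule_clauses(self, kw, coding_ok, lof_ok, thresholds):
        c = self.make(**kw)
        assert qualify_cnv(c, "coding", thresholds) is coding_ok
        assert qualify_cnv(c, "lof", thresholds) is lof_ok

    def test_negative_exon_count_rejected(self):
        with pytest.raises(ValueError):
            self.make(n_exons_overlapped=-1)


class TestCollapseBurden:
    def test_examples(self, thresholds):
        samples = ["s1", "s2", "s3"]
        variants = [
            make_variant(carriers=frozenset({"s1"})),  # qualifying missense
            make_variant(
                variant_id="1:200:G:C",
                consequence="synonymous_variant",
                polyphen_score=None,
                sift_score=None,
                carriers=frozenset({"s2"}),
            ),
        ]
        cnvs = [
            CnvEvent("s3", "GENE_B", "deletion", 1, True, 0.0004, 0.0004),
        ]
        coding = collapse_burden(variants, cnvs, samples, ["GENE_A", "GENE_B"], "coding", thresholds)
        lof = collapse_burden(variants, cnvs, samples, ["GENE_A", "GENE_B"], "lof", thresholds)
        assert coding.entries.loc["s1", "GENE_A"] == 1
        assert lof.entries.loc["s1", "GENE_A"] == 0
        assert coding.entries.loc["s2", "GENE_A"] == 0
        assert lof.entries.loc["s2", "GENE_A"] == 0
        assert lof.entries.loc["s3", "GENE_B"] == 1
        assert int(lof.carrier_counts["GENE_B"]) == 1

    def test_zero_carrier_gene_column_retained(self, thresholds):
        bm = collapse_burden([], [], ["s1"], ["EMPTY_GENE"], "coding", thresholds)
        assert list(bm.entries.columns) == ["EMPTY_GENE"]
        assert int(bm.carrier_counts["EMPTY_GENE"]) == 0

    def test_unknown_carrier_fatal(self, thresholds):
        v = make_variant(carriers=frozenset({"ghost"}))
        with pytest.raises(KeyError, match="ghost"):
            collapse_burden([v], [], ["s1"], ["GENE_A"], "coding", thresholds)


# ---- randomized instances against an independently-written oracle ----

CONSEQ = sorted(CONSEQUENCE_VOCABULARY)
POPS = ("afr", "amr", "nfe")


@st.composite
def variant_strategy(draw, n_samples=12, n_genes=3):
    conseq = draw(st.sampled_from(CONSEQ))
    scored = conseq == "missense_variant" and draw(st.booleans())
    carriers = draw(
        st.sets(st.sampled_from([f"s{i}" for i in range(n_samples)]), min_size=1, max_size=4)
    )
    return AnnotatedVariant(
        variant_id=f"1:{draw(st.integers(1, 10**6))}:A:T",
        gene_id=f"G{draw(st.integers(0, n_genes - 1))}",
        consequence=conseq,
        polyphen_score=draw(st.floats(0, 1)) if scored else None,
        sift_score=draw(st.floats(0, 1)) if scored else None,
        gnomad_afs={p: draw(st.floats(0, 0.01)) for p in POPS},
        local_af=draw(st.floats(0, 0.01)),
        carriers=frozenset(carriers),
    )


def oracle_qualifies(v, model, t):
    """Independent clause-by-clause reading of the qualification rules."""
    lof_terms = {"stop_lost", "start_lost", "splice_donor_variant",
                 "frameshift_variant", "splice_acceptor_variant", "stop_gained"}
    coding_terms = lof_terms | {"missense_variant", "inframe_deletion", "inframe_insertion"}
    in_set = v.consequence in (lof_terms if model == "lof" else coding_terms)
    pp_benign = v.polyphen_score is not None and v.polyphen_score < 0.15
    sift_benign = v.sift_score is not None and v.sift_score > 0.05
    benign = pp_benign or sift_benign
    rare = all(af < 0.001 for af in v.gnomad_afs.values()) and v.local_af < 0.001
    return in_set and not benign and rare


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(variant_strategy(), min_size=1, max_size=50), st.sampled_from(["coding", "lof"]))
def test_carrier_sets_match_bruteforce_oracle(variants, model):
    t = ThresholdConfig()
    samples = [f"s{i}" for i in range(12)]
    genes = ["G0", "G1", "G2"]
    bm = collapse_burden(variants, [], samples, genes, model, t)
    for g in genes:
        expected = set()
        for v in variants:
            if v.gene_id == g and oracle_qualifies(v, model, t):
                expected |= v.carriers
        assert bm.carriers_of(g) == frozenset(expected)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(variant_strategy(), min_size=1, max_size=30))
def test_tightening_maf_never_increases_carriers(variants):
    samples = [f"s{i}" for i in range(12)]
    genes = ["G0", "G1", "G2"]
    loose = collapse_burden(variants, [], samples, genes, "coding", ThresholdConfig(maf_max=0.001))
    tight = collapse_burden(variants, [], samples, genes, "coding", ThresholdConfig(maf_max=0.0005))
    assert (tight.carrier_counts <= loose.carrier_counts).all()


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(variant_strategy(), min_size=1, max_size=30))
def test_lof_carriers_subset_of_coding(variants):
    t = ThresholdConfig()
    samples = [f"s{i}" for i in range(12)]
    genes = ["G0", "G1", "G2"]
    coding = collapse_burden(variants, [], samples, genes, "coding", t)
    lof = collapse_burden(variants, [], samples, genes, "lof", t)
    assert np.all(lof.entries.to_numpy() <= coding.entries.to_numpy())
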