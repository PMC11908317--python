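"""Variant predicate algebra and genotype classifier behavior."""

import pytest
from hypothesis import given, settings, strategies as st

from phenogpc import (
    BiallelicMode,
    Sex,
    VariantRecord,
    allele_count_classifier,
    biallelic_classifier,
    change_length_cmp,
    diagnosis_classifier,
    effect_is,
    exon_overlaps,
    is_structural_deletion,
    key_equals,
    monoallelic_classifier,
    protein_region_overlaps,
    ref_length_cmp,
    sex_classifier,
    structural_type_is,
)
from phenogpc.variants import PredicateError, VariantPredicate

from conftest import make_individual, missense_het, stopgain_het


def variant(**kw):
    base = dict(key="v", effects=frozenset(), allele_count_in_individual=1)
    base.update(kw)
    return VariantRecord(**base)


# strategy for random variants exercising every leaf attribute
variants_strategy = st.builds(
    variant,
    effects=st.frozensets(
        st.sampled_from(["missense_variant", "stop_gained", "frameshift_variant"]), max_size=2
    ),
    exons=st.frozensets(st.integers(min_value=1, max_value=10), max_size=3),
    protein_range=st.one_of(
        st.none(),
        st.tuples(st.integers(1, 50), st.integers(1, 50)).map(lambda t: (min(t), max(t))),
    ),
    structural_type=st.sampled_from([None, "DEL", "DUP"]),
    change_length=st.one_of(st.none(), st.integers(-100, 100)),
)

predicates_strategy = st.sampled_from(
    [
        effect_is("missense_variant"),
        effect_is("stop_gained"),
        exon_overlaps(3),
        protein_region_overlaps(10, 20),
        structural_type_is("DEL"),
        change_length_cmp("<=", -50),
        is_structural_deletion(50),
    ]
)


class TestPredicates:
    def test_point_mutation_composite(self):
        point = (
            effect_is("missense_variant")
            & ref_length_cmp("==", 1)
            & change_length_cmp("==", 0)
        )
        snv = variant(effects=frozenset({"missense_variant"}), ref="A", alt="G", pos=5, contig="1")
        indel = variant(effects=frozenset({"missense_variant"}), ref="AT", alt="G", pos=5, contig="1")
        assert point(snv)
        assert not point(indel)

    def test_structural_deletion_fifty_bp_threshold(self):
        sv = is_structural_deletion(50)
        imprecise = variant(structural_type="DEL")
        big_del = variant(ref="A" * 61, alt="A", pos=1, contig="1")
        small_del = variant(ref="ATTT", alt="A", pos=1, contig="1")
        assert sv(imprecise)
        assert sv(big_del)  # change length -60
        assert not sv(small_del)  # -3 bp

    def test_missing_attribute_leaf_is_false_not_error(self):
        no_protein = variant(protein_range=None)
        assert protein_region_overlaps(1, 10)(no_protein) is False
        assert exon_overlaps(2)(variant()) is False

    def test_region_overlap_is_closed_interval(self):
        p = protein_region_overlaps(10, 20)
        assert p(variant(protein_range=(20, 25)))  # touches at 20
        assert p(variant(protein_range=(1, 10)))
        assert not p(variant(protein_range=(21, 30)))

    def test_key_and_structural_type_leaves(self):
        assert key_equals("v")(variant())
        assert structural_type_is("DUP")(variant(structural_type="DUP"))

    def test_malformed_trees_fail_at_construction(self):
        with pytest.raises(PredicateError):
            protein_region_overlaps(5, 2)
        with pytest.raises(PredicateError):
            change_length_cmp("~", 3)
        with pytest.raises(PredicateError):
            VariantPredicate.from_dict({"kind": "NOT", "children": []})
        with pytest.raises(PredicateError):
            VariantPredicate.from_dict({"kind": "NO_SUCH_LEAF"})

    def test_json_round_trip(self):
        pred = (effect_is("missense_variant") | is_structural_deletion(50)) & ~exon_overlaps(2)
        again = VariantPredicate.from_dict(pred.to_dict())
        for _ in range(3):
            v = variant(effects=frozenset({"missense_variant"}), exons=frozenset({2}))
            assert pred(v) == again(v)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(p=predicates_strategy, q=predicates_strategy, v=variants_strategy)
    def test_boolean_laws(self, p, q, v):
        assert (~p)(v) == (not p(v))
        # De Morgan
        assert (~(p & q))(v) == ((~p) | (~q))(v)
        assert (~(p | q))(v) == ((~p) & (~q))(v)


MISSENSE = effect_is("missense_variant")
STOP = effect_is("stop_gained")


def het(effects, count=1, key="v"):
    return variant(key=key, effects=frozenset(effects), allele_count_in_individual=count)


class TestMonoallelic:
    def test_het_missense_goes_to_class_a(self):
        clf = monoallelic_classifier(MISSENSE, STOP)
        ind = make_individual(variants=[het({"missense_variant"})])
        assert clf.assign(ind).label == "A"

    def test_homozygous_missense_omitted(self):
        clf = monoallelic_classifier(MISSENSE, STOP)
        ind = make_individual(variants=[het({"missense_variant"}, count=2)])
        assert clf.assign(ind) is None

    def test_matching_neither_predicate_omitted(self):
        clf = monoallelic_classifier(MISSENSE, STOP)
        ind = make_individual(variants=[het({"frameshift_variant"})])
        assert clf.assign(ind) is None

    def test_allele_matching_both_predicates_omitted(self):
        clf = monoallelic_classifier(MISSENSE, effect_is("missense_variant"))
        ind = make_individual(variants=[het({"missense_variant"})])
        assert clf.assign(ind) is None

    def test_default_b_is_complement(self):
        clf = monoallelic_classifier(MISSENSE)
        assert clf.assign(make_individual(variants=[het({"stop_gained"})])).label == "B"


class TestBiallelic:
    def test_compound_het_three_way_is_ab(self):
        clf = biallelic_classifier(STOP, mode=BiallelicMode.THREE_WAY)
        ind = make_individual(
            variants=[het({"stop_gained"}, key="v1"), het({"missense_variant"}, key="v2")]
        )
        assert clf.assign(ind).label == "AB"

    def test_homozygous_a_is_aa(self):
        clf = biallelic_classifier(STOP)
        ind = make_individual(variants=[het({"stop_gained"}, count=2)])
        assert clf.assign(ind).label == "AA"

    def test_monoallelic_individual_omitted(self):
        clf = biallelic_classifier(STOP)
        assert clf.assign(make_individual(variants=[het({"stop_gained"})])) is None

    @pytest.mark.parametrize(
        "mode,a_count,expected",
        [
            (BiallelicMode.AA_AB_VS_BB, 2, "AA+AB"),
            (BiallelicMode.AA_AB_VS_BB, 1, "AA+AB"),
            (BiallelicMode.AA_AB_VS_BB, 0, "BB"),
            (BiallelicMode.AA_VS_AB_BB, 2, "AA"),
            (BiallelicMode.AA_VS_AB_BB, 1, "AB+BB"),
            (BiallelicMode.AA_VS_AB_BB, 0, "AB+BB"),
        ],
    )
    def test_two_way_modes_coarsen_three_way(self, mode, a_count, expected):
        clf = biallelic_classifier(STOP, mode=mode)
        if a_count == 2:
            vs = [het({"stop_gained"}, count=2)]
        elif a_count == 1:
            vs = [het({"stop_gained"}, key="v1"), het({"missense_variant"}, key="v2")]
        else:
            vs = [het({"missense_variant"}, count=2)]
        assert clf.assign(make_individual(variants=vs)).label == expected

    def test_two_way_merge_preserves_counts(self):
        individuals = [
            make_individual(iid="aa", variants=[het({"stop_gained"}, count=2)]),
            make_individual(
                iid="ab", variants=[het({"stop_gained"}, key="v1"), het({"missense_variant"}, key="v2")]
            ),
            make_individual(iid="bb", variants=[het({"missense_variant"}, count=2)]),
        ]
        three, _ = biallelic_classifier(STOP).partition(individuals)
        merged, _ = biallelic_classifier(STOP, mode=BiallelicMode.AA_AB_VS_BB).partition(individuals)
        three_counts = {c.label: len(v) for c, v in three.items()}
        merged_counts = {c.label: len(v) for c, v in merged.items()}
        assert merged_counts["AA+AB"] == three_counts["AA"] + three_counts["AB"]
        assert merged_counts["BB"] == three_counts["BB"]


class TestOtherClassifiers:
    def test_allele_count_one_vs_two(self):
        clf = allele_count_classifier(MISSENSE)
        one = make_individual(iid="x", variants=[het({"missense_variant"})])
        two = make_individual(iid="y", variants=[het({"missense_variant"}, count=2)])
        assert clf.assign(one).label == "monoallelic"
        assert clf.assign(two).label == "biallelic"

    def test_sex_unknown_omitted(self):
        clf = sex_classifier()
        assert clf.assign(make_individual(sex=Sex.MALE)).label == "MALE"
        assert clf.assign(make_individual(sex=Sex.UNKNOWN)) is None

    def test_diagnosis_both_or_neither_omitted(self):
        clf = diagnosis_classifier("OMIM:147920", "OMIM:300867")
        a = make_individual(iid="a", diseases=[("OMIM:147920", None)])
        both = make_individual(iid="b", diseases=[("OMIM:147920", None), ("OMIM:300867", None)])
        neither = make_individual(iid="c")
        assert clf.assign(a).label == "OMIM:147920"
        assert clf.assign(both) is None
        assert clf.assign(neither) is None

    def test_partition_is_disjoint_and_covers(self):
        clf = monoallelic_classifier(MISSENSE, STOP)
        inds = [
            make_individual(iid=f"P{i}", variants=[v])
            for i, v in enumerate(
                [het({"missense_variant"}), het({"stop_gained"}), het({"frameshift_variant"})]
            )
        ] + [make_individual(iid="P9")]
        by_class, omitted = clf.partition(inds)
        assigned = [i for members in by_class.values() for i in members]
        assert len(assigned) + len(omitted) == len(inds)
        assert {i.id for i in assigned} | {i.id for i in omitted} == {i.id for i in inds}
        assert not ({i.id for i in assigned} & {i.id for i in omitted})
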