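import pytest

from phenogpc import (
    AgeDuration,
    Individual,
    MeasurementValue,
    ObservationStatus,
    OntologyGraph,
    PhenotypeObservation,
    Sex,
    TermId,
    VariantRecord,
    build_cohort,
    make_toy_ontology,
)


@pytest.fixture(scope="session")
def chain_graph() -> OntologyGraph:
    """Three-term is_a chain: TOY:3 -> TOY:2 -> TOY:1 (root)."""
    return OntologyGraph(
        terms={"TOY:1": "root", "TOY:2": "mid", "TOY:3": "leaf"},
        edges=[("TOY:3", "TOY:2"), ("TOY:2", "TOY:1")],
        root="TOY:1",
    )


@pytest.fixture(scope="session")
def diamond_graph() -> OntologyGraph:
    """Diamond: D below B and C, both below A (root)."""
    return OntologyGraph(
        terms={f"TOY:{i}": l for i, l in enumerate("ABCD", start=1)},
        edges=[("TOY:4", "TOY:2"), ("TOY:4", "TOY:3"), ("TOY:2", "TOY:1"), ("TOY:3", "TOY:1")],
        root="TOY:1",
    )


@pytest.fixture(scope="session")
def toy_graph() -> OntologyGraph:
    """Depth-4, branching-3 toy tree: 1 + 3 + 9 + 27 = 40 terms."""
    return make_toy_ontology(depth=4, branching=3, seed=11)


def make_individual(
    iid="P1",
    sex=Sex.UNKNOWN,
    observed=(),
    excluded=(),
    variants=(),
    diseases=(),
    measurements=(),
    **kwargs,
):
    """Terse builder for test individuals."""
    phenos = kwargs.pop("phenotypes", None)
    if phenos is None:
        phenos = [
            PhenotypeObservation(term=TermId(t), status=ObservationStatus.OBSERVED)
            for t in observed
        ] + [
            PhenotypeObservation(term=TermId(t), status=ObservationStatus.EXCLUDED)
            for t in excluded
        ]
    return Individual(
        id=iid,
        sex=sex,
        phenotypes=tuple(phenos),
        variants=tuple(variants),
        diseases=tuple(diseases),
        measurements=tuple(measurements),
        **kwargs,
    )


def missense_het(key="v-mis"):
    return VariantRecord(
        key=key, effects=frozenset({"missense_variant"}), contig="1", pos=100,
        ref="A", alt="G", allele_count_in_individual=1,
    )


def stopgain_het(key="v-stop"):
    return VariantRecord(
        key=key, effects=frozenset({"stop_gained"}), contig="1", pos=200,
        ref="C", alt="T", allele_count_in_individual=1,
    )
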