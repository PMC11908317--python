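"""Seeded generators for toy ontologies and cohorts with planted effects.

These generators make every part of the pipeline testable without any
download: a toy phenotype ontology (a rooted tree, optionally with diamond
edges so some terms have two parents) and a cohort of individuals whose
phenopacket-subset records carry class-conditional variants, Bernoulli
observed/excluded annotations at leaf terms, exponential onset ages with
right censoring, and normal measurements.  Effects are *planted* by giving
the two genotype classes different term frequencies, onset rates, or
measurement means; the ground-truth ledger records what was planted.

Annotations are planted at leaf terms only, so internal-node counts arise
purely through true-path-rule propagation — which naturally exercises the
parent-equals-child filtering rule.  Each individual draws from its own
random stream derived from ``(seed, index)``, making cohorts reproducible
under any generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .cohort import (
    AgeDuration,
    Cohort,
    Individual,
    MeasurementValue,
    PhenotypeObservation,
    Sex,
    VariantRecord,
    VitalStatus,
    build_cohort,
)
from .ontology import ObservationStatus, OntologyGraph, TermId

__all__ = [
    "make_toy_ontology",
    "SimulationParams",
    "PlantedEffect",
    "simulate_cohort",
]


def make_toy_ontology(
    depth: int,
    branching: int,
    seed: int = 0,
    diamond_fraction: float = 0.0,
) -> OntologyGraph:
    """Deterministic toy phenotype ontology.

    A rooted tree with ``depth`` levels (root included) and ``branching``
    children per node; with ``diamond_fraction`` > 0 that share of
    non-root, non-level-1 terms gains a second parent picked uniformly from
    the level above, yielding diamond motifs.  Term ids are ``TOY:n`` in
    breadth-first order with the root ``TOY:1`` standing in for the
    phenotypic-abnormality subroot.
    """
    if depth < 2 or branching < 1:
        raise ValueError("depth must be >= 2 and branching >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, str] = {"TOY:1": "Phenotypic abnormality (synthetic)"}
    edges: list[tuple[str, str]] = []
    levels: list[list[str]] = [["TOY:1"]]
    next_id = 2
    for level in range(1, depth):
        current: list[str] = []
        for parent in levels[level - 1]:
            for _ in range(branching):
                tid = f"TOY:{next_id}"
                next_id += 1
                terms[tid] = f"synthetic term {tid} (level {level})"
                edges.append((tid, parent))
                current.append(tid)
        levels.append(current)
    if diamond_fraction > 0:
        for level in range(2, depth):
            for tid in levels[level]:
                if rng.random() < diamond_fraction and len(levels[level - 1]) > 1:
                    (existing_parent,) = [p for c, p in edges if c == tid]
                    candidates = [p for p in levels[level - 1] if p != existing_parent]
                    edges.append((tid, str(rng.choice(candidates))))
    return OntologyGraph(terms, edges, "TOY:1")


@dataclass(frozen=True)
class PlantedEffect:
    """Class-conditional Bernoulli frequency of one (leaf) term."""

    term: str
    freq_a: float
    freq_b: float

    def __post_init__(self) -> None:
        for f in (self.freq_a, self.freq_b):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency out of [0, 1]: {f}")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for a simulated two-class cohort.

    Defaults emulate a mid-sized published rare-disease cohort: 50
    individuals per genotype class (class A carries a heterozygous missense
    variant, class B a heterozygous stop-gained variant), terms assayed
    with probability ``coverage`` and observed with the class-conditional
    frequency (excluded otherwise).  Optional onset model: exponential
    onset ages (mean ``1/rate`` years) for one endpoint term with a share
    of individuals right-censored at their last encounter; optional
    measurement model: normal with class-specific means.  The seed is
    mandatory — identical parameters and seed give byte-identical cohorts.
    """

    seed: int
    n_a: int = 50
    n_b: int = 50
    effects: tuple[PlantedEffect, ...] = ()
    coverage: float = 1.0
    onset_term: Optional[str] = None
    onset_rate_a: float = 0.2  # events per year
    onset_rate_b: float = 0.2
    censor_fraction: float = 0.0
    measurement_code: Optional[str] = None
    measurement_mean_a: float = 0.0
    measurement_mean_b: float = 0.0
    measurement_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("class sizes must be >= 1")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must be in [0, 1]")
        if not (0.0 <= self.censor_fraction <= 1.0):
            raise ValueError("censor_fraction must be in [0, 1]")


def _days(years: float) -> AgeDuration:
    d = max(1, int(round(years * 365.25)))
    return AgeDuration(iso8601=f"P{d}D", days=float(d))


def _simulate_individual(
    idx: int,
    in_class_a: bool,
    graph: OntologyGraph,
    params: SimulationParams,
) -> Individual:
    rng = np.random.default_rng([params.seed, idx])
    variant = VariantRecord(
        key="var-missense-A" if in_class_a else "var-stopgain-B",
        effects=frozenset(["missense_variant"] if in_class_a else ["stop_gained"]),
        contig="1",
        pos=1000 + (0 if in_class_a else 60),
        ref="C",
        alt="T",
        allele_count_in_individual=1,
    )
    phenotypes: list[PhenotypeObservation] = []
    for eff in params.effects:
        if rng.random() >= params.coverage:
            continue  # not assayed
        freq = eff.freq_a if in_class_a else eff.freq_b
        observed = rng.random() < freq
        phenotypes.append(
            PhenotypeObservation(
                term=graph.primary(eff.term),
                status=ObservationStatus.OBSERVED if observed else ObservationStatus.EXCLUDED,
            )
        )
    last_encounter_years = 10.0 + 40.0 * rng.random()
    if params.onset_term is not None:
        rate = params.onset_rate_a if in_class_a else params.onset_rate_b
        onset_years = rng.exponential(1.0 / rate)
        censored = rng.random() < params.censor_fraction
        if censored:
            last_encounter_years = min(last_encounter_years, max(onset_years * rng.random(), 0.1))
        elif onset_years < last_encounter_years:
            phenotypes.append(
                PhenotypeObservation(
                    term=graph.primary(params.onset_term),
                    status=ObservationStatus.OBSERVED,
                    onset=_days(onset_years),
                )
            )
    measurements: list[MeasurementValue] = []
    if params.measurement_code is not None:
        mean = params.measurement_mean_a if in_class_a else params.measurement_mean_b
        measurements.append(
            MeasurementValue(
                assay=params.measurement_code,
                value=float(rng.normal(mean, params.measurement_sd)),
                unit="1",
            )
        )
    return Individual(
        id=f"sim-{idx:04d}",
        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        age_last_encounter=_days(last_encounter_years),
        vital_status=VitalStatus.UNKNOWN,
        phenotypes=tuple(phenotypes),
        variants=(variant,),
        measurements=tuple(measurements),
    )


def simulate_cohort(
    graph: OntologyGraph, params: SimulationParams
) -> tuple[Cohort, dict]:
    """Generate a cohort plus a ground-truth ledger of what was planted."""
    individuals = []
    for idx in range(params.n_a + params.n_b):
        in_a = idx < params.n_a
        individuals.append(_simulate_individual(idx, in_a, graph, params))
    ledger = {
        "seed": params.seed,
        "n_a": params.n_a,
        "n_b": params.n_b,
        "planted_terms": {
            str(graph.primary(e.term)): {"freq_a": e.freq_a, "freq_b": e.freq_b}
            for e in params.effects
        },
        "onset": (
            None
            if params.onset_term is None
            else {
                "term": str(graph.primary(params.onset_term)),
                "rate_a_per_year": params.onset_rate_a,
                "rate_b_per_year": params.onset_rate_b,
                "censor_fraction": params.censor_fraction,
            }
        ),
        "measurement": (
            None
            if params.measurement_code is None
            else {
                "code": params.measurement_code,
                "mean_a": params.measurement_mean_a,
                "mean_b": params.measurement_mean_b,
                "sd": params.measurement_sd,
            }
        ),
    }
    return build_cohort(individuals), ledger
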