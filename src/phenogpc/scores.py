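"""Phenotype severity scorers and their comparison between genotype classes.

Severity scores condense an individual's phenotype into one number so that
genotype classes can be compared with a Mann-Whitney U test.  Two scorers
ship with the package, both ontology-aware via true-path-rule rollup:

* the *counting scorer* — given a list of stipulated organ-system terms,
  score = number of terms with at least one observed annotation at the term
  or any descendant (each term contributes at most 1);
* a *modified de Vries score* — a rubric for intellectual-disability
  syndromes awarding points for ID severity, prenatal and postnatal growth
  abnormalities, facial and non-facial dysmorphisms, and other congenital
  anomalies, range 0-10.

Any callable ``(individual) -> float`` works as a custom scorer; returning
NaN excludes the individual from the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import Cohort, Individual
from .ontology import ObservationStatus, OntologyGraph, TermId
from .stats import GpcResult, mann_whitney_u
from .variants import GenotypeClassifier

__all__ = [
    "counting_score",
    "DeVriesRubric",
    "DEFAULT_DE_VRIES_RUBRIC",
    "de_vries_score",
    "make_counting_scorer",
    "make_de_vries_scorer",
    "apply_scorer",
]

NOT_A_NUMBER = float("nan")


def counting_score(
    individual: Individual, graph: OntologyGraph, target_terms: Sequence[str]
) -> float:
    """Number of target terms observed directly or through a descendant.

    An individual annotated to both *Ventricular septal defect* and *Atrial
    septal defect* contributes 1, not 2, toward a target of *Abnormal heart
    morphology*: after propagation the target term itself is observed, and
    each target counts at most once.
    """
    targets = {graph.primary(t) for t in target_terms}
    observed = individual.propagated(graph).observed()
    return float(len(targets & observed))


@dataclass(frozen=True)
class DeVriesRubric:
    """Configurable operationalization of the modified de Vries score.

    Each category names HPO terms; membership is decided by descendant
    rollup (e.g. *Disproportionate short stature* counts for the *Short
    stature* item).  Points: severe/profound ID 2, mild/moderate ID 1
    (highest applicable only); any prenatal growth abnormality 2; postnatal
    growth items 1 each capped at 2; two or more distinct observed facial
    dysmorphism terms 2; non-facial dysmorphism / congenital anomaly items
    1 each capped at 2.  Total range 0-10.  An individual with no assayed
    (observed or excluded) term in any category scores NaN and is excluded.
    """

    severe_id_terms: tuple[str, ...]
    mild_id_terms: tuple[str, ...]
    prenatal_growth_terms: tuple[str, ...]
    postnatal_growth_terms: tuple[str, ...]
    facial_dysmorphism_root: str
    anomaly_terms: tuple[str, ...]

    def all_terms(self) -> tuple[str, ...]:
        return (
            self.severe_id_terms
            + self.mild_id_terms
            + self.prenatal_growth_terms
            + self.postnatal_growth_terms
            + (self.facial_dysmorphism_root,)
            + self.anomaly_terms
        )


#: default rubric in real HPO ids
DEFAULT_DE_VRIES_RUBRIC = DeVriesRubric(
    severe_id_terms=("HP:0010864", "HP:0002187"),  # severe / profound ID
    mild_id_terms=("HP:0001256", "HP:0002342"),  # mild / moderate ID
    prenatal_growth_terms=("HP:0001511", "HP:0001518"),  # IUGR, SGA
    postnatal_growth_terms=(
        "HP:0004322",  # short stature
        "HP:0000098",  # tall stature
        "HP:0000252",  # microcephaly
        "HP:0000256",  # macrocephaly
    ),
    facial_dysmorphism_root="HP:0000271",  # abnormality of the face
    anomaly_terms=(
        "HP:0000924",  # abnormality of the skeletal system
        "HP:0001627",  # abnormal heart morphology
        "HP:0000119",  # abnormality of the genitourinary system
        "HP:0000707",  # abnormality of the nervous system
    ),
)


def _observed_under(term: TermId, observed: frozenset[TermId]) -> bool:
    return term in observed  # propagation already rolled descendants up


def de_vries_score(
    individual: Individual,
    graph: OntologyGraph,
    rubric: DeVriesRubric = DEFAULT_DE_VRIES_RUBRIC,
) -> float:
    """Modified de Vries severity score in [0, 10], or NaN if unassayed."""
    for t in rubric.all_terms():
        if t not in graph:
            raise ValueError(f"rubric term absent from ontology: {t}")
    prop = individual.propagated(graph)
    observed = prop.observed()
    assayed = observed | prop.excluded()

    rubric_terms = {graph.primary(t) for t in rubric.all_terms()}
    assayed_in_rubric = any(
        t in assayed or (graph.descendants(t) & assayed) for t in rubric_terms
    )
    if not assayed_in_rubric:
        return NOT_A_NUMBER

    score = 0.0
    # intellectual disability: highest applicable severity only
    if any(graph.primary(t) in observed for t in rubric.severe_id_terms):
        score += 2
    elif any(graph.primary(t) in observed for t in rubric.mild_id_terms):
        score += 1
    # prenatal growth abnormality
    if any(graph.primary(t) in observed for t in rubric.prenatal_growth_terms):
        score += 2
    # postnatal growth items, 1 point each, capped at 2
    postnatal = sum(
        1 for t in rubric.postnatal_growth_terms if graph.primary(t) in observed
    )
    score += min(postnatal, 2)
    # facial dysmorphisms: >= 2 distinct directly-annotated terms under the
    # face root (propagated intermediates would inflate the count)
    face_root = graph.primary(rubric.facial_dysmorphism_root)
    face_region = graph.descendants(face_root, include_self=True)
    facial = {
        graph.primary(p.term)
        for p in individual.phenotypes
        if p.status is ObservationStatus.OBSERVED and graph.primary(p.term) in face_region
    }
    if len(facial) >= 2:
        score += 2
    # non-facial dysmorphisms and congenital anomalies, capped at 2
    anomalies = sum(1 for t in rubric.anomaly_terms if graph.primary(t) in observed)
    score += min(anomalies, 2)
    return score


def make_counting_scorer(
    graph: OntologyGraph, target_terms: Sequence[str]
) -> Callable[[Individual], float]:
    """Bind the counting scorer to an ontology and target-term set."""
    resolved = [graph.primary(t) for t in target_terms]
    return lambda ind: counting_score(ind, graph, resolved)


def make_de_vries_scorer(
    graph: OntologyGraph, rubric: DeVriesRubric = DEFAULT_DE_VRIES_RUBRIC
) -> Callable[[Individual], float]:
    return lambda ind: de_vries_score(ind, graph, rubric)


def apply_scorer(
    cohort: Cohort,
    classifier: GenotypeClassifier,
    scorer: Callable[[Individual], float],
    name: str = "phenotype score",
) -> GpcResult:
    """Score the cohort and compare the first two genotype classes by MWU.

    Omitted and NaN-scored individuals are dropped and tallied.  With fewer
    than two non-empty classes the result is marked not-performed.
    """
    by_class, omitted = classifier.partition(list(cohort))
    n_excluded = len(omitted)
    scored: dict = {}
    for cls, members in by_class.items():
        vals = []
        for ind in members:
            s = scorer(ind)
            if math.isnan(s):
                n_excluded += 1
            else:
                vals.append(s)
        scored[cls] = vals
    nonempty = [(c, v) for c, v in sorted(scored.items(), key=lambda cv: cv[0].index) if v]
    if len(nonempty) < 2:
        return GpcResult(
            hypothesis=name,
            kind="score",
            class_summaries=(),
            statistic=None,
            p_raw=None,
            n_used=0,
            n_excluded=n_excluded,
            note="not performed: fewer than 2 non-empty genotype classes",
        )
    (cls_a, a), (cls_b, b) = nonempty[:2]
    res = mann_whitney_u(a, b)
    stat, p = res if res is not None else (None, None)
    summaries = tuple(
        f"{c.label}: n={len(v)}, median={float(np.median(v)):g}" for c, v in ((cls_a, a), (cls_b, b))
    )
    return GpcResult(
        hypothesis=name,
        kind="score",
        class_summaries=summaries,
        statistic=stat,
        p_raw=p,
        n_used=len(a) + len(b),
        n_excluded=n_excluded,
    )
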