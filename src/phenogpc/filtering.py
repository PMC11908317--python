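"""Rule-based independent filtering of HPO terms before categorical testing.

With hundreds of annotated HPO terms per cohort, testing everything and
correcting for multiplicity destroys power.  Independent filtering prunes
hypotheses by criteria that are independent of the test statistic under the
null, so Type-I error control is preserved while far fewer tests share the
multiple-testing burden.  Five rules are applied, in order, to each term's
per-genotype-class observed/excluded counts (after true-path-rule
propagation); a term skipped by an earlier rule is never evaluated by a
later one:

1. *General-level terms*: the phenotypic-abnormality subroot, its direct
   children (configurable depth), and terms outside the subroot are skipped
   — a real signal will surface at a more specific descendant.
2. *Identical to a child*: a parent whose full count vector equals that of
   one of its children adds no information — its test would return exactly
   the child's p-value.
3. *Low coverage*: terms assayed (observed or excluded) in fewer than a
   fraction of the cohort (default 0.4) are skipped.
4. *Underpowered total*: with 2 genotype classes a total assayed count
   below 7, or with 3 classes below 6, can never reach significance.
5. *Empty genotype class*: a class with neither observed nor excluded
   annotations cannot support a comparison.

Decisions are a pure function of counts and graph structure; no p-value is
ever computed here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .ontology import OntologyGraph, TermId

__all__ = [
    "IfHpoConfig",
    "TermCounts",
    "FilterReason",
    "FilterDecision",
    "select_testable_terms",
    "decisions_to_frame",
]


@dataclass(frozen=True)
class IfHpoConfig:
    """Thresholds for the five filtering rules.

    ``min_coverage_fraction`` — minimum assayed fraction of the cohort
    (rule 3); ``min_total_2x2`` / ``min_total_3x2`` — minimum total assayed
    count for 2-class / 3-class comparisons (rule 4); ``general_level_depth``
    — how many levels below the subroot count as "general" (rule 1);
    ``coverage_counts_excluded`` — whether rule 3's coverage counts
    excluded annotations as assayed (default) or observed ones only.
    """

    min_coverage_fraction: float = 0.4
    min_total_2x2: int = 7
    min_total_3x2: int = 6
    general_level_depth: int = 1
    coverage_counts_excluded: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_coverage_fraction <= 1.0):
            raise ValueError("min_coverage_fraction must be in (0, 1]")
        if self.min_total_2x2 < 1 or self.min_total_3x2 < 1:
            raise ValueError("minimum total thresholds must be >= 1")


@dataclass(frozen=True)
class TermCounts:
    """Per-genotype-class observed/excluded counts for one term."""

    n_observed: tuple[int, ...]
    n_excluded: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.n_observed) != len(self.n_excluded):
            raise ValueError("observed/excluded vectors must be same length")
        if any(x < 0 for x in self.n_observed + self.n_excluded):
            raise ValueError("counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.n_observed)

    @property
    def total_assayed(self) -> int:
        return sum(self.n_observed) + sum(self.n_excluded)

    @property
    def total_observed(self) -> int:
        return sum(self.n_observed)

    def as_table(self) -> list[list[int]]:
        """k x 2 contingency table: rows = classes, cols = (observed, excluded)."""
        return [[o, e] for o, e in zip(self.n_observed, self.n_excluded)]


class FilterReason(enum.Enum):
    TESTED = "TESTED"
    GENERAL_LEVEL = "GENERAL_LEVEL"
    SAME_AS_CHILD = "SAME_AS_CHILD"
    LOW_COVERAGE = "LOW_COVERAGE"
    UNDERPOWERED_TOTAL = "UNDERPOWERED_TOTAL"
    EMPTY_GENOTYPE_CLASS = "EMPTY_GENOTYPE_CLASS"


@dataclass(frozen=True)
class FilterDecision:
    """Per-term verdict: tested, or skipped with the first matching reason."""

    term: TermId
    tested: bool
    reason: FilterReason
    counts: TermCounts

    def __post_init__(self) -> None:
        if self.tested != (self.reason is FilterReason.TESTED):
            raise ValueError("tested flag must agree with reason")


def select_testable_terms(
    counts_by_term: Mapping[TermId, TermCounts],
    graph: OntologyGraph,
    cohort_size: int,
    config: IfHpoConfig | None = None,
) -> list[FilterDecision]:
    """Apply the five skip rules to every annotated term, in fixed order.

    ``counts_by_term`` holds propagated counts for each term actually
    annotated (observed or excluded) somewhere in the cohort; terms never
    annotated are not enumerated.  Returns one decision per input term,
    in sorted term order.
    """
    cfg = config or IfHpoConfig()
    decisions: list[FilterDecision] = []
    for term in sorted(counts_by_term):
        counts = counts_by_term[term]
        reason = _first_matching_rule(term, counts, counts_by_term, graph, cohort_size, cfg)
        decisions.append(
            FilterDecision(term=term, tested=reason is FilterReason.TESTED, reason=reason, counts=counts)
        )
    return decisions


def _first_matching_rule(
    term: TermId,
    counts: TermCounts,
    counts_by_term: Mapping[TermId, TermCounts],
    graph: OntologyGraph,
    cohort_size: int,
    cfg: IfHpoConfig,
) -> FilterReason:
    # rule 1: general-level terms (and terms outside the subroot)
    if graph.is_general_level(term, depth=cfg.general_level_depth):
        return FilterReason.GENERAL_LEVEL
    # rule 2: identical counts to any child that carries counts
    for child in graph.children(term):
        if child in counts_by_term and counts_by_term[child] == counts:
            return FilterReason.SAME_AS_CHILD
    # rule 3: assayed in too small a fraction of the cohort
    coverage_count = counts.total_assayed if cfg.coverage_counts_excluded else counts.total_observed
    if coverage_count < cfg.min_coverage_fraction * cohort_size:
        return FilterReason.LOW_COVERAGE
    # rule 4: total below the nominal-power threshold
    threshold = cfg.min_total_2x2 if counts.n_classes == 2 else cfg.min_total_3x2
    if counts.total_assayed < threshold:
        return FilterReason.UNDERPOWERED_TOTAL
    # rule 5: a genotype class with no annotations at all
    for o, e in zip(counts.n_observed, counts.n_excluded):
        if o == 0 and e == 0:
            return FilterReason.EMPTY_GENOTYPE_CLASS
    return FilterReason.TESTED


def decisions_to_frame(
    decisions: Sequence[FilterDecision],
    graph: OntologyGraph,
    class_labels: Sequence[str],
) -> pd.DataFrame:
    """Export the filter ledger ("MTC filter report") as a flat table."""
    rows = []
    for d in decisions:
        row: dict = {
            "term": str(d.term),
            "label": graph.label(d.term),
            "tested": d.tested,
            "reason": d.reason.value,
        }
        for lbl, o, e in zip(class_labels, d.counts.n_observed, d.counts.n_excluded):
            row[f"observed[{lbl}]"] = o
            row[f"excluded[{lbl}]"] = e
        rows.append(row)
    return pd.DataFrame(rows)
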