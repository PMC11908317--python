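"""End-to-end analysis: cohort -> classifier -> filter -> tests -> report.

``run_categorical`` enumerates every HPO term annotated in the cohort
(restricted to the phenotypic-abnormality subhierarchy), builds one
observed/excluded contingency table per term from propagated annotations,
selects the testable terms (independent filtering by default, or a
user-supplied term list, or all terms), runs Fisher's exact test on each,
and corrects across exactly the tests performed.  ``run_continuous`` and
``run_survival`` compare a numeric measurement (t-test) or a time-to-event
endpoint (logrank) between two genotype classes; these families receive no
multiple-testing correction and report raw p-values with exclusion tallies.
``render_lollipop`` draws the cohort's protein-coding variants against a
user-supplied domain table.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import Cohort
from .filtering import (
    FilterDecision,
    FilterReason,
    IfHpoConfig,
    TermCounts,
    decisions_to_frame,
    select_testable_terms,
)
from .ontology import ObservationStatus, OntologyGraph, TermId
from .stats import ALPHA, GpcResult, MtcMethod, adjust_pvalues, fisher_exact, logrank, t_test
from .survival import Endpoint, SurvivalDatum, endpoint_observation, km_table
from .variants import GenotypeClass, GenotypeClassifier

__all__ = [
    "TermSelection",
    "AnalysisConfig",
    "ProteinMeta",
    "CategoricalAnalysis",
    "run_categorical",
    "run_continuous",
    "run_survival",
    "render_lollipop",
    "results_to_frame",
    "write_report",
]


class TermSelection(enum.Enum):
    """How the categorical analysis chooses which HPO terms to test."""

    INDEPENDENT_FILTER = "independent_filter"
    SPECIFIED_TERMS = "specified_terms"
    ALL_TERMS = "all_terms"


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one categorical analysis run."""

    term_selection: TermSelection = TermSelection.INDEPENDENT_FILTER
    specified_terms: tuple[str, ...] = ()
    if_hpo: IfHpoConfig = field(default_factory=IfHpoConfig)
    mtc_method: MtcMethod = MtcMethod.BH
    alpha: float = ALPHA


@dataclass(frozen=True)
class ProteinMeta:
    """Protein length and domain table for the lollipop plot."""

    length: int
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        for name, start, end in self.domains:
            if not (1 <= start <= end <= self.length):
                raise ValueError(f"domain {name}: ({start}, {end}) outside 1..{self.length}")


@dataclass(frozen=True)
class CategoricalAnalysis:
    """Results of one categorical run plus the complete filter ledger."""

    results: tuple[GpcResult, ...]
    decisions: tuple[FilterDecision, ...]
    class_labels: tuple[str, ...]
    n_omitted: int

    @property
    def n_tested(self) -> int:
        return len(self.results)

    def significant(self) -> tuple[GpcResult, ...]:
        return tuple(r for r in self.results if r.significant)


def term_counts_by_class(
    cohort: Cohort, graph: OntologyGraph, classifier: GenotypeClassifier
) -> tuple[dict[TermId, TermCounts], tuple[GenotypeClass, ...], int]:
    """Propagated per-term observed/excluded counts for each genotype class.

    Terms are restricted to the phenotypic-abnormality subhierarchy
    (subroot included, so the filter's general-level rule can account for
    it); terms never annotated in the cohort are not enumerated.
    """
    by_class, omitted = classifier.partition(list(cohort))
    classes = tuple(c for c in classifier.classes)
    in_scope = graph.descendants(graph.root, include_self=True)
    obs: dict[TermId, list[int]] = {}
    exc: dict[TermId, list[int]] = {}
    k = len(classes)
    for ci, cls in enumerate(classes):
        for ind in by_class[cls]:
            prop = ind.propagated(graph)
            for t, status in prop.statuses.items():
                if t not in in_scope:
                    continue
                if status is ObservationStatus.OBSERVED:
                    obs.setdefault(t, [0] * k)[ci] += 1
                    exc.setdefault(t, [0] * k)
                else:
                    exc.setdefault(t, [0] * k)[ci] += 1
                    obs.setdefault(t, [0] * k)
    counts = {
        t: TermCounts(n_observed=tuple(obs[t]), n_excluded=tuple(exc[t])) for t in obs
    }
    return counts, classes, len(omitted)


def run_categorical(
    cohort: Cohort,
    graph: OntologyGraph,
    classifier: GenotypeClassifier,
    config: AnalysisConfig | None = None,
) -> CategoricalAnalysis:
    """Fisher-exact screen over HPO terms with multiplicity control.

    The correction spans exactly the tests performed after term selection,
    and results are sorted by adjusted p-value.
    """
    cfg = config or AnalysisConfig()
    counts, classes, n_omitted = term_counts_by_class(cohort, graph, classifier)
    class_labels = tuple(c.label for c in classes)
    # rule 3's denominator is the entire cohort, not just classified members
    cohort_size = len(cohort)

    if cfg.term_selection is TermSelection.INDEPENDENT_FILTER:
        decisions = select_testable_terms(counts, graph, cohort_size, cfg.if_hpo)
    elif cfg.term_selection is TermSelection.SPECIFIED_TERMS:
        wanted = {graph.primary(t) for t in cfg.specified_terms}
        decisions = [
            FilterDecision(
                term=t,
                tested=t in wanted,
                reason=FilterReason.TESTED if t in wanted else FilterReason.GENERAL_LEVEL,
                counts=c,
            )
            for t, c in sorted(counts.items())
        ]
        # user-specified mode: untested terms are out of scope, not "general";
        # keep only the requested terms in the ledger
        decisions = [d for d in decisions if d.term in wanted]
    else:  # ALL_TERMS
        decisions = [
            FilterDecision(term=t, tested=True, reason=FilterReason.TESTED, counts=c)
            for t, c in sorted(counts.items())
        ]

    tested = [d for d in decisions if d.tested]
    raw = [fisher_exact(d.counts.as_table()) for d in tested]
    adjusted = adjust_pvalues(raw, cfg.mtc_method) if raw else []
    if cfg.mtc_method is MtcMethod.NONE:
        adjusted = raw
    results = []
    for d, p, q in zip(tested, raw, adjusted):
        summaries = tuple(
            f"{lbl}: {o}/{o + e}"
            for lbl, o, e in zip(class_labels, d.counts.n_observed, d.counts.n_excluded)
        )
        results.append(
            GpcResult(
                hypothesis=str(d.term),
                kind="categorical",
                class_summaries=summaries,
                statistic=None,
                p_raw=p,
                p_adjusted=q,
                n_used=d.counts.total_assayed,
                n_excluded=(cohort_size - n_omitted) - d.counts.total_assayed,
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.hypothesis))
    return CategoricalAnalysis(
        results=tuple(results),
        decisions=tuple(decisions),
        class_labels=class_labels,
        n_omitted=n_omitted,
    )


def run_continuous(
    cohort: Cohort,
    classifier: GenotypeClassifier,
    measurement_code: str,
    welch: bool = False,
) -> GpcResult:
    """Compare a coded measurement between two genotype classes by t-test."""
    by_class, omitted = classifier.partition(list(cohort))
    classes = classifier.classes[:2]
    values: list[list[float]] = []
    n_missing = len(omitted)
    for cls in classes:
        vals = []
        for ind in by_class[cls]:
            m = ind.measurement(measurement_code)
            if m is None:
                n_missing += 1
            else:
                vals.append(m.value)
        values.append(vals)
    res = t_test(values[0], values[1], welch=welch)
    if res is None:
        return GpcResult(
            hypothesis=measurement_code,
            kind="measurement",
            class_summaries=(),
            statistic=None,
            p_raw=None,
            n_excluded=n_missing,
            note="not performed: fewer than 2 values in a genotype class",
        )
    stat, p = res
    summaries = tuple(
        f"{cls.label}: n={len(v)}, mean={sum(v) / len(v):.4g}" for cls, v in zip(classes, values)
    )
    return GpcResult(
        hypothesis=measurement_code,
        kind="measurement",
        class_summaries=summaries,
        statistic=stat,
        p_raw=p,
        n_used=len(values[0]) + len(values[1]),
        n_excluded=n_missing,
    )


def run_survival(
    cohort: Cohort,
    graph: OntologyGraph,
    classifier: GenotypeClassifier,
    endpoint: Endpoint,
) -> tuple[GpcResult, dict[str, pd.DataFrame]]:
    """Logrank comparison of an endpoint between two genotype classes.

    Returns the test result and per-class Kaplan-Meier tables; individuals
    without usable timing are tallied as excluded (MISSING).
    """
    by_class, omitted = classifier.partition(list(cohort))
    classes = classifier.classes[:2]
    data: list[list[SurvivalDatum]] = []
    n_missing = len(omitted)
    for cls in classes:
        usable = []
        for ind in by_class[cls]:
            d = endpoint_observation(ind, graph, endpoint)
            if d is None:
                n_missing += 1
            else:
                usable.append(d)
        data.append(usable)
    name = endpoint.target or "death"
    tables = {
        cls.label: km_table(d, label=cls.label) for cls, d in zip(classes, data)
    }
    if not data[0] or not data[1]:
        return (
            GpcResult(
                hypothesis=name,
                kind="survival",
                class_summaries=(),
                statistic=None,
                p_raw=None,
                n_excluded=n_missing,
                note="not performed: a genotype class has no usable survival data",
            ),
            tables,
        )
    res = logrank(
        [d.duration_days for d in data[0]],
        [d.event for d in data[0]],
        [d.duration_days for d in data[1]],
        [d.event for d in data[1]],
    )
    if res is None:
        return (
            GpcResult(
                hypothesis=name,
                kind="survival",
                class_summaries=(),
                statistic=None,
                p_raw=None,
                n_excluded=n_missing,
                note="not performed: no events in either genotype class",
            ),
            tables,
        )
    stat, p = res
    summaries = tuple(
        f"{cls.label}: n={len(d)}, events={sum(x.event for x in d)}"
        for cls, d in zip(classes, data)
    )
    return (
        GpcResult(
            hypothesis=name,
            kind="survival",
            class_summaries=summaries,
            statistic=stat,
            p_raw=p,
            n_used=len(data[0]) + len(data[1]),
            n_excluded=n_missing,
        ),
        tables,
    )


# -- figure --------------------------------------------------------------

_EFFECT_COLORS = {
    "missense_variant": "#1f77b4",
    "stop_gained": "#d62728",
    "frameshift_variant": "#ff7f0e",
    "splice_site": "#9467bd",
    "start_lost": "#8c564b",
    "inframe_deletion": "#2ca02c",
}


def render_lollipop(
    cohort: Cohort,
    protein_meta: ProteinMeta,
    out_path: Union[str, Path],
) -> dict:
    """Draw cohort variants as lollipops over the protein domain cartoon.

    One lollipop per distinct protein-position variant, with height and
    marker size proportional to the cohort allele count and color keyed to
    the functional effect.  Variants without a protein position (including
    structural variants) are omitted and tallied.  Returns a summary dict
    with the number of plotted and omitted variants.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts: dict[tuple[int, str], int] = {}
    effects: dict[tuple[int, str], str] = {}
    n_omitted = 0
    for ind in cohort:
        for v in ind.variants:
            if v.protein_range is None:
                n_omitted += v.allele_count_in_individual
                continue
            pos = v.protein_range[0]
            key = (pos, v.key)
            counts[key] = counts.get(key, 0) + v.allele_count_in_individual
            effects[key] = sorted(v.effects)[0] if v.effects else "other"

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.hlines(0, 1, protein_meta.length, color="0.6", lw=4, zorder=1)
    for name, start, end in protein_meta.domains:
        ax.axvspan(start, end, ymin=0.02, ymax=0.18, alpha=0.5, zorder=2)
        ax.text((start + end) / 2, -0.12, name, ha="center", va="top", fontsize=8)
    if counts:
        max_count = max(counts.values())
        for (pos, key), c in sorted(counts.items()):
            color = _EFFECT_COLORS.get(effects[(pos, key)], "0.3")
            height = 0.3 + 0.7 * c / max_count
            ax.plot([pos, pos], [0, height], color=color, lw=1, zorder=3)
            ax.scatter([pos], [height], s=30 + 120 * c / max_count, color=color, zorder=4)
    else:
        ax.text(protein_meta.length / 2, 0.5, "no displayable variants", ha="center")
    ax.set_xlim(0, protein_meta.length * 1.02)
    ax.set_ylim(-0.35, 1.25)
    ax.set_xlabel("protein residue")
    ax.set_yticks([])
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)
    fig.tight_layout()
    fig.savefig(out_path, format="svg")
    plt.close(fig)
    return {"n_plotted": len(counts), "n_omitted_alleles": n_omitted}


# -- report export -------------------------------------------------------


def results_to_frame(results: Sequence[GpcResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "hypothesis": r.hypothesis,
                "kind": r.kind,
                "classes": " | ".join(r.class_summaries),
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "n_used": r.n_used,
                "n_excluded": r.n_excluded,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)


def write_report(
    out_dir: Union[str, Path],
    analysis: CategoricalAnalysis,
    graph: OntologyGraph,
    extra_results: Sequence[GpcResult] = (),
    km_tables: dict[str, pd.DataFrame] | None = None,
    config: AnalysisConfig | None = None,
) -> None:
    """Write result TSVs, the filter ledger, KM tables, and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_to_frame(analysis.results).to_csv(out / "categorical_results.tsv", sep="\t", index=False)
    decisions_to_frame(analysis.decisions, graph, analysis.class_labels).to_csv(
        out / "filter_ledger.tsv", sep="\t", index=False
    )
    if extra_results:
        results_to_frame(extra_results).to_csv(out / "other_results.tsv", sep="\t", index=False)
    for label, tbl in (km_tables or {}).items():
        tbl.to_csv(out / f"km_{label}.tsv", sep="\t", index=False)
    cfg = config or AnalysisConfig()
    cfg_text = json.dumps(
        {
            "term_selection": cfg.term_selection.value,
            "mtc_method": cfg.mtc_method.name,
            "alpha": cfg.alpha,
            "if_hpo": {
                "min_coverage_fraction": cfg.if_hpo.min_coverage_fraction,
                "min_total_2x2": cfg.if_hpo.min_total_2x2,
                "min_total_3x2": cfg.if_hpo.min_total_3x2,
            },
        },
        sort_keys=True,
    )
    manifest = {
        "config": json.loads(cfg_text),
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "n_terms_annotated": len(analysis.decisions),
        "n_terms_tested": analysis.n_tested,
        "n_significant": len(analysis.significant()),
        "n_omitted_by_classifier": analysis.n_omitted,
        "class_labels": list(analysis.class_labels),
        "software_version": _version(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _version() -> str:
    from . import __version__

    return __version__
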