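"""Variant predicate algebra and genotype classifiers.

A *variant predicate* is a Boolean-valued test over a variant's attributes
(functional effect, exon, protein region, structural type, length change),
composable with AND / OR / NOT into arbitrarily expressive criteria — e.g.
a "point mutation" is a missense change affecting one reference base with
change length zero, and a "structural deletion" is either an imprecise
chromosomal deletion or a sequence deletion of at least 50 bp.

A *genotype classifier* uses predicates (or sex / diagnosis attributes) to
assign each cohort member to a genotype class, or to omit them when their
genotype does not fit the hypothesis being tested.  Classes from one
classifier are disjoint and, together with the omitted set, cover the
cohort.

A predicate leaf whose attribute is absent from the variant (e.g. a protein
region test on a variant without protein coordinates) evaluates to False so
that predicates run safely over mixed SNV / structural-variant cohorts.
"""

from __future__ import annotations

import enum
import logging
import operator
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .cohort import Individual, VariantRecord

__all__ = [
    "VariantPredicate",
    "GenotypeClass",
    "GenotypeClassifier",
    "BiallelicMode",
    "effect_is",
    "exon_overlaps",
    "protein_region_overlaps",
    "key_equals",
    "structural_type_is",
    "change_length_cmp",
    "ref_length_cmp",
    "is_structural_deletion",
    "monoallelic_classifier",
    "biallelic_classifier",
    "allele_count_classifier",
    "sex_classifier",
    "diagnosis_classifier",
]

logger = logging.getLogger(__name__)

_CMP_OPS: Mapping[str, Callable[[int, int], bool]] = {
    "==": operator.eq,
    "!=": operator.ne,
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}

#: structural-type labels regarded as chromosomal-scale deletions
_STRUCTURAL_DELETION_TYPES = {"DEL", "chromosomal_deletion"}


class PredicateError(ValueError):
    """Malformed predicate construction (never raised at evaluation time)."""


@dataclass(frozen=True)
class VariantPredicate:
    """A node in a Boolean predicate tree over variant attributes.

    Instances are built through the module-level factory functions and
    combined with ``&``, ``|`` and ``~``.  Calling the predicate on a
    :class:`VariantRecord` evaluates it.
    """

    kind: str
    argument: object = None
    children: tuple["VariantPredicate", ...] = ()

    def __call__(self, v: VariantRecord) -> bool:
        return _EVALUATORS[self.kind](self, v)

    def __and__(self, other: "VariantPredicate") -> "VariantPredicate":
        return VariantPredicate(kind="AND", children=(self, other))

    def __or__(self, other: "VariantPredicate") -> "VariantPredicate":
        return VariantPredicate(kind="OR", children=(self, other))

    def __invert__(self) -> "VariantPredicate":
        return VariantPredicate(kind="NOT", children=(self,))

    # -- JSON (de)serialization for analysis configs --------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.argument is not None:
            d["argument"] = list(self.argument) if isinstance(self.argument, tuple) else self.argument
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariantPredicate":
        kind = d.get("kind")
        if kind not in _EVALUATORS:
            raise PredicateError(f"unknown predicate kind: {kind!r}")
        children = tuple(cls.from_dict(c) for c in d.get("children", []))
        arg = d.get("argument")
        if kind in ("AND", "OR") and len(children) < 2:
            raise PredicateError(f"{kind} requires >= 2 children")
        if kind == "NOT" and len(children) != 1:
            raise PredicateError("NOT requires exactly 1 child")
        if kind not in ("AND", "OR", "NOT"):
            if children:
                raise PredicateError(f"leaf {kind} cannot have children")
            return _LEAF_BUILDERS[kind](arg)
        return cls(kind=kind, children=children)


def _cmp_arg(arg) -> tuple[str, int]:
    op, value = arg
    if op not in _CMP_OPS:
        raise PredicateError(f"unknown comparison operator {op!r}")
    return op, int(value)


# -- leaf factories ------------------------------------------------------


def effect_is(effect: str) -> VariantPredicate:
    """True when ``effect`` is among the variant's functional annotations."""
    return VariantPredicate(kind="EFFECT_IS", argument=str(effect))


def exon_overlaps(exon: int) -> VariantPredicate:
    """True when the variant touches the given 1-based exon number."""
    if int(exon) < 1:
        raise PredicateError("exon numbers are 1-based")
    return VariantPredicate(kind="EXON_OVERLAPS", argument=int(exon))


def protein_region_overlaps(start: int, end: int) -> VariantPredicate:
    """True when the variant's protein range intersects [start, end] (1-based, inclusive)."""
    if not (1 <= int(start) <= int(end)):
        raise PredicateError(f"bad protein region ({start}, {end})")
    return VariantPredicate(kind="PROTEIN_REGION_OVERLAPS", argument=(int(start), int(end)))


def key_equals(key: str) -> VariantPredicate:
    """True for the single variant with this stable key."""
    return VariantPredicate(kind="KEY_EQUALS", argument=str(key))


def structural_type_is(structural_type: str) -> VariantPredicate:
    return VariantPredicate(kind="STRUCTURAL_TYPE_IS", argument=str(structural_type))


def change_length_cmp(op: str, value: int) -> VariantPredicate:
    """Compare the signed change length (alt len - ref len), e.g. ``("<=", -50)``."""
    return VariantPredicate(kind="CHANGE_LENGTH_CMP", argument=_cmp_arg((op, value)))


def ref_length_cmp(op: str, value: int) -> VariantPredicate:
    """Compare the number of affected reference bases."""
    return VariantPredicate(kind="REF_LENGTH_CMP", argument=_cmp_arg((op, value)))


def is_structural_deletion(min_deletion_length: int = 50) -> VariantPredicate:
    """An imprecise chromosomal deletion, or a sequence deletion of at least
    ``min_deletion_length`` base pairs (default 50)."""
    if int(min_deletion_length) < 1:
        raise PredicateError("min_deletion_length must be positive")
    return VariantPredicate(kind="IS_STRUCTURAL_DELETION", argument=int(min_deletion_length))


_LEAF_BUILDERS: Mapping[str, Callable] = {
    "EFFECT_IS": effect_is,
    "EXON_OVERLAPS": exon_overlaps,
    "PROTEIN_REGION_OVERLAPS": lambda arg: protein_region_overlaps(*arg),
    "KEY_EQUALS": key_equals,
    "STRUCTURAL_TYPE_IS": structural_type_is,
    "CHANGE_LENGTH_CMP": lambda arg: change_length_cmp(*arg),
    "REF_LENGTH_CMP": lambda arg: ref_length_cmp(*arg),
    "IS_STRUCTURAL_DELETION": is_structural_deletion,
}


# -- evaluation ----------------------------------------------------------


def _eval_effect(p: VariantPredicate, v: VariantRecord) -> bool:
    return p.argument in v.effects


def _eval_exon(p: VariantPredicate, v: VariantRecord) -> bool:
    return p.argument in v.exons


def _eval_protein_region(p: VariantPredicate, v: VariantRecord) -> bool:
    if v.protein_range is None:
        return False
    s, e = p.argument
    vs, ve = v.protein_range
    return vs <= e and s <= ve


def _eval_key(p: VariantPredicate, v: VariantRecord) -> bool:
    return v.key == p.argument


def _eval_structural_type(p: VariantPredicate, v: VariantRecord) -> bool:
    return v.structural_type == p.argument


def _eval_change_length(p: VariantPredicate, v: VariantRecord) -> bool:
    if v.change_length is None:
        return False
    op, val = p.argument
    return _CMP_OPS[op](v.change_length, val)


def _eval_ref_length(p: VariantPredicate, v: VariantRecord) -> bool:
    if v.ref is None:
        return False
    op, val = p.argument
    return _CMP_OPS[op](len(v.ref), val)


def _eval_structural_deletion(p: VariantPredicate, v: VariantRecord) -> bool:
    if v.structural_type in _STRUCTURAL_DELETION_TYPES and v.change_length is None:
        return True  # imprecise chromosomal deletion
    if v.change_length is not None and v.change_length <= -p.argument:
        return True
    return False


_EVALUATORS: Mapping[str, Callable[[VariantPredicate, VariantRecord], bool]] = {
    "EFFECT_IS": _eval_effect,
    "EXON_OVERLAPS": _eval_exon,
    "PROTEIN_REGION_OVERLAPS": _eval_protein_region,
    "KEY_EQUALS": _eval_key,
    "STRUCTURAL_TYPE_IS": _eval_structural_type,
    "CHANGE_LENGTH_CMP": _eval_change_length,
    "REF_LENGTH_CMP": _eval_ref_length,
    "IS_STRUCTURAL_DELETION": _eval_structural_deletion,
    "AND": lambda p, v: all(c(v) for c in p.children),
    "OR": lambda p, v: any(c(v) for c in p.children),
    "NOT": lambda p, v: not p.children[0](v),
}


# -- genotype classifiers ------------------------------------------------


@dataclass(frozen=True)
class GenotypeClass:
    """A labelled, ordered genotype class within one classifier."""

    label: str
    index: int


class BiallelicMode(enum.Enum):
    """How a biallelic classifier partitions the A-allele count {0, 1, 2}."""

    THREE_WAY = "AA|AB|BB"
    AA_AB_VS_BB = "AA+AB|BB"
    AA_VS_AB_BB = "AA|AB+BB"


@dataclass(frozen=True)
class GenotypeClassifier:
    """Assigns each individual to a genotype class or omits them.

    Built through the ``*_classifier`` factory functions.  ``assign``
    returns a :class:`GenotypeClass` or ``None`` for omitted individuals.
    """

    name: str
    classes: tuple[GenotypeClass, ...]
    _assign: Callable[[Individual], Optional[GenotypeClass]] = field(repr=False)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.classes]
        if len(set(labels)) != len(labels):
            raise PredicateError(f"duplicate class labels in classifier {self.name}")

    def assign(self, individual: Individual) -> Optional[GenotypeClass]:
        return self._assign(individual)

    def partition(self, individuals: Sequence[Individual]):
        """Split individuals into per-class lists plus the omitted list."""
        by_class: dict[GenotypeClass, list[Individual]] = {c: [] for c in self.classes}
        omitted: list[Individual] = []
        for ind in individuals:
            cls = self.assign(ind)
            if cls is None:
                omitted.append(ind)
            else:
                by_class[cls].append(ind)
        return by_class, omitted


def _allele_count(individual: Individual, pred: VariantPredicate) -> int:
    return sum(
        v.allele_count_in_individual for v in individual.variants if pred(v)
    )


def monoallelic_classifier(
    a_predicate: VariantPredicate,
    b_predicate: Optional[VariantPredicate] = None,
    a_label: str = "A",
    b_label: str = "B",
) -> GenotypeClassifier:
    """Partition by a single allele matching A vs a single allele matching B.

    Suited to autosomal dominant and X-linked conditions (one causal
    allele: heterozygous, or hemizygous in males).  When ``b_predicate``
    is omitted it defaults to NOT A.  Individuals with any other allele
    configuration — zero or two matching alleles, or alleles matching both
    predicates — are omitted.
    """
    b_pred = b_predicate if b_predicate is not None else ~a_predicate
    cls_a, cls_b = GenotypeClass(a_label, 0), GenotypeClass(b_label, 1)

    def assign(ind: Individual) -> Optional[GenotypeClass]:
        if b_predicate is not None and any(
            a_predicate(v) and b_pred(v) for v in ind.variants
        ):
            logger.warning("%s: allele matches both A and B predicates; omitted", ind.id)
            return None
        a = _allele_count(ind, a_predicate)
        b = _allele_count(ind, b_pred)
        if a == 1 and b == 0:
            return cls_a
        if b == 1 and a == 0:
            return cls_b
        return None

    return GenotypeClassifier(name="monoallelic", classes=(cls_a, cls_b), _assign=assign)


def biallelic_classifier(
    a_predicate: VariantPredicate,
    b_predicate: Optional[VariantPredicate] = None,
    mode: BiallelicMode = BiallelicMode.THREE_WAY,
    a_label: str = "A",
    b_label: str = "B",
) -> GenotypeClassifier:
    """Partition individuals with two causal alleles by A-allele count.

    Suited to autosomal recessive conditions.  With the three-way mode the
    classes are AA, AB, BB (a 3x2 contingency table); the two-way modes
    merge AA+AB vs BB or AA vs AB+BB.  Individuals whose alleles match
    neither predicate, or who do not carry exactly two accounted alleles,
    are omitted.
    """
    b_pred = b_predicate if b_predicate is not None else ~a_predicate
    aa, ab, bb = f"{a_label}{a_label}", f"{a_label}{b_label}", f"{b_label}{b_label}"
    if mode is BiallelicMode.THREE_WAY:
        classes = (GenotypeClass(aa, 0), GenotypeClass(ab, 1), GenotypeClass(bb, 2))
        mapping = {2: classes[0], 1: classes[1], 0: classes[2]}
    elif mode is BiallelicMode.AA_AB_VS_BB:
        classes = (GenotypeClass(f"{aa}+{ab}", 0), GenotypeClass(bb, 1))
        mapping = {2: classes[0], 1: classes[0], 0: classes[1]}
    else:
        classes = (GenotypeClass(aa, 0), GenotypeClass(f"{ab}+{bb}", 1))
        mapping = {2: classes[0], 1: classes[1], 0: classes[1]}

    def assign(ind: Individual) -> Optional[GenotypeClass]:
        if b_predicate is not None and any(a_predicate(v) and b_pred(v) for v in ind.variants):
            logger.warning("%s: allele matches both A and B predicates; omitted", ind.id)
            return None
        a = _allele_count(ind, a_predicate)
        b = _allele_count(ind, b_pred)
        if a + b != 2:
            return None
        return mapping[a]

    return GenotypeClassifier(name="biallelic", classes=classes, _assign=assign)


def allele_count_classifier(target: VariantPredicate) -> GenotypeClassifier:
    """Partition by carrying one vs two alleles matched by ``target``."""
    one, two = GenotypeClass("monoallelic", 0), GenotypeClass("biallelic", 1)

    def assign(ind: Individual) -> Optional[GenotypeClass]:
        n = _allele_count(ind, target)
        if n == 1:
            return one
        if n == 2:
            return two
        return None

    return GenotypeClassifier(name="allele_count", classes=(one, two), _assign=assign)


def sex_classifier() -> GenotypeClassifier:
    """Partition by sex; individuals of unknown sex are omitted."""
    from .cohort import Sex

    male, female = GenotypeClass("MALE", 0), GenotypeClass("FEMALE", 1)

    def assign(ind: Individual) -> Optional[GenotypeClass]:
        if ind.sex is Sex.MALE:
            return male
        if ind.sex is Sex.FEMALE:
            return female
        return None

    return GenotypeClassifier(name="sex", classes=(male, female), _assign=assign)


def diagnosis_classifier(disease_a: str, disease_b: str) -> GenotypeClassifier:
    """Partition by which of two disease diagnoses an individual carries.

    Individuals diagnosed with both or neither disease are omitted.
    """
    cls_a, cls_b = GenotypeClass(disease_a, 0), GenotypeClass(disease_b, 1)

    def assign(ind: Individual) -> Optional[GenotypeClass]:
        ids = {d for d, _ in ind.diseases}
        has_a, has_b = disease_a in ids, disease_b in ids
        if has_a and not has_b:
            return cls_a
        if has_b and not has_a:
            return cls_b
        return None

    return GenotypeClassifier(name="diagnosis", classes=(cls_a, cls_b), _assign=assign)
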