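"""Data model for individuals and cohorts, with a GA4GH phenopacket reader.

Reads the subset of Phenopacket Schema v2 JSON fields needed for
genotype-phenotype correlation analysis: subject sex / age / vital status,
phenotypic features with observed-or-excluded status and onset, diseases,
numeric measurements (assay code, value, unit), and causal variants with
their functional annotation and allelic state.  Ages are normalized to days
(1 y = 365.25 d, 1 mo = 30.44 d) and displayed in years.  Missing data are
never imputed: an unparseable onset is dropped with a warning, and absent
sections yield empty lists.
"""

from __future__ import annotations

import enum
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .ontology import ObservationStatus, OntologyGraph, TermId, propagate

__all__ = [
    "AgeDuration",
    "PhenotypeObservation",
    "VariantRecord",
    "MeasurementValue",
    "Individual",
    "Cohort",
    "Sex",
    "VitalStatus",
    "PhenopacketError",
    "read_phenopacket",
    "read_cohort_dir",
    "build_cohort",
    "cohort_summary",
]

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30.44

_ISO_PERIOD_RE = re.compile(
    r"^P(?:(?P<y>\d+(?:\.\d+)?)Y)?(?:(?P<m>\d+(?:\.\d+)?)M)?"
    r"(?:(?P<w>\d+(?:\.\d+)?)W)?(?:(?P<d>\d+(?:\.\d+)?)D)?$"
)


class PhenopacketError(ValueError):
    """Malformed phenopacket document or invalid cohort."""


@dataclass(frozen=True)
class AgeDuration:
    """An age expressed as an ISO-8601 period, e.g. ``P3Y6M``."""

    iso8601: str
    days: float

    @classmethod
    def parse(cls, iso: str) -> "AgeDuration":
        m = _ISO_PERIOD_RE.match(iso)
        if not m or iso == "P":
            raise PhenopacketError(f"unparseable ISO-8601 period: {iso!r}")
        y = float(m.group("y") or 0)
        mo = float(m.group("m") or 0)
        w = float(m.group("w") or 0)
        d = float(m.group("d") or 0)
        days = y * DAYS_PER_YEAR + mo * DAYS_PER_MONTH + w * 7 + d
        return cls(iso8601=iso, days=days)

    @property
    def years(self) -> float:
        return self.days / DAYS_PER_YEAR


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class VitalStatus(enum.Enum):
    ALIVE = "ALIVE"
    DECEASED = "DECEASED"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class PhenotypeObservation:
    """One observed or excluded HPO term, optionally with onset age."""

    term: TermId
    status: ObservationStatus
    onset: Optional[AgeDuration] = None

    def __post_init__(self) -> None:
        if self.onset is not None and self.status is not ObservationStatus.OBSERVED:
            raise PhenopacketError(f"onset given for non-observed term {self.term}")


@dataclass(frozen=True)
class VariantRecord:
    """A causal variant carried by one individual.

    Coordinates follow VCF convention (1-based, explicit ref/alt); protein
    residues and exon numbers are 1-based; ``protein_range`` is inclusive.
    ``change_length`` is alt length minus ref length (0 for substitutions,
    negative for deletions).  Symbolic / structural variants may omit the
    sequence fields and carry ``structural_type`` instead.
    """

    key: str
    effects: frozenset[str] = field(default_factory=frozenset)
    contig: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    structural_type: Optional[str] = None
    protein_range: Optional[tuple[int, int]] = None
    exons: frozenset[int] = field(default_factory=frozenset)
    change_length: Optional[int] = None
    allele_count_in_individual: int = 1

    def __post_init__(self) -> None:
        if self.allele_count_in_individual not in (1, 2):
            raise PhenopacketError(
                f"variant {self.key}: allele count must be 1 or 2, "
                f"got {self.allele_count_in_individual}"
            )
        if self.pos is not None and self.pos < 1:
            raise PhenopacketError(f"variant {self.key}: pos must be >= 1")
        if self.ref is not None and self.alt is not None:
            implied = len(self.alt) - len(self.ref)
            if self.change_length is not None and self.change_length != implied:
                raise PhenopacketError(
                    f"variant {self.key}: change_length {self.change_length} "
                    f"inconsistent with ref/alt ({implied})"
                )
            if self.change_length is None:
                object.__setattr__(self, "change_length", implied)
        if self.protein_range is not None:
            s, e = self.protein_range
            if not (1 <= s <= e):
                raise PhenopacketError(f"variant {self.key}: bad protein_range {self.protein_range}")


@dataclass(frozen=True)
class MeasurementValue:
    """One numeric assay result, coded (e.g. LOINC) with a UCUM unit."""

    assay: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if not self.unit:
            raise PhenopacketError("measurement unit must be non-empty")
        if not (self.value == self.value and abs(self.value) != float("inf")):
            raise PhenopacketError(f"measurement value must be finite: {self.value}")


@dataclass(frozen=True)
class Individual:
    """One phenopacket's clinical trajectory."""

    id: str
    sex: Sex = Sex.UNKNOWN
    age_last_encounter: Optional[AgeDuration] = None
    vital_status: VitalStatus = VitalStatus.UNKNOWN
    age_at_death: Optional[AgeDuration] = None
    diseases: tuple[tuple[str, Optional[AgeDuration]], ...] = ()
    phenotypes: tuple[PhenotypeObservation, ...] = ()
    variants: tuple[VariantRecord, ...] = ()
    measurements: tuple[MeasurementValue, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise PhenopacketError("individual id must be non-empty")
        if self.age_at_death is not None and self.vital_status is not VitalStatus.DECEASED:
            raise PhenopacketError(f"{self.id}: age_at_death given but vital status is not DECEASED")
        total_alleles = sum(v.allele_count_in_individual for v in self.variants)
        if self.variants and total_alleles not in (1, 2):
            raise PhenopacketError(
                f"{self.id}: total causal allele count must be 1 or 2, got {total_alleles}"
            )

    def propagated(self, graph: OntologyGraph):
        """Roll up this individual's annotations over the ontology."""
        return propagate(graph, [(p.term, p.status) for p in self.phenotypes])

    def measurement(self, assay: str) -> Optional[MeasurementValue]:
        for m in self.measurements:
            if m.assay == assay:
                return m
        return None


@dataclass(frozen=True)
class Cohort:
    individuals: tuple[Individual, ...]

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)


def build_cohort(individuals: Iterable[Individual]) -> Cohort:
    """Validate and assemble a cohort; duplicate ids are rejected."""
    inds = tuple(individuals)
    if not inds:
        raise PhenopacketError("a cohort must contain at least one individual")
    seen: dict[str, int] = {}
    dupes = []
    for ind in inds:
        if ind.id in seen:
            dupes.append(ind.id)
        seen[ind.id] = 1
    if dupes:
        raise PhenopacketError(f"duplicate individual ids: {sorted(set(dupes))}")
    return Cohort(individuals=inds)


# -- phenopacket JSON reading -------------------------------------------

_ALLELIC_STATE_COUNTS = {
    "homozygous": 2,
    "heterozygous": 1,
    "hemizygous": 1,
}


def _parse_age(block: Mapping, context: str) -> Optional[AgeDuration]:
    iso = None
    if "age" in block:
        iso = block["age"].get("iso8601duration")
    elif "iso8601duration" in block:
        iso = block["iso8601duration"]
    if iso is None:
        return None
    try:
        return AgeDuration.parse(iso)
    except PhenopacketError:
        warnings.warn(f"{context}: dropping unparseable onset {iso!r}")
        return None


def _parse_variant(gi: Mapping, idx: int) -> Optional[VariantRecord]:
    vi = gi.get("variantInterpretation", {})
    vd = vi.get("variationDescriptor", {})
    if not vd:
        return None
    key = vd.get("id") or f"variant-{idx}"
    vcf = vd.get("vcfRecord", {}) or {}
    allelic = (vd.get("allelicState", {}) or {}).get("label", "heterozygous")
    count = _ALLELIC_STATE_COUNTS.get(allelic.lower(), 1)
    ext = vd.get("extensions", {}) or {}
    prange = ext.get("proteinRange")
    return VariantRecord(
        key=key,
        effects=frozenset(ext.get("effects", []) or vd.get("effects", [])),
        contig=vcf.get("chrom"),
        pos=int(vcf["pos"]) if "pos" in vcf else None,
        ref=vcf.get("ref"),
        alt=vcf.get("alt"),
        structural_type=(vd.get("structuralType", {}) or {}).get("label"),
        protein_range=tuple(prange) if prange else None,
        exons=frozenset(ext.get("exons", [])),
        change_length=ext.get("changeLength"),
        allele_count_in_individual=count,
    )


def read_phenopacket(document: Union[str, Path, Mapping]) -> Individual:
    """Read one Phenopacket Schema v2 JSON document into an :class:`Individual`.

    Unrecognized fields are ignored; ``excluded: true`` maps to EXCLUDED;
    a homozygous allelic state yields allele count 2, heterozygous or
    hemizygous yields 1.
    """
    if isinstance(document, (str, Path)):
        with open(document) as fh:
            document = json.load(fh)
    pid = document.get("id")
    if not pid:
        raise PhenopacketError("phenopacket lacks an id")
    subject = document.get("subject", {}) or {}
    sex = Sex.__members__.get(subject.get("sex", "UNKNOWN"), Sex.UNKNOWN)
    age_last = _parse_age(subject.get("timeAtLastEncounter", {}) or {}, pid)
    vs_block = subject.get("vitalStatus", {}) or {}
    vital = VitalStatus.__members__.get(vs_block.get("status", "UNKNOWN"), VitalStatus.UNKNOWN)
    age_death = None
    if vital is VitalStatus.DECEASED and "timeOfDeath" in vs_block:
        age_death = _parse_age(vs_block["timeOfDeath"], pid)

    phenotypes = []
    for feat in document.get("phenotypicFeatures", []) or []:
        term = TermId(feat["type"]["id"])
        excluded = bool(feat.get("excluded", False))
        status = ObservationStatus.EXCLUDED if excluded else ObservationStatus.OBSERVED
        onset = None
        if not excluded and "onset" in feat:
            onset = _parse_age(feat["onset"], f"{pid}/{term}")
        phenotypes.append(PhenotypeObservation(term=term, status=status, onset=onset))

    diseases = []
    for dis in document.get("diseases", []) or []:
        did = dis["term"]["id"]
        onset = _parse_age(dis.get("onset", {}) or {}, f"{pid}/{did}")
        diseases.append((did, onset))

    measurements = []
    for meas in document.get("measurements", []) or []:
        assay = (meas.get("assay", {}) or {}).get("id", "")
        q = (meas.get("value", {}) or {}).get("quantity", {}) or {}
        if not assay or "value" not in q:
            continue
        measurements.append(
            MeasurementValue(
                assay=assay,
                value=float(q["value"]),
                unit=(q.get("unit", {}) or {}).get("id", "") or "1",
            )
        )

    variants = []
    idx = 0
    for interp in document.get("interpretations", []) or []:
        diag = (interp.get("diagnosis", {}) or {})
        for gi in diag.get("genomicInterpretations", []) or []:
            v = _parse_variant(gi, idx)
            if v is not None:
                variants.append(v)
                idx += 1

    return Individual(
        id=pid,
        sex=sex,
        age_last_encounter=age_last,
        vital_status=vital,
        age_at_death=age_death,
        diseases=tuple(diseases),
        phenotypes=tuple(phenotypes),
        variants=tuple(variants),
        measurements=tuple(measurements),
    )


def read_cohort_dir(directory: Union[str, Path]) -> Cohort:
    """Load every ``*.json`` phenopacket in a directory into a cohort."""
    paths = sorted(Path(directory).glob("*.json"))
    if not paths:
        raise PhenopacketError(f"no phenopacket JSON files in {directory}")
    return build_cohort(read_phenopacket(p) for p in paths)


# -- internal JSON dump (round-trippable) --------------------------------


def individual_to_dict(ind: Individual) -> dict:
    """Serialize an individual to the phenopacket-subset JSON dialect.

    The output reads back identically through :func:`read_phenopacket`.
    """
    doc: dict = {"id": ind.id, "subject": {"sex": ind.sex.value}}
    if ind.age_last_encounter is not None:
        doc["subject"]["timeAtLastEncounter"] = {
            "age": {"iso8601duration": ind.age_last_encounter.iso8601}
        }
    if ind.vital_status is not VitalStatus.UNKNOWN:
        vs: dict = {"status": ind.vital_status.value}
        if ind.age_at_death is not None:
            vs["timeOfDeath"] = {"age": {"iso8601duration": ind.age_at_death.iso8601}}
        doc["subject"]["vitalStatus"] = vs
    if ind.phenotypes:
        feats = []
        for p in ind.phenotypes:
            f: dict = {"type": {"id": str(p.term)}}
            if p.status is ObservationStatus.EXCLUDED:
                f["excluded"] = True
            if p.onset is not None:
                f["onset"] = {"age": {"iso8601duration": p.onset.iso8601}}
            feats.append(f)
        doc["phenotypicFeatures"] = feats
    if ind.diseases:
        doc["diseases"] = [
            {"term": {"id": did}, **({"onset": {"age": {"iso8601duration": onset.iso8601}}} if onset else {})}
            for did, onset in ind.diseases
        ]
    if ind.measurements:
        doc["measurements"] = [
            {"assay": {"id": m.assay}, "value": {"quantity": {"value": m.value, "unit": {"id": m.unit}}}}
            for m in ind.measurements
        ]
    if ind.variants:
        gis = []
        for v in ind.variants:
            vd: dict = {"id": v.key, "extensions": {}}
            if v.effects:
                vd["extensions"]["effects"] = sorted(v.effects)
            if v.exons:
                vd["extensions"]["exons"] = sorted(v.exons)
            if v.protein_range is not None:
                vd["extensions"]["proteinRange"] = list(v.protein_range)
            if v.change_length is not None and (v.ref is None or v.alt is None):
                vd["extensions"]["changeLength"] = v.change_length
            if v.contig is not None:
                vd["vcfRecord"] = {"chrom": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt}
            if v.structural_type is not None:
                vd["structuralType"] = {"label": v.structural_type}
            state = "homozygous" if v.allele_count_in_individual == 2 else "heterozygous"
            vd["allelicState"] = {"label": state}
            gis.append({"variantInterpretation": {"variationDescriptor": vd}})
        doc["interpretations"] = [{"diagnosis": {"genomicInterpretations": gis}}]
    return doc


def write_cohort_dir(cohort: Cohort, directory: Union[str, Path]) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for ind in cohort:
        with open(d / f"{ind.id}.json", "w") as fh:
            json.dump(individual_to_dict(ind), fh, indent=1, sort_keys=True)


# -- summary tables ------------------------------------------------------


def cohort_summary(cohort: Cohort, graph: OntologyGraph, top_k: int = 20) -> dict[str, pd.DataFrame]:
    """Descriptive tables: n, sex, top propagated HPO terms, diseases, variants."""
    n = len(cohort)
    sex_counts = pd.Series([i.sex.value for i in cohort]).value_counts()
    term_obs: dict[str, int] = {}
    for ind in cohort:
        for t in ind.propagated(graph).observed():
            term_obs[t] = term_obs.get(t, 0) + 1
    terms = (
        pd.DataFrame(
            [(t, graph.label(t), c) for t, c in term_obs.items()],
            columns=["term", "label", "n_observed"],
        )
        .sort_values(["n_observed", "term"], ascending=[False, True])
        .head(top_k)
        .reset_index(drop=True)
    )
    diseases = pd.Series([d for i in cohort for d, _ in i.diseases]).value_counts()
    effect_alleles: dict[str, int] = {}
    variant_alleles: dict[str, int] = {}
    for ind in cohort:
        for v in ind.variants:
            variant_alleles[v.key] = variant_alleles.get(v.key, 0) + v.allele_count_in_individual
            for eff in v.effects:
                effect_alleles[eff] = effect_alleles.get(eff, 0) + v.allele_count_in_individual
    total_alleles = sum(variant_alleles.values())
    variants = pd.DataFrame(
        [(k, c, c / total_alleles if total_alleles else 0.0) for k, c in sorted(variant_alleles.items())],
        columns=["variant", "allele_count", "allele_frequency"],
    )
    return {
        "overview": pd.DataFrame({"n_individuals": [n]}),
        "sex": sex_counts.rename_axis("sex").to_frame("count"),
        "hpo_terms": terms,
        "diseases": diseases.rename_axis("disease").to_frame("count"),
        "variant_effects": pd.Series(effect_alleles, dtype="int64").rename_axis("effect").to_frame("allele_count").sort_index(),
        "variants": variants,
    }
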