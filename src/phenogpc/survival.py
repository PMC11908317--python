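"""Right-censored time-to-event endpoints derived from clinical records.

Three endpoint kinds are supported: death, disease onset, and onset of a
phenotypic feature (HPO term).  For HPO-term endpoints the ontology is used
to roll annotations up: if the endpoint is *Seizure* and the individual has
onsets for *Tonic seizure* and *Generalized myoclonic seizure*, the event
time is the youngest of those onsets.  An individual without the event but
with a known age at last encounter is right-censored at that age.  Missing
data are never imputed — an observed endpoint term without an onset age
makes the individual MISSING (returned as None) rather than an event at an
unknown time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Individual, VitalStatus
from .ontology import ObservationStatus, OntologyGraph, TermId

__all__ = [
    "SurvivalDatum",
    "EndpointKind",
    "Endpoint",
    "endpoint_observation",
    "km_table",
]


@dataclass(frozen=True)
class SurvivalDatum:
    """A duration in days and whether the event was observed (vs censored)."""

    duration_days: float
    event: bool

    def __post_init__(self) -> None:
        if not (self.duration_days > 0 and self.duration_days < float("inf")):
            raise ValueError(f"duration must be finite and positive: {self.duration_days}")


class EndpointKind(enum.Enum):
    DEATH = "DEATH"
    DISEASE_ONSET = "DISEASE_ONSET"
    TERM_ONSET = "TERM_ONSET"


@dataclass(frozen=True)
class Endpoint:
    kind: EndpointKind
    target: Optional[str] = None  # disease id or HPO term id

    def __post_init__(self) -> None:
        if self.kind is not EndpointKind.DEATH and not self.target:
            raise ValueError(f"{self.kind.value} endpoint requires a target id")

    @classmethod
    def death(cls) -> "Endpoint":
        return cls(kind=EndpointKind.DEATH)

    @classmethod
    def disease_onset(cls, disease_id: str) -> "Endpoint":
        return cls(kind=EndpointKind.DISEASE_ONSET, target=disease_id)

    @classmethod
    def term_onset(cls, term: str) -> "Endpoint":
        return cls(kind=EndpointKind.TERM_ONSET, target=term)


def endpoint_observation(
    individual: Individual, graph: OntologyGraph, endpoint: Endpoint
) -> Optional[SurvivalDatum]:
    """Derive one survival datum, or None when timing is unusable (MISSING)."""
    if endpoint.kind is EndpointKind.DEATH:
        return _death_observation(individual)
    if endpoint.kind is EndpointKind.DISEASE_ONSET:
        return _disease_onset_observation(individual, endpoint.target)
    return _term_onset_observation(individual, graph, endpoint.target)


def _censored_at_last_encounter(individual: Individual) -> Optional[SurvivalDatum]:
    if individual.age_last_encounter is None or individual.age_last_encounter.days <= 0:
        return None
    return SurvivalDatum(duration_days=individual.age_last_encounter.days, event=False)


def _death_observation(ind: Individual) -> Optional[SurvivalDatum]:
    if ind.vital_status is VitalStatus.DECEASED:
        if ind.age_at_death is None or ind.age_at_death.days <= 0:
            return None
        return SurvivalDatum(duration_days=ind.age_at_death.days, event=True)
    # alive or unknown: censored at last encounter when known
    return _censored_at_last_encounter(ind)


def _disease_onset_observation(ind: Individual, disease_id: str) -> Optional[SurvivalDatum]:
    for did, onset in ind.diseases:
        if did == disease_id:
            if onset is None or onset.days <= 0:
                return None  # diagnosed but onset unknown: no imputation
            return SurvivalDatum(duration_days=onset.days, event=True)
    return _censored_at_last_encounter(ind)


def _term_onset_observation(
    ind: Individual, graph: OntologyGraph, term: str
) -> Optional[SurvivalDatum]:
    target = graph.primary(term)
    region = graph.descendants(target, include_self=True)
    onsets: list[float] = []
    observed_without_onset = False
    for p in ind.phenotypes:
        if p.status is not ObservationStatus.OBSERVED:
            continue
        if graph.primary(p.term) not in region:
            continue
        if p.onset is None or p.onset.days <= 0:
            observed_without_onset = True
        else:
            onsets.append(p.onset.days)
    if observed_without_onset:
        return None  # event happened at an unknown time
    if onsets:
        return SurvivalDatum(duration_days=min(onsets), event=True)
    # no observation of the endpoint (including explicit exclusion):
    # censored at last encounter when known
    return _censored_at_last_encounter(ind)


def km_table(data: list[SurvivalDatum], label: str = "KM") -> pd.DataFrame:
    """Kaplan-Meier table (time, at-risk, events, survival) for export."""
    if not data:
        return pd.DataFrame(columns=["time_days", "at_risk", "events", "survival"])
    kmf = KaplanMeierFitter(label=label)
    kmf.fit([d.duration_days for d in data], [d.event for d in data])
    ev = kmf.event_table
    surv = kmf.survival_function_[label]
    return pd.DataFrame(
        {
            "time_days": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "events": ev["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(ev.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
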