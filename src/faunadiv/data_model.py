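"""Domain types and the status-category algebra.

Per-region faunal change is encoded as one status category per
(species, region) pair.  Six categories describe how a species relates to
a region over the study window (roughly 8000 years before present up to
2020), and the algebra below turns those categories into species sets at
each timepoint and into the loss/gain sets that drive the diversity
decomposition:

* ``NATIVE_PERSISTING`` -- native at the start, still present in 2020.
* ``NATIVE_EXTIRPATED`` -- native at the start, lost from the region and
  not present in 2020 (the loss may or may not be a global extinction).
* ``NATIVE_REGAINED`` -- native at the start, lost, and present again in
  2020 through reintroduction or natural recolonization.
* ``NATIVE_COLONIST`` -- not present at the start; arrived by natural
  range expansion and present in 2020.
* ``INTRODUCED`` -- not present at the start; established through human
  introduction and present in 2020.
* ``FUTURE_POTENTIAL`` -- not in the 2020 assemblage but identified as a
  candidate for future reintroduction or recolonization (including
  surrogates for globally extinct species).

The ``recent`` flag dichotomizes change events at 1945 (events in or
after 1945 are "recent"), which supports an intermediate mid-20th-century
assemblage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "DIET_VARS",
    "ACTIVITY_VARS",
    "FORAGING_STRATA",
    "StatusCategory",
    "Timepoint",
    "Subgroup",
    "SpeciesRecord",
    "StatusRecord",
    "Region",
    "RegionalAssemblage",
    "assemble",
    "loss_gain_sets",
    "subgroup_filter",
]

#: Diet composition variables (percentages summing to 100).
DIET_VARS = (
    "diet_inv",
    "diet_vert",
    "diet_fish",
    "diet_scav",
    "diet_fruit",
    "diet_seed",
    "diet_plant",
)

#: Activity-period binary flags; at least one must be set per species.
ACTIVITY_VARS = ("act_nocturnal", "act_crepuscular", "act_diurnal")

#: Recognized foraging-stratum labels.
FORAGING_STRATA = ("ground", "scansorial", "arboreal", "aerial", "marine")

#: Mass threshold (grams) splitting large from small non-volant mammals.
LARGE_MASS_THRESHOLD_G = 2000.0


class StatusCategory(enum.Enum):
    """How a species relates to a region across the study window."""

    NATIVE_PERSISTING = "NATIVE_PERSISTING"
    NATIVE_EXTIRPATED = "NATIVE_EXTIRPATED"
    NATIVE_REGAINED = "NATIVE_REGAINED"
    NATIVE_COLONIST = "NATIVE_COLONIST"
    INTRODUCED = "INTRODUCED"
    FUTURE_POTENTIAL = "FUTURE_POTENTIAL"


#: Categories for which the 1945 era flag carries no information.
_NO_ERA = {StatusCategory.NATIVE_PERSISTING, StatusCategory.FUTURE_POTENTIAL}


class Timepoint(enum.Enum):
    """Assemblage snapshots supported by the analysis."""

    BP8000 = "BP8000"
    Y1945 = "Y1945"
    Y2020 = "Y2020"
    FUTURE = "FUTURE"


class Subgroup(enum.Enum):
    """Species subsets used for the supplementary-style analyses."""

    ALL = "all"
    LARGE_NONVOLANT = "large_nonvolant"
    SMALL_NONVOLANT = "small_nonvolant"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species with its functional traits and bookkeeping flags.

    Parameters
    ----------
    species_id:
        Unique key; must match tree tip labels and trait-space rows.
    mass_g:
        Adult body mass in grams, strictly positive.
    diet_pct:
        Seven diet-category percentages (order of :data:`DIET_VARS`)
        summing to 100.
    foraging_stratum:
        One label from :data:`FORAGING_STRATA`.
    activity:
        Three binary flags (nocturnal, crepuscular, diurnal); at least
        one set.
    habitat:
        Set of habitat-class labels (multi-label).
    volant:
        True for bats (powered flight).
    globally_extinct:
        True if no wild population survives anywhere.
    surrogate_available:
        True if a living relative or domestic descendant can stand in
        for the species in future-reintroduction scenarios.
    """

    species_id: str
    name: str
    mass_g: float
    diet_pct: tuple[float, ...]
    foraging_stratum: str
    activity: tuple[bool, bool, bool]
    habitat: frozenset[str] = field(default_factory=frozenset)
    volant: bool = False
    globally_extinct: bool = False
    surrogate_available: bool = False

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not (isinstance(self.mass_g, (int, float)) and math.isfinite(self.mass_g)):
            raise ValueError(f"{self.species_id}: mass_g missing or non-finite")
        if self.mass_g <= 0:
            raise ValueError(f"{self.species_id}: mass_g must be positive, got {self.mass_g}")
        if len(self.diet_pct) != len(DIET_VARS):
            raise ValueError(
                f"{self.species_id}: expected {len(DIET_VARS)} diet percentages, "
                f"got {len(self.diet_pct)}"
            )
        if any(p < 0 for p in self.diet_pct):
            raise ValueError(f"{self.species_id}: diet percentages must be non-negative")
        total = sum(self.diet_pct)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"{self.species_id}: diet percentages sum to {total}, not 100")
        if self.foraging_stratum not in FORAGING_STRATA:
            raise ValueError(
                f"{self.species_id}: unknown foraging stratum {self.foraging_stratum!r}"
            )
        if len(self.activity) != 3 or not any(self.activity):
            raise ValueError(f"{self.species_id}: at least one activity flag must be set")


@dataclass(frozen=True)
class StatusRecord:
    """Status of one species in one region.

    ``recent`` is True when the change event occurred in or after 1945,
    False when it occurred earlier, and None for categories without a
    change event (persisting natives and future candidates).
    """

    species_id: str
    region_id: str
    category: StatusCategory
    recent: bool | None = None

    def __post_init__(self) -> None:
        if self.category in _NO_ERA:
            if self.recent is not None:
                raise ValueError(
                    f"({self.species_id}, {self.region_id}): recent flag is "
                    f"meaningless for {self.category.value}"
                )
        elif self.recent is None:
            raise ValueError(
                f"({self.species_id}, {self.region_id}): recent flag required "
                f"for {self.category.value}"
            )


@dataclass(frozen=True)
class Region:
    region_id: str
    name: str
    island: bool


@dataclass(frozen=True)
class RegionalAssemblage:
    """The species set present in one region at one timepoint."""

    region_id: str
    timepoint: Timepoint
    species_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.species_ids)


# Categories contributing to each snapshot.
_BP8000_CATS = {
    StatusCategory.NATIVE_PERSISTING,
    StatusCategory.NATIVE_EXTIRPATED,
    StatusCategory.NATIVE_REGAINED,
}
_Y2020_CATS = {
    StatusCategory.NATIVE_PERSISTING,
    StatusCategory.NATIVE_REGAINED,
    StatusCategory.NATIVE_COLONIST,
    StatusCategory.INTRODUCED,
}
_LOSS_CATS = {StatusCategory.NATIVE_EXTIRPATED, StatusCategory.NATIVE_REGAINED}
_GAIN_CATS = {
    StatusCategory.NATIVE_REGAINED,
    StatusCategory.NATIVE_COLONIST,
    StatusCategory.INTRODUCED,
}


def _region_records(
    status_records: list[StatusRecord], region_id: str
) -> list[StatusRecord]:
    records = [r for r in status_records if r.region_id == region_id]
    if not any(r.region_id == region_id for r in status_records) and not records:
        # Distinguish "region absent from table" from "region with no records"
        # only when the table is non-empty; an empty table yields an empty
        # assemblage (vacuous case).
        if status_records:
            raise KeyError(f"region {region_id!r} has no status records")
    seen: set[str] = set()
    for r in records:
        if r.species_id in seen:
            raise ValueError(
                f"duplicate status record for ({r.species_id}, {region_id})"
            )
        seen.add(r.species_id)
    return records


def assemble(
    status_records: list[StatusRecord],
    region_id: str,
    timepoint: Timepoint | str,
) -> RegionalAssemblage:
    """Resolve the species set present in ``region_id`` at ``timepoint``.

    The snapshots follow from the category definitions:

    * BP8000: all natives (persisting, extirpated, regained).
    * Y2020: persisting and regained natives, colonists, introductions.
    * FUTURE: the 2020 set plus future-potential candidates.
    * Y1945: the BP8000 set minus pre-1945 losses plus pre-1945 gains
      (a regained species whose record is flagged pre-1945 has both been
      lost and returned by 1945; one flagged recent has not yet been
      lost -- either way it is present at 1945).
    """
    if isinstance(timepoint, str):
        try:
            timepoint = Timepoint(timepoint)
        except ValueError as exc:
            raise ValueError(f"unknown timepoint {timepoint!r}") from exc
    records = _region_records(status_records, region_id)

    if timepoint is Timepoint.BP8000:
        ids = {r.species_id for r in records if r.category in _BP8000_CATS}
    elif timepoint is Timepoint.Y2020:
        ids = {r.species_id for r in records if r.category in _Y2020_CATS}
    elif timepoint is Timepoint.FUTURE:
        ids = {
            r.species_id
            for r in records
            if r.category in _Y2020_CATS or r.category is StatusCategory.FUTURE_POTENTIAL
        }
    elif timepoint is Timepoint.Y1945:
        ids = {r.species_id for r in records if r.category in _BP8000_CATS}
        for r in records:
            if r.recent is False:
                if r.category is StatusCategory.NATIVE_EXTIRPATED:
                    ids.discard(r.species_id)
                elif r.category in _GAIN_CATS:
                    ids.add(r.species_id)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown timepoint {timepoint!r}")
    return RegionalAssemblage(region_id, timepoint, frozenset(ids))


def loss_gain_sets(
    status_records: list[StatusRecord], region_id: str
) -> tuple[frozenset[str], frozenset[str]]:
    """Species lost from and gained by a region between 8000 BP and 2020.

    A regained species appears in *both* sets: it was extirpated (a loss
    relative to the starting assemblage) and later returned (a gain).
    This double counting is what makes the loss/gain/net decomposition
    additive: ``(BP8000 \\ losses) | gains == Y2020`` exactly.
    """
    records = _region_records(status_records, region_id)
    loss = frozenset(r.species_id for r in records if r.category in _LOSS_CATS)
    gain = frozenset(r.species_id for r in records if r.category in _GAIN_CATS)
    return loss, gain


def subgroup_filter(
    species: list[SpeciesRecord], group: Subgroup | str
) -> list[SpeciesRecord]:
    """Filter a species list to an analysis subgroup.

    ``large_nonvolant`` is strictly above 2 kg and ``small_nonvolant`` at
    or below 2 kg, so the two groups partition the non-volant species.
    """
    group = Subgroup(group) if isinstance(group, str) else group
    if group is Subgroup.ALL:
        return list(species)
    for rec in species:
        if rec.mass_g is None or not math.isfinite(rec.mass_g):  # defensive
            raise ValueError(f"{rec.species_id}: mass required for subgroup filtering")
    if group is Subgroup.LARGE_NONVOLANT:
        return [s for s in species if not s.volant and s.mass_g > LARGE_MASS_THRESHOLD_G]
    return [s for s in species if not s.volant and s.mass_g <= LARGE_MASS_THRESHOLD_G]
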