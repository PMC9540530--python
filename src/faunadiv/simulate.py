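"""Synthetic input generation: trees, traits, regions and status tables.

The generator produces complete, self-consistent datasets with the
statistical structure the turnover analysis assumes: a continental
species pool (~228 species), an ensemble of dated ultrametric trees over
that pool, mixed-type trait tables, and per-region status tables in
which islands are depauperate (fewer natives) but proportionally more
exposed to introductions and extirpations than continental regions.

Trees are Yule (pure-birth) trees: exponential waiting times between
speciation events, every lineage equally likely to split, tips extended
to the present so the tree is ultrametric.  Dating realism is irrelevant
here -- only the branch-length algebra of the diversity metrics matters.

A deterministic single-region continental fixture reproduces the
bookkeeping of the European mammal pool: 198 species present 8000 years
ago, 17 of them extirpated continent-wide (12 globally extinct), 30
introduced species, 211 present in 2020, 228 species in total.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_model import (
    DIET_VARS,
    FORAGING_STRATA,
    Region,
    SpeciesRecord,
    StatusCategory,
    StatusRecord,
)
from .phylo import PhyloTreeEnsemble, parse_newick

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_trees",
    "simulate_traits",
    "simulate_status",
    "simulate_dataset",
    "continental_fixture",
]

HABITAT_LABELS = ("forest", "grassland", "wetland", "rocky", "shrubland", "urban")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults mirror the scale of the European mammal analysis: a pool of
    228 species over 45 regions (islands depauperate relative to the
    mainland), a 100-tree ensemble for routine runs (1000 for full-scale
    ones), log-normal body masses spanning several orders of magnitude,
    Dirichlet diet compositions, and island/continental contrasts in
    extirpation and introduction pressure.
    """

    seed: int
    n_species: int = 228
    n_trees: int = 100
    n_regions: int = 45
    island_fraction: float = 0.4
    # Expected native richness at 8000 BP per region class.
    mean_island_richness: float = 25.0
    mean_continental_richness: float = 120.0
    # Per-native-species category probabilities (rest persist).
    p_extirpated_island: float = 0.12
    p_extirpated_continental: float = 0.05
    p_regained_island: float = 0.02
    p_regained_continental: float = 0.04
    # Expected numbers of gained species per region.
    mean_introduced_island: float = 12.0
    mean_introduced_continental: float = 6.0
    mean_colonist_island: float = 1.0
    mean_colonist_continental: float = 2.0
    # Expected number of future-reintroduction candidates per region.
    mean_future_island: float = 1.0
    mean_future_continental: float = 4.0
    p_recent: float = 0.5
    # Trait distribution parameters.
    log_mass_mean: float = 2.0
    log_mass_sd: float = 1.1
    volant_log_mass_mean: float = 1.0
    volant_log_mass_sd: float = 0.3
    diet_concentration: float = 0.5
    volant_fraction: float = 0.08
    n_globally_extinct: int = 12
    n_with_surrogate: int = 5
    stratum_probs: tuple[float, ...] = (0.55, 0.15, 0.2, 0.0, 0.1)
    activity_probs: tuple[float, float, float] = (0.5, 0.3, 0.5)
    habitat_prob: float = 0.4
    birth_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        for name in (
            "island_fraction",
            "p_extirpated_island",
            "p_extirpated_continental",
            "p_regained_island",
            "p_regained_continental",
            "p_recent",
            "volant_fraction",
            "habitat_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.stratum_probs) - 1.0) > 1e-9:
            raise ValueError("stratum_probs must sum to 1")
        for cls in ("island", "continental"):
            total = getattr(self, f"p_extirpated_{cls}") + getattr(self, f"p_regained_{cls}")
            if total > 1.0:
                raise ValueError(
                    f"{cls} extirpation + regain probabilities exceed 1 ({total})"
                )
        if self.n_with_surrogate > self.n_globally_extinct:
            raise ValueError("cannot have more surrogates than extinct species")


@dataclass
class SyntheticDataset:
    """A complete input bundle: traits, regions, statuses and trees."""

    species: list[SpeciesRecord]
    regions: list[Region]
    status_records: list[StatusRecord]
    ensemble: PhyloTreeEnsemble
    config: SimulationConfig | None = None

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]


def _species_labels(n: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(1, n + 1)]


class _YuleNode:
    __slots__ = ("birth", "children", "label", "length")

    def __init__(self, birth: float):
        self.birth = birth
        self.children: list[_YuleNode] = []
        self.label: str | None = None
        self.length: float = 0.0


def _yule_newick(labels: list[str], rng: np.random.Generator, birth_rate: float) -> str:
    """One ultrametric pure-birth tree in Newick form, tips shuffled."""
    n = len(labels)
    root = _YuleNode(0.0)
    root.children = [_YuleNode(0.0), _YuleNode(0.0)]
    active = list(root.children)
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(k)
        node = active[idx]
        node.children = [_YuleNode(t), _YuleNode(t)]
        active[idx] = node.children[0]
        active.append(node.children[1])
    t += rng.exponential(1.0 / (birth_rate * n))  # terminal hold
    order = rng.permutation(n)
    for lab_idx, node in zip(order, active):
        node.label = labels[lab_idx]

    def render(node: _YuleNode, end: float) -> str:
        if node.children:
            end_here = node.children[0].birth
            inner = ",".join(render(c, t) for c in node.children)
            body = f"({inner})"
        else:
            end_here = end
            body = node.label
        return f"{body}:{end_here - node.birth:.10f}"

    inner = ",".join(render(c, t) for c in root.children)
    return f"({inner});"


def simulate_trees(config: SimulationConfig, labels: list[str] | None = None) -> PhyloTreeEnsemble:
    """Simulate an ensemble of Yule trees over one shared tip set."""
    rng = np.random.default_rng(config.seed)
    if labels is None:
        labels = _species_labels(config.n_species)
    lines = [
        _yule_newick(labels, rng, config.birth_rate) for _ in range(config.n_trees)
    ]
    return parse_newick("\n".join(lines))


def _round_to_100(raw: np.ndarray) -> tuple[float, ...]:
    """Largest-remainder rounding of a composition to integers summing 100."""
    scaled = raw / raw.sum() * 100.0
    floors = np.floor(scaled)
    shortfall = int(round(100 - floors.sum()))
    order = np.argsort(-(scaled - floors), kind="stable")
    out = floors.copy()
    out[order[:shortfall]] += 1
    return tuple(float(x) for x in out)


def simulate_traits(config: SimulationConfig) -> list[SpeciesRecord]:
    """Draw a complete trait table for the species pool."""
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_species
    labels = _species_labels(n)
    n_volant = int(round(config.volant_fraction * n))
    volant_ids = set(rng.choice(n, size=n_volant, replace=False)) if n_volant else set()
    nonvolant = [i for i in range(n) if i not in volant_ids]
    extinct_ids = set(
        rng.choice(nonvolant, size=min(config.n_globally_extinct, len(nonvolant)), replace=False)
    )
    surrogate_ids = set(
        rng.choice(sorted(extinct_ids), size=config.n_with_surrogate, replace=False)
        if extinct_ids
        else []
    )
    records = []
    for i in range(n):
        volant = i in volant_ids
        if volant:
            logm = rng.normal(config.volant_log_mass_mean, config.volant_log_mass_sd)
            stratum = "aerial"
        else:
            logm = rng.normal(config.log_mass_mean, config.log_mass_sd)
            stratum = FORAGING_STRATA[
                rng.choice(len(config.stratum_probs), p=config.stratum_probs)
            ]
        diet = _round_to_100(
            rng.dirichlet(np.full(len(DIET_VARS), config.diet_concentration))
            + 1e-12
        )
        activity = tuple(rng.random() < p for p in config.activity_probs)
        if not any(activity):
            activity = (True, activity[1], activity[2])
        habitat = frozenset(
            h for h in HABITAT_LABELS if rng.random() < config.habitat_prob
        )
        if not habitat:
            habitat = frozenset({HABITAT_LABELS[int(rng.integers(len(HABITAT_LABELS)))]})
        records.append(
            SpeciesRecord(
                species_id=labels[i],
                name=f"Species {labels[i][2:]}",
                mass_g=float(10.0**logm),
                diet_pct=diet,
                foraging_stratum=stratum,
                activity=activity,
                habitat=habitat,
                volant=volant,
                globally_extinct=i in extinct_ids,
                surrogate_available=i in surrogate_ids,
            )
        )
    return records


def simulate_status(
    config: SimulationConfig, species: list[SpeciesRecord]
) -> tuple[list[StatusRecord], list[Region]]:
    """Draw regions and per-region status tables.

    Islands draw fewer natives but face proportionally more extirpation
    and introduction pressure than continental regions.  Globally
    extinct species can only be extirpated natives (or surrogate-backed
    future candidates); they never appear in any 2020 assemblage.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_islands = int(round(config.island_fraction * config.n_regions))
    regions = []
    for i in range(1, config.n_regions + 1):
        island = i <= n_islands
        kind = "Island" if island else "Mainland"
        regions.append(Region(f"reg{i:03d}", f"{kind} {i}", island))

    ids = [sp.species_id for sp in species]
    extinct = {sp.species_id for sp in species if sp.globally_extinct}
    surrogate = {sp.species_id for sp in species if sp.surrogate_available}
    records: list[StatusRecord] = []
    for region in regions:
        if region.island:
            mean_rich = config.mean_island_richness
            p_ext, p_reg = config.p_extirpated_island, config.p_regained_island
            mean_intro = config.mean_introduced_island
            mean_col = config.mean_colonist_island
            mean_future = config.mean_future_island
        else:
            mean_rich = config.mean_continental_richness
            p_ext, p_reg = config.p_extirpated_continental, config.p_regained_continental
            mean_intro = config.mean_introduced_continental
            mean_col = config.mean_colonist_continental
            mean_future = config.mean_future_continental
        n_native = int(np.clip(rng.poisson(mean_rich), 2, len(ids)))
        natives = list(rng.choice(ids, size=n_native, replace=False))
        assigned: dict[str, StatusCategory] = {}
        for sp_id in natives:
            u = rng.random()
            if sp_id in extinct:
                # A globally extinct species cannot persist to 2020; it is
                # either an extirpation or (if regained pre-extinction
                # elsewhere is impossible) simply extirpated.
                cat = StatusCategory.NATIVE_EXTIRPATED
            elif u < p_ext:
                cat = StatusCategory.NATIVE_EXTIRPATED
            elif u < p_ext + p_reg:
                cat = StatusCategory.NATIVE_REGAINED
            else:
                cat = StatusCategory.NATIVE_PERSISTING
            assigned[sp_id] = cat
        remaining = [s for s in ids if s not in assigned and s not in extinct]
        rng.shuffle(remaining)
        n_intro = min(rng.poisson(mean_intro), len(remaining))
        for sp_id in remaining[:n_intro]:
            assigned[sp_id] = StatusCategory.INTRODUCED
        rest = remaining[n_intro:]
        n_col = min(rng.poisson(mean_col), len(rest))
        for sp_id in rest[:n_col]:
            assigned[sp_id] = StatusCategory.NATIVE_COLONIST
        # Future candidates: unassigned species, skipping extinct ones
        # without a surrogate (nothing could be reintroduced for those).
        pool = [
            s
            for s in ids
            if s not in assigned and (s not in extinct or s in surrogate)
        ]
        rng.shuffle(pool)
        n_future = min(rng.poisson(mean_future), len(pool))
        for sp_id in pool[:n_future]:
            assigned[sp_id] = StatusCategory.FUTURE_POTENTIAL
        for sp_id in sorted(assigned):
            cat = assigned[sp_id]
            recent = None
            if cat not in (StatusCategory.NATIVE_PERSISTING, StatusCategory.FUTURE_POTENTIAL):
                recent = bool(rng.random() < config.p_recent)
            records.append(StatusRecord(sp_id, region.region_id, cat, recent))
    return records, regions


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic input bundle from one config."""
    species = simulate_traits(config)
    status, regions = simulate_status(config, species)
    ensemble = simulate_trees(config, [sp.species_id for sp in species])
    return SyntheticDataset(species, regions, status, ensemble, config)


# --- deterministic continental fixture -------------------------------------

_FIXTURE_SEED = 20220807
_FIXTURE_N_SPECIES = 228
_FIXTURE_N_BP8000 = 198
_FIXTURE_N_EXTIRPATED = 17
_FIXTURE_N_REGAINED = 10
_FIXTURE_N_INTRODUCED = 30
_FIXTURE_N_EXTINCT = 12
_FIXTURE_N_SURROGATE = 5


def continental_fixture(n_trees: int = 25) -> SyntheticDataset:
    """Deterministic whole-continent dataset matching the European pool.

    One continental region with 198 native species at 8000 BP, of which
    17 were extirpated continent-wide (12 of those globally extinct,
    5 with living surrogates) and 10 extirpated-then-regained, plus 30
    introduced species: 211 species in 2020 and 228 in total.
    """
    config = SimulationConfig(
        seed=_FIXTURE_SEED,
        n_species=_FIXTURE_N_SPECIES,
        n_trees=n_trees,
        n_regions=1,
        n_globally_extinct=0,  # flags are assigned deterministically below
        n_with_surrogate=0,
    )
    species = simulate_traits(config)
    labels = [sp.species_id for sp in species]

    n_persist = _FIXTURE_N_BP8000 - _FIXTURE_N_EXTIRPATED - _FIXTURE_N_REGAINED
    persisting = labels[:n_persist]
    regained = labels[n_persist : n_persist + _FIXTURE_N_REGAINED]
    extirpated = labels[
        n_persist + _FIXTURE_N_REGAINED : _FIXTURE_N_BP8000
    ]
    introduced = labels[_FIXTURE_N_BP8000 :]
    assert len(introduced) == _FIXTURE_N_INTRODUCED

    extinct = set(extirpated[: _FIXTURE_N_EXTINCT])
    with_surrogate = set(extirpated[: _FIXTURE_N_SURROGATE])
    species = [
        replace(
            sp,
            volant=False if sp.species_id in extinct else sp.volant,
            globally_extinct=sp.species_id in extinct,
            surrogate_available=sp.species_id in with_surrogate,
        )
        for sp in species
    ]

    region = Region("europe", "Whole continent", island=False)
    records = [
        StatusRecord(s, "europe", StatusCategory.NATIVE_PERSISTING) for s in persisting
    ]
    records += [
        StatusRecord(s, "europe", StatusCategory.NATIVE_REGAINED, recent=(i % 2 == 0))
        for i, s in enumerate(regained)
    ]
    records += [
        StatusRecord(s, "europe", StatusCategory.NATIVE_EXTIRPATED, recent=(i % 3 == 0))
        for i, s in enumerate(extirpated)
    ]
    records += [
        StatusRecord(s, "europe", StatusCategory.INTRODUCED, recent=(i % 2 == 0))
        for i, s in enumerate(introduced)
    ]
    ensemble = simulate_trees(config, labels)
    return SyntheticDataset(species, [region], records, ensemble, config)
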