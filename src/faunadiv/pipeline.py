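"""Per-region diversity, the loss/gain/net decomposition, and summaries.

Each region's assemblage is measured at each timepoint with three
metrics, all scaled to [0, 1] against the full species pool so values
are comparable across metrics and regions:

* scaled richness -- species count divided by the pool size;
* scaled phylogenetic diversity -- ensemble-mean Faith's PD divided by
  total tree branch length;
* scaled functional richness -- convex-hull volume in the 5-axis trait
  space divided by the pool hull volume (undefined, reported missing,
  when an assemblage has no more species than axes).

Net change between 8000 BP and 2020 decomposes additively: with S0 the
8000 BP set, L the lost species and G the gained species, the loss term
is D(S0 \\ L) - D(S0), the gain term D(S2020) - D(S0 \\ L), and
net = loss + gain by construction (the intermediate set is evaluated
once and shared).  Losses are applied before gains; the reverse order
changes the panel values for PD and FRic (not the net), and the chosen
order matches the narrative sequence extirpations-then-gains.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np
from scipy import stats

from .data_model import (
    Region,
    RegionalAssemblage,
    SpeciesRecord,
    StatusCategory,
    StatusRecord,
    Subgroup,
    Timepoint,
    assemble,
    loss_gain_sets,
)
from .functional import hull_overlap_fraction, hull_volume
from .phylo import PhyloTreeEnsemble, faith_pd, total_branch_length
from .trait_space import TraitSpace

__all__ = [
    "METRICS",
    "DiversityResult",
    "ChangeDecomposition",
    "MetricEvaluator",
    "richness_scaled",
    "region_diversity",
    "decompose",
    "future_gain",
    "occupancy_overlap",
    "assemblage_profiles",
    "summarize",
    "run_regions",
]

METRICS = ("richness", "pd", "fric")

#: Ties on the continuous metrics: |net| below this is "no change".
DEFAULT_TIE_TOL = 1e-9


@dataclass
class DiversityResult:
    region_id: str
    timepoint: Timepoint
    subgroup: Subgroup
    n_species: int
    richness_scaled: float
    pd_scaled: float
    pd_sd: float
    fric_scaled: float | None

    def __post_init__(self) -> None:
        for v in (self.richness_scaled, self.pd_scaled):
            if not -1e-12 <= v <= 1 + 1e-9:
                raise ValueError(f"scaled metric out of [0, 1]: {v}")
        if self.fric_scaled is not None and not -1e-12 <= self.fric_scaled <= 1 + 1e-9:
            raise ValueError(f"scaled FRic out of [0, 1]: {self.fric_scaled}")


@dataclass
class ChangeDecomposition:
    """loss <= 0 <= gain, net = loss + gain, for one region and metric."""

    region_id: str
    metric: str
    loss: float | None
    gain: float | None
    net: float | None

    @property
    def missing(self) -> bool:
        return self.net is None


def richness_scaled(tips, total_count: int) -> float:
    """Species count scaled by the pool size."""
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    return len(set(tips)) / total_count


class MetricEvaluator:
    """Evaluate all three scaled metrics against a fixed species universe.

    The universe (optionally a subgroup of the full pool) fixes the
    scaling denominators: its size for richness, each tree's reference
    branch-length sum for PD, and its trait-space hull for FRic.  For
    the full pool the PD denominator is the total branch length of the
    tree; for a proper subgroup it is the spanning subtree of the
    subgroup, so that the complete subgroup still scores 1.
    """

    def __init__(
        self,
        ensemble: PhyloTreeEnsemble,
        trait_space: TraitSpace,
        universe_ids: set[str] | None = None,
    ):
        self.ensemble = ensemble
        self.trait_space = trait_space
        all_tips = set(ensemble.tip_labels)
        if universe_ids is None:
            universe_ids = all_tips
        universe_ids = set(universe_ids)
        missing = universe_ids - all_tips
        if missing:
            raise KeyError(f"species missing from trees: {sorted(missing)}")
        self.universe = frozenset(universe_ids)
        self._order = sorted(universe_ids)
        self._is_full_pool = universe_ids == all_tips
        self._pd_denoms = np.array(
            [
                total_branch_length(t)
                if self._is_full_pool
                else faith_pd(t, universe_ids)
                for t in ensemble
            ]
        )
        if np.any(self._pd_denoms <= 0):
            raise ValueError("PD reference branch length is zero for some tree")
        self.global_points = trait_space.points(self._order)
        self._global_hull = hull_volume(self.global_points)
        if not self._global_hull.defined:
            raise ValueError(f"pool hull undefined: {self._global_hull.reason}")
        self.global_hull_volume = self._global_hull.volume

    def restrict(self, tips) -> set[str]:
        return set(tips) & self.universe

    def richness(self, tips) -> float:
        return len(self.restrict(tips)) / len(self.universe)

    def pd(self, tips) -> tuple[float, float]:
        tips = self.restrict(tips)
        pds = np.array([faith_pd(t, tips) for t in self.ensemble])
        ratios = pds / self._pd_denoms
        return float(ratios.mean()), float(ratios.std(ddof=0))

    def points(self, tips) -> np.ndarray:
        return self.trait_space.points(sorted(self.restrict(tips)))

    def fric(self, tips) -> float | None:
        sub = hull_volume(self.points(tips))
        if not sub.defined:
            return None
        return sub.volume / self.global_hull_volume

    def value(self, metric: str, tips) -> float | None:
        if metric == "richness":
            return self.richness(tips)
        if metric == "pd":
            return self.pd(tips)[0]
        if metric == "fric":
            return self.fric(tips)
        raise ValueError(f"unknown metric {metric!r}")


def _check_coverage(
    assemblage: RegionalAssemblage, evaluator: MetricEvaluator, species_ids: set[str]
) -> None:
    missing = assemblage.species_ids - species_ids
    if missing:
        raise KeyError(
            f"region {assemblage.region_id}: species not in inputs: {sorted(missing)}"
        )


def region_diversity(
    status_records: list[StatusRecord],
    region_id: str,
    timepoint: Timepoint | str,
    evaluator: MetricEvaluator,
    subgroup: Subgroup | str = Subgroup.ALL,
) -> DiversityResult:
    """All three scaled metrics for one region at one timepoint."""
    subgroup = Subgroup(subgroup) if isinstance(subgroup, str) else subgroup
    assemblage = assemble(status_records, region_id, timepoint)
    _check_coverage(assemblage, evaluator, set(evaluator.ensemble.tip_labels))
    tips = evaluator.restrict(assemblage.species_ids)
    pd_mean, pd_sd = evaluator.pd(tips)
    return DiversityResult(
        region_id=region_id,
        timepoint=assemblage.timepoint,
        subgroup=subgroup,
        n_species=len(tips),
        richness_scaled=evaluator.richness(tips),
        pd_scaled=pd_mean,
        pd_sd=pd_sd,
        fric_scaled=evaluator.fric(tips),
    )


def decompose(
    status_records: list[StatusRecord],
    region_id: str,
    evaluator: MetricEvaluator,
    metric: str,
) -> ChangeDecomposition:
    """Loss/gain/net change of one metric for one region.

    With S0 the 8000 BP assemblage, L/G the loss and gain sets and
    S1 = (S0 \\ L) | G the 2020 assemblage:
    loss = D(S0 \\ L) - D(S0) <= 0, gain = D(S1) - D(S0 \\ L) >= 0,
    net = loss + gain.  For FRic the decomposition is missing when any
    of the three sets has an undefined hull.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    s0 = evaluator.restrict(
        assemble(status_records, region_id, Timepoint.BP8000).species_ids
    )
    s1 = evaluator.restrict(
        assemble(status_records, region_id, Timepoint.Y2020).species_ids
    )
    loss_set, _ = loss_gain_sets(status_records, region_id)
    sp = s0 - loss_set
    if metric == "richness":
        # Signed set cardinalities over the pool size, exact by construction.
        total = len(evaluator.universe)
        loss = (len(sp) - len(s0)) / total
        gain = (len(s1) - len(sp)) / total
        return ChangeDecomposition(region_id, metric, loss, gain, loss + gain)
    d0 = evaluator.value(metric, s0)
    dp = evaluator.value(metric, sp)
    d1 = evaluator.value(metric, s1)
    if d0 is None or dp is None or d1 is None:
        return ChangeDecomposition(region_id, metric, None, None, None)
    loss = dp - d0
    gain = d1 - dp
    return ChangeDecomposition(region_id, metric, loss, gain, loss + gain)


def future_gain(
    status_records: list[StatusRecord],
    region_id: str,
    evaluator: MetricEvaluator,
    species_by_id: dict[str, SpeciesRecord] | None = None,
) -> dict[str, float | None]:
    """Diversity gain if all future-reintroduction candidates establish.

    Per metric: D(2020 set plus future candidates) - D(2020 set).  A
    candidate that is globally extinct must have a surrogate (a living
    relative or domestic descendant carrying the ancestor's traits and
    phylogenetic position); otherwise nothing could be reintroduced and
    the record is an input error.
    """
    future_tips = {
        r.species_id
        for r in status_records
        if r.region_id == region_id and r.category is StatusCategory.FUTURE_POTENTIAL
    }
    if species_by_id is not None:
        for sp_id in sorted(future_tips):
            rec = species_by_id.get(sp_id)
            if rec is None:
                raise KeyError(f"future candidate {sp_id!r} has no trait record")
            if rec.globally_extinct and not rec.surrogate_available:
                raise ValueError(
                    f"future candidate {sp_id!r} is globally extinct with no surrogate"
                )
    s1 = evaluator.restrict(
        assemble(status_records, region_id, Timepoint.Y2020).species_ids
    )
    s_future = s1 | evaluator.restrict(future_tips)
    gains: dict[str, float | None] = {}
    for metric in METRICS:
        d1 = evaluator.value(metric, s1)
        df = evaluator.value(metric, s_future)
        gains[metric] = None if (d1 is None or df is None) else df - d1
    return gains


def occupancy_overlap(
    status_records: list[StatusRecord],
    region_id: str,
    evaluator: MetricEvaluator,
) -> float | None:
    """Fraction of the 8000 BP functional space still occupied in 2020.

    Missing (None) when either assemblage's hull is undefined.
    """
    s0 = evaluator.restrict(
        assemble(status_records, region_id, Timepoint.BP8000).species_ids
    )
    s1 = evaluator.restrict(
        assemble(status_records, region_id, Timepoint.Y2020).species_ids
    )
    h0 = hull_volume(evaluator.points(s0))
    h1 = hull_volume(evaluator.points(s1))
    if not (h0.defined and h1.defined):
        return None
    return hull_overlap_fraction(evaluator.points(s0), evaluator.points(s1))


def assemblage_profiles(
    status_records: list[StatusRecord],
    region_id: str,
    timepoint: Timepoint | str,
    species_by_id: dict[str, SpeciesRecord],
) -> dict | None:
    """Mean body mass and mean diet composition of an assemblage."""
    assemblage = assemble(status_records, region_id, timepoint)
    if not assemblage.species_ids:
        return None
    recs = [species_by_id[s] for s in sorted(assemblage.species_ids)]
    masses = np.array([r.mass_g for r in recs])
    diets = np.array([r.diet_pct for r in recs])
    return {
        "mean_mass_g": float(masses.mean()),
        "mean_diet_pct": [float(x) for x in diets.mean(axis=0)],
    }


def _tie(metric: str, net: float, tie_tol: float) -> bool:
    return net == 0.0 if metric == "richness" else abs(net) < tie_tol


def summarize(
    decompositions: list[ChangeDecomposition],
    levels: list[DiversityResult] | None = None,
    regions: list[Region] | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> dict:
    """Cross-region summary of net changes and metric correspondence.

    Per metric: counts of regions increased / decreased / unchanged,
    median and range of net change, and island vs continental medians
    when region metadata is given.  When per-region levels are supplied,
    pairwise Spearman and Pearson correlations among the metric levels
    and among the net changes are included.
    """
    if not decompositions:
        raise ValueError("nothing to summarize")
    island_by_region = {r.region_id: r.island for r in regions} if regions else {}
    out: dict = {"metrics": {}}
    nets_by_metric: dict[str, dict[str, float]] = {}
    for metric in METRICS:
        rows = [d for d in decompositions if d.metric == metric]
        if not rows:
            continue
        nets = {d.region_id: d.net for d in rows if d.net is not None}
        nets_by_metric[metric] = nets
        values = list(nets.values())
        inc = sum(
            1 for v in values if v > 0 and not _tie(metric, v, tie_tol)
        )
        dec = sum(
            1 for v in values if v < 0 and not _tie(metric, v, tie_tol)
        )
        unchanged = sum(1 for v in values if _tie(metric, v, tie_tol))
        entry = {
            "n_regions": len(rows),
            "n_missing": len(rows) - len(values),
            "n_increased": inc,
            "n_decreased": dec,
            "n_unchanged": unchanged,
            "median_net": float(median(values)) if values else None,
            "range_net": [float(min(values)), float(max(values))] if values else None,
        }
        if island_by_region:
            for cls, flag in (("island", True), ("continental", False)):
                sub = [
                    v
                    for rid, v in nets.items()
                    if island_by_region.get(rid) is flag
                ]
                entry[f"median_net_{cls}"] = float(median(sub)) if sub else None
        out["metrics"][metric] = entry

    def _pairwise(series: dict[str, dict[str, float]]) -> dict:
        corr = {}
        pairs = [("richness", "pd"), ("richness", "fric"), ("pd", "fric")]
        for a, b in pairs:
            if a not in series or b not in series:
                continue
            shared = sorted(set(series[a]) & set(series[b]))
            if len(shared) < 3:
                continue
            xa = [series[a][k] for k in shared]
            xb = [series[b][k] for k in shared]
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            corr[f"{a}_vs_{b}"] = {
                "pearson": float(stats.pearsonr(xa, xb)[0]),
                "spearman": float(stats.spearmanr(xa, xb)[0]),
                "n": len(shared),
            }
        return corr

    out["net_change_correlations"] = _pairwise(nets_by_metric)
    if levels:
        series: dict[str, dict[str, float]] = {m: {} for m in METRICS}
        for row in levels:
            key = f"{row.region_id}@{row.timepoint.value}"
            series["richness"][key] = row.richness_scaled
            series["pd"][key] = row.pd_scaled
            if row.fric_scaled is not None:
                series["fric"][key] = row.fric_scaled
        out["level_correlations"] = _pairwise(series)
    return out


def run_regions(
    status_records: list[StatusRecord],
    regions: list[Region],
    evaluator: MetricEvaluator,
    subgroup: Subgroup | str = Subgroup.ALL,
    timepoints: tuple[Timepoint, ...] = (Timepoint.BP8000, Timepoint.Y2020),
    with_overlap: bool = True,
) -> tuple[list[DiversityResult], list[ChangeDecomposition], dict[str, float | None]]:
    """Levels, decompositions and hull overlap for every region."""
    levels: list[DiversityResult] = []
    decomps: list[ChangeDecomposition] = []
    overlaps: dict[str, float | None] = {}
    for region in regions:
        for tp in timepoints:
            levels.append(
                region_diversity(status_records, region.region_id, tp, evaluator, subgroup)
            )
        for metric in METRICS:
            decomps.append(
                decompose(status_records, region.region_id, evaluator, metric)
            )
        if with_overlap:
            overlaps[region.region_id] = occupancy_overlap(
                status_records, region.region_id, evaluator
            )
    return levels, decomps, overlaps
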