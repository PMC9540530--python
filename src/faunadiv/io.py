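"""Readers and writers for the documented CSV and Newick formats.

All CSVs are UTF-8, comma-separated, with a mandatory header row and
``.`` decimals.  Missing metric values are serialized as empty fields,
never as 0.  Writers are deterministic, so identical in-memory objects
always produce byte-identical files.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

from .data_model import (
    ACTIVITY_VARS,
    DIET_VARS,
    Region,
    SpeciesRecord,
    StatusCategory,
    StatusRecord,
)
from .phylo import PhyloTree, PhyloTreeEnsemble, read_newick_trees
from .pipeline import ChangeDecomposition, DiversityResult

__all__ = [
    "SPECIES_COLUMNS",
    "read_species_csv",
    "write_species_csv",
    "read_status_csv",
    "write_status_csv",
    "read_regions_csv",
    "write_regions_csv",
    "read_newick_trees",
    "write_newick",
    "write_results_csv",
    "write_decomposition_csv",
    "write_provenance",
    "file_sha256",
]

SPECIES_COLUMNS = (
    "species_id",
    "name",
    "mass_g",
    *DIET_VARS,
    "foraging_stratum",
    *ACTIVITY_VARS,
    "habitat_flags",
    "volant",
    "globally_extinct",
    "surrogate_available",
)

STATUS_COLUMNS = ("species_id", "region_id", "category", "recent")
REGION_COLUMNS = ("region_id", "name", "island")
RESULTS_COLUMNS = (
    "region_id",
    "timepoint",
    "subgroup",
    "n_species",
    "richness_scaled",
    "pd_scaled",
    "pd_sd",
    "fric_scaled",
    "overlap_8000_2020",
)
DECOMPOSITION_COLUMNS = ("region_id", "metric", "loss", "gain", "net")


class FormatError(ValueError):
    """A malformed input file (bad header, value, or cross-reference)."""


def _check_header(path, row: list[str], expected: tuple[str, ...]) -> None:
    if row != list(expected):
        raise FormatError(
            f"{path}: malformed header {row!r}; expected {','.join(expected)}"
        )


def _bool(path, lineno: int, value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1"):
        return True
    if v in ("false", "0"):
        return False
    raise FormatError(f"{path}: line {lineno}: invalid boolean {value!r}")


def _fmt_num(x: float) -> str:
    """Shortest float representation that round-trips."""
    return repr(float(x))


def read_species_csv(path) -> list[SpeciesRecord]:
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        _check_header(path, header, SPECIES_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SPECIES_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            d = dict(zip(SPECIES_COLUMNS, row))
            try:
                records.append(
                    SpeciesRecord(
                        species_id=d["species_id"],
                        name=d["name"],
                        mass_g=float(d["mass_g"]),
                        diet_pct=tuple(float(d[v]) for v in DIET_VARS),
                        foraging_stratum=d["foraging_stratum"],
                        activity=tuple(
                            _bool(path, lineno, d[v]) for v in ACTIVITY_VARS
                        ),
                        habitat=frozenset(
                            h for h in d["habitat_flags"].split(";") if h
                        ),
                        volant=_bool(path, lineno, d["volant"]),
                        globally_extinct=_bool(path, lineno, d["globally_extinct"]),
                        surrogate_available=_bool(
                            path, lineno, d["surrogate_available"]
                        ),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    seen = set()
    for rec in records:
        if rec.species_id in seen:
            raise FormatError(f"{path}: duplicate species_id {rec.species_id!r}")
        seen.add(rec.species_id)
    return records


def write_species_csv(path, species: list[SpeciesRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SPECIES_COLUMNS)
        for sp in species:
            writer.writerow(
                [
                    sp.species_id,
                    sp.name,
                    _fmt_num(sp.mass_g),
                    *[_fmt_num(p) for p in sp.diet_pct],
                    sp.foraging_stratum,
                    *[str(bool(f)).lower() for f in sp.activity],
                    ";".join(sorted(sp.habitat)),
                    str(sp.volant).lower(),
                    str(sp.globally_extinct).lower(),
                    str(sp.surrogate_available).lower(),
                ]
            )


def read_status_csv(path, known_species: set[str] | None = None) -> list[StatusRecord]:
    path = Path(path)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        _check_header(path, header, STATUS_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(STATUS_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            sp_id, region_id, cat_str, recent_str = row
            if known_species is not None and sp_id not in known_species:
                raise FormatError(
                    f"{path}: line {lineno}: unknown species_id {sp_id!r}"
                )
            try:
                category = StatusCategory(cat_str)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: unknown category {cat_str!r}"
                ) from None
            recent = None if recent_str == "" else _bool(path, lineno, recent_str)
            try:
                records.append(StatusRecord(sp_id, region_id, category, recent))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_status_csv(path, records: list[StatusRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(STATUS_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.species_id,
                    r.region_id,
                    r.category.value,
                    "" if r.recent is None else str(r.recent).lower(),
                ]
            )


def read_regions_csv(path) -> list[Region]:
    path = Path(path)
    regions = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        _check_header(path, header, REGION_COLUMNS)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(REGION_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            regions.append(Region(row[0], row[1], _bool(path, lineno, row[2])))
    seen = set()
    for r in regions:
        if r.region_id in seen:
            raise FormatError(f"{path}: duplicate region_id {r.region_id!r}")
        seen.add(r.region_id)
    return regions


def write_regions_csv(path, regions: list[Region]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REGION_COLUMNS)
        for r in regions:
            writer.writerow([r.region_id, r.name, str(r.island).lower()])


def _newick_of(tree: PhyloTree) -> str:
    """Serialize an encoded tree back to Newick (deterministic)."""
    n = len(tree.parent)
    children: list[list[int]] = [[] for _ in range(n)]
    root = -1
    for i, p in enumerate(tree.parent):
        if p < 0:
            root = i
        else:
            children[p].append(i)

    def render(i: int) -> str:
        if not children[i]:
            body = tree.tip_labels[i]
        else:
            body = "(" + ",".join(render(c) for c in children[i]) + ")"
        return f"{body}:{tree.edge_lengths[i]:.10f}"

    if children[root]:
        inner = ",".join(render(c) for c in children[root])
        return f"({inner});"
    return f"{tree.tip_labels[root]}:{tree.edge_lengths[root]:.10f};"


def write_newick(path, ensemble: PhyloTreeEnsemble) -> None:
    """Write a multi-tree Newick file, one tree per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for tree in ensemble:
            fh.write(_newick_of(tree) + "\n")


def _field(x) -> str:
    return "" if x is None else _fmt_num(x)


def write_results_csv(
    path,
    results: list[DiversityResult],
    overlaps: dict[str, float | None] | None = None,
) -> None:
    overlaps = overlaps or {}
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RESULTS_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.region_id,
                    r.timepoint.value,
                    r.subgroup.value,
                    r.n_species,
                    _fmt_num(r.richness_scaled),
                    _fmt_num(r.pd_scaled),
                    _fmt_num(r.pd_sd),
                    _field(r.fric_scaled),
                    _field(overlaps.get(r.region_id)),
                ]
            )


def write_decomposition_csv(path, decompositions: list[ChangeDecomposition]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(DECOMPOSITION_COLUMNS)
        for d in decompositions:
            writer.writerow(
                [d.region_id, d.metric, _field(d.loss), _field(d.gain), _field(d.net)]
            )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, config: dict, inputs: list) -> None:
    """Machine-readable provenance: config echo plus input checksums."""
    record = {
        "config": config,
        "inputs": {
            str(p): file_sha256(p) for p in inputs if Path(p).exists()
        },
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
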