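"""Mixed-trait functional space: weighted Gower dissimilarity and PCoA.

Species traits mix continuous (body mass, diet percentages), categorical
(foraging stratum) and binary (activity, habitat) variables, so pairwise
dissimilarity uses Gower's coefficient: a weighted mean of per-variable
dissimilarities, each in [0, 1].  Continuous variables are range
normalized (|xi - xj| / range over all species), categorical and binary
variables score 0/1 on mismatch.  Range normalization is the
standardization for continuous inputs; body mass enters on a log10 scale
since it spans several orders of magnitude (configurable).

Weights equalize trait *groups* rather than raw variables: mass, diet,
stratum, activity and habitat each carry total weight 1, split equally
within the group (each of the seven diet percentages gets 1/7, each of
the three activity flags 1/3, and so on).

Gower dissimilarities are generally non-Euclidean; an elementwise square
root transform makes the matrix near-Euclidean, after which principal
coordinates analysis (classical MDS: double-center -1/2 J D^2 J and
eigendecompose) embeds species into k Euclidean axes.  Small negative
eigenvalues are tolerated; if the most negative exceeds 5% of the
largest the embedding is refused with a pointer to the transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .data_model import ACTIVITY_VARS, DIET_VARS, SpeciesRecord

__all__ = [
    "DissimilarityMatrix",
    "TraitSpace",
    "trait_matrix",
    "default_weights",
    "gower",
    "sqrt_transform",
    "pcoa",
    "build_trait_space",
]

logger = logging.getLogger(__name__)

#: Reject embeddings whose most negative eigenvalue exceeds this
#: fraction of the largest positive one.
NEG_EIGVAL_TOLERANCE = 0.05


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with species order."""

    species_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match species order")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("entries must lie in [0, 1]")
        self.values = v

    def __len__(self) -> int:
        return len(self.species_ids)


@dataclass
class TraitSpace:
    """Species coordinates on k retained principal-coordinate axes."""

    species_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,), positive, non-increasing
    variance_represented: float

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.species_ids)}
        if np.any(self.eigenvalues <= 0):
            raise ValueError("retained eigenvalues must be strictly positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if self.coordinates.shape[1] >= len(self.species_ids):
            raise ValueError("axis count must be smaller than species count")

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def points(self, species_ids) -> np.ndarray:
        """Coordinates for a species subset, in the given order."""
        try:
            rows = [self._index[s] for s in species_ids]
        except KeyError as exc:
            raise KeyError(f"species {exc.args[0]!r} not in trait space") from None
        return self.coordinates[rows]


def trait_matrix(
    species: list[SpeciesRecord], log_mass: bool = True
) -> tuple[np.ndarray, list[str], list[str]]:
    """Flatten species records into a numeric variable matrix.

    Returns (values, variable names, variable kinds) where kind is
    "continuous" or "binary"/"categorical".  The categorical stratum is
    kept as an integer code compared by mismatch.  Habitat flags are the
    union of labels observed across the input.
    """
    habitats = sorted({h for sp in species for h in sp.habitat})
    names: list[str] = ["log10_mass_g" if log_mass else "mass_g"]
    kinds: list[str] = ["continuous"]
    names += list(DIET_VARS)
    kinds += ["continuous"] * len(DIET_VARS)
    names.append("foraging_stratum")
    kinds.append("categorical")
    names += list(ACTIVITY_VARS)
    kinds += ["binary"] * len(ACTIVITY_VARS)
    names += [f"habitat_{h}" for h in habitats]
    kinds += ["binary"] * len(habitats)

    strata = sorted({sp.foraging_stratum for sp in species})
    stratum_code = {s: i for i, s in enumerate(strata)}
    rows = []
    for sp in species:
        mass = math.log10(sp.mass_g) if log_mass else sp.mass_g
        row = [mass, *sp.diet_pct, stratum_code[sp.foraging_stratum]]
        row += [float(f) for f in sp.activity]
        row += [float(h in sp.habitat) for h in habitats]
        rows.append(row)
    return np.asarray(rows, dtype=float), names, kinds


def default_weights(names: list[str]) -> dict[str, float]:
    """Equal weight per trait group, split equally within each group."""
    groups: dict[str, list[str]] = {}
    for name in names:
        if name in DIET_VARS:
            groups.setdefault("diet", []).append(name)
        elif name in ACTIVITY_VARS:
            groups.setdefault("activity", []).append(name)
        elif name.startswith("habitat_"):
            groups.setdefault("habitat", []).append(name)
        elif name == "foraging_stratum":
            groups.setdefault("stratum", []).append(name)
        else:
            groups.setdefault("mass", []).append(name)
    weights = {}
    for members in groups.values():
        for m in members:
            weights[m] = 1.0 / len(members)
    return weights


def gower(
    species: list[SpeciesRecord],
    weights: dict[str, float] | None = None,
    log_mass: bool = True,
) -> DissimilarityMatrix:
    """Weighted Gower dissimilarity between species on mixed traits.

    Missing values (NaN) are dropped pairwise, renormalizing the weight
    sum; a variable constant across all species has no range and is
    dropped with a warning.
    """
    if len(species) < 2:
        raise ValueError("need at least two species")
    ids = tuple(sp.species_id for sp in species)
    X, names, kinds = trait_matrix(species, log_mass=log_mass)
    if weights is None:
        weights = default_weights(names)
    missing = [n for n in names if n not in weights]
    if missing:
        raise ValueError(f"weights missing for variables: {missing}")
    w = np.array([float(weights[n]) for n in names])
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    n, p = X.shape
    keep = np.ones(p, dtype=bool)
    ranges = np.ones(p)
    for j, kind in enumerate(kinds):
        col = X[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.all(finite == finite[0]):
            logger.warning("variable %s is constant; dropped from Gower", names[j])
            keep[j] = False
        elif kind == "continuous":
            ranges[j] = finite.max() - finite.min()

    D = np.zeros((n, n))
    kindarr = np.array(kinds)
    for i in range(n):
        for jj in range(i + 1, n):
            xi, xj = X[i], X[jj]
            valid = keep & np.isfinite(xi) & np.isfinite(xj)
            if not valid.any():
                raise ValueError(
                    f"no comparable variables for pair ({ids[i]}, {ids[jj]})"
                )
            d = np.where(
                kindarr == "continuous",
                np.abs(xi - xj) / ranges,
                (xi != xj).astype(float),
            )
            D[i, jj] = D[jj, i] = float(
                (w[valid] * d[valid]).sum() / w[valid].sum()
            )
    return DissimilarityMatrix(ids, D)


def sqrt_transform(D: DissimilarityMatrix) -> DissimilarityMatrix:
    """Elementwise square root; shrinks non-Euclidean negative structure."""
    return DissimilarityMatrix(D.species_ids, np.sqrt(D.values))


def pcoa(D: DissimilarityMatrix, k: int = 5) -> TraitSpace:
    """Principal coordinates analysis retaining the top ``k`` axes.

    Double-centers -1/2 J D^2 J, eigendecomposes, and keeps the k
    largest eigenvalues (which must all be positive).  Coordinates are
    eigenvectors scaled by sqrt(eigenvalue), with a deterministic sign
    convention (the first nonzero loading of each axis is positive).
    """
    n = len(D)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n; got k={k}, n={n}")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    largest = eigvals[0]
    if largest <= 0:
        raise ValueError("no positive eigenvalues; matrix is degenerate")
    most_negative = eigvals[-1]
    if most_negative < 0 and -most_negative > NEG_EIGVAL_TOLERANCE * largest:
        raise ValueError(
            f"negative eigenvalue {most_negative:.3g} exceeds "
            f"{NEG_EIGVAL_TOLERANCE:.0%} of the largest ({largest:.3g}); "
            "apply a square-root transform to the dissimilarities first"
        )
    pos_tol = 1e-10 * largest
    n_pos = int(np.sum(eigvals > pos_tol))
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive eigenvalues available, cannot retain {k} axes"
        )
    lam = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(lam)
    # Deterministic orientation: first coordinate of nonneglible
    # magnitude on each axis is made positive.
    for j in range(k):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-9 * np.sqrt(lam[j]))
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    variance = float(lam.sum() / eigvals[eigvals > pos_tol].sum())
    return TraitSpace(D.species_ids, coords, lam, variance)


def build_trait_space(
    species: list[SpeciesRecord],
    k: int = 5,
    weights: dict[str, float] | None = None,
    log_mass: bool = True,
) -> TraitSpace:
    """Gower -> square root -> PCoA, the full trait-space construction."""
    return pcoa(sqrt_transform(gower(species, weights=weights, log_mass=log_mass)), k=k)
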