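"""Gold-labeled synthetic benchmark datasets.

The validation design the package tests against consists of 2D point
clouds drawn from circular Gaussian groups: the probability density of
each group falls off with distance from its centre as a normal
distribution.  Variants vary the group shapes (elongated Gaussians,
rings) or subsample each group to a different density.  Centres are
auto-spread so that groups do not significantly overlap; labels record
the generating group and serve as the external gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import PointSet

__all__ = [
    "SyntheticSpec",
    "generate_gaussian_clusters",
    "generate_density_variant",
    "PRESETS",
    "make_preset",
]

#: default minimal centre separation, in units of the largest sigma
DEFAULT_SEPARATION = 10.0
_CENTER_RETRY_BUDGET = 5000


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a labeled Gaussian-mixture point set.

    Parameters
    ----------
    n_clusters : int
        Number of groups.
    points_per_cluster : int or sequence of int
        Group sizes (a scalar applies to every group).
    sigma : float or sequence of float
        Isotropic standard deviation per group (default 1.0).
    centers : (n_clusters, dim) array, optional
        Explicit centres; if omitted they are auto-spread with pairwise
        distance >= ``separation * max(sigma)``.
    separation : float
        Minimal centre separation in units of the largest sigma
        (default 10: groups are well separated, with at most a handful of
        boundary points).
    dim : int
        Dimensionality (default 2).
    elongation : sequence of float, optional
        Per-group axis-ratio for anisotropic (elongated) groups; 1 = circular.
        Off (all 1) by default.
    density_fractions : sequence of float, optional
        Per-group subsample fractions in [0.05, 0.95] for the
        variable-density variant.
    seed : int, optional
        Seed for the generator; identical specs yield identical data.
    """

    n_clusters: int
    points_per_cluster: object = 150
    sigma: object = 1.0
    centers: np.ndarray | None = None
    separation: float = DEFAULT_SEPARATION
    dim: int = 2
    elongation: object = None
    density_fractions: object = None
    seed: int | None = None

    def sizes(self) -> np.ndarray:
        sizes = np.broadcast_to(
            np.asarray(self.points_per_cluster, dtype=int), (self.n_clusters,)
        )
        if (sizes < 2).any():
            raise ValueError("every cluster needs at least 2 points")
        return np.array(sizes)

    def sigmas(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.sigma, dtype=float), (self.n_clusters,))
        if (s <= 0).any():
            raise ValueError("sigma must be positive")
        return np.array(s)


def _spread_centers(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample centres with pairwise distance >= separation*max(sigma)."""
    if spec.centers is not None:
        centers = np.asarray(spec.centers, dtype=float)
        if centers.shape != (spec.n_clusters, spec.dim):
            raise ValueError(
                f"centers must have shape ({spec.n_clusters}, {spec.dim})"
            )
        return centers
    min_dist = spec.separation * spec.sigmas().max()
    # box wide enough that the requested packing is loose
    side = min_dist * max(2.0, 1.5 * np.sqrt(spec.n_clusters))
    centers: list[np.ndarray] = []
    for _ in range(_CENTER_RETRY_BUDGET):
        cand = rng.uniform(0.0, side, size=spec.dim)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
            if len(centers) == spec.n_clusters:
                return np.array(centers)
    raise RuntimeError(
        f"could not place {spec.n_clusters} centres at separation "
        f"{spec.separation} within the retry budget; use fewer clusters "
        "or a smaller sigma"
    )


def generate_gaussian_clusters(spec: SyntheticSpec) -> PointSet:
    """Draw labeled points from (optionally elongated) Gaussian groups.

    Each group's points are sampled from a normal distribution around its
    centre; with ``elongation`` r > 1 the first principal axis of the group
    is stretched by r and the group is given a random orientation.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _spread_centers(spec, rng)
    sizes = spec.sizes()
    sigmas = spec.sigmas()
    elong = (
        np.ones(spec.n_clusters)
        if spec.elongation is None
        else np.broadcast_to(np.asarray(spec.elongation, dtype=float), (spec.n_clusters,))
    )
    coords = []
    labels = []
    for g in range(spec.n_clusters):
        pts = rng.normal(0.0, sigmas[g], size=(sizes[g], spec.dim))
        if elong[g] != 1.0:
            pts[:, 0] *= elong[g]
            if spec.dim == 2:  # random orientation for elongated groups
                theta = rng.uniform(0, 2 * np.pi)
                c, s = np.cos(theta), np.sin(theta)
                pts = pts @ np.array([[c, -s], [s, c]])
        coords.append(pts + centers[g])
        labels.append(np.full(sizes[g], g))
    return PointSet(np.vstack(coords), np.concatenate(labels))


def generate_density_variant(spec: SyntheticSpec) -> PointSet:
    """Generate full Gaussian groups, then subsample each to its fraction.

    Fractions must lie in [0.05, 0.95]; each group keeps
    ``round(fraction * size)`` points, floored at 2 so no group degenerates
    to a singleton.  Labels are preserved.
    """
    if spec.density_fractions is None:
        raise ValueError("density_fractions must be supplied for this variant")
    fractions = np.broadcast_to(
        np.asarray(spec.density_fractions, dtype=float), (spec.n_clusters,)
    )
    if (fractions < 0.05).any() or (fractions > 0.95).any():
        raise ValueError("density fractions must lie in [0.05, 0.95]")
    full = generate_gaussian_clusters(spec)
    rng = np.random.default_rng(spec.seed).spawn(1)[0]
    keep = []
    for g in range(spec.n_clusters):
        members = np.flatnonzero(full.labels == g)
        n_keep = max(2, int(round(fractions[g] * members.size)))
        keep.append(rng.choice(members, size=n_keep, replace=False))
    keep = np.sort(np.concatenate(keep))
    return PointSet(full.coordinates[keep], full.labels[keep])


def _density_preset(seed: int | None) -> SyntheticSpec:
    frac_rng = np.random.default_rng(seed)
    fractions = frac_rng.uniform(0.05, 0.95, size=20)
    return SyntheticSpec(
        n_clusters=20,
        points_per_cluster=100,
        density_fractions=fractions,
        seed=seed,
    )


#: preset builders mirroring the benchmark designs: group counts and total
#: sizes of the standard validation datasets
PRESETS = {
    "p300": lambda seed: SyntheticSpec(2, 150, seed=seed),
    "p450": lambda seed: SyntheticSpec(3, 150, seed=seed),
    "p1500": lambda seed: SyntheticSpec(10, 150, seed=seed),
    "p3000": lambda seed: SyntheticSpec(20, 150, seed=seed),
    "p5000": lambda seed: SyntheticSpec(
        15,
        333,
        sigma=tuple(0.7 + 0.08 * i for i in range(15)),
        elongation=tuple(1.0 if i % 3 else 2.5 for i in range(15)),
        seed=seed,
    ),
    "density": _density_preset,
}


def make_preset(name: str, seed: int | None = None) -> PointSet:
    """Generate one of the named benchmark presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name](seed)
    if spec.density_fractions is not None:
        return generate_density_variant(spec)
    return generate_gaussian_clusters(spec)
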