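"""Multivariate brain maps and their interpretability metrics.

A *multivariate brain map* (MBM) is the weight vector of a linear decoder
normalized to the unit hyper-sphere.  Given an ensemble of MBMs estimated on
perturbed training sets and a reference map (the true solution, or a
heuristic for it), three cosine-based quantities are defined:

interpretability
    eta = (1/m) * sum_j cos(angle(map_j, reference)) — the mean cosine
    similarity between ensemble members and the reference.
reproducibility
    psi = (1/m) * sum_j cos(angle(map_j, mu)) where mu is the normalized
    mean (the *main map*) of the ensemble.  Algebraically psi equals the
    length of the plain (un-normalized) mean of the members — the resultant
    length familiar from directional statistics.
representativeness
    beta = |mu . reference| — the absolute cosine between the main map and
    the reference.

These satisfy the exact decomposition eta = psi * beta whenever the main
map's signed dot product with the reference is non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateMapError",
    "MultivariateBrainMap",
    "MapEnsemble",
    "InterpretabilityReport",
    "normalize_map",
    "cosine_similarity",
    "main_map",
    "reproducibility",
    "representativeness",
    "interpretability",
    "cosine_null_sd",
    "cosine_significance",
]

#: tolerance for unit-norm and algebraic-identity checks (exact algebra in
#: double precision)
IDENTITY_TOL = 1e-9


class DegenerateMapError(ValueError):
    """Raised when a map cannot be normalized (zero weight vector).

    For a regularized decoder this signals a fully-shrunk fit: every
    coefficient was driven to exactly zero, so the decoder carries no
    directional information and has no MBM.
    """


@dataclass(frozen=True)
class MultivariateBrainMap:
    """A unit 2-norm weight vector on the p-sphere.

    Parameters
    ----------
    weights : ndarray of shape (p,)
        Unit-norm, finite weight vector.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a nonempty 1-D vector")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        nrm = float(np.linalg.norm(w))
        if abs(nrm - 1.0) > IDENTITY_TOL:
            raise ValueError(
                f"weights must have unit 2-norm (got {nrm!r}); "
                "use normalize_map() to build an MBM from raw weights"
            )
        object.__setattr__(self, "weights", w)

    @property
    def p(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class MapEnsemble:
    """An ordered collection of m MBMs sharing one feature space.

    ``provenance`` records how the perturbed training sets were drawn
    (scheme, seed, counts) so ensembles remain reproducible.
    """

    maps: tuple[MultivariateBrainMap, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        maps = tuple(self.maps)
        if len(maps) < 1:
            raise ValueError("ensemble needs at least one map")
        p = maps[0].p
        if any(mp.p != p for mp in maps):
            raise ValueError("all ensemble maps must share the same p")
        object.__setattr__(self, "maps", maps)
        if not self.provenance:
            object.__setattr__(self, "provenance", {"scheme": "unspecified"})

    @property
    def m(self) -> int:
        return len(self.maps)

    @property
    def p(self) -> int:
        return self.maps[0].p

    def as_matrix(self) -> np.ndarray:
        """Stack the ensemble as an (m, p) array."""
        return np.vstack([mp.weights for mp in self.maps])


@dataclass(frozen=True)
class InterpretabilityReport:
    """Joint report of eta, psi, beta and the decomposition residual.

    ``decomposition_residual`` is |eta - psi*beta|; it is guaranteed below
    1e-9 when the main map and the reference point into the same half-space.
    """

    eta: float
    psi: float
    beta: float
    per_map_cosines: np.ndarray
    decomposition_residual: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_map_cosines", np.asarray(self.per_map_cosines, float)
        )


def normalize_map(raw_weights) -> MultivariateBrainMap:
    """Project a raw weight vector onto the unit hyper-sphere.

    Raises
    ------
    DegenerateMapError
        If the vector is identically zero (fully-shrunk decoder).
    """
    w = np.asarray(raw_weights, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise ValueError("raw_weights must be a nonempty 1-D vector")
    if not np.all(np.isfinite(w)):
        raise ValueError("raw_weights must be finite")
    nrm = float(np.linalg.norm(w))
    if nrm == 0.0:
        raise DegenerateMapError("cannot normalize an all-zero weight vector")
    return MultivariateBrainMap(w / nrm)


def _unit(v) -> np.ndarray:
    if isinstance(v, MultivariateBrainMap):
        return v.weights
    return normalize_map(v).weights


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two maps (dot product of unit vectors)."""
    ua, ub = _unit(a), _unit(b)
    if ua.size != ub.size:
        raise ValueError(f"dimension mismatch: {ua.size} vs {ub.size}")
    return float(np.clip(ua @ ub, -1.0, 1.0))


def main_map(ensemble: MapEnsemble) -> MultivariateBrainMap:
    """Normalized vector sum of the ensemble members (the map mu).

    Raises
    ------
    DegenerateMapError
        If the members cancel exactly (zero resultant, e.g. an antipodal
        pair), in which case no mean direction exists.
    """
    s = ensemble.as_matrix().sum(axis=0)
    if np.linalg.norm(s) == 0.0:
        raise DegenerateMapError(
            "ensemble has zero resultant; main map undefined"
        )
    return normalize_map(s)


def reproducibility(ensemble: MapEnsemble) -> float:
    """Mean cosine of ensemble members to their main map (psi).

    Equals the 2-norm of the plain mean of the member vectors (resultant
    length), hence lies in [0, 1]; 1 means all members coincide.
    """
    mu = main_map(ensemble)
    cosines = ensemble.as_matrix() @ mu.weights
    return float(np.mean(cosines))


def representativeness(mu, reference) -> float:
    """Absolute cosine between a main map and the reference map (beta)."""
    return abs(cosine_similarity(mu, reference))


def interpretability(ensemble: MapEnsemble, reference) -> InterpretabilityReport:
    """eta, psi, beta and the decomposition residual for an ensemble.

    ``reference`` is the map the ensemble is judged against: the known true
    solution when one exists, otherwise a plausibility heuristic such as the
    cERF map.  eta and psi use signed cosines; beta takes the absolute
    value, so eta = psi * beta holds exactly only in the sign-consistent
    regime (main map . reference >= 0).  Sign-flipped ensembles produce a
    warning, not an error.
    """
    ref = _unit(reference)
    if ensemble.p != ref.size:
        raise ValueError(
            f"dimension mismatch: ensemble p={ensemble.p}, reference p={ref.size}"
        )
    per_map = ensemble.as_matrix() @ ref
    eta = float(np.mean(per_map))
    mu = main_map(ensemble)
    psi = reproducibility(ensemble)
    signed = float(mu.weights @ ref)
    beta = abs(signed)
    residual = abs(eta - psi * beta)
    if signed < 0:
        warnings.warn(
            "main map points away from the reference (negative dot product); "
            "eta = psi*beta decomposition does not apply",
            RuntimeWarning,
            stacklevel=2,
        )
    return InterpretabilityReport(
        eta=eta,
        psi=psi,
        beta=beta,
        per_map_cosines=per_map,
        decomposition_residual=residual,
    )


def cosine_null_sd(p: int) -> float:
    """Null standard deviation 1/sqrt(p) of the cosine of two random maps.

    For two independent uniformly random unit vectors in dimension p the
    cosine has mean 0 and variance exactly 1/p, and is asymptotically
    normal; any observed cosine several null SDs from zero therefore marks
    a meaningful alignment in high dimension.
    """
    p = int(p)
    if p < 1:
        raise ValueError("p must be a positive integer")
    return 1.0 / np.sqrt(p)


def cosine_significance(observed_cosine: float, p: int) -> float:
    """Two-sided normal tail probability of an observed cosine under the null.

    Uses the N(0, 1/p) null for the cosine of independent random unit
    vectors in dimension p.
    """
    z = abs(float(observed_cosine)) / cosine_null_sd(p)
    return float(2.0 * stats.norm.sf(z))
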