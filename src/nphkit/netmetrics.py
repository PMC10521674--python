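"""Graph coefficients of the structural connectome.

Every coefficient is computed in a binary and a weighted variant on the
subject connectivity matrix.  Weighted conventions follow the
Bullmore-Sporns / Rubinov-Sporns canon:

* distances use edge length 1/w (stronger connections are shorter);
* triangle-based coefficients (clustering, transitivity) first normalise
  weights to a maximum of 1 and use geometric-mean triangle intensity;
* the weighted rich-club is the within-club weight sum over the sum of
  the same number of largest weights anywhere in the graph;
* density and the path-based coefficients act on raw weights, so scaling
  all weights by c scales weighted density by c and weighted path length
  by 1/c while every binary coefficient is unchanged.

Path-based coefficients are evaluated on the largest connected component
when the graph is disconnected (possible after aggressive region-of-
avoidance filtering); degenerate cases substitute 0 and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .errors import InvariantError
from .types import ConnectivityMatrix

RICH_CLUB_KS = (5, 10, 15, 20)

FEATURE_ORDER_26 = tuple(
    f"{name}_{variant}"
    for name in (
        "density", "clustering", "transitivity", "char_path", "small_world",
        "global_efficiency", "diameter", "radius", "assortativity",
        *[f"rich_club_k{k}" for k in RICH_CLUB_KS],
    )
    for variant in ("binary", "weighted")
)

#: alternative reading in which density has no binary/weighted split
FEATURE_ORDER_25 = tuple(f for f in FEATURE_ORDER_26 if f != "density_weighted")


def _as_weights(m) -> np.ndarray:
    if isinstance(m, ConnectivityMatrix):
        return m.weights
    W = np.asarray(m, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvariantError("expected a square connectivity matrix")
    return W


def _variant_weights(m, variant: str) -> np.ndarray:
    W = _as_weights(m)
    if variant == "binary":
        return (W > 0).astype(float)
    if variant == "weighted":
        return W.astype(float)
    raise InvariantError(f"unknown variant {variant!r} (binary|weighted)")


def _degrees(W) -> np.ndarray:
    return (W > 0).sum(axis=1).astype(float)


def _distance_matrix(W, variant) -> np.ndarray:
    """All-pairs shortest-path distances; weighted edges have length 1/w."""
    A = W > 0
    if variant == "binary":
        return shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)
    L = np.zeros_like(W)
    L[A] = 1.0 / W[A]
    return shortest_path(csr_matrix(L), method="D", directed=False)


def _largest_component(W) -> np.ndarray:
    n_comp, memb = connected_components(csr_matrix(W > 0), directed=False)
    sizes = np.bincount(memb)
    return memb == np.argmax(sizes)


# ---------------------------------------------------------------- metrics
# each _x_impl returns (value, degenerate_flag); the public wrapper either
# raises on the degenerate precondition (documented per operation) or
# returns the substituted value

def _density_impl(m, variant):
    W = _variant_weights(m, variant)
    n = W.shape[0]
    if n < 2:
        return 0.0, True
    possible = n * (n - 1) / 2.0
    total = float(np.triu(W, 1).sum())
    return total / possible, not np.any(W > 0)


def density(m, variant: str = "binary") -> float:
    """Fraction of present connections (or total weight) over possible pairs."""
    W = _variant_weights(m, variant)
    if W.shape[0] < 2:
        raise InvariantError("density needs at least 2 nodes")
    return _density_impl(m, variant)[0]


def _triangle_terms(W, variant):
    """(per-node triangle intensity*2, binary degree) for clustering/transitivity."""
    A = (W > 0).astype(float)
    if variant == "binary":
        M = A
    else:
        mx = W.max()
        M = np.cbrt(W / mx) if mx > 0 else A
    tri2 = np.diag(M @ M @ M)  # = 2 * triangle intensity per node
    return tri2, A.sum(axis=1)


def _clustering_impl(m, variant):
    W = _variant_weights(m, variant)
    n = W.shape[0]
    if n < 3:
        return 0.0, True
    tri2, k = _triangle_terms(W, variant)
    denom = k * (k - 1)
    local = np.where(denom > 0, tri2 / np.where(denom > 0, denom, 1.0), 0.0)
    return float(local.mean()), not np.any(W > 0)


def clustering_average(m, variant: str = "binary") -> float:
    """Mean local clustering; isolated and degree-1 nodes contribute 0."""
    if _as_weights(m).shape[0] < 3:
        raise InvariantError("clustering needs at least 3 nodes")
    return _clustering_impl(m, variant)[0]


def _transitivity_impl(m, variant):
    W = _variant_weights(m, variant)
    if W.shape[0] < 3:
        return 0.0, True
    tri2, k = _triangle_terms(W, variant)
    denom = (k * (k - 1)).sum()
    if denom == 0:
        return 0.0, True
    return float(tri2.sum() / denom), False


def transitivity(m, variant: str = "binary") -> float:
    """Ratio of (intensity-weighted) triangles to connected triplets."""
    return _transitivity_impl(m, variant)[0]


def _char_path_impl(m, variant):
    W = _variant_weights(m, variant)
    comp = _largest_component(W)
    if comp.sum() < 2:
        return 0.0, True
    D = _distance_matrix(W, variant)[np.ix_(comp, comp)]
    off = ~np.eye(D.shape[0], dtype=bool)
    return float(D[off].mean()), False


def char_path_length(m, variant: str = "binary") -> float:
    """Mean shortest-path distance over the largest connected component."""
    value, degenerate = _char_path_impl(m, variant)
    if degenerate:
        raise InvariantError("characteristic path length undefined: no connected pair")
    return value


def _global_efficiency_impl(m, variant):
    W = _variant_weights(m, variant)
    n = W.shape[0]
    if n < 2:
        return 0.0, True
    D = _distance_matrix(W, variant)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    return float(inv[off].mean()), not np.any(W > 0)


def global_efficiency(m, variant: str = "binary") -> float:
    """Mean inverse distance over all ordered pairs (0 for disconnected pairs)."""
    return _global_efficiency_impl(m, variant)[0]


def _eccentricities(m, variant):
    W = _variant_weights(m, variant)
    comp = _largest_component(W)
    if comp.sum() < 2:
        return None
    D = _distance_matrix(W, variant)[np.ix_(comp, comp)]
    return D.max(axis=1)


def _diameter_impl(m, variant):
    ecc = _eccentricities(m, variant)
    return (0.0, True) if ecc is None else (float(ecc.max()), False)


def _radius_impl(m, variant):
    ecc = _eccentricities(m, variant)
    return (0.0, True) if ecc is None else (float(ecc.min()), False)


def diameter(m, variant: str = "binary") -> float:
    """Maximum eccentricity on the largest connected component."""
    value, degenerate = _diameter_impl(m, variant)
    if degenerate:
        raise InvariantError("diameter undefined: graph has no edges")
    return value


def radius(m, variant: str = "binary") -> float:
    """Minimum eccentricity on the largest connected component."""
    value, degenerate = _radius_impl(m, variant)
    if degenerate:
        raise InvariantError("radius undefined: graph has no edges")
    return value


def _random_same_size(n, n_edges, rng):
    """Uniform G(n, m) edge sample as an index pair list."""
    iu = np.triu_indices(n, 1)
    pick = rng.choice(iu[0].size, size=n_edges, replace=False)
    return iu[0][pick], iu[1][pick]


def _small_world_impl(m, variant, n_null=20, seed=0):
    W = _variant_weights(m, variant)
    n = W.shape[0]
    iu = np.triu_indices(n, 1)
    pos = W[iu] > 0
    n_edges = int(pos.sum())
    if n_edges == 0:
        return 0.0, True
    L_obs, deg = _char_path_impl(m, variant)
    if deg:
        return 0.0, True
    weights_pool = W[iu][pos]
    rng = np.random.default_rng(seed)
    nulls = []
    for _ in range(n_null):
        ii, jj = _random_same_size(n, n_edges, rng)
        Wn = np.zeros((n, n))
        vals = np.ones(n_edges) if variant == "binary" else rng.permutation(weights_pool)
        Wn[ii, jj] = vals
        Wn += Wn.T
        L_null, deg_null = _char_path_impl(Wn, variant)
        if not deg_null:
            nulls.append(L_null)
    if not nulls:
        return 0.0, True
    return float(L_obs / np.mean(nulls)), False


def small_worldness(m, variant: str = "binary", n_null: int = 20, seed: int = 0) -> float:
    """Path length relative to size-matched uniform random graphs.

    As printed in the source protocol this is the path-length ratio only
    (no clustering normalisation): CPL(G) divided by the mean CPL of
    ``n_null`` seeded G(n, m) graphs with identical node and edge counts.
    The weighted null keeps the observed weight multiset, permuted onto
    the random edges.
    """
    value, degenerate = _small_world_impl(m, variant, n_null=n_null, seed=seed)
    if degenerate:
        raise InvariantError("small-worldness undefined: graph (or null) has no connected pair")
    return value


def _assortativity_impl(m, variant):
    W = _variant_weights(m, variant)
    A = W > 0
    iu = np.triu_indices(W.shape[0], 1)
    ii, jj = iu[0][A[iu]], iu[1][A[iu]]
    if ii.size < 2:
        return 0.0, True
    deg = W.sum(axis=1) if variant == "weighted" else _degrees(W)
    x = np.concatenate([deg[ii], deg[jj]])  # both edge orientations
    y = np.concatenate([deg[jj], deg[ii]])
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, True
    return float(np.corrcoef(x, y)[0, 1]), False


def assortativity(m, variant: str = "binary") -> float:
    """Pearson correlation of endpoint degrees over edges; 0 if degenerate."""
    return _assortativity_impl(m, variant)[0]


def _rich_club_impl(m, k, variant):
    if k < 1:
        raise InvariantError("rich-club level k must be >= 1")
    W = _variant_weights(m, variant)
    deg = _degrees(W)
    R = deg >= k
    nR = int(R.sum())
    if nR <= 1:
        return 0.0, True
    sub = W[np.ix_(R, R)]
    iu_sub = np.triu_indices(nR, 1)
    if variant == "binary":
        possible = nR * (nR - 1) / 2.0
        return float((sub[iu_sub] > 0).sum() / possible), False
    n_club_edges = int((sub[iu_sub] > 0).sum())
    if n_club_edges == 0:
        return 0.0, True
    iu = np.triu_indices(W.shape[0], 1)
    all_w = np.sort(W[iu][W[iu] > 0])[::-1]
    top = all_w[:n_club_edges].sum()
    return float(sub[iu_sub].sum() / top), False


def rich_club(m, k: int, variant: str = "binary") -> float:
    """Rich-club coefficient phi(k) over nodes of degree >= k."""
    return _rich_club_impl(m, k, variant)[0]


@dataclass
class NetworkFeatureVector:
    """Named Table-style network coefficients (26 by default)."""

    values: dict[str, float]
    degenerate: dict[str, bool]
    order: tuple[str, ...] = FEATURE_ORDER_26

    def __post_init__(self):
        if set(self.values) != set(self.order):
            raise InvariantError("feature names do not match the declared order")
        if any(not np.isfinite(v) for v in self.values.values()):
            raise InvariantError("network features must be finite after substitution")

    @property
    def names(self) -> tuple[str, ...]:
        return self.order

    def to_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in self.order], dtype=float)

    def __len__(self):
        return len(self.order)


def assemble_features(m_weighted, m_binary=None, n_null: int = 20, seed: int = 0,
                      feature_mode: str = "26") -> NetworkFeatureVector:
    """Compute the full named coefficient vector for one connectome.

    ``m_binary`` defaults to the binarised weighted matrix.  Degenerate
    coefficients (empty club, zero degree variance, no connected pair)
    substitute 0 and are flagged rather than raising, so a heavily
    filtered connectome still yields a finite feature vector.
    """
    from .roa import binarize

    if m_binary is None:
        m_binary = binarize(m_weighted)
    Wb = _as_weights(m_binary)
    Ww = _as_weights(m_weighted)
    if Wb.shape != Ww.shape:
        raise InvariantError("binary and weighted matrices must share labels")
    src = {"binary": m_binary, "weighted": m_weighted}

    impls = {
        "density": _density_impl,
        "clustering": _clustering_impl,
        "transitivity": _transitivity_impl,
        "char_path": _char_path_impl,
        "global_efficiency": _global_efficiency_impl,
        "diameter": _diameter_impl,
        "radius": _radius_impl,
        "assortativity": _assortativity_impl,
    }
    values, flags = {}, {}
    for variant in ("binary", "weighted"):
        mm = src[variant]
        for name, fn in impls.items():
            values[f"{name}_{variant}"], flags[f"{name}_{variant}"] = fn(mm, variant)
        values[f"small_world_{variant}"], flags[f"small_world_{variant}"] = _small_world_impl(
            mm, variant, n_null=n_null, seed=seed
        )
        for k in RICH_CLUB_KS:
            key = f"rich_club_k{k}_{variant}"
            values[key], flags[key] = _rich_club_impl(mm, k, variant)

    order = FEATURE_ORDER_26 if feature_mode == "26" else FEATURE_ORDER_25
    values = {k: values[k] for k in order}
    flags = {k: flags[k] for k in order}
    return NetworkFeatureVector(values=values, degenerate=flags, order=order)
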