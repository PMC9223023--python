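"""Queen-contiguity weights and spatial autocorrelation statistics.

Implements the exploratory spatial data analysis toolkit the ODR study runs
on the predicted municipal values:

* Queen-contiguity spatial weights built from zone polygons (two zones are
  neighbors iff their boundaries share at least one point, vertex or edge),
  with binary or row standardization and GAL-format I/O;
* global Moran's I with analytic randomization inference and permutation
  inference (two-sided pseudo p-values);
* local Moran's I (LISA) with quadrant labels (HH/LL/HL/LH), conditional-
  permutation variance and z-based significance classes;
* Getis-Ord Gi* (self-inclusive, binary weights) with hot/cold-spot classes
  at the |z| = 1.96 / 2.58 thresholds.

Conventions: x values are mean-centered internally; Moran statistics use
row-standardized weights by default, Gi* always binary weights including
self. Under the no-autocorrelation null E[I] = E[I_i] = -1/(n-1).

Units with no neighbors (islands) have an undefined spatial lag: they are
retained in the weights (empty neighbor set, logged) but excluded from local
statistics with an explicit flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import shapely
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "GlobalMoranResult",
    "LocalMoranResult",
    "GiStarResult",
    "build_queen_weights",
    "lattice_queen_weights",
    "read_gal",
    "write_gal",
    "global_moran",
    "local_moran",
    "getis_ord_gistar",
    "classify_significance",
]

Z_05 = 1.96
Z_01 = 2.58


@dataclass
class SpatialWeights:
    """Sparse contiguity weights.

    ``neighbors[i]`` is the sorted integer array of unit i's neighbors and
    ``weights[i]`` the matching weight array. The neighbor relation must be
    symmetric before standardization; ``standardization`` is ``"binary"``
    (w_ij = 1) or ``"row"`` (each row sums to 1).
    """

    n: int
    neighbors: list
    weights: list
    standardization: str = "binary"
    include_self: bool = False
    ids: list = None

    def __post_init__(self):
        if self.ids is None:
            self.ids = [str(i) for i in range(self.n)]
        self.neighbors = [np.asarray(nb, dtype=np.int64) for nb in self.neighbors]
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        if len(self.neighbors) != self.n or len(self.weights) != self.n:
            raise ValueError("neighbors/weights length must equal n")
        if not self.include_self:
            for i, nb in enumerate(self.neighbors):
                if i in nb:
                    raise ValueError(f"unit {i} neighbors itself")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_neighbor_sets(cls, neighbor_sets, ids=None) -> "SpatialWeights":
        """Binary weights from ``{i: set of j}`` (symmetry enforced)."""
        n = len(neighbor_sets)
        for i, nbs in neighbor_sets.items():
            for j in nbs:
                if i not in neighbor_sets[j]:
                    raise ValueError(f"asymmetric neighbor relation ({i}, {j})")
        neighbors = [np.sort(np.fromiter(neighbor_sets[i], dtype=np.int64, count=len(neighbor_sets[i])))
                     for i in range(n)]
        weights = [np.ones(len(nb)) for nb in neighbors]
        return cls(n, neighbors, weights, "binary", False, ids)

    # -- views --------------------------------------------------------------

    @property
    def islands(self):
        return [i for i, nb in enumerate(self.neighbors) if nb.size == 0]

    @property
    def s0(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def sparse(self) -> sp.csr_matrix:
        rows = np.repeat(np.arange(self.n), [nb.size for nb in self.neighbors])
        cols = np.concatenate(self.neighbors) if self.n else np.empty(0, dtype=np.int64)
        vals = np.concatenate(self.weights) if self.n else np.empty(0)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def lag(self, x) -> np.ndarray:
        """Spatial lag Wx; NaN for islands (undefined)."""
        out = self.sparse() @ np.asarray(x, dtype=float)
        for i in self.islands:
            out[i] = np.nan
        return out

    # -- transforms ---------------------------------------------------------

    def row_standardized(self) -> "SpatialWeights":
        weights = []
        for nb, w in zip(self.neighbors, self.weights):
            s = w.sum()
            weights.append(w / s if s > 0 else w.copy())
        return SpatialWeights(self.n, [nb.copy() for nb in self.neighbors],
                              weights, "row", self.include_self, list(self.ids))

    def binary(self) -> "SpatialWeights":
        return SpatialWeights(self.n, [nb.copy() for nb in self.neighbors],
                              [np.ones(nb.size) for nb in self.neighbors],
                              "binary", self.include_self, list(self.ids))

    def with_self(self) -> "SpatialWeights":
        """Binary weights with each unit added to its own neighborhood
        (the Gi* convention)."""
        neighbors, weights = [], []
        for i, nb in enumerate(self.neighbors):
            nbs = np.sort(np.append(nb, i)) if i not in nb else nb.copy()
            neighbors.append(nbs)
            weights.append(np.ones(nbs.size))
        return SpatialWeights(self.n, neighbors, weights, "binary", True, list(self.ids))


def build_queen_weights(zones) -> SpatialWeights:
    """Queen-contiguity weights from zone polygons.

    Two zones are neighbors iff their geometries share at least one boundary
    point (an edge or a single vertex both count). Islands are retained with
    empty neighbor sets and logged.
    """
    geoms = list(zones.geometries)
    ids = list(zones.zone_ids)
    if len(geoms) < 2:
        raise ValueError("need at least two zones to build contiguity weights")
    tree = STRtree(geoms)
    ii, jj = tree.query(geoms, predicate="intersects")
    sets = {i: set() for i in range(len(geoms))}
    for i, j in zip(ii.tolist(), jj.tolist()):
        if i == j:
            continue
        # bulk predicate already guarantees a shared point
        sets[i].add(j)
        sets[j].add(i)
    w = SpatialWeights.from_neighbor_sets(sets, ids=ids)
    for i in w.islands:
        logger.warning("zone %s is an island (no Queen neighbors)", ids[i])
    return w


def lattice_queen_weights(rows, cols, ids=None) -> SpatialWeights:
    """Analytic Queen adjacency of a rows x cols lattice (row-major order)."""
    sets = {}
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            nbs = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        nbs.add(rr * cols + cc)
            sets[i] = nbs
    return SpatialWeights.from_neighbor_sets(sets, ids=ids)


# -- GAL I/O ----------------------------------------------------------------


def write_gal(w: SpatialWeights, path):
    """Write the neighbor structure in the GAL adjacency-list convention."""
    with open(path, "w") as fh:
        fh.write(f"{w.n}\n")
        for i, nb in enumerate(w.neighbors):
            fh.write(f"{w.ids[i]} {nb.size}\n")
            if nb.size:
                fh.write(" ".join(w.ids[j] for j in nb) + "\n")


def read_gal(path) -> SpatialWeights:
    with open(path) as fh:
        tokens_by_line = [line.split() for line in fh if line.strip()]
    header = tokens_by_line[0]
    # plain "n" header or the 4-token GeoDa variant "0 n shapefile field"
    n = int(header[1]) if len(header) == 4 else int(header[0])
    ids, neighbor_ids = [], []
    k = 1
    for _ in range(n):
        zid, deg = tokens_by_line[k][0], int(tokens_by_line[k][1])
        k += 1
        nbs = []
        if deg > 0:
            nbs = tokens_by_line[k]
            if len(nbs) != deg:
                raise ValueError(f"GAL record for {zid} lists {len(nbs)} != {deg} neighbors")
            k += 1
        ids.append(zid)
        neighbor_ids.append(nbs)
    index = {zid: i for i, zid in enumerate(ids)}
    sets = {i: {index[z] for z in nbs} for i, nbs in enumerate(neighbor_ids)}
    return SpatialWeights.from_neighbor_sets(sets, ids=ids)


# -- global Moran's I -------------------------------------------------------


@dataclass
class GlobalMoranResult:
    I: float
    expectation: float
    variance: float
    z: float
    pseudo_p: float
    n_permutations: int
    inference: str = "randomization"


def _check_xw(x, w: SpatialWeights, min_n=2):
    x = np.asarray(x, dtype=float)
    if x.shape != (w.n,):
        raise ValueError("x length must equal the number of spatial units")
    if w.n < min_n:
        raise ValueError(f"need at least {min_n} spatial units")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: zero variance, statistic undefined")
    if w.s0 == 0:
        raise ValueError("weights have no connectivity (all islands)")
    return x


def _moran_stat(z, W, s0):
    """I = (n/S0) * z'Wz / z'z for mean-centered z (columns vectorized)."""
    n = z.shape[0]
    num = np.einsum("ij,ij->j", z, W @ z) if z.ndim == 2 else float(z @ (W @ z))
    den = np.sum(z * z, axis=0)
    return (n / s0) * num / den


def global_moran(x, w: SpatialWeights, inference="randomization",
                 n_perm=999, seed=None) -> GlobalMoranResult:
    """Global Moran's I with randomization-analytic or permutation inference.

    ``inference="randomization"`` uses the closed-form moments of I under
    random relabelling (Cliff-Ord); ``"permutation"`` uses the empirical
    distribution over ``n_perm`` random relabellings, with two-sided pseudo
    p = (1 + #{|I_perm - E| >= |I_obs - E|}) / (1 + n_perm). The z value is
    always (I - E)/sqrt(variance) with the variance of the chosen mode.
    """
    x = _check_xw(x, w)
    n = w.n
    W = w.sparse()
    s0 = w.s0
    z = x - x.mean()
    I = float(_moran_stat(z[:, None], W, s0)[0])
    e_i = -1.0 / (n - 1)

    if inference == "randomization":
        if n < 4:
            raise ValueError("randomization variance needs n >= 4; "
                             "use permutation inference for tiny maps")
        Wd = W.toarray()
        s1 = 0.5 * float(np.sum((Wd + Wd.T) ** 2))
        s2 = float(np.sum((Wd.sum(axis=1) + Wd.sum(axis=0)) ** 2))
        m2 = float(np.mean(z**2))
        b2 = float(np.mean(z**4)) / m2**2
        num = (n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
               - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2))
        den = (n - 1) * (n - 2) * (n - 3) * s0**2
        variance = num / den - e_i**2
        zscore = (I - e_i) / math.sqrt(variance)
        # two-sided normal p as the analytic analogue of the pseudo p
        from scipy.stats import norm
        p = float(2.0 * norm.sf(abs(zscore)))
        return GlobalMoranResult(I, e_i, variance, zscore, p, 0, "randomization")

    if inference != "permutation":
        raise ValueError("inference must be 'randomization' or 'permutation'")
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(z)
    sims = np.asarray(_moran_stat(perms, W, s0))
    variance = float(np.var(sims, ddof=1))
    zscore = (I - e_i) / math.sqrt(variance) if variance > 0 else float("nan")
    extreme = int(np.sum(np.abs(sims - e_i) >= abs(I - e_i) - 1e-14))
    p = (1.0 + extreme) / (1.0 + n_perm)
    return GlobalMoranResult(I, e_i, variance, zscore, p, n_perm, "permutation")


# -- local Moran's I (LISA) -------------------------------------------------


@dataclass
class LocalMoranResult:
    unit_id: str
    Ii: float
    e_Ii: float
    var_Ii: float
    zi: float
    pseudo_p: float
    quadrant: str      # HH / LL / HL / LH
    significant: str   # ns / p05 / p01
    island: bool = False


def classify_significance(z) -> str:
    """Two-sided significance class from a z value: |z| < 1.96 -> ns,
    1.96 <= |z| < 2.58 -> p05, |z| >= 2.58 -> p01 (boundaries inclusive)."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    az = abs(z)
    if az >= Z_01:
        return "p01"
    if az >= Z_05:
        return "p05"
    return "ns"


def local_moran(x, w: SpatialWeights, n_perm=999, seed=None) -> list:
    """Local Moran's I_i with conditional-permutation inference.

    I_i = n (x_i - xbar) * sum_j w_ij (x_j - xbar) / sum_k (x_k - xbar)^2.
    The variance of each I_i comes from ``n_perm`` conditional permutations
    (x_i held fixed, the other n-1 values shuffled among its neighbors);
    the expectation under the null is -1/(n-1). z_i = (I_i - E)/sd and the
    significance class follows the |z| = 1.96 / 2.58 thresholds. Quadrants
    are assigned from the signs of the centered value and its spatial lag.
    Islands get NaN statistics and ``island=True``.
    """
    x = _check_xw(x, w)
    n = w.n
    z = x - x.mean()
    m2_sum = float(np.sum(z**2))
    e_ii = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)

    results = []
    for i in range(n):
        nb = w.neighbors[i]
        wi = w.weights[i]
        if nb.size == 0:
            results.append(LocalMoranResult(w.ids[i], np.nan, e_ii, np.nan,
                                            np.nan, np.nan, "ns", "ns", island=True))
            continue
        lag = float(wi @ z[nb])
        Ii = n * z[i] * lag / m2_sum
        # conditional permutation: draw neighbor values from z without z_i
        others = np.delete(z, i)
        idx = np.argsort(rng.random((n_perm, others.size)), axis=1)[:, : nb.size]
        sim_lag = np.take(others, idx) @ wi
        sims = n * z[i] * sim_lag / m2_sum
        var = float(np.var(sims, ddof=1))
        zi = (Ii - e_ii) / math.sqrt(var) if var > 0 else np.nan
        extreme = int(np.sum(np.abs(sims - sims.mean()) >= abs(Ii - sims.mean()) - 1e-14))
        p = (1.0 + extreme) / (1.0 + n_perm)
        quadrant = ("H" if z[i] > 0 else "L") + ("H" if lag > 0 else "L")
        sig = classify_significance(zi) if np.isfinite(zi) else "ns"
        results.append(LocalMoranResult(w.ids[i], float(Ii), e_ii, var,
                                        float(zi), p, quadrant, sig))
    return results


# -- Getis-Ord Gi* ----------------------------------------------------------


@dataclass
class GiStarResult:
    unit_id: str
    gi_star: float
    cls: str  # cold_99 / cold_95 / ns / hot_95 / hot_99


def _gi_class(g) -> str:
    if g >= Z_01:
        return "hot_99"
    if g >= Z_05:
        return "hot_95"
    if g <= -Z_01:
        return "cold_99"
    if g <= -Z_05:
        return "cold_95"
    return "ns"


def getis_ord_gistar(x, w: SpatialWeights) -> list:
    """Getis-Ord Gi* hot/cold-spot statistic (z-valued, self-inclusive).

    Gi* = (sum_j w_ij x_j - xbar sum_j w_ij) /
          (S sqrt([n sum_j w_ij^2 - (sum_j w_ij)^2] / (n - 1)))

    with S the population standard deviation of x (divisor n) and binary
    weights including the unit itself (enforced here regardless of the input
    standardization). Classes: hot/cold at |Gi*| >= 1.96, strong at 2.58.
    """
    x = _check_xw(x, w)
    ws = w.with_self()
    n = ws.n
    xbar = float(x.mean())
    s = float(np.sqrt(np.mean(x**2) - xbar**2))
    if s == 0:
        raise ValueError("x is constant: S = 0, Gi* undefined")
    results = []
    for i in range(n):
        nb = ws.neighbors[i]
        wi = ws.weights[i]
        wsum = float(wi.sum())
        w2sum = float((wi**2).sum())
        num = float(wi @ x[nb]) - xbar * wsum
        den = s * math.sqrt((n * w2sum - wsum**2) / (n - 1))
        if den == 0.0:
            # neighborhood spans the whole dataset: Gi* has zero variance
            logger.warning("unit %s neighbors every unit; Gi* undefined", ws.ids[i])
            results.append(GiStarResult(ws.ids[i], float("nan"), "ns"))
            continue
        g = num / den
        results.append(GiStarResult(ws.ids[i], float(g), _gi_class(g)))
    return results
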