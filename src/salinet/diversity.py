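"""Alpha/beta diversity and distance-based multivariate tests.

Covers observed richness and Shannon diversity, Bray-Curtis
dissimilarity, great-circle geographic distance, non-metric
multidimensional scaling, PERMANOVA, and (partial) Mantel tests.
PERMANOVA and Mantel are implemented here with explicit seeded
permutation schemes so p-values are exactly reproducible; scikit-bio's
implementations serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.manifold import MDS

from .datatypes import OtuTable, SalinetError, SampleMetadata

EARTH_RADIUS_KM = 6371.0088


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Observed OTU richness S and Shannon index H' (natural log).

    H' = -sum(p_i ln p_i) over OTUs with positive count; an all-zero
    sample gets S = 0, H' = 0 with a warning.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        warnings.warn("all-zero sample(s): richness and Shannon set to 0", UserWarning)
    s_obs = (counts > 0).sum(axis=1)
    shannon = np.zeros(len(totals))
    for i, row in enumerate(counts):
        if totals[i] == 0:
            continue
        p = row[row > 0] / totals[i]
        shannon[i] = -np.sum(p * np.log(p))
    return pd.DataFrame(
        {"observed_otus": s_obs, "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d_ij = sum|x-y| / sum(x+y) in [0, 1]."""
    if table.n_samples < 2:
        raise SalinetError("need at least 2 samples for Bray-Curtis")
    counts = table.counts.to_numpy(dtype=float)
    zero = counts.sum(axis=1) == 0
    if zero.sum() >= 2:
        ids = [s for s, z in zip(table.sample_ids, zero) if z]
        raise SalinetError(f"Bray-Curtis undefined between all-zero samples: {ids}")
    condensed = pdist(counts, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def geographic_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between sample sites."""
    for col in ("latitude", "longitude"):
        if col not in metadata.data.columns or metadata.data[col].isna().any():
            raise SalinetError(f"missing coordinates: {col}")
    lat = np.radians(metadata.data["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata.data["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=metadata.sample_ids)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two points in km."""
    p1, p2 = np.radians([lat1, lat2])
    dphi = np.radians(lat2 - lat1)
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 50,
    seed: int | None = 0,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs ``n_starts`` random initialisations of iterative monotone
    (isotonic) regression + SMACOF and keeps the best-stress solution;
    coordinates are centred.  Stress is Kruskal's stress-1.
    """
    n = dist.shape[0]
    if k >= n:
        raise SalinetError(f"k={k} must be smaller than the number of samples ({n})")
    model = MDS(
        n_components=k,
        metric_mds=False,
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        metric="precomputed",
        normalized_stress=True,
        init="random",
        eps=1e-9,
    )
    coords = model.fit_transform(dist.data)
    coords = coords - coords.mean(axis=0)
    frame = pd.DataFrame(
        coords, index=pd.Index(list(dist.ids), name="sample_id"),
        columns=[f"MDS{i + 1}" for i in range(k)],
    )
    return NmdsResult(coordinates=frame, stress=float(model.stress_))


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ssw += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    with np.errstate(divide="ignore"):
        f = (ssa / (n_groups - 1)) / (ssw / (n - n_groups))
    return f, ssa / sst


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F partitions the squared distances into among- and
    within-group sums of squares; significance is by permutation of the
    group labels with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    labels = pd.Series(list(groups))
    codes, uniques = pd.factorize(labels)
    if len(uniques) < 2:
        raise SalinetError("PERMANOVA needs at least 2 groups")
    if len(labels) != dist.shape[0]:
        raise SalinetError("group labels must match distance matrix size")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs, r2 = _permanova_f(d2, codes, len(uniques))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_f(d2, perm, len(uniques))
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r2), p_value=p,
                           n_permutations=n_perm)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    partial: bool


def _lower(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices(mat.shape[0], -1)]


def _residuals(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    conditioning: DistanceMatrix | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "pearson",
) -> MantelResult:
    """(Partial) Mantel correlation between two distance matrices.

    The statistic is the Pearson (or Spearman) correlation of the lower
    triangles.  The partial variant correlates the residuals of both
    triangles on the conditioning triangle.  Significance permutes the
    rows/columns of ``dx`` jointly, recomputing residuals each time.
    """
    ids = list(dx.ids)
    if list(dy.ids) != ids or (conditioning is not None and list(conditioning.ids) != ids):
        raise SalinetError("distance matrices must share the same sample ids in order")
    x = np.asarray(dx.data, dtype=float)
    yv = _lower(np.asarray(dy.data, dtype=float))
    zv = _lower(np.asarray(conditioning.data, dtype=float)) if conditioning is not None else None

    def rank(v: np.ndarray) -> np.ndarray:
        return pd.Series(v).rank().to_numpy()

    def stat(xmat: np.ndarray) -> float:
        xv = _lower(xmat)
        if method == "spearman":
            a, b = rank(xv), rank(yv)
            c = rank(zv) if zv is not None else None
        elif method == "pearson":
            a, b, c = xv, yv, zv
        else:
            raise SalinetError(f"unknown method {method!r}")
        if c is not None:
            scale_a, scale_b = a.std(), b.std()
            a, b = _residuals(a, c), _residuals(b, c)
            # fully-explained residuals are numerical noise; their
            # correlation is 0 by convention, not a random sign
            if a.std() < 1e-10 * max(scale_a, 1e-30) or b.std() < 1e-10 * max(scale_b, 1e-30):
                return 0.0
        denom = a.std() * b.std()
        if denom == 0:
            raise SalinetError("constant distance triangle: Mantel r undefined")
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = stat(x)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(stat(x[np.ix_(perm, perm)])) >= abs(r_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm,
                        partial=conditioning is not None)


def distance_decay_r2(dist_community: DistanceMatrix, dist_predictor: DistanceMatrix) -> float:
    """R^2 of the ordinary regression of community dissimilarity on a
    predictor distance (the descriptive scatter-fit companion to the
    Mantel test)."""
    y = _lower(np.asarray(dist_community.data, dtype=float))
    x = _lower(np.asarray(dist_predictor.data, dtype=float))
    return float(np.corrcoef(x, y)[0, 1] ** 2)
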