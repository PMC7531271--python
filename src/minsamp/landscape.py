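"""Landscape-genetic statistics: IBD/IBE and central-abundance tests.

Isolation by distance (IBD) and by environment (IBE) are tested with
multiple regression on distance matrices (MRM): ordinary least squares
of the unfolded lower triangle of the pairwise-FST matrix on the
unfolded geographic and environmental distance matrices jointly, with
significance from permutations of the response matrix (rows and columns
permuted together, predictors fixed).

The central-abundance hypothesis (CAH) — genetic diversity declines
with distance from the geographic or niche centroid — is tested with a
simple linear regression of per-population Hs on centroid distance.

Environmental structure is summarised by the first principal component
of the (scaled) environmental variables, as is standard for bioclimatic
covariates with heterogeneous units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datasets import PopMetadata

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrices:
    pop_ids: list[str]
    geographic: np.ndarray
    environmental: np.ndarray
    genetic: np.ndarray


@dataclass
class MrmResult:
    beta_geo: float
    beta_env: float
    intercept: float
    r_squared: float
    p_geo: float
    p_env: float
    n_permutations: int


@dataclass
class CahResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    predictor: str


# ---------------------------------------------------------------------------


def env_pc1(env: np.ndarray, scale: bool = True,
            return_model: bool = False):
    """Scores of the first principal component of environmental variables.

    PCA is computed on centred and (by default) unit-variance-scaled
    variables, appropriate for covariates with heterogeneous units.
    Zero-variance variables are dropped with a warning.  The sign is
    fixed so the loading with the largest magnitude is positive.
    """
    env = np.asarray(env, dtype=float)
    if env.ndim != 2 or env.shape[1] < 2:
        raise ValueError("need a populations x variables matrix with >= 2 variables")
    if env.shape[0] < 3:
        raise ValueError("need at least 3 populations for a PCA")
    sd = env.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variable(s)")
    X = env[:, keep] - env[:, keep].mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    # SVD of the centred matrix: PC1 scores = u1 * s1
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    load = vt[0]
    sign = np.sign(load[np.argmax(np.abs(load))]) or 1.0
    scores = sign * u[:, 0] * s[0]
    if return_model:
        explained = s ** 2 / (s ** 2).sum()
        return scores, sign * load, float(explained[0])
    return scores


def haversine_matrix(lonlat: np.ndarray) -> np.ndarray:
    """Great-circle distances (km) between decimal-degree (lon, lat) rows."""
    rad = np.radians(np.asarray(lonlat, dtype=float))
    lon, lat = rad[:, 0], rad[:, 1]
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def distance_matrices(meta: PopMetadata, genetic: np.ndarray,
                      pop_ids: list[str] | None = None) -> DistanceMatrices:
    """Assemble the geographic / environmental / genetic distance trio.

    Geographic distance is great-circle (haversine, km) for lon/lat
    metadata and Euclidean for planar synthetic coordinates.
    Environmental distance is the absolute difference of PC1 scores.
    ``genetic`` is a pairwise-FST matrix over the same populations, in
    the same order (or in ``pop_ids`` order if given).
    """
    genetic = np.asarray(genetic, dtype=float)
    if pop_ids is not None:
        if set(pop_ids) != set(meta.pop_ids):
            missing = sorted(set(pop_ids) ^ set(meta.pop_ids))
            raise ValueError(f"population id mismatch: {missing}")
        order = [meta.pop_ids.index(p) for p in pop_ids]
        meta = meta.take_pops(np.array(order))
    if genetic.shape != (meta.n_pops, meta.n_pops):
        raise ValueError("genetic distance matrix shape does not match metadata")
    if meta.planar:
        d = meta.coords
        geo = np.linalg.norm(d[:, None, :] - d[None, :, :], axis=2)
    else:
        geo = haversine_matrix(meta.coords)
    pc1 = meta.pc1 if meta.pc1 is not None else env_pc1(meta.env)
    env = np.abs(pc1[:, None] - pc1[None, :])
    return DistanceMatrices(pop_ids=list(meta.pop_ids), geographic=geo,
                            environmental=env, genetic=genetic)


def _unfold(mat: np.ndarray) -> np.ndarray:
    """Lower triangle (excluding the diagonal) as a vector."""
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def _mrm_design(geographic: np.ndarray,
                environmental: np.ndarray | None):
    xg = _unfold(geographic)
    if np.std(xg) == 0:
        raise ValueError("constant predictor distance matrix")
    cols = [np.ones_like(xg), xg]
    if environmental is not None:
        xe = _unfold(environmental)
        if np.std(xe) == 0:
            raise ValueError("constant predictor distance matrix")
        if np.abs(np.corrcoef(xg, xe)[0, 1]) >= 1.0 - 1e-12:
            raise ValueError("perfectly collinear predictors")
        cols.append(xe)
    return np.column_stack(cols)


def mrm(genetic: np.ndarray, geographic: np.ndarray,
        environmental: np.ndarray | None = None, n_permutations: int = 1000,
        seed: int | None = None) -> MrmResult:
    """Multiple regression on distance matrices with permutation tests.

    Fits ``genetic ~ geographic + environmental`` jointly (or
    ``genetic ~ geographic`` alone when ``environmental`` is None, which
    is then plain OLS on the unfolded distances) on the unfolded lower
    triangles.  Significance per coefficient is the proportion of
    permutations (response matrix rows and columns permuted together,
    predictors fixed; observed configuration included in the count) with
    ``|beta*| >= |beta_observed|``.
    """
    S = genetic.shape[0]
    if S < 4:
        raise ValueError("MRM needs at least 4 populations")
    X = _mrm_design(geographic, environmental)
    y = _unfold(genetic)
    good = ~np.isnan(y)
    XtXi_Xt = np.linalg.pinv(X[good])
    beta = XtXi_Xt @ y[good]
    fitted = X[good] @ beta
    ss_res = ((y[good] - fitted) ** 2).sum()
    ss_tot = ((y[good] - y[good].mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    rng = np.random.default_rng(seed)
    count = np.ones(X.shape[1])
    for _ in range(n_permutations - 1):
        perm = rng.permutation(S)
        yp = _unfold(genetic[np.ix_(perm, perm)])
        bp = XtXi_Xt @ yp[good]
        count += np.abs(bp) >= np.abs(beta)
    p = count / n_permutations
    has_env = environmental is not None
    return MrmResult(beta_geo=float(beta[1]),
                     beta_env=float(beta[2]) if has_env else float("nan"),
                     intercept=float(beta[0]), r_squared=float(r2),
                     p_geo=float(p[1]),
                     p_env=float(p[2]) if has_env else float("nan"),
                     n_permutations=n_permutations)


def mrm_fit_only(genetic: np.ndarray, geographic: np.ndarray,
                 environmental: np.ndarray | None = None) -> MrmResult:
    """The MRM point estimates without permutation testing (p = NaN);
    used inside replicate loops where only the coefficients matter."""
    X = _mrm_design(geographic, environmental)
    y = _unfold(genetic)
    good = ~np.isnan(y)
    if good.sum() < 4:
        raise ValueError("too few defined pairwise distances")
    beta, *_ = np.linalg.lstsq(X[good], y[good], rcond=None)
    fitted = X[good] @ beta
    ss_res = ((y[good] - fitted) ** 2).sum()
    ss_tot = ((y[good] - y[good].mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    has_env = environmental is not None
    return MrmResult(beta_geo=float(beta[1]),
                     beta_env=float(beta[2]) if has_env else float("nan"),
                     intercept=float(beta[0]), r_squared=float(r2),
                     p_geo=float("nan"), p_env=float("nan"), n_permutations=0)


def centroid_distances(meta: PopMetadata, n_niche_pcs: int = 2) -> PopMetadata:
    """Distances to the geographic and niche centroids.

    The geographic centroid is the coordinate-wise mean of the
    population coordinates; the niche centroid is the mean position in
    the space of the first ``n_niche_pcs`` environmental principal
    components.  Distances are Euclidean in the respective space.
    Returns a copy of the metadata with the derived columns filled in.
    """
    if meta.n_pops < 2:
        raise ValueError("need at least 2 populations")
    coords = meta.coords
    geo_cd = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
    env = meta.env
    n = meta.n_pops
    sd = env.std(axis=0, ddof=1) if n > 1 else np.zeros(env.shape[1])
    X = env[:, sd > 0]
    if X.shape[1] >= 2:
        Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(n_niche_pcs, len(s))
        niche = u[:, :k] * s[:k]
    elif X.shape[1] == 1:
        niche = X - X.mean(axis=0)
    else:                           # no varying environmental variable
        niche = np.zeros((n, 1))
    niche_cd = np.linalg.norm(niche - niche.mean(axis=0), axis=1)
    out = meta.take_pops(np.arange(meta.n_pops))
    if env.shape[1] >= 2 and n >= 3 and X.shape[1] >= 2:
        out.pc1 = env_pc1(env)
    elif X.shape[1] >= 1:
        out.pc1 = X[:, 0] - X[:, 0].mean()
    else:
        out.pc1 = np.zeros(n)
    out.geo_centroid_dist = geo_cd
    out.niche_centroid_dist = niche_cd
    return out


def cah_regression(hs_per_pop: np.ndarray, centroid_distance: np.ndarray,
                   predictor: str = "geographic") -> CahResult:
    """Central-abundance test: linear regression of Hs on centroid distance."""
    x = np.asarray(centroid_distance, dtype=float)
    y = np.asarray(hs_per_pop, dtype=float)
    good = ~np.isnan(x) & ~np.isnan(y)
    if good.sum() < 3:
        raise ValueError("need at least 3 populations with data")
    if np.std(x[good]) == 0:
        raise ValueError("constant centroid-distance predictor")
    res = sps.linregress(x[good], y[good])
    return CahResult(slope=float(res.slope), intercept=float(res.intercept),
                     p_value=float(res.pvalue),
                     r_squared=float(res.rvalue ** 2), predictor=predictor)
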