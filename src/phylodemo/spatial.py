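"""Spatially explicit diversity analyses.

Covers isolation by distance (Mantel test of linearized phi_ST against
log10 geodesic distance), climate-stability surfaces from suitability
rasters at several time slices, range centroids of thresholded
palaeodistributions, and quantile-regression clines of genetic diversity
against suitability, stability, or distance to a centroid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .scenarios import InvalidParameterError

EARTH_RADIUS_KM = 6371.0


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (a distance matrix is constant)."""


@dataclass(frozen=True)
class GeoPoint:
    """Latitude/longitude in decimal degrees (spherical Earth)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90:
            raise InvalidParameterError(f"latitude {self.lat} out of range")
        if not -180 <= self.lon <= 180:
            raise InvalidParameterError(f"longitude {self.lon} out of range")


@dataclass(frozen=True)
class SuitabilityRaster:
    """A regular lat/lon grid of habitat suitability in [0, 1].

    ESRI-ASCII-style cell-center registration: row 0 is the northernmost
    row; ``(xll, yll)`` is the lower-left corner of the grid.
    """

    values: np.ndarray
    xll: float
    yll: float
    cellsize: float
    time_slice: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        valid = v != self.nodata
        if np.any((v[valid] < 0) | (v[valid] > 1)):
            raise InvalidParameterError("suitability values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def grid_matches(self, other: "SuitabilityRaster") -> bool:
        return (
            self.shape == other.shape
            and self.xll == other.xll
            and self.yll == other.yll
            and self.cellsize == other.cellsize
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of cell centers, matching ``values`` shape."""
        nrows, ncols = self.shape
        lon = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        lat = self.yll + (nrows - 1 - np.arange(nrows) + 0.5) * self.cellsize
        return np.meshgrid(lat, lon, indexing="ij")


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km (haversine, R = 6,371 km)."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    s = (
        math.sin(dphi / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def distance_matrix(points: list[GeoPoint]) -> np.ndarray:
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = geodesic_distance(points[i], points[j])
    return d


@dataclass(frozen=True)
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    tail: str = "two-sided"


def _mantel_r(A: np.ndarray, B: np.ndarray, iu: tuple) -> float:
    a, b = A[iu], B[iu]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise UndefinedCorrelationError("constant distance matrix")
    return float(np.corrcoef(a, b)[0, 1])


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    ``r`` is the Pearson correlation over the upper off-diagonal
    triangle; ``p`` is the proportion of simultaneous row/column
    permutations of ``B`` with ``|r_perm| >= |r_obs|`` (two-sided).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or B.shape != (n, n) or n < 3:
        raise InvalidParameterError("need square matrices of dimension >= 3")
    if not (np.allclose(A, A.T) and np.allclose(B, B.T)):
        raise InvalidParameterError("distance matrices must be symmetric")
    if np.any(np.diag(A) != 0) or np.any(np.diag(B) != 0):
        raise InvalidParameterError("distance matrices need zero diagonals")
    iu = np.triu_indices(n, 1)
    r_obs = _mantel_r(A, B, iu)
    if rng is None:
        rng = np.random.default_rng()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _mantel_r(A, B[np.ix_(perm, perm)], iu)
        if abs(r_p) >= abs(r_obs):
            hits += 1
    p = hits / n_perm if n_perm else float("nan")
    return MantelResult(r=r_obs, r_squared=r_obs**2, p_value=p,
                        n_permutations=n_perm)


def mantel_exact(A: np.ndarray, B: np.ndarray) -> float:
    """Exact two-sided Mantel p by enumerating every permutation (tiny n)."""
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    r_obs = _mantel_r(A, B, iu)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.array(perm)
        r_p = _mantel_r(A, B[np.ix_(idx, idx)], iu)
        total += 1
        if abs(r_p) >= abs(r_obs) - 1e-12:
            hits += 1
    return hits / total


def suitability_stability(
    rasters: list[SuitabilityRaster], threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Climate stability and refugium mask across time slices.

    Stability per cell is minus the mean absolute pairwise difference of
    suitability across slices (0 = perfectly stable, more negative =
    less stable).  The refugium mask marks cells at or above
    ``threshold`` in every slice.
    """
    if len(rasters) < 2:
        raise InvalidParameterError("need at least two time slices")
    first = rasters[0]
    for r in rasters[1:]:
        if not first.grid_matches(r):
            raise InvalidParameterError("raster grids do not align")
    stack = np.stack([r.values for r in rasters])
    diffs = [
        np.abs(stack[i] - stack[j])
        for i, j in itertools.combinations(range(len(rasters)), 2)
    ]
    stability = -np.mean(diffs, axis=0)
    refugium = np.all(stack >= threshold, axis=0)
    return stability, refugium


def range_centroid(raster: SuitabilityRaster, threshold: float) -> GeoPoint:
    """Unweighted centroid of cell centers at or above the threshold."""
    mask = raster.values >= threshold
    if not np.any(mask):
        raise InvalidParameterError("no cells above threshold; empty range")
    lat, lon = raster.cell_centers()
    return GeoPoint(lat=float(lat[mask].mean()), lon=float(lon[mask].mean()))


def centroid_distances(
    points: list[GeoPoint], centroid: GeoPoint
) -> np.ndarray:
    """Geodesic distance (km) from each population to a range centroid."""
    return np.array([geodesic_distance(p, centroid) for p in points])


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    intercept: float
    slope: float
    pinball_loss: float
    n_obs: int


def pinball_loss(y: np.ndarray, pred: np.ndarray, tau: float) -> float:
    """Mean check-function loss of a quantile fit."""
    resid = y - pred
    return float(np.mean(np.where(resid >= 0, tau * resid, (tau - 1) * resid)))


def quantile_regression(
    x: np.ndarray, y: np.ndarray, tau: float = 0.5
) -> QuantileFit:
    """Linear quantile regression minimizing the pinball loss.

    Solved exactly as a linear program (HiGHS); tau = 0.5 is the
    least-absolute-deviation line.  Ties among optimal lines are broken
    by the LP solver's deterministic vertex choice.
    """
    from scipy.optimize import linprog

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InvalidParameterError("x and y must be equal-length vectors, n >= 3")
    if not 0 < tau < 1:
        raise InvalidParameterError("tau must lie in (0, 1)")
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("constant predictor: slope undefined")
    n = len(x)
    # variables: a+, a-, b+, b-, u (pos resid, n), v (neg resid, n)
    c = np.concatenate([[0, 0, 0, 0], np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1
    A_eq[:, 1] = -1
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[:, 4:4 + n] = np.eye(n)
    A_eq[:, 4 + n:] = -np.eye(n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile regression LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return QuantileFit(
        tau=tau,
        intercept=float(a),
        slope=float(b),
        pinball_loss=pinball_loss(y, a + b * x, tau),
        n_obs=n,
    )


def linearize_phist(phi: np.ndarray) -> np.ndarray:
    """Slatkin's linearization phi/(1-phi), elementwise, diagonal left 0."""
    phi = np.asarray(phi, dtype=float)
    out = np.where(phi < 1.0, phi / (1.0 - phi), np.inf)
    np.fill_diagonal(out, 0.0)
    return out


def isolation_by_distance(
    phist_matrix: np.ndarray,
    points: list[GeoPoint],
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    linearize: bool = True,
) -> MantelResult:
    """Mantel test of (linearized) phi_ST against log10 geodesic distance.

    Zero geographic distances are floored at half the minimum positive
    distance before taking logs.
    """
    phi = np.asarray(phist_matrix, dtype=float)
    if phi.shape[0] != len(points):
        raise InvalidParameterError("phi_ST matrix and point list disagree")
    gen = linearize_phist(phi) if linearize else phi.copy()
    geo = distance_matrix(points)
    off = geo[np.triu_indices(len(points), 1)]
    positive = off[off > 0]
    if positive.size == 0:
        raise UndefinedCorrelationError("all populations are co-located")
    floor = positive.min() / 2.0
    geo = np.maximum(geo, floor)
    log_geo = np.log10(geo)
    np.fill_diagonal(log_geo, 0.0)
    return mantel_test(gen, log_geo, n_perm=n_perm, rng=rng)
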