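"""Concentration × time response surfaces and thin-plate-spline smoothing.

Each gene's control-subtracted log2 response lives on the 8 × 5 design grid.
Before smoothing, coordinates are transformed to u = log10(c/µM),
v = log10(t/h): the design is geometric in concentration and near-geometric
in time, so the raw scales would pile all low-dose nodes into a corner.

The smoother minimises ``rho * sum(residual^2) + (1 - rho) * bending energy``
over the transformed plane — the classical thin-plate smoothing-spline
objective. rho = 1 interpolates exactly; rho -> 0 flattens towards the
least-squares plane (affine functions are the null space of the bending
penalty and are always reproduced exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial.distance import pdist


class SurfaceError(ValueError):
    pass


@dataclass
class ResponseSurfaceSet:
    """Per-gene control-subtracted log2 responses on the design grid."""

    gene_ids: list[str]
    conc_grid: np.ndarray  # µM, strictly ascending
    time_grid: np.ndarray  # h, strictly ascending
    values: np.ndarray  # genes × n_conc × n_time; NaN on unobserved cells
    observed: np.ndarray | None = None  # n_conc × n_time bool mask
    chemical: str | None = None
    bio_rep: int | None = None

    def __post_init__(self) -> None:
        self.conc_grid = np.asarray(self.conc_grid, dtype=float)
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, grid in (("conc_grid", self.conc_grid), ("time_grid", self.time_grid)):
            if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
                raise SurfaceError(f"{name} must be positive and strictly increasing")
        if self.values.shape != (
            len(self.gene_ids),
            len(self.conc_grid),
            len(self.time_grid),
        ):
            raise SurfaceError("values shape does not match gene/grid dimensions")
        if self.observed is None:
            self.observed = np.ones((len(self.conc_grid), len(self.time_grid)), dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not np.all(np.isfinite(self.values[:, self.observed])):
            raise SurfaceError("non-finite response on an observed design cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset_genes(self, genes) -> "ResponseSurfaceSet":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return ResponseSurfaceSet(
            [self.gene_ids[i] for i in idx],
            self.conc_grid,
            self.time_grid,
            self.values[idx],
            self.observed,
            self.chemical,
            self.bio_rep,
        )

    def matrix(self) -> np.ndarray:
        """Genes × (n_conc * n_time) flattened view of the observed cells."""
        return self.values.reshape(self.n_genes, -1)


def _transform(conc: np.ndarray, time_h: np.ndarray) -> np.ndarray:
    return np.column_stack([np.log10(conc), np.log10(time_h)])


def auto_rho(nodes: np.ndarray) -> float:
    """rho = 1 / (1 + h^3 / 6), h the mean nearest-neighbour spacing of the
    node sites in transformed coordinates — the customary smoothing-spline
    default for scattered thin-plate fits."""
    if len(nodes) < 2:
        return 1.0
    d = pdist(nodes)
    n = len(nodes)
    dm = np.full((n, n), np.inf)
    iu = np.triu_indices(n, 1)
    dm[iu] = d
    dm.T[iu] = d
    h = float(dm.min(axis=1).mean())
    return 1.0 / (1.0 + h**3 / 6.0)


@dataclass
class SmoothSurface:
    """A smoothed response surface with a continuous (c, t) -> y evaluator.

    Evaluation outside the design rectangle is refused unless
    ``extrapolate=True``; a thin-plate spline grows like r^2 log r away from
    its nodes, so silent extrapolation would be quietly wrong.
    """

    nodes: np.ndarray  # transformed (u, v) node coordinates
    node_values: np.ndarray
    rho: float
    conc_bounds: tuple[float, float]  # µM
    time_bounds: tuple[float, float]  # h
    _rbf: RBFInterpolator = field(repr=False, default=None)

    def __call__(self, conc, time_h, extrapolate: bool = False) -> np.ndarray:
        return self.evaluate(conc, time_h, extrapolate=extrapolate)

    def evaluate(self, conc, time_h, extrapolate: bool = False) -> np.ndarray:
        conc = np.atleast_1d(np.asarray(conc, dtype=float))
        time_h = np.atleast_1d(np.asarray(time_h, dtype=float))
        conc, time_h = np.broadcast_arrays(conc, time_h)
        if not extrapolate:
            tol = 1e-9
            (clo, chi), (tlo, thi) = self.conc_bounds, self.time_bounds
            bad_c = (conc < clo * (1 - tol)) | (conc > chi * (1 + tol))
            bad_t = (time_h < tlo * (1 - tol)) | (time_h > thi * (1 + tol))
            if bad_c.any() or bad_t.any():
                i = int(np.argmax(bad_c | bad_t))
                raise SurfaceError(
                    f"point (c={conc.flat[i]} µM, t={time_h.flat[i]} h) outside the "
                    f"design rectangle [{clo}, {chi}] µM × [{tlo}, {thi}] h; "
                    "pass extrapolate=True to override"
                )
        out = self._rbf(_transform(conc.ravel(), time_h.ravel()))
        return out.reshape(conc.shape)

    def on_grid(self, conc_grid: np.ndarray, time_grid: np.ndarray) -> np.ndarray:
        cc, tt = np.meshgrid(conc_grid, time_grid, indexing="ij")
        return self.evaluate(cc, tt)


def smooth_surface(
    y: np.ndarray,
    conc_grid: np.ndarray,
    time_grid: np.ndarray,
    rho: float | str = "auto",
) -> SmoothSurface:
    """Fit a thin-plate smoothing spline to one gene's response matrix.

    ``y`` is n_conc × n_time; NaN cells (missing design cells) are omitted
    from the node set. ``rho`` in (0, 1]: 1 interpolates, smaller smooths
    harder; "auto" uses :func:`auto_rho`.
    """
    conc_grid = np.asarray(conc_grid, dtype=float)
    time_grid = np.asarray(time_grid, dtype=float)
    y = np.asarray(y, dtype=float)
    cc, tt = np.meshgrid(conc_grid, time_grid, indexing="ij")
    ok = np.isfinite(y)
    nodes = _transform(cc[ok], tt[ok])
    vals = y[ok]
    if len(vals) < 3:
        raise SurfaceError("need at least 3 observed cells to fit a surface")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(nodes)), nodes])) < 3:
        raise SurfaceError("design nodes are collinear in transformed coordinates")
    if rho == "auto":
        rho = auto_rho(nodes)
    rho = float(rho)
    if not 0 < rho <= 1:
        raise SurfaceError(f"rho must lie in (0, 1], got {rho}")
    # rho*RSS + (1-rho)*bending  <=>  RBF ridge with smoothing (1-rho)/rho
    rbf = RBFInterpolator(
        nodes, vals, kernel="thin_plate_spline", degree=1, smoothing=(1 - rho) / rho
    )
    return SmoothSurface(
        nodes=nodes,
        node_values=vals,
        rho=rho,
        conc_bounds=(float(conc_grid[0]), float(conc_grid[-1])),
        time_bounds=(float(time_grid[0]), float(time_grid[-1])),
        _rbf=rbf,
    )


def evaluate_surface(s: SmoothSurface, points, extrapolate: bool = False) -> np.ndarray:
    """Evaluate a smoothed surface at (concentration µM, time h) pairs."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return s.evaluate(pts[:, 0], pts[:, 1], extrapolate=extrapolate)


def smooth_surface_set(
    surfaces: ResponseSurfaceSet, rho: float | str = "auto"
) -> ResponseSurfaceSet:
    """Smooth every gene's surface and resample on the design grid.

    The factor decomposition downstream needs a complete matrix; smoothing
    also fills design cells that were missing in the raw means.
    """
    G = surfaces.n_genes
    out = np.empty_like(surfaces.values)
    for g in range(G):
        s = smooth_surface(
            np.where(surfaces.observed, surfaces.values[g], np.nan),
            surfaces.conc_grid,
            surfaces.time_grid,
            rho=rho,
        )
        out[g] = s.on_grid(surfaces.conc_grid, surfaces.time_grid)
    return ResponseSurfaceSet(
        list(surfaces.gene_ids),
        surfaces.conc_grid,
        surfaces.time_grid,
        out,
        np.ones_like(surfaces.observed, dtype=bool),
        surfaces.chemical,
        surfaces.bio_rep,
    )
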