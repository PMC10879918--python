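"""One-factor (PCA) model of the collective gene response.

The model decomposes the stack of smoothed gene surfaces as

    y_gct = sum_r w_gr * f_r(c, t) + e_gct

with orthonormal factors f_r on the design grid and per-gene loadings w_gr.
It is fitted by an uncentred singular-value decomposition of the
genes × (n_conc * n_time) matrix: responses are already control-subtracted
deviations, so the model carries no intercept and the decomposition is of
the second-moment (not mean-centred covariance) matrix; ``center=True``
switches to the classical covariance convention.

Sign convention: (f_1, w_.1) are flipped jointly so that f_1 sums to a
non-negative value over the grid — the common-factor surface is then
predominantly non-negative and the sign of a gene's loading reads directly
as up- (positive) or down- (negative) regulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .response_surface import ResponseSurfaceSet, SmoothSurface, smooth_surface


class FactorModelError(ValueError):
    pass


@dataclass
class FactorModel:
    conc_grid: np.ndarray
    time_grid: np.ndarray
    factors: np.ndarray  # r × n_conc × n_time, orthonormal over grid cells
    loadings: np.ndarray  # genes × r
    eigenvalues: np.ndarray  # descending, lambda_r = sigma_r^2
    gene_ids: list[str]
    n_factors_kept: int
    center: bool = False
    mean_surface: np.ndarray | None = None  # grid mean when center=True
    chemical: str | None = None
    bio_rep: int | None = None
    _evaluators: dict = field(default_factory=dict, repr=False)

    @property
    def n_factors(self) -> int:
        return self.factors.shape[0]

    @property
    def relative_eigenvalues(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot

    def loading(self, gene_id: str, r: int = 0) -> float:
        return float(self.loadings[self.gene_ids.index(gene_id), r])

    def factor_evaluator(self, r: int = 0) -> SmoothSurface:
        """Continuous f_r(c, t): a rho = 1 thin-plate interpolant of the
        factor's grid values in log10 coordinates. The factor exists only on
        the grid after the decomposition; the interpolant makes the level-set
        equation f(c, t) = v solvable between grid nodes."""
        if r not in self._evaluators:
            self._evaluators[r] = smooth_surface(
                self.factors[r], self.conc_grid, self.time_grid, rho=1.0
            )
        return self._evaluators[r]

    def reconstruct(self, p: int | None = None) -> np.ndarray:
        p = self.n_factors if p is None else p
        rec = np.tensordot(self.loadings[:, :p], self.factors[:p], axes=(1, 0))
        if self.center and self.mean_surface is not None:
            rec = rec + self.mean_surface[None]
        return rec

    def residuals(self, values: np.ndarray, p: int | None = None) -> np.ndarray:
        """e_gct = y - common part, against the supplied fitted input."""
        return values - self.reconstruct(self.n_factors_kept if p is None else p)


def fit_factor_model(
    surfaces: ResponseSurfaceSet,
    p: int = 1,
    center: bool = False,
) -> FactorModel:
    """Fit the factor model to a set of (smoothed) gene surfaces by SVD."""
    if surfaces.n_genes < 2:
        raise FactorModelError("need >= 2 genes to fit a factor model")
    Y = surfaces.matrix()
    if not np.all(np.isfinite(Y)):
        raise FactorModelError("factor fit requires complete (smoothed) grids")
    mean_surface = None
    if center:
        mean_flat = Y.mean(axis=0)
        mean_surface = mean_flat.reshape(len(surfaces.conc_grid), len(surfaces.time_grid))
        Y = Y - mean_flat[None]
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Y.shape) * np.finfo(float).eps)) if s.size else 0
    if p > len(s):
        p = len(s)
    n_kept = min(p, max(rank, 1))
    factors = Vt.reshape(len(s), len(surfaces.conc_grid), len(surfaces.time_grid))
    loadings = U * s[None, :]
    # deterministic sign fix: each factor sums >= 0 over the grid;
    # ties broken by the sign of the largest-magnitude grid cell
    for r in range(len(s)):
        tot = factors[r].sum()
        if tot == 0:
            flat = factors[r].ravel()
            tot = flat[np.argmax(np.abs(flat))]
        if tot < 0:
            factors[r] = -factors[r]
            loadings[:, r] = -loadings[:, r]
    return FactorModel(
        conc_grid=surfaces.conc_grid,
        time_grid=surfaces.time_grid,
        factors=factors,
        loadings=loadings,
        eigenvalues=s**2,
        gene_ids=list(surfaces.gene_ids),
        n_factors_kept=n_kept,
        center=center,
        mean_surface=mean_surface,
        chemical=surfaces.chemical,
        bio_rep=surfaces.bio_rep,
    )


def eigen_spectrum(model: FactorModel | list[FactorModel]) -> pd.DataFrame:
    """Relative eigenvalue shares as percentages.

    Given several models (e.g. one per biological replicate) the shares are
    averaged across them, factor by factor.
    """
    models = model if isinstance(model, list) else [model]
    n = min(m.n_factors for m in models)
    rel = np.mean([m.relative_eigenvalues[:n] for m in models], axis=0)
    return pd.DataFrame(
        {"factor": np.arange(1, n + 1), "relative_eigenvalue_pct": rel * 100}
    )


def loading_distribution(model: FactorModel, bins: int = 30, r: int = 0) -> pd.DataFrame:
    """Histogram summary of the factor-r gene loadings."""
    w = model.loadings[:, r]
    counts, edges = np.histogram(w, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def reconstruct_gene(model: FactorModel, gene_id: str, p: int | None = None) -> np.ndarray:
    """Fitted response surface of one gene from the first p factors."""
    if gene_id not in model.gene_ids:
        raise FactorModelError(f"unknown gene: {gene_id!r}")
    if p is None:
        p = model.n_factors_kept
    if p > model.n_factors:
        raise FactorModelError(f"p={p} exceeds the {model.n_factors} fitted factors")
    g = model.gene_ids.index(gene_id)
    rec = np.tensordot(model.loadings[g, :p], model.factors[:p], axes=(0, 0))
    if model.center and model.mean_surface is not None:
        rec = rec + model.mean_surface
    return rec


# ---------------------------------------------------------------------------
# archive


def save_model(model: FactorModel, path: str | Path) -> None:
    """Portable .npz archive: grids, factors, loadings, eigenvalues and a
    JSON provenance record."""
    meta = {
        "gene_ids": model.gene_ids,
        "n_factors_kept": model.n_factors_kept,
        "center": model.center,
        "chemical": model.chemical,
        "bio_rep": model.bio_rep,
    }
    np.savez(
        path,
        conc_grid=model.conc_grid,
        time_grid=model.time_grid,
        factors=model.factors,
        loadings=model.loadings,
        eigenvalues=model.eigenvalues,
        mean_surface=(
            model.mean_surface if model.mean_surface is not None else np.array([])
        ),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> FactorModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        mean_surface = z["mean_surface"]
        return FactorModel(
            conc_grid=z["conc_grid"],
            time_grid=z["time_grid"],
            factors=z["factors"],
            loadings=z["loadings"],
            eigenvalues=z["eigenvalues"],
            gene_ids=list(meta["gene_ids"]),
            n_factors_kept=int(meta["n_factors_kept"]),
            center=bool(meta["center"]),
            mean_surface=mean_surface if mean_surface.size else None,
            chemical=meta["chemical"],
            bio_rep=meta["bio_rep"],
        )
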