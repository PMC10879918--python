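"""isoBMR curves: contours of the common-factor surface at benchmark levels.

The benchmark response level for gene g is ``bmr_factor * sigma_g / |w_g|``
(response units on the common-factor surface); the median isoBMR curve is
the contour of f(c, t) at the median of these per-gene levels, and
percentile curves use other quantiles. The default BMR factor 1.349 is the
conventional number of control SDs spanned by the central 50% of a normal
distribution (so the benchmark response moves a typical gene outside its
control noise band).

Contours are extracted per time by 1-D bisection in log10 concentration —
the "projection" reading of a BMC at a given exposure time. On a
non-monotone surface the lowest crossing is taken (the most conservative
BMC) and the time is flagged. Because every gene's fitted response is a
rescaling of the one common factor, gene-specific curves are parallel
(never cross); curves are reported in log-log coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .factor_model import FactorModel, FactorModelError
from .preprocess import GeneNoise

BMR_FACTOR_DEFAULT = 1.349
LOADING_EPS = 1e-8  # |w| below this is excluded from level computation
LOG10C_TOL = 1e-6  # bisection tolerance in log10 concentration


class CurveError(ValueError):
    pass


@dataclass
class IsoBMRCurve:
    """An ordered (time, concentration) polyline solving f(c, t) = level."""

    chemical: str | None
    level: float
    bmr_factor: float
    kind: str  # "median" | "percentile" | "gene"
    q_or_gene: float | str | None
    times_h: np.ndarray
    concs_uM: np.ndarray
    multi_crossing_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.times_h)

    @property
    def log10_times(self) -> np.ndarray:
        return np.log10(self.times_h)

    @property
    def log10_concs(self) -> np.ndarray:
        return np.log10(self.concs_uM)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chemical": self.chemical,
                "curve_kind": self.kind,
                "q_or_gene": self.q_or_gene,
                "level": self.level,
                "time_h": self.times_h,
                "conc_uM": self.concs_uM,
                "log10_time": self.log10_times,
                "log10_conc": self.log10_concs,
            }
        )


def gene_levels(
    model: FactorModel,
    noise: GeneNoise,
    bmr_factor: float = BMR_FACTOR_DEFAULT,
    loading_eps: float = LOADING_EPS,
) -> pd.Series:
    """Per-gene benchmark levels bmr_factor * sigma_g / |w_g|.

    Genes with |w_g| below ``loading_eps`` are excluded (the division is
    numerically meaningless; a near-zero loading means the gene does not
    follow the common factor at all). |w_g| is used for down-regulated genes
    too: their fitted response is a negative rescaling of the same surface,
    so they cross the benchmark magnitude at the same common-factor level.
    """
    w = model.loadings[:, 0]
    sigma = noise.for_genes(model.gene_ids)
    keep = np.abs(w) > loading_eps
    if not keep.any():
        raise CurveError("no gene with |loading| above the exclusion threshold")
    levels = bmr_factor * sigma[keep] / np.abs(w[keep])
    return pd.Series(levels, index=np.asarray(model.gene_ids)[keep], name="level")


def compute_level_median(
    model: FactorModel, noise: GeneNoise, bmr_factor: float = BMR_FACTOR_DEFAULT
) -> float:
    """Median over genes of bmr_factor * sigma_g / |w_g|."""
    return float(gene_levels(model, noise, bmr_factor).median())


def compute_level_percentile(
    model: FactorModel,
    noise: GeneNoise,
    q: float,
    bmr_factor: float = BMR_FACTOR_DEFAULT,
) -> float:
    """q-th percentile of the per-gene levels (linear-interpolation quantile,
    the numpy default); q = 50 reproduces the median."""
    if not 0 < q < 100:
        raise CurveError(f"percentile q must lie in (0, 100), got {q}")
    lv = gene_levels(model, noise, bmr_factor)
    return float(np.percentile(lv.to_numpy(), q))


def extract_iso_curve(
    model: FactorModel,
    level: float,
    n_times: int = 200,
    n_scan: int = 256,
    chemical: str | None = None,
    kind: str = "median",
    q_or_gene=None,
) -> IsoBMRCurve:
    """Extract the contour f(c, t) = level of the first-factor surface.

    For each of ``n_times`` log-spaced times across the design span, the
    smallest concentration crossing the level is found by a coarse scan in
    log10 c followed by bisection (tolerance 1e-6 log10 units). Times with
    no crossing are omitted; a level above the surface maximum everywhere
    yields an empty curve (reported, not an error).
    """
    if level <= 0:
        raise CurveError(f"level must be positive, got {level}")
    f = model.factor_evaluator(0)
    clo, chi = model.conc_grid[0], model.conc_grid[-1]
    tlo, thi = model.time_grid[0], model.time_grid[-1]
    times = np.logspace(np.log10(tlo), np.log10(thi), n_times)
    lc_grid = np.linspace(np.log10(clo), np.log10(chi), n_scan)
    out_t, out_c, multi = [], [], []
    for t in times:
        vals = f.evaluate(10**lc_grid, np.full_like(lc_grid, t)) - level
        crossings = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
        exact = np.nonzero(vals == 0)[0]
        if exact.size:
            lc = lc_grid[exact[0]]
            if crossings.size and crossings[0] < exact[0]:
                lc = _bisect(f, t, level, lc_grid[crossings[0]], lc_grid[crossings[0] + 1])
            out_t.append(t)
            out_c.append(10**lc)
            if exact.size + crossings.size > 1:
                multi.append(t)
            continue
        if crossings.size == 0:
            continue
        lc = _bisect(f, t, level, lc_grid[crossings[0]], lc_grid[crossings[0] + 1])
        out_t.append(t)
        out_c.append(10**lc)
        if crossings.size > 1:
            multi.append(t)
    return IsoBMRCurve(
        chemical=chemical if chemical is not None else model.chemical,
        level=float(level),
        bmr_factor=BMR_FACTOR_DEFAULT,
        kind=kind,
        q_or_gene=q_or_gene,
        times_h=np.asarray(out_t),
        concs_uM=np.asarray(out_c),
        multi_crossing_times=np.asarray(multi),
    )


def _bisect(f, t: float, level: float, lo: float, hi: float) -> float:
    return brentq(
        lambda lc: f.evaluate(10**lc, t).item() - level, lo, hi, xtol=LOG10C_TOL
    )


def gene_iso_curve(
    model: FactorModel,
    noise: GeneNoise,
    gene_id: str,
    bmr_factor: float = BMR_FACTOR_DEFAULT,
    **kw,
) -> IsoBMRCurve:
    """The gene-specific isoBMR curve at level bmr_factor * sigma_g / |w_g|."""
    if gene_id not in model.gene_ids:
        raise FactorModelError(f"unknown gene: {gene_id!r}")
    w = model.loading(gene_id, 0)
    if abs(w) <= LOADING_EPS:
        raise CurveError(f"gene {gene_id!r} has |loading| <= {LOADING_EPS}")
    sigma = float(noise.for_genes([gene_id])[0])
    level = bmr_factor * sigma / abs(w)
    return extract_iso_curve(model, level, kind="gene", q_or_gene=gene_id, **kw)


def bmc_at_time(curve: IsoBMRCurve, t: float, extrapolate: bool = False) -> float:
    """Benchmark concentration at exposure time t, by log-linear
    interpolation along the curve's (log10 t, log10 c) polyline.

    Outside the curve's time span interpolation is refused unless
    ``extrapolate=True``, in which case a power law log10 c = a + b log10 t
    is fitted to the tail half of the curve and evaluated at t.
    """
    if len(curve) == 0:
        raise CurveError("empty curve")
    lt, lc = curve.log10_times, curve.log10_concs
    x = np.log10(t)
    if lt[0] <= x <= lt[-1]:
        return float(10 ** np.interp(x, lt, lc))
    if not extrapolate:
        raise CurveError(
            f"t = {t} h outside the curve's span [{curve.times_h[0]:.3g}, "
            f"{curve.times_h[-1]:.3g}] h; pass extrapolate=True for a power-law tail"
        )
    half = max(2, len(lt) // 2)
    b, a = np.polyfit(lt[-half:], lc[-half:], 1)
    return float(10 ** (a + b * x))


def curve_slope(curve: IsoBMRCurve, t_min: float | None = None, t_max: float | None = None) -> float:
    """Least-squares log-log slope d log10 c / d log10 t over an optional
    time window (early transient responses can be excluded by windowing)."""
    sel = np.ones(len(curve), dtype=bool)
    if t_min is not None:
        sel &= curve.times_h >= t_min
    if t_max is not None:
        sel &= curve.times_h <= t_max
    if sel.sum() < 2:
        raise CurveError("need >= 2 curve points in the window to fit a slope")
    b, _ = np.polyfit(curve.log10_times[sel], curve.log10_concs[sel], 1)
    return float(b)


def curve_set_report(
    averaged_model: FactorModel,
    noise: GeneNoise,
    replicate_models: list[FactorModel] | None = None,
    percentiles: tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90),
    bmr_factor: float = BMR_FACTOR_DEFAULT,
    **kw,
) -> pd.DataFrame:
    """Tabulate percentile curves, the median curve of the averaged model and
    per-replicate median curves, in both raw and log10 coordinates."""
    frames = []
    for q in percentiles:
        v = compute_level_percentile(averaged_model, noise, q, bmr_factor)
        c = extract_iso_curve(averaged_model, v, kind="percentile", q_or_gene=q, **kw)
        frames.append(c.to_frame())
    v_med = compute_level_median(averaged_model, noise, bmr_factor)
    frames.append(
        extract_iso_curve(averaged_model, v_med, kind="median", q_or_gene=50, **kw).to_frame()
    )
    for m in replicate_models or []:
        v = compute_level_median(m, noise, bmr_factor)
        c = extract_iso_curve(m, v, kind="replicate", q_or_gene=m.bio_rep, **kw)
        frames.append(c.to_frame())
    return pd.concat(frames, ignore_index=True)


def plot_curves(table: pd.DataFrame, ax=None, title: str | None = None):
    """Log-log rendering of a curve table (median highlighted)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for (kind, q), sub in table.groupby(["curve_kind", "q_or_gene"], dropna=False):
        if kind == "median":
            ax.plot(sub["log10_time"], sub["log10_conc"], color="red", lw=2, label="median")
        else:
            ax.plot(sub["log10_time"], sub["log10_conc"], color="grey", lw=0.8, alpha=0.8)
    ax.set_xlabel("log10 time (h)")
    ax.set_ylabel("log10 concentration (µM)")
    if title:
        ax.set_title(title)
    return ax
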