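"""Low-expression filtering, CPM/log2 normalisation, per-condition means,
vehicle-control subtraction and per-gene noise estimation.

The per-gene noise sigma_g (the standard deviation entering the benchmark
response level ``bmr_factor * sigma_g / |w_g|``) is, by default, the sample
SD of log2 expression across vehicle-control replicates at each time point,
averaged over time points — a control-noise estimate in line with the usual
control-SD-based benchmark response. An alternative pooling across all
replicate groups is available via ``method="replicate"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CountMatrix, SampleAnnotation, annotation_to_frame

SIGMA_FLOOR = 1e-6  # keeps benchmark levels finite for zero-variance genes


class PreprocessError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """log2 counts-per-million, genes × samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise PreprocessError("expression values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneNoise:
    """Per-gene log2-scale noise SD (sigma_g), floored at SIGMA_FLOOR."""

    gene_ids: list[str]
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise PreprocessError("sigma must be non-negative")

    def for_genes(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return self.sigma[[pos[g] for g in genes]]


@dataclass
class ConditionMeans:
    """Mean log2 expression per (chemical, concentration, time[, bio_rep]) cell.

    ``cells`` carries one row per cell with its replicate count ``n``;
    ``values`` is genes × cells in the same column order. Control cells have
    chemical None and concentration 0.
    """

    gene_ids: list[str]
    cells: pd.DataFrame
    values: np.ndarray


def filter_low_expression(
    counts: CountMatrix, min_mean_reads: float = 10.0
) -> CountMatrix:
    """Keep genes whose mean raw count across all samples is >= the cutoff.

    The inclusive-threshold mean-reads filter is the standard first step for
    targeted count panels; 10 mean reads is the conventional default.
    """
    if counts.n_genes == 0:
        raise PreprocessError("empty count matrix")
    means = counts.counts.mean(axis=1)
    keep = means >= min_mean_reads
    if not keep.any():
        raise PreprocessError(
            f"no gene passes the {min_mean_reads} mean-read filter; "
            "review the threshold or the input counts"
        )
    return counts.subset_genes(keep)


def cpm_log2(counts: CountMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount). Pseudocount is on the CPM scale."""
    totals = counts.counts.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise PreprocessError(
            f"sample {counts.sample_ids[zero[0]]!r} has zero total count"
        )
    cpm = counts.counts / totals[None, :] * 1e6
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), np.log2(cpm + pseudocount)
    )


def _annotation_frame(
    expr: ExpressionMatrix, annotation: Sequence[SampleAnnotation]
) -> pd.DataFrame:
    ann = annotation_to_frame(annotation)
    missing = set(expr.sample_ids) - set(ann["sample_id"])
    if missing:
        raise PreprocessError(
            f"annotation does not cover sample(s): {sorted(missing)[:5]}"
        )
    ann = ann.set_index("sample_id").loc[list(expr.sample_ids)].reset_index()
    ann["chemical"] = ann["chemical"].replace("", None)
    return ann


def condition_means(
    expr: ExpressionMatrix,
    annotation: Sequence[SampleAnnotation],
    average_bio: bool = True,
) -> ConditionMeans:
    """Average replicates within each treatment cell.

    Technical replicates are always averaged. With ``average_bio=True``
    biological replicates are pooled into the cell as well; otherwise each
    (cell, bio_rep) combination keeps its own column, for per-replicate
    model fits.
    """
    ann = _annotation_frame(expr, annotation)
    key = ["chemical", "concentration_uM", "time_h"]
    if not average_bio:
        key = key + ["bio_rep"]
    groups = ann.groupby(key, dropna=False, sort=True)
    cols, ns, mats = [], [], []
    for cell_key, idx in groups.indices.items():
        cols.append(cell_key if isinstance(cell_key, tuple) else (cell_key,))
        ns.append(len(idx))
        mats.append(expr.values[:, idx].mean(axis=1))
    cells = pd.DataFrame(cols, columns=key)
    cells["chemical"] = cells["chemical"].where(pd.notna(cells["chemical"]), None)
    cells["n"] = ns
    return ConditionMeans(list(expr.gene_ids), cells, np.column_stack(mats))


def subtract_vehicle(means: ConditionMeans):
    """Subtract the time-matched vehicle-control mean from every treated cell.

    Returns one :class:`~isobmr.response_surface.ResponseSurfaceSet` per
    (chemical[, bio_rep]) present, as a dict keyed by chemical or by
    (chemical, bio_rep) when the means were computed per biological replicate.
    """
    from .response_surface import ResponseSurfaceSet

    cells = means.cells
    per_rep = "bio_rep" in cells.columns
    is_ctrl = cells["concentration_uM"] == 0
    if not is_ctrl.any():
        raise PreprocessError("no vehicle-control cells present")

    def ctrl_col(time_h: float, bio_rep=None) -> np.ndarray:
        sel = is_ctrl & (cells["time_h"] == time_h)
        if per_rep and bio_rep is not None:
            sel = sel & (cells["bio_rep"] == bio_rep)
        idx = np.nonzero(sel.to_numpy())[0]
        if idx.size == 0:
            raise PreprocessError(
                f"missing vehicle control for time point {time_h} h"
                + (f", bio_rep {bio_rep}" if per_rep else "")
            )
        return means.values[:, idx].mean(axis=1)

    out = {}
    treated = cells[~is_ctrl]
    group_cols = ["chemical", "bio_rep"] if per_rep else ["chemical"]
    for gkey, sub in treated.groupby(group_cols, sort=True):
        chem = gkey[0] if per_rep else (gkey[0] if isinstance(gkey, tuple) else gkey)
        rep = int(gkey[1]) if per_rep else None
        conc_grid = np.sort(sub["concentration_uM"].unique())
        time_grid = np.sort(sub["time_h"].unique())
        G = len(means.gene_ids)
        vals = np.full((G, len(conc_grid), len(time_grid)), np.nan)
        mask = np.zeros((len(conc_grid), len(time_grid)), dtype=bool)
        for row in sub.itertuples():
            ci = int(np.searchsorted(conc_grid, row.concentration_uM))
            ti = int(np.searchsorted(time_grid, row.time_h))
            col = means.values[:, row.Index]
            vals[:, ci, ti] = col - ctrl_col(row.time_h, rep)
            mask[ci, ti] = True
        rss = ResponseSurfaceSet(
            gene_ids=list(means.gene_ids),
            conc_grid=conc_grid,
            time_grid=time_grid,
            values=vals,
            observed=mask,
            chemical=chem,
            bio_rep=rep,
        )
        out[(chem, rep) if per_rep else chem] = rss
    return out


def estimate_sigma(
    expr: ExpressionMatrix,
    annotation: Sequence[SampleAnnotation],
    method: str = "control",
    floor: float = SIGMA_FLOOR,
) -> GeneNoise:
    """Per-gene noise SD on the log2 scale.

    ``control`` (default): SD across vehicle-control replicates at each time
    point, averaged over time points. ``replicate``: SD pooled across
    replicates within every treatment cell, averaged over cells.
    """
    ann = _annotation_frame(expr, annotation)
    if method == "control":
        ctrl = ann[ann["concentration_uM"] == 0]
        if ctrl.empty:
            raise PreprocessError("no vehicle-control samples")
        sds = []
        for t, sub in ctrl.groupby("time_h"):
            if len(sub) < 2:
                raise PreprocessError(
                    f"time point {t} h has {len(sub)} control replicate(s); >= 2 required"
                )
            sds.append(expr.values[:, sub.index.to_numpy()].std(axis=1, ddof=1))
        sigma = np.mean(sds, axis=0)
    elif method == "replicate":
        key = ["chemical", "concentration_uM", "time_h"]
        sds = []
        for _, sub in ann.groupby(key, dropna=False):
            if len(sub) >= 2:
                sds.append(expr.values[:, sub.index.to_numpy()].std(axis=1, ddof=1))
        if not sds:
            raise PreprocessError("no replicated cells to estimate sigma from")
        sigma = np.mean(sds, axis=0)
    else:
        raise PreprocessError(f"unknown sigma method: {method!r}")
    return GeneNoise(list(expr.gene_ids), np.maximum(sigma, floor))
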