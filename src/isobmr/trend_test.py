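"""Two-sided Williams' trend test and differential-expression selection.

Williams' test compares the highest dose group's isotonic-regression
(amalgamated) mean against the control mean:

    t_bar = (mu*_K - ybar_0) / (s * sqrt(1/n_K + 1/n_0))

where mu*_K is the pool-adjacent-violators estimate of the top-dose mean
under a monotone nondecreasing dose-response and s^2 the pooled within-group
variance. P-values come from seeded Monte-Carlo permutation of sample
labels; the two-sided p doubles the smaller one-sided p (Bonferroni over
direction) and caps at 1.

A gene is called differentially expressed for a chemical when, at at least
one time point, the two-sided p < alpha and the largest |log2 fold change|
versus the time-matched control exceeds the lfc threshold (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import SampleAnnotation
from .preprocess import ExpressionMatrix, _annotation_frame


class TrendTestError(ValueError):
    pass


@dataclass
class TrendTestResult:
    gene_id: str | None
    time_h: float | None
    statistic: float
    p_value: float
    direction: str  # "up" | "down"
    max_abs_lfc: float | None = None


@dataclass
class DEGSet:
    """Genes retained for one chemical, with the qualifying evidence."""

    chemical: str
    gene_ids: list[str]  # retained genes, input order
    table: pd.DataFrame  # gene_id, time_h, statistic, p_value, direction, max_abs_lfc, retained
    per_time_counts: pd.Series  # DEG count per time point (gene counted where it qualifies)


# ---------------------------------------------------------------------------
# isotonic core


def pava_isotonic_means(group_means, group_sizes) -> np.ndarray:
    """Weighted least-squares projection onto the nondecreasing cone
    (pool-adjacent-violators), weights = group sizes."""
    means = np.asarray(group_means, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    if means.size == 0:
        raise TrendTestError("empty input to PAVA")
    if means.shape != sizes.shape or np.any(sizes < 1):
        raise TrendTestError("group_sizes must match group_means and be >= 1")
    # blocks as (weighted sum, weight, multiplicity)
    sums: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for m, w in zip(means, sizes):
        sums.append(m * w)
        wts.append(w)
        counts.append(1)
        while len(sums) > 1 and sums[-2] / wts[-2] > sums[-1] / wts[-1]:
            s_last, w_last, c_last = sums.pop(), wts.pop(), counts.pop()
            sums[-1] += s_last
            wts[-1] += w_last
            counts[-1] += c_last
    out = np.empty_like(means)
    i = 0
    for s, w, c in zip(sums, wts, counts):
        out[i : i + c] = s / w
        i += c
    return out


def _amalgamated_top(values: np.ndarray, boundaries: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Isotonic fitted mean of the LAST group, vectorised over rows.

    For a nondecreasing fit the last fitted value equals the maximum over i
    of the weighted mean of groups i..K (max of suffix means).
    """
    sums = np.add.reduceat(values, boundaries, axis=-1)  # (..., K) group sums
    csum = np.cumsum(sums[..., ::-1], axis=-1)
    cn = np.cumsum(sizes[::-1])
    return (csum / cn).max(axis=-1)


def _williams_stat(
    values: np.ndarray, boundaries: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """Williams t_bar for rows of ``values`` laid out control-first in
    contiguous groups. Returns the statistic (may be +/-inf when the pooled
    variance is zero)."""
    n0 = sizes[0]
    ctrl_mean = values[..., : int(n0)].mean(axis=-1)
    top = _amalgamated_top(values[..., int(n0) :], boundaries[1:] - int(n0), sizes[1:])
    group_means = np.add.reduceat(values, boundaries, axis=-1) / sizes
    within_ss = (values**2).sum(axis=-1) - (group_means**2 * sizes).sum(axis=-1)
    df = values.shape[-1] - len(sizes)
    if df <= 0:
        raise TrendTestError("no residual degrees of freedom for the pooled variance")
    s2 = within_ss / df
    denom = np.sqrt(s2 * (1.0 / sizes[-1] + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = (top - ctrl_mean) / denom
    # zero pooled variance: +/-inf if means differ, 0 if everything is flat
    flat = denom == 0
    if np.any(flat):
        diff = top - ctrl_mean
        stat = np.where(flat & (diff > 0), np.inf, stat)
        stat = np.where(flat & (diff < 0), -np.inf, stat)
        stat = np.where(flat & (diff == 0), 0.0, stat)
    return stat


def _layout(control, dose_groups):
    control = np.asarray(control, dtype=float)
    if control.size < 2:
        raise TrendTestError("need >= 2 control replicates")
    if len(dose_groups) < 1:
        raise TrendTestError("need >= 1 dose group")
    groups = [control] + [np.asarray(g, dtype=float) for g in dose_groups]
    if any(g.size < 1 for g in groups):
        raise TrendTestError("every group needs >= 1 replicate")
    sizes = np.array([g.size for g in groups], dtype=float)
    boundaries = np.concatenate([[0], np.cumsum(sizes[:-1])]).astype(int)
    return np.concatenate(groups), boundaries, sizes


def williams_test(
    control,
    dose_groups,
    direction: str = "up",
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> TrendTestResult:
    """One-sided Williams' trend test with a permutation p-value.

    ``direction="down"`` negates the data (a decreasing trend on x is an
    increasing trend on -x).
    """
    values, boundaries, sizes = _layout(control, dose_groups)
    if direction not in ("up", "down"):
        raise TrendTestError(f"direction must be 'up' or 'down', got {direction!r}")
    if direction == "down":
        values = -values
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = float(_williams_stat(values, boundaries, sizes))
    if np.ptp(values) == 0:
        return TrendTestResult(None, None, 0.0, 1.0, direction)
    perm = np.empty((n_perm, values.size))
    for b in range(n_perm):
        perm[b] = rng.permutation(values)
    pstat = _williams_stat(perm, boundaries, sizes)
    p = (1 + int(np.sum(pstat >= obs))) / (n_perm + 1)
    if not np.isfinite(obs):
        p = 1 / (n_perm + 1) if obs > 0 else 1.0
    return TrendTestResult(None, None, obs, p, direction)


def two_sided_williams(
    control,
    dose_groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> TrendTestResult:
    """Two-sided Williams' test: both directions on shared permutations,
    p_two = min(1, 2 * min(p_up, p_down)), direction = argmin."""
    values, boundaries, sizes = _layout(control, dose_groups)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.ptp(values) == 0:
        return TrendTestResult(None, None, 0.0, 1.0, "up")
    obs_up = float(_williams_stat(values, boundaries, sizes))
    obs_dn = float(_williams_stat(-values, boundaries, sizes))
    perm = np.empty((n_perm, values.size))
    for b in range(n_perm):
        perm[b] = rng.permutation(values)
    stat_up = _williams_stat(perm, boundaries, sizes)
    stat_dn = _williams_stat(-perm, boundaries, sizes)
    p_up = (1 + int(np.sum(stat_up >= obs_up))) / (n_perm + 1)
    p_dn = (1 + int(np.sum(stat_dn >= obs_dn))) / (n_perm + 1)
    if not np.isfinite(obs_up) or not np.isfinite(obs_dn):
        if obs_up == np.inf:
            p_up = 1 / (n_perm + 1)
        if obs_dn == np.inf:
            p_dn = 1 / (n_perm + 1)
    if p_up <= p_dn:
        return TrendTestResult(None, None, obs_up, min(1.0, 2 * p_up), "up")
    return TrendTestResult(None, None, obs_dn, min(1.0, 2 * p_dn), "down")


# ---------------------------------------------------------------------------
# batch path: all genes at one time point share the design and permutations


def _batch_two_sided(
    values: np.ndarray,  # genes × N, groups contiguous control-first
    boundaries: np.ndarray,
    sizes: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sided Williams over genes. Returns (stat, p_two, dir_up)."""
    G, N = values.shape
    obs_up = _williams_stat(values, boundaries, sizes)
    obs_dn = _williams_stat(-values, boundaries, sizes)
    ge_up = np.ones(G, dtype=np.int64)
    ge_dn = np.ones(G, dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.permutation(N)
        pv = values[:, idx]
        ge_up += _williams_stat(pv, boundaries, sizes) >= obs_up
        ge_dn += _williams_stat(-pv, boundaries, sizes) >= obs_dn
    p_up = ge_up / (n_perm + 1)
    p_dn = ge_dn / (n_perm + 1)
    p_up = np.where(obs_up == np.inf, 1 / (n_perm + 1), p_up)
    p_dn = np.where(obs_dn == np.inf, 1 / (n_perm + 1), p_dn)
    flat = np.ptp(values, axis=1) == 0
    up = p_up <= p_dn
    stat = np.where(up, obs_up, obs_dn)
    p_two = np.minimum(1.0, 2 * np.where(up, p_up, p_dn))
    stat = np.where(flat, 0.0, stat)
    p_two = np.where(flat, 1.0, p_two)
    return stat, p_two, up


def select_degs(
    expr: ExpressionMatrix,
    annotation: list[SampleAnnotation],
    chemical: str,
    alpha: float = 0.05,
    lfc: float = 1.0,
    n_perm: int = 999,
    seed: int = 0,
) -> DEGSet:
    """Select differentially expressed genes for one chemical.

    Per gene × time point: two-sided Williams' test of the concentration
    groups against the time-matched vehicle controls, plus the largest
    |log2 fold change| across concentrations. Technical and biological
    replicates are pooled into the groups.
    """
    ann = _annotation_frame(expr, annotation)
    is_ctrl = ann["concentration_uM"] == 0
    chem_rows = ann["chemical"] == chemical
    if not chem_rows.any():
        raise TrendTestError(f"chemical {chemical!r} not present in the annotation")
    times = np.sort(ann.loc[chem_rows, "time_h"].unique())
    rng = np.random.default_rng(seed)
    frames = []
    for t in times:
        ctrl_idx = np.nonzero((is_ctrl & (ann["time_h"] == t)).to_numpy())[0]
        if ctrl_idx.size < 2:
            raise TrendTestError(f"time point {t} h has < 2 vehicle controls")
        concs = np.sort(ann.loc[chem_rows & (ann["time_h"] == t), "concentration_uM"].unique())
        group_idx = [ctrl_idx] + [
            np.nonzero(
                (chem_rows & (ann["time_h"] == t) & (ann["concentration_uM"] == c)).to_numpy()
            )[0]
            for c in concs
        ]
        sizes = np.array([len(ix) for ix in group_idx], dtype=float)
        boundaries = np.concatenate([[0], np.cumsum(sizes[:-1])]).astype(int)
        vals = expr.values[:, np.concatenate(group_idx)]
        stat, p_two, up = _batch_two_sided(vals, boundaries, sizes, n_perm, rng)
        ctrl_mean = expr.values[:, ctrl_idx].mean(axis=1)
        lfcs = np.column_stack(
            [expr.values[:, ix].mean(axis=1) - ctrl_mean for ix in group_idx[1:]]
        )
        max_abs_lfc = np.abs(lfcs).max(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.gene_ids,
                    "time_h": t,
                    "statistic": stat,
                    "p_value": p_two,
                    "direction": np.where(up, "up", "down"),
                    "max_abs_lfc": max_abs_lfc,
                    "retained": (p_two < alpha) & (max_abs_lfc > lfc),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    retained_any = table.groupby("gene_id", sort=False)["retained"].any()
    gene_ids = [g for g in expr.gene_ids if retained_any[g]]
    per_time = table[table["retained"]].groupby("time_h").size()
    per_time = per_time.reindex(times, fill_value=0)
    return DEGSet(chemical, gene_ids, table, per_time)
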