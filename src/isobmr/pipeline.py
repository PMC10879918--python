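"""End-to-end orchestration: counts -> DEGs -> smoothed surfaces -> factor
model -> isoBMR curves. The CLI, the test-suite and the acceptance script
all drive the pipeline through this module."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd

from .curves import (
    BMR_FACTOR_DEFAULT,
    IsoBMRCurve,
    compute_level_median,
    curve_set_report,
    extract_iso_curve,
)
from .data_io import CountMatrix, SampleAnnotation
from .factor_model import FactorModel, fit_factor_model
from .preprocess import (
    GeneNoise,
    condition_means,
    cpm_log2,
    estimate_sigma,
    filter_low_expression,
    subtract_vehicle,
)
from .response_surface import smooth_surface_set
from .trend_test import DEGSet, select_degs


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All tunable constants of the workflow in one auditable place."""

    min_mean_reads: float = 10.0
    pseudocount: float = 1.0
    alpha: float = 0.05
    lfc: float = 1.0
    n_perm: int = 999
    bmr_factor: float = BMR_FACTOR_DEFAULT
    percentiles: tuple = (10, 20, 30, 40, 50, 60, 70, 80, 90)
    rho: float | str = "auto"
    mode: str = "averaged"  # averaged | per-replicate
    sigma_method: str = "control"
    center: bool = False
    n_factors: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("averaged", "per-replicate"):
            raise ConfigError(f"mode must be 'averaged' or 'per-replicate', got {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.rho != "auto" and not 0 < float(self.rho) <= 1:
            raise ConfigError("rho must be 'auto' or in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "percentiles" in d:
            d = {**d, "percentiles": tuple(d["percentiles"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["percentiles"] = list(d["percentiles"])
        return d


@dataclass
class PipelineResult:
    chemical: str
    config: PipelineConfig
    degs: DEGSet
    noise: GeneNoise
    averaged_model: FactorModel
    replicate_models: list[FactorModel] = field(default_factory=list)
    median_level: float = float("nan")
    median_curve: IsoBMRCurve | None = None
    curve_table: pd.DataFrame | None = None


def run_pipeline(
    counts: CountMatrix,
    annotation: Sequence[SampleAnnotation],
    chemical: str,
    config: PipelineConfig | None = None,
    with_report: bool = True,
) -> PipelineResult:
    """Run the whole workflow for one chemical.

    Always fits the averaged-replicate model (the basis for the median and
    percentile curves); in ``per-replicate`` mode additionally fits one
    model per biological replicate for reproducibility curves.
    """
    cfg = config or PipelineConfig()
    counts_f = filter_low_expression(counts, cfg.min_mean_reads)
    expr = cpm_log2(counts_f, cfg.pseudocount)
    degs = select_degs(
        expr, list(annotation), chemical,
        alpha=cfg.alpha, lfc=cfg.lfc, n_perm=cfg.n_perm, seed=cfg.seed,
    )
    noise = estimate_sigma(expr, list(annotation), method=cfg.sigma_method)

    means = condition_means(expr, list(annotation), average_bio=True)
    surf = subtract_vehicle(means)[chemical].subset_genes(degs.gene_ids)
    smoothed = smooth_surface_set(surf, rho=cfg.rho)
    model = fit_factor_model(smoothed, p=cfg.n_factors, center=cfg.center)

    rep_models: list[FactorModel] = []
    if cfg.mode == "per-replicate":
        rep_means = condition_means(expr, list(annotation), average_bio=False)
        rep_surfs = subtract_vehicle(rep_means)
        for (chem, rep), s in sorted(rep_surfs.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            if chem != chemical:
                continue
            sm = smooth_surface_set(s.subset_genes(degs.gene_ids), rho=cfg.rho)
            rep_models.append(fit_factor_model(sm, p=cfg.n_factors, center=cfg.center))

    v_med = compute_level_median(model, noise, cfg.bmr_factor)
    median_curve = extract_iso_curve(model, v_med, kind="median", q_or_gene=50)
    table = None
    if with_report:
        table = curve_set_report(
            model, noise, rep_models, percentiles=cfg.percentiles, bmr_factor=cfg.bmr_factor
        )
    return PipelineResult(
        chemical=chemical,
        config=cfg,
        degs=degs,
        noise=noise,
        averaged_model=model,
        replicate_models=rep_models,
        median_level=v_med,
        median_curve=median_curve,
        curve_table=table,
    )
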