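"""Synthetic experimental designs and count data from a known one-factor
truth, so every pipeline stage can be tested without external data.

The generative model mirrors the pipeline's own factor model run backwards:
each gene's mean log2 CPM is ``baseline_g + w_g * f(c, t)`` (baseline alone
for vehicle controls) plus Gaussian log-scale noise, converted to an
expected read count through the sample library size and drawn
negative-binomially. Dispersion -> 0 collapses to Poisson. Well-position
effects are deliberately not simulated (the reference design randomised
plate layouts precisely to remove them); ``plate_offset`` exists as a hook
to stress robustness.

Truth surfaces:
  haber:     f = s * max(0, log10(c * t / k))   — constant c*t isoeffect
             lines (slope -1 in log-log), the classical Haber behaviour
  hill_time: f = E * c^n / (c^n + K(t)^n), K(t) = K48 * (48/t)^gamma —
             a Hill curve in concentration whose midpoint drops with time
  separable: f = g(c) * h(t) with g = max(0, log10(c / c0)), h = (t/48)^gamma
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curves import IsoBMRCurve
from .data_io import CountMatrix, ExperimentDesign, SampleAnnotation


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Generative parameters of a one-factor concentration-time response."""

    factor_form: str = "haber"  # haber | hill_time | separable
    factor_params: dict = field(
        default_factory=lambda: {"s": 1.0, "k": 10.0}  # k in µM·h
    )
    n_genes: int = 2000
    fraction_up: float = 0.15
    fraction_down: float = 0.05
    loading_low: float = 0.5  # |w| of non-null genes drawn U(low, high)
    loading_high: float = 1.5
    baseline_mean: float = 6.0  # log2 CPM
    baseline_sd: float = 2.0
    baseline_min: float = 1.0
    noise_sd: float = 0.15  # log2-scale Gaussian sd
    nb_dispersion: float = 0.01
    library_size: float = 3e6  # reads per sample
    plate_offset: float = 0.0  # optional log2 shift per plate (robustness hook)
    seed: int = 0

    # filled by realise()
    gene_ids: list[str] = field(default_factory=list)
    loadings: np.ndarray | None = None
    baselines: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fraction_up + self.fraction_down > 1:
            raise SyntheticError("fraction_up + fraction_down must be <= 1")
        if self.factor_form not in ("haber", "hill_time", "separable"):
            raise SyntheticError(f"unknown factor form: {self.factor_form!r}")

    def realise(self) -> "SyntheticTruth":
        """Draw per-gene loadings and baselines (idempotent per seed)."""
        rng = np.random.default_rng(self.seed)
        G = self.n_genes
        self.gene_ids = [f"G{i:05d}" for i in range(G)]
        n_up = int(round(self.fraction_up * G))
        n_dn = int(round(self.fraction_down * G))
        w = np.zeros(G)
        mags = rng.uniform(self.loading_low, self.loading_high, n_up + n_dn)
        w[:n_up] = mags[:n_up]
        w[n_up : n_up + n_dn] = -mags[n_up:]
        self.loadings = w
        self.baselines = np.maximum(
            rng.normal(self.baseline_mean, self.baseline_sd, G), self.baseline_min
        )
        return self

    # ----- true factor surface ---------------------------------------------

    def factor_surface(self, conc, time_h) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        t = np.asarray(time_h, dtype=float)
        p = self.factor_params
        if self.factor_form == "haber":
            return p["s"] * np.maximum(0.0, np.log10(c * t / p["k"]))
        if self.factor_form == "hill_time":
            K = p["K48"] * (48.0 / t) ** p["gamma"]
            cn = c ** p["n"]
            return p["E"] * cn / (cn + K ** p["n"])
        g = np.maximum(0.0, np.log10(c / p["c0"]))
        h = (t / 48.0) ** p.get("gamma", 0.0)
        return g * h


def generate_design(
    design: ExperimentDesign | None = None, seed: int = 0
) -> list[SampleAnnotation]:
    """Enumerate the full plate layout as sample annotations.

    Per time point and biological replicate the 8 concentrations split into
    ``n_plates_per_timepoint`` plates (top half on plate 1, bottom half on
    plate 2, ...), each plate carrying every chemical at its share of
    concentrations × technical replicates plus the vehicle controls. Well
    positions are permuted independently for each biological replicate.
    """
    if design is None:
        design = ExperimentDesign()
    rng = np.random.default_rng(seed)
    n_conc = design.n_concentrations
    n_per_plate = n_conc // design.n_plates_per_timepoint
    rows = string.ascii_uppercase[:8]
    all_wells = [f"{r}{c}" for r in rows for c in range(1, 13)]
    per_plate = (
        len(design.chemicals) * n_per_plate * design.n_tech_reps
        + design.n_controls_per_plate
    )
    if per_plate > 96:
        raise SyntheticError(f"{per_plate} samples exceed the 96 wells of a plate")
    out: list[SampleAnnotation] = []
    sid = 0
    for t in design.time_points_h:
        for bio in range(1, design.n_bio_reps + 1):
            for plate_i in range(design.n_plates_per_timepoint):
                plate = f"T{t:g}_B{bio}_P{plate_i + 1}"
                wells = list(rng.permutation(all_wells)[:per_plate])
                wi = 0
                for chem in design.chemicals:
                    concs = design.concentrations_per_chemical[chem]
                    sl = concs[plate_i * n_per_plate : (plate_i + 1) * n_per_plate]
                    for conc in sl:
                        for tech in range(1, design.n_tech_reps + 1):
                            out.append(
                                SampleAnnotation(
                                    sample_id=f"S{sid:05d}",
                                    chemical=chem,
                                    concentration=conc,
                                    time_h=t,
                                    bio_rep=bio,
                                    tech_rep=tech,
                                    plate=plate,
                                    well=wells[wi],
                                )
                            )
                            sid += 1
                            wi += 1
                for ctrl in range(1, design.n_controls_per_plate + 1):
                    out.append(
                        SampleAnnotation(
                            sample_id=f"S{sid:05d}",
                            chemical=None,
                            concentration=0.0,
                            time_h=t,
                            bio_rep=bio,
                            tech_rep=ctrl,
                            plate=plate,
                            well=wells[wi],
                        )
                    )
                    sid += 1
                    wi += 1
    return out


def simulate_counts(
    truth: SyntheticTruth, annotation: Sequence[SampleAnnotation]
) -> CountMatrix:
    """Draw the count matrix for an annotated design from the truth.

    Fully reproducible from ``truth.seed``; two calls with the same truth
    and annotation yield identical matrices.
    """
    if truth.loadings is None:
        truth.realise()
    rng = np.random.default_rng(truth.seed + 1)  # distinct stream from realise()
    G, S = truth.n_genes, len(annotation)
    mu_log2 = np.tile(truth.baselines[:, None], (1, S))
    plates = sorted({a.plate for a in annotation})
    plate_shift = {p: truth.plate_offset * i for i, p in enumerate(plates)}
    for j, a in enumerate(annotation):
        if not a.is_control:
            mu_log2[:, j] += truth.loadings * truth.factor_surface(a.concentration, a.time_h)
        mu_log2[:, j] += plate_shift[a.plate]
    if truth.noise_sd > 0:
        mu_log2 += rng.normal(0.0, truth.noise_sd, size=(G, S))
    mean_counts = 2.0**mu_log2 / 1e6 * truth.library_size
    alpha = truth.nb_dispersion
    if alpha <= 0:
        counts = rng.poisson(mean_counts)
    else:
        n = 1.0 / alpha
        p = n / (n + mean_counts)
        counts = rng.negative_binomial(n, p)
    return CountMatrix(
        list(truth.gene_ids), [a.sample_id for a in annotation], counts.astype(np.int64)
    )


def analytic_iso_curve(
    truth: SyntheticTruth,
    level: float,
    time_bounds: tuple[float, float] = (2.0, 48.0),
    conc_bounds: tuple[float, float] | None = None,
    n_times: int = 200,
) -> IsoBMRCurve:
    """Exact contour of the true factor surface at ``level`` — the oracle
    against which pipeline-extracted curves are compared."""
    if level <= 0:
        raise SyntheticError("level must be positive")
    times = np.logspace(np.log10(time_bounds[0]), np.log10(time_bounds[1]), n_times)
    p = truth.factor_params
    if truth.factor_form == "haber":
        log10c = level / p["s"] + np.log10(p["k"]) - np.log10(times)
        concs = 10**log10c
    elif truth.factor_form == "hill_time":
        if level >= p["E"]:
            concs = np.full_like(times, np.nan)
        else:
            K = p["K48"] * (48.0 / times) ** p["gamma"]
            concs = K * (level / (p["E"] - level)) ** (1.0 / p["n"])
    else:  # separable
        h = (times / 48.0) ** p.get("gamma", 0.0)
        concs = p["c0"] * 10 ** (level / h)
    ok = np.isfinite(concs)
    if conc_bounds is not None:
        ok &= (concs >= conc_bounds[0]) & (concs <= conc_bounds[1])
    if not ok.any():
        raise SyntheticError("level outside the surface range on the time window")
    return IsoBMRCurve(
        chemical=None,
        level=float(level),
        bmr_factor=np.nan,
        kind="analytic",
        q_or_gene=None,
        times_h=times[ok],
        concs_uM=concs[ok],
    )


def expected_sigma(truth: SyntheticTruth) -> np.ndarray:
    """Delta-method prediction of the per-gene control log2-CPM SD:
    sqrt(noise_sd^2 + (1/m + dispersion) / ln(2)^2) at the baseline mean
    count m — used by oracle tests to match pipeline sigma estimates."""
    if truth.baselines is None:
        truth.realise()
    m = 2.0**truth.baselines / 1e6 * truth.library_size
    count_var_log2 = (1.0 / m + truth.nb_dispersion) / np.log(2) ** 2
    return np.sqrt(truth.noise_sd**2 + count_var_log2)
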