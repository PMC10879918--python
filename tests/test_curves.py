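import numpy as np
import pytest

from isobmr import (
    GeneNoise,
    bmc_at_time,
    compute_level_median,
    compute_level_percentile,
    curve_set_report,
    curve_slope,
    extract_iso_curve,
    fit_factor_model,
    gene_iso_curve,
    gene_levels,
)
from isobmr.curves import CurveError
from isobmr.response_surface import ResponseSurfaceSet

CONC = 50.0 / 2.5 ** np.arange(8)[::-1]
TIME = np.array([2.0, 6.0, 12.0, 24.0, 48.0])


def _model_from_surface(f, w=(1.0, 2.0, 4.0)):
    """One-factor model whose first factor spans the given grid surface."""
    w = np.asarray(w, dtype=float)
    Y = w[:, None, None] * np.asarray(f)[None]
    surf = ResponseSurfaceSet([f"g{i}" for i in range(len(w))], CONC, TIME, Y, chemical="x")
    return fit_factor_model(surf, p=1)


def _noise(model, sigma=1.0):
    return GeneNoise(list(model.gene_ids), np.full(len(model.gene_ids), sigma))


@pytest.fixture(scope="module")
def haber_model():
    cc, tt = np.meshgrid(CONC, TIME, indexing="ij")
    # affine in (log c, log t) on the whole grid: k below c_min * t_min
    f = np.log10(cc * tt / 0.1)
    return _model_from_surface(f)


@pytest.fixture(scope="module")
def sep_model():
    cc, tt = np.meshgrid(CONC, TIME, indexing="ij")
    f = np.log10(cc / 0.05)  # independent of time, positive on grid
    return _model_from_surface(f)


# ---------------------------------------------------------------------------
# levels


def test_median_level_forced_arithmetic(haber_model):
    """sigma = (1,1,1), w = (1,2,4), factor 1.349 -> median of
    (1.349, 0.6745, 0.337250) = 0.6745 — in units of the raw surface;
    the fitted factor is unit-norm so the level scales by ||f||."""
    model = haber_model
    noise = _noise(model)
    v = compute_level_median(model, noise, bmr_factor=1.349)
    # loadings are w_g * ||f||; median of 1.349/|w_g * ||f|||
    lv = 1.349 / np.abs(model.loadings[:, 0])
    assert v == np.median(lv)
    np.testing.assert_allclose(v * model.loadings[0, 0], 0.6745, atol=1e-10)


def test_identical_genes_level(sep_model):
    model = sep_model
    noise = _noise(model, sigma=2.0)
    lv = gene_levels(model, noise)
    v = compute_level_median(model, noise)
    s = 2.0 / np.abs(model.loadings[:, 0])
    np.testing.assert_allclose(lv.to_numpy(), 1.349 * s, atol=1e-12)
    assert v == np.median(1.349 * s)


def test_median_equals_sort_oracle():
    rng = np.random.default_rng(1)
    cc, tt = np.meshgrid(CONC, TIME, indexing="ij")
    f = np.log10(cc * tt / 0.1)
    w = rng.uniform(0.5, 3.0, 1001) * rng.choice([-1, 1], 1001)
    model = _model_from_surface(f, w)
    sigma = rng.uniform(0.1, 1.0, 1001)
    noise = GeneNoise(list(model.gene_ids), sigma)
    v = compute_level_median(model, noise)
    levels = sorted(1.349 * sigma[i] / abs(model.loadings[i, 0]) for i in range(1001))
    assert v == levels[500]


def test_percentile_rules(haber_model):
    noise = _noise(haber_model)
    assert compute_level_percentile(haber_model, noise, 50) == compute_level_median(
        haber_model, noise
    )
    qs = [10, 25, 50, 75, 90]
    vs = [compute_level_percentile(haber_model, noise, q) for q in qs]
    assert all(a <= b + 1e-15 for a, b in zip(vs, vs[1:]))
    with pytest.raises(CurveError):
        compute_level_percentile(haber_model, noise, 0)


def test_percentile_linear_interpolation_oracle():
    cc, tt = np.meshgrid(CONC, TIME, indexing="ij")
    f = np.log10(cc * tt / 0.1)
    fn = np.linalg.norm(f)
    # engineer loadings so the levels are exactly 1..10 (sigma = 1)
    w = 1.349 / (fn * np.arange(1, 11, dtype=float))
    model = _model_from_surface(f, w)
    noise = _noise(model)
    v10 = compute_level_percentile(model, noise, 10)
    np.testing.assert_allclose(v10, np.percentile(np.arange(1, 11), 10), rtol=1e-10)


def test_near_zero_loadings_excluded():
    cc, tt = np.meshgrid(CONC, TIME, indexing="ij")
    f = np.log10(cc * tt / 0.1)
    model = _model_from_surface(f, (1.0, 1e-15, 2.0))
    # SVD of exact rank-1 data keeps the zero-ish loading tiny
    lv = gene_levels(model, _noise(model))
    assert len(lv) == 2


# ---------------------------------------------------------------------------
# contours


def test_separable_surface_gives_constant_concentration(sep_model):
    # fitted factor is log10(c/c0)/s with s = ||f||; level v -> c = c0 * 10^(v*s)
    c0 = 0.05
    s = np.linalg.norm(np.log10(np.meshgrid(CONC, TIME, indexing="ij")[0] / c0))
    v = 2.0 / s  # contour at c = 5 µM, inside the grid
    curve = extract_iso_curve(sep_model, v)
    expected = c0 * 10 ** (v * s)
    assert len(curve) == 200
    np.testing.assert_allclose(curve.concs_uM, expected, rtol=1e-4)
    assert np.all(np.diff(curve.times_h) > 0)


def test_haber_surface_slope_minus_one(haber_model):
    fgrid = np.log10(
        np.meshgrid(CONC, TIME, indexing="ij")[0]
        * np.meshgrid(CONC, TIME, indexing="ij")[1]
        / 0.1
    )
    s = np.linalg.norm(fgrid)
    v = 2.0 / s  # contour log10(c t / 0.1) = 2 -> c t = 10^2 * 0.1
    curve = extract_iso_curve(haber_model, v)
    assert abs(curve_slope(curve) + 1.0) < 1e-3
    np.testing.assert_allclose(curve.concs_uM * curve.times_h, 10.0, rtol=1e-3)


def test_curve_points_satisfy_level_equation(haber_model):
    # sigma chosen so the median gene's contour (c*t = 10^3 * 0.1) crosses
    # the design rectangle
    fn = np.abs(haber_model.loadings[0, 0])
    sigma = 3.0 * 2 * fn / (1.349 * fn)
    v = compute_level_median(haber_model, _noise(haber_model, sigma))
    curve = extract_iso_curve(haber_model, v)
    assert len(curve) > 100
    f = haber_model.factor_evaluator(0)
    vals = f.evaluate(curve.concs_uM, curve.times_h)
    assert np.max(np.abs(vals - v)) < 1e-4


def test_bisection_matches_dense_scan(sep_model):
    """Lowest-crossing bisection agrees with a 1e5-point brute-force scan."""
    v = 0.3
    curve = extract_iso_curve(sep_model, v, n_times=5)
    f = sep_model.factor_evaluator(0)
    lc_dense = np.linspace(np.log10(CONC[0]), np.log10(CONC[-1]), 100_000)
    for t, c in zip(curve.times_h, curve.concs_uM):
        vals = f.evaluate(10**lc_dense, np.full_like(lc_dense, t)) - v
        first = np.nonzero(vals[:-1] * vals[1:] < 0)[0][0]
        assert abs(np.log10(c) - lc_dense[first]) < 1e-4


def test_level_above_surface_max_yields_empty_curve(haber_model):
    curve = extract_iso_curve(haber_model, 1e6)
    assert len(curve) == 0


def test_nonpositive_level_rejected(haber_model):
    with pytest.raises(CurveError, match="positive"):
        extract_iso_curve(haber_model, -1.0)


# ---------------------------------------------------------------------------
# gene curves, projection, reports


def test_gene_with_median_level_reproduces_median_curve(haber_model):
    model = haber_model
    noise = _noise(model)  # levels 1.349/|w|; median gene is g1 (w=2)
    med = compute_level_median(model, noise)
    gcurve = gene_iso_curve(model, noise, "g1")
    mcurve = extract_iso_curve(model, med)
    np.testing.assert_allclose(gcurve.concs_uM, mcurve.concs_uM, rtol=1e-9)


def test_more_sensitive_gene_lies_lower(haber_model):
    # sigmas chosen so both contours span the whole time window
    noise = GeneNoise(list(haber_model.gene_ids), np.array([2.15, 1.0, 6.82]))
    c_sensitive = gene_iso_curve(haber_model, noise, "g2")  # lower level
    c_insensitive = gene_iso_curve(haber_model, noise, "g0")
    shared = np.intersect1d(c_sensitive.times_h, c_insensitive.times_h)
    a = np.interp(shared, c_sensitive.times_h, c_sensitive.concs_uM)
    b = np.interp(shared, c_insensitive.times_h, c_insensitive.concs_uM)
    assert len(shared) > 150 and np.all(a < b)


def test_gene_curves_never_cross(haber_model):
    noise = GeneNoise(list(haber_model.gene_ids), np.array([0.3, 0.5, 0.9]))
    curves = [gene_iso_curve(haber_model, noise, g) for g in haber_model.gene_ids]
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            a, b = curves[i], curves[j]
            shared, ia, ib = np.intersect1d(a.times_h, b.times_h, return_indices=True)
            if len(shared) == 0:
                continue
            diff = a.log10_concs[ia] - b.log10_concs[ib]
            assert np.all(diff > 2e-6) or np.all(diff < -2e-6) or np.all(np.abs(diff) < 2e-6)


def test_bmc_at_time_polyline_node_and_interpolation(haber_model):
    fn = np.abs(haber_model.loadings[0, 0])
    v = np.log10(20.0 / 0.1) / fn  # Haber line c*t = 20, spans all times
    curve = extract_iso_curve(haber_model, v)
    assert len(curve) == 200
    t0 = curve.times_h[37]
    np.testing.assert_allclose(bmc_at_time(curve, t0), curve.concs_uM[37], rtol=1e-12)
    # Haber line: doubling time halves concentration
    t = 5.0
    np.testing.assert_allclose(
        bmc_at_time(curve, 2 * t), bmc_at_time(curve, t) / 2, rtol=1e-3
    )


def test_bmc_outside_span_refused_then_power_law(haber_model):
    fn = np.abs(haber_model.loadings[0, 0])
    curve = extract_iso_curve(haber_model, np.log10(20.0 / 0.1) / fn)
    with pytest.raises(CurveError, match="span"):
        bmc_at_time(curve, 96.0)
    # power-law tail of a Haber line continues with slope -1
    np.testing.assert_allclose(
        bmc_at_time(curve, 96.0, extrapolate=True),
        bmc_at_time(curve, 48.0) / 2,
        rtol=1e-3,
    )


def test_curve_set_report_nested_percentiles(haber_model):
    rng = np.random.default_rng(2)
    noise = GeneNoise(list(haber_model.gene_ids), rng.uniform(0.2, 0.6, 3))
    table = curve_set_report(haber_model, noise, percentiles=(10, 50, 90))
    for t in sorted(set(table["time_h"]))[::40]:
        sub = table[(table["time_h"] == t) & (table["curve_kind"] == "percentile")]
        sub = sub.sort_values("q_or_gene")
        assert sub["conc_uM"].is_monotonic_increasing


def test_identical_replicates_give_identical_curves(haber_model):
    noise = _noise(haber_model, 0.4)
    table = curve_set_report(
        haber_model, noise, replicate_models=[haber_model, haber_model], percentiles=(50,)
    )
    reps = table[table["curve_kind"] == "replicate"]
    a = reps[reps["q_or_gene"] == reps["q_or_gene"].iloc[0]]
    pivot = reps.groupby("time_h")["conc_uM"].nunique()
    assert (pivot == 1).all()


def test_replicate_curve_spread_tracks_noise(small_pipeline, small_truth):
    """Per-replicate median curves from one truth stay within a small
    log10-concentration band of each other."""
    res = small_pipeline
    assert len(res.replicate_models) == 3
    from isobmr import compute_level_median, extract_iso_curve

    curves = []
    for m in res.replicate_models:
        v = compute_level_median(m, res.noise)
        curves.append(extract_iso_curve(m, v))
    shared = curves[0].times_h
    for c in curves[1:]:
        shared = np.intersect1d(shared, c.times_h)
    logc = np.array(
        [np.interp(shared, c.times_h, c.log10_concs) for c in curves]
    )
    spread = logc.max(axis=0) - logc.min(axis=0)
    assert np.median(spread) < 3 * small_truth.noise_sd
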