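import numpy as np
import pytest
from scipy import integrate

from immunoscape.density import (
    KernelSpec,
    QUARTIC_PEAK,
    density_grid,
    estimate_density,
    proximity_to_cancer,
    quartic_kernel,
    select_bandwidth,
)
from immunoscape.synthetic import TumorSimParams, simulate_tumor

from _oracles import brute_force_density
from conftest import make_cell_map


def test_kernel_peak_and_support():
    assert quartic_kernel(np.array([0.0, 0.0])) == pytest.approx(3 / np.pi)
    assert quartic_kernel(np.array([1.0, 0.0])) == 0.0
    assert quartic_kernel(np.array([0.8, 0.8])) == 0.0  # ‖u‖ > 1
    inside = quartic_kernel(np.array([0.5, 0.5]))
    assert inside == pytest.approx((3 / np.pi) * (1 - 0.5) ** 2)


def test_kernel_integrates_to_one():
    # polar quadrature of (3/π)(1−r²)²·2πr over [0, 1]
    val, err = integrate.quad(lambda r: (3 / np.pi) * (1 - r**2) ** 2 * 2 * np.pi * r, 0, 1)
    assert abs(val - 1.0) < 1e-6


def test_single_cell_peak_and_compact_support():
    spec = KernelSpec(bandwidth=1.0)
    cancer = np.array([[0.0, 0.0]])
    assert estimate_density(cancer, spec, [[0.0, 0.0]])[0] == pytest.approx(3 / np.pi)
    assert estimate_density(cancer, spec, [[2.0, 0.0]])[0] == 0.0
    spec50 = KernelSpec(bandwidth=50.0)
    assert estimate_density(cancer, spec50, [[0.0, 0.0]])[0] == pytest.approx(
        QUARTIC_PEAK / 50.0**2
    )


def test_matches_brute_force_sum():
    rng = np.random.default_rng(0)
    for trial in range(25):
        n = rng.integers(1, 200)
        cancer = rng.uniform(0, 300, (n, 2))
        queries = rng.uniform(-20, 320, (rng.integers(1, 50), 2))
        h = float(rng.uniform(5, 80))
        fast = estimate_density(cancer, KernelSpec(bandwidth=h), queries)
        slow = brute_force_density(cancer, h, queries)
        np.testing.assert_allclose(fast, slow, atol=1e-9, rtol=0)


def test_zero_cancer_cells_error():
    with pytest.raises(ValueError, match="zero cancer"):
        estimate_density(np.empty((0, 2)), KernelSpec(), [[0, 0]])


def test_monotone_in_added_cancer_cells():
    rng = np.random.default_rng(1)
    cancer = rng.uniform(0, 100, (50, 2))
    queries = rng.uniform(0, 100, (40, 2))
    spec = KernelSpec(bandwidth=30.0)
    base = estimate_density(cancer, spec, queries)
    more = estimate_density(np.vstack([cancer, [[50, 50]]]), spec, queries)
    assert (more >= base - 1e-15).all()


def test_scale_equivariance():
    rng = np.random.default_rng(2)
    cancer = rng.uniform(0, 100, (30, 2))
    queries = rng.uniform(0, 100, (20, 2))
    c = 3.7
    f1 = estimate_density(cancer, KernelSpec(bandwidth=25.0), queries)
    f2 = estimate_density(cancer * c, KernelSpec(bandwidth=25.0 * c), queries * c)
    np.testing.assert_allclose(f2, f1 / c**2, rtol=1e-12)


def test_grid_nodes_equal_point_evaluator():
    m = make_cell_map(
        cancer=[(10, 10), (30, 40), (70, 20)],
        lymph=[],
        window=(0, 0, 100, 100),
    )
    spec = KernelSpec(bandwidth=25.0)
    field = density_grid(m, spec, spacing=10.0)
    gx, gy = np.meshgrid(field.xs, field.ys)
    direct = estimate_density(m.cancer_xy, spec, np.column_stack([gx.ravel(), gy.ravel()]))
    np.testing.assert_array_equal(field.values.ravel(), direct)
    # kernel bound: no node exceeds h⁻²·(3/π)·n_cancer
    assert field.values.max() <= (3 / np.pi) / 25.0**2 * 3 + 1e-15


def test_grid_translation_equivariance():
    m = make_cell_map(cancer=[(10, 10), (40, 60)], lymph=[], window=(0, 0, 100, 100))
    spec = KernelSpec(bandwidth=20.0)
    f1 = density_grid(m, spec, spacing=5.0)
    f2 = density_grid(m.translated(13.0, -7.0), spec, spacing=5.0)
    np.testing.assert_array_equal(f1.values, f2.values)


def test_grid_spacing_larger_than_window_errors(toy_map):
    with pytest.raises(ValueError, match="spacing"):
        density_grid(toy_map, KernelSpec(), spacing=1e6)


def test_proximity_matches_density_and_handles_edges(toy_map):
    spec = KernelSpec(bandwidth=20.0)
    prox = proximity_to_cancer(toy_map, spec)
    direct = estimate_density(toy_map.cancer_xy, spec, toy_map.lymphocyte_xy)
    np.testing.assert_array_equal(prox.values, direct)
    assert prox.values[1] == 0.0  # lymphocyte at (50,50), > h from all cancer
    no_lymph = make_cell_map(cancer=[(0, 0)], lymph=[])
    with pytest.warns(UserWarning, match="no lymphocytes"):
        empty = proximity_to_cancer(no_lymph, spec)
    assert len(empty) == 0
    no_cancer = make_cell_map(cancer=[], lymph=[(0, 0)], window=(0, 0, 1, 1))
    with pytest.raises(ValueError, match="no cancer"):
        proximity_to_cancer(no_cancer, spec)


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def _thomas_maps_with_truth(n_maps, seed):
    """Maps from a known intensity: fixed parents, Poisson offspring.

    With parents fixed, the generating intensity is exactly
    λ(u) = Σ_p offspring_mean · N(u; p, nest_sd²·I), evaluable in closed form.
    """
    params = TumorSimParams(
        window=(1200.0, 1200.0),
        nest_rate=8.0,
        offspring_mean=60.0,
        nest_sd=55.0,
        stromal_rate=0.0,
        lymph_counts=(0, 0, 0),
        adjacent_offset=50.0,
        regime_jitter=5.0,
        seed=seed,
    )
    maps = [simulate_tumor(TumorSimParams(**{**params.__dict__, "seed": seed + i}), f"m{i}")[0]
            for i in range(n_maps)]
    return params, maps


def _true_intensity(params, seed, grid):
    rng = np.random.default_rng(seed)
    w, h = params.window
    area_mm2 = w * h / 1e6
    n_parents = rng.poisson(params.nest_rate * area_mm2)
    parents = rng.uniform((0, 0), (w, h), size=(n_parents, 2))
    lam = np.zeros(len(grid))
    for p in parents:
        d2 = ((grid - p) ** 2).sum(axis=1)
        lam += params.offspring_mean * np.exp(-d2 / (2 * params.nest_sd**2)) / (
            2 * np.pi * params.nest_sd**2
        )
    return lam


def test_bandwidth_single_candidate_and_determinism():
    _, maps = _thomas_maps_with_truth(2, seed=400)
    h, curve = select_bandwidth(maps, [37.0], seed=1)
    assert h == 37.0 and curve.shape == (1, 2)
    h1, c1 = select_bandwidth(maps, [20.0, 60.0], n_images=1, seed=5)
    h2, c2 = select_bandwidth(maps, [20.0, 60.0], n_images=1, seed=5)
    assert h1 == h2
    np.testing.assert_array_equal(c1, c2)


def test_bandwidth_tracks_true_ise_argmin():
    # LSCV choice must land within one grid step of the h minimizing the
    # integrated squared error against the known generating intensity
    params, maps = _thomas_maps_with_truth(4, seed=800)
    h_grid = np.array([15.0, 30.0, 60.0, 120.0, 240.0])
    chosen, curve = select_bandwidth(maps, h_grid, n_images=4, seed=0)

    step = 12.0
    xs = np.arange(0, params.window[0] + step, step)
    gx, gy = np.meshgrid(xs, xs)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    ise = []
    for h in h_grid:
        total = 0.0
        for i, m in enumerate(maps):
            lam_true = _true_intensity(params, 800 + i, grid)
            lam_hat = estimate_density(m.cancer_xy, KernelSpec(bandwidth=h), grid)
            total += ((lam_hat - lam_true) ** 2).sum() * step**2
        ise.append(total / len(maps))
    best_true = int(np.argmin(ise))
    best_chosen = int(np.flatnonzero(h_grid == chosen)[0])
    assert abs(best_chosen - best_true) <= 1


def test_bandwidth_skips_sparse_maps():
    _, maps = _thomas_maps_with_truth(1, seed=300)
    sparse = make_cell_map(cancer=[(5, 5)], lymph=[], window=(0, 0, 10, 10))
    with pytest.warns(UserWarning, match="skipped"):
        h, _ = select_bandwidth([sparse, maps[0]], [40.0, 80.0], n_images=2, seed=0)
    with pytest.raises(ValueError, match="≥2 cancer"):
        select_bandwidth([sparse], [40.0], seed=0)
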