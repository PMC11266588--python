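"""The LGDF level-set engine against independent brute-force oracles."""

import dataclasses

import numpy as np
import pytest

from retlesion.lgdf import (
    LGDFParams,
    LevelSetState,
    data_force,
    evolve_step,
    init_level_set,
    lgdf_energy,
    local_gaussian_stats,
    segment_lesion,
    smoothed_heaviside_delta,
)

# ---------------------------------------------------------------- oracles


def omega_kernel_2d(sigma, radius):
    """Square-truncated Gaussian window, discretely normalised to sum 1."""
    t = np.arange(-radius, radius + 1)
    yy, xx = np.meshgrid(t, t, indexing="ij")
    k = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return k / k.sum()


def conv_clamped(field, kernel):
    """2-D correlation with index clamping (replicate borders)."""
    h, w = field.shape
    radius = kernel.shape[0] // 2
    out = np.zeros_like(field, dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    y = min(max(i + dy, 0), h - 1)
                    x = min(max(j + dx, 0), w - 1)
                    acc += kernel[dy + radius, dx + radius] * field[y, x]
            out[i, j] = acc
    return out


def stats_bruteforce(image, phi, params):
    """Per-pixel double-loop evaluation of the local Gaussian statistics."""
    kernel = omega_kernel_2d(params.kernel_sigma, params.kernel_radius)
    h_eps = 0.5 * (1 + (2 / np.pi) * np.arctan(phi / params.epsilon))
    results = []
    for m in (h_eps, 1 - h_eps):
        cm = conv_clamped(m, kernel)
        cim = conv_clamped(image * m, kernel)
        ci2m = conv_clamped(image**2 * m, kernel)
        den = np.maximum(cm, 1e-10)
        u = cim / den
        var = np.maximum((u**2 * cm - 2 * u * cim + ci2m) / den, params.var_floor)
        results.append((u, var))
    (u1, v1), (u2, v2) = results
    return u1, u2, v1, v2


def force_bruteforce(image, u1, u2, v1, v2, params):
    """e1 - e2 by direct summation over the window at every pixel."""
    kernel = omega_kernel_2d(params.kernel_sigma, params.kernel_radius)
    h, w = image.shape
    radius = params.kernel_radius
    out = np.zeros_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            e = [0.0, 0.0]
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    y = min(max(i + dy, 0), h - 1)
                    x = min(max(j + dx, 0), w - 1)
                    wgt = kernel[dy + radius, dx + radius]
                    for k, (u, v) in enumerate(((u1, v1), (u2, v2))):
                        e[k] += wgt * (
                            0.5 * np.log(v[y, x])
                            + (u[y, x] - image[i, j]) ** 2 / (2 * v[y, x])
                        )
            out[i, j] = e[0] - e[1]
    return out


def grad_central(phi):
    p = np.pad(phi, 1, mode="edge")
    return (p[2:, 1:-1] - p[:-2, 1:-1]) / 2, (p[1:-1, 2:] - p[1:-1, :-2]) / 2


def step_bruteforce(image, phi, params):
    """Independent finite-difference evaluation of one descent step."""
    u1, u2, v1, v2 = stats_bruteforce(image, phi, params)
    force = force_bruteforce(image, u1, u2, v1, v2, params)
    delta = (params.epsilon / np.pi) / (params.epsilon**2 + phi**2)
    gy, gx = grad_central(phi)
    mag = np.maximum(np.sqrt(gx**2 + gy**2), 1e-10)
    ky, _ = grad_central(gy / mag)
    _, kx = grad_central(gx / mag)
    kappa = ky + kx
    p = np.pad(phi, 1, mode="edge")
    lap = p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4 * phi
    return phi + params.dt * (
        -delta * force + params.nu * delta * kappa + params.mu * (lap - kappa)
    )


def energy_bruteforce(image, phi, params):
    """Double-integral evaluation of the total energy functional."""
    u1, u2, v1, v2 = stats_bruteforce(image, phi, params)
    kernel = omega_kernel_2d(params.kernel_sigma, params.kernel_radius)
    h_eps = 0.5 * (1 + (2 / np.pi) * np.arctan(phi / params.epsilon))
    h, w = image.shape
    radius = params.kernel_radius
    e_lgdf = 0.0
    for i in range(h):
        for j in range(w):
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    y = min(max(i + dy, 0), h - 1)
                    x = min(max(j + dx, 0), w - 1)
                    wgt = kernel[dy + radius, dx + radius]
                    for u, v, m in ((u1, v1, h_eps), (u2, v2, 1 - h_eps)):
                        logp = (
                            np.log(np.sqrt(2 * np.pi) * np.sqrt(v[i, j]))
                            + (u[i, j] - image[y, x]) ** 2 / (2 * v[i, j])
                        )
                        e_lgdf += wgt * logp * m[y, x]
    gy, gx = grad_central(h_eps)
    length = np.sum(np.sqrt(gx**2 + gy**2))
    gy, gx = grad_central(phi)
    penalty = np.sum(0.5 * (np.sqrt(gx**2 + gy**2) - 1) ** 2)
    return e_lgdf + params.nu * length + params.mu * penalty


def _random_instance(rng, n=9):
    image = rng.integers(0, 256, (n, n)).astype(float)
    phi = rng.uniform(-3, 3, (n, n))
    params = LGDFParams(seed_center=(n // 2, n // 2), seed_radius=2.0)
    return image, phi, params


def _state_with_stats(image, phi, params):
    u1, u2, v1, v2 = local_gaussian_stats(image, phi, params)
    return LevelSetState(phi=phi, u1=u1, u2=u2, var1=v1, var2=v2)


# ---------------------------------------------------------------- tests


class TestSmoothedHeaviside:
    def test_closed_forms_at_origin(self):
        h, d = smoothed_heaviside_delta(0.0, epsilon=2.0)
        assert h == pytest.approx(0.5)
        assert d == pytest.approx(1 / (np.pi * 2.0))

    def test_odd_symmetry(self):
        x = np.linspace(-10, 10, 101)
        h_pos, _ = smoothed_heaviside_delta(x)
        h_neg, _ = smoothed_heaviside_delta(-x)
        assert np.allclose(h_pos + h_neg, 1.0)

    def test_delta_is_derivative_of_heaviside(self):
        x = np.linspace(-5, 5, 2001)
        h, d = smoothed_heaviside_delta(x, epsilon=1.5)
        step = x[1] - x[0]
        numeric = np.gradient(h, step)
        assert np.allclose(numeric[2:-2], d[2:-2], atol=step**2 * 10)

    def test_bad_epsilon(self):
        with pytest.raises(ValueError):
            smoothed_heaviside_delta(0.0, epsilon=0.0)


class TestInitLevelSet:
    def test_disc_raster_count(self):
        phi = init_level_set((64, 64), (32, 32), 10.0, c0=2.0)
        yy, xx = np.ogrid[:64, :64]
        expected = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 100).sum()
        assert (phi < 0).sum() == expected
        assert set(np.unique(phi)) == {-2.0, 2.0}

    def test_degenerate_radius(self):
        with pytest.raises(ValueError):
            init_level_set((32, 32), (16, 16), 0.0)

    def test_seed_outside_image(self):
        with pytest.raises(ValueError):
            init_level_set((32, 32), (30, 30), 10.0)


class TestLocalGaussianStats:
    def test_constant_image(self):
        image = np.full((16, 16), 123.0)
        phi = init_level_set((16, 16), (8, 8), 4.0)
        params = LGDFParams(seed_center=(8, 8), seed_radius=4.0)
        u1, u2, v1, v2 = local_gaussian_stats(image, phi, params)
        assert np.allclose(u1, 123.0) and np.allclose(u2, 123.0)
        assert np.allclose(v1, params.var_floor) and np.allclose(v2, params.var_floor)

    def test_matches_bruteforce(self, rng):
        image, phi, params = _random_instance(rng)
        got = local_gaussian_stats(image, phi, params)
        expected = stats_bruteforce(image, phi, params)
        for g, e in zip(got, expected):
            assert np.allclose(g, e, atol=1e-8)

    def test_two_region_means_recovered_away_from_boundary(self):
        image = np.full((32, 32), 50.0)
        image[:, 16:] = 200.0
        phi = np.where(np.arange(32)[None, :] >= 16, -2.0, 2.0) * np.ones((32, 32))
        params = LGDFParams(seed_center=(16, 24), seed_radius=4.0)
        u1, u2, _, _ = local_gaussian_stats(image, phi, params)
        assert np.allclose(u2[:, 24:], 200.0, atol=1.0)  # region 2 = phi<0
        assert np.allclose(u1[:, :8], 50.0, atol=1.0)


class TestDataForce:
    def test_symmetric_regions_zero_force(self, rng):
        image = rng.uniform(0, 255, (12, 12))
        params = LGDFParams(seed_center=(6, 6), seed_radius=3.0)
        u = rng.uniform(50, 200, (12, 12))
        v = rng.uniform(10, 100, (12, 12))
        state = LevelSetState(phi=np.zeros((12, 12)), u1=u, u2=u, var1=v, var2=v)
        assert np.allclose(data_force(image, state, params), 0.0, atol=1e-12)

    def test_matches_bruteforce(self, rng):
        image, phi, params = _random_instance(rng)
        state = _state_with_stats(image, phi, params)
        expected = force_bruteforce(image, state.u1, state.u2, state.var1, state.var2, params)
        assert np.allclose(data_force(image, state, params), expected, atol=1e-8)

    def test_invariance_under_intensity_scaling(self, rng):
        image, phi, params = _random_instance(rng)
        state = _state_with_stats(image, phi, params)
        b = 3.0
        scaled = LevelSetState(
            phi=phi, u1=b * state.u1, u2=b * state.u2,
            var1=b**2 * state.var1, var2=b**2 * state.var2,
        )
        f = data_force(image, state, params)
        f_scaled = data_force(b * image, scaled, params)
        assert np.allclose(f, f_scaled, atol=1e-8)


class TestEvolveStep:
    def test_matches_stencil_oracle(self, rng):
        image = rng.integers(0, 256, (16, 16)).astype(float)
        phi = rng.uniform(-3, 3, (16, 16))
        params = LGDFParams(seed_center=(8, 8), seed_radius=3.0)
        new_state = evolve_step(image, LevelSetState(phi=phi), params)
        assert np.allclose(new_state.phi, step_bruteforce(image, phi, params), atol=1e-8)
        assert new_state.iteration == 1

    def test_signed_distance_is_regularizer_fixed_point(self):
        # constant image -> zero data force; phi the exact radial SDF of a
        # circle, for which |grad phi| = 1 and curvature = 1/rho analytically
        n = 33
        yy, xx = np.mgrid[:n, :n]
        rho = np.sqrt((yy - 16.0) ** 2 + (xx - 16.0) ** 2)
        phi = rho - 8.0
        image = np.full((n, n), 90.0)
        params = LGDFParams(seed_center=(16, 16), seed_radius=8.0)
        new_state = evolve_step(image, LevelSetState(phi=phi.copy()), params)
        change = np.abs(new_state.phi - phi)
        _, delta = smoothed_heaviside_delta(phi, params.epsilon)
        # update bounded by the nu-term plus discretisation slack; the
        # mu-term cancels (laplacian of an SDF equals its curvature); grid
        # borders excluded (replicate padding halves the one-sided gradient)
        away = rho >= 3
        away[:2] = away[-2:] = away[:, :2] = away[:, -2:] = False
        bound = params.dt * (params.nu * delta / np.maximum(rho, 1.0) + 0.05)
        assert (change[away] <= bound[away]).all()

    def test_energy_descends_on_two_region_fixture(self, two_region_image):
        image, _ = two_region_image
        params = LGDFParams(seed_center=(32, 32), seed_radius=10.0)
        state = LevelSetState(phi=init_level_set(image.shape, (32, 32), 10.0))
        energies = []
        for _ in range(50):
            state = evolve_step(image, state, params)
            energies.append(lgdf_energy(image, state, params))
        e = np.asarray(energies)
        assert (np.diff(e) <= np.abs(e[:-1]) * 1e-6).all()

    def test_variance_floor_and_finiteness_maintained(self, two_region_image):
        image, _ = two_region_image
        params = LGDFParams(seed_center=(32, 32), seed_radius=10.0)
        state = LevelSetState(phi=init_level_set(image.shape, (32, 32), 10.0))
        for _ in range(25):
            state = evolve_step(image, state, params)
            assert np.isfinite(state.phi).all()
            assert (state.var1 >= params.var_floor).all()
            assert (state.var2 >= params.var_floor).all()


class TestEnergy:
    def test_matches_double_integral_oracle(self, rng):
        image, phi, params = _random_instance(rng)
        state = _state_with_stats(image, phi, params)
        assert lgdf_energy(image, state, params) == pytest.approx(
            energy_bruteforce(image, phi, params), rel=1e-8
        )

    def test_distance_penalty_vanishes_for_exact_sdf(self):
        n = 33
        yy, xx = np.mgrid[:n, :n]
        phi = np.sqrt((yy - 16.0) ** 2 + (xx - 16.0) ** 2) - 8.0
        params = LGDFParams(seed_center=(16, 16), seed_radius=8.0, mu=1.0)
        image = np.full((n, n), 100.0)
        state = _state_with_stats(image, phi, params)
        base = dataclasses.replace(params, mu=1e-12)
        penalty = lgdf_energy(image, state, params) - lgdf_energy(image, state, base)
        assert penalty / n**2 < 1e-2  # per-pixel discretisation tolerance

    def test_straight_contour_length(self):
        n = 32
        phi = (np.arange(n)[None, :] - 15.5) * np.ones((n, n))
        params = LGDFParams(seed_center=(16, 8), seed_radius=4.0, nu=1.0)
        image = np.full((n, n), 100.0)
        state = _state_with_stats(image, phi, params)
        base = dataclasses.replace(params, nu=1e-12)
        length = (
            lgdf_energy(image, state, params) - lgdf_energy(image, state, base)
        ) / (params.nu - 1e-12)
        assert length == pytest.approx(32.0, rel=0.10)


class TestSegmentLesion:
    def test_deterministic(self, two_region_image):
        image, _ = two_region_image
        params = LGDFParams(seed_center=(32, 32), seed_radius=10.0, iterations=50)
        m1, _, _ = segment_lesion(image, params, trace_every=0)
        m2, _, _ = segment_lesion(image, params, trace_every=0)
        assert np.array_equal(m1, m2)

    def test_two_region_recovery(self, two_region_image):
        image, truth = two_region_image
        params = LGDFParams(seed_center=(32, 32), seed_radius=10.0, iterations=200)
        mask, _, trace = segment_lesion(image, params, trace_every=50)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95
        assert len(trace) == 4

    def test_uniform_image_keeps_seed_circle(self):
        image = np.full((96, 96), 120.0)
        params = LGDFParams(seed_center=(48, 48), seed_radius=10.0)
        mask, _, _ = segment_lesion(image, params, trace_every=0)
        yy, xx = np.ogrid[:96, :96]
        seed = (yy - 48) ** 2 + (xx - 48) ** 2 <= 100
        dice = 2 * (mask & seed).sum() / (mask.sum() + seed.sum())
        assert dice >= 0.8

    def test_missing_seed_rejected(self, two_region_image):
        image, _ = two_region_image
        with pytest.raises(ValueError):
            segment_lesion(image, LGDFParams())
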