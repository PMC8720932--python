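"""Validation protocols: seeded simulations that measure how well the
metric and the inference machinery behave.

Each function recomputes one figure of merit from scratch — oracle
agreement of the metric, closed-form pattern values, invariances,
luminance preservation across the default transform bank, mixed-model
slope recovery and LRT calibration, bootstrap CI coverage, and the
shift-analysis behavior.  Both the acceptance test suite and
``scripts/acceptance.py`` call these.

Problem sizes are chosen to complete on one CPU core in a few minutes;
see the methods note for the rationale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .chroma_metric import (
    average_chromaticity_difference,
    field_average_difference,
    local_chromaticity_difference,
    pair_distance,
)
from .colorspace import ChromaLumImage, rgb_to_chromalum
from .discomfort_stats import (
    fit_discomfort_lmm,
    likelihood_ratio_test,
    spearman_bootstrap,
    spearman_point,
)
from .natural_stats import corpus_distribution, shift_correlation_analysis
from .spectral_metric import luminance_edge_energy
from .stimulus_transform import (
    TransformSpec,
    apply_chromatic_transform,
    generate_transform_bank,
    transform_chroma_field,
    verify_luminance_preservation,
)
from .synthetic_data import (
    ObserverModel,
    make_synthetic_corpus,
    make_two_color_image,
    simulate_ratings,
)

__all__ = [
    "metric_oracle_max_deviation",
    "pattern_metric_ratios",
    "invariance_errors",
    "luminance_preservation_stats",
    "slope_recovery_coverage",
    "lrt_type1_rate",
    "statistic_oracles",
    "bootstrap_ci_coverage",
    "shift_behavior",
    "corpus_moments",
    "triple_level_stats",
]


def _brute_force_average(u, v):
    """Oracle for the metric: explicit double loop over all pixels and
    their existing 8-neighbors (independent of the vectorized path)."""
    h, w = u.shape
    acc = 0.0
    for y in range(h):
        for x in range(w):
            s, n = 0.0, 0
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w:
                        s += float(
                            np.hypot(u[y, x] - u[yy, xx], v[y, x] - v[yy, xx])
                        )
                        n += 1
            acc += s / n
    return acc / (h * w)


def metric_oracle_max_deviation(n_fields: int = 100, seed: int = 0) -> float:
    """Max |vectorized − brute force| metric over random small fields."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fields):
        h = int(rng.integers(2, 17))
        w = int(rng.integers(2, 17))
        u = rng.uniform(0, 0.7, (h, w))
        v = rng.uniform(0, 0.7, (h, w))
        field = ChromaLumImage(u, v, np.ones((h, w)))
        fast = field_average_difference(field)
        slow = _brute_force_average(u, v)
        worst = max(worst, abs(fast - slow))
    return worst


def pattern_metric_ratios() -> dict:
    """Metric of analytic two-color patterns relative to closed forms.

    A large 1-pixel checkerboard tends to d/2 (interior pixels: 4 of 8
    neighbors differ); 1-pixel vertical stripes have interior heatmap
    value 6d/8.  Both after the full sRGB round trip."""
    out = {}
    cb = make_two_color_image((1, 0, 0), (0, 1, 0), "checkerboard", 256)
    f = rgb_to_chromalum(cb)
    d = pair_distance(
        (f.u_prime[0, 0], f.v_prime[0, 0]),
        (f.u_prime[0, 1], f.v_prime[0, 1]),
    )
    out["checkerboard_ratio"] = average_chromaticity_difference(cb) / (d / 2)
    st = make_two_color_image((0, 0, 1), (1, 1, 0), "stripes", 64)
    f = rgb_to_chromalum(st)
    d = pair_distance(
        (f.u_prime[0, 0], f.v_prime[0, 0]),
        (f.u_prime[0, 1], f.v_prime[0, 1]),
    )
    hm = local_chromaticity_difference(f)
    out["stripes_interior_ratio"] = float(
        hm[1:-1, 1:-1].mean() / (6 * d / 8)
    )
    return out


def invariance_errors(seed: int = 0) -> dict:
    """Constant-chromaticity zero, rotation invariance and scaling
    linearity of the metric (field level)."""
    rng = np.random.default_rng(seed)
    from .colorspace import decode_srgb, encode_srgb

    base = decode_srgb(np.full((32, 32, 3), [0.7, 0.45, 0.25]))
    img = encode_srgb(base * rng.uniform(0.2, 1.0, (32, 32, 1)))
    const_metric = average_chromaticity_difference(img)

    field = ChromaLumImage(
        rng.uniform(0.15, 0.3, (16, 16)),
        rng.uniform(0.4, 0.55, (16, 16)),
        rng.uniform(0.1, 0.9, (16, 16)),
    )
    m0 = field_average_difference(field)
    rot_err = 0.0
    for theta in (0.5, 1.7, 3.9):
        m = field_average_difference(
            transform_chroma_field(field, TransformSpec(theta, 1.0))
        )
        rot_err = max(rot_err, abs(m - m0) / m0)
    scale_err = 0.0
    for s in (0.3, 0.8, 1.9):
        m = field_average_difference(
            transform_chroma_field(field, TransformSpec(0.0, s))
        )
        scale_err = max(scale_err, abs(m - s * m0) / (s * m0))
    return {
        "constant_chroma_metric": const_metric,
        "rotation_rel_error": rot_err,
        "scaling_rel_error": scale_err,
    }


def luminance_preservation_stats(seed: int = 0, size: int = 48) -> dict:
    """Worst-case luminance and edge-energy deviation over the default
    350-spec transform bank on two synthetic fixture images."""
    imgs, _ = make_synthetic_corpus(
        2, target_mu=0.0105, target_sigma=0.003, seed=seed, size=size
    )
    bank = generate_transform_bank()
    worst_lum = 0.0
    worst_ee = 0.0
    for img in imgs:
        ee0 = luminance_edge_energy(rgb_to_chromalum(img).lum)
        for spec in bank:
            out = apply_chromatic_transform(img, spec)
            worst_lum = max(
                worst_lum, verify_luminance_preservation(img, out)
            )
            ee = luminance_edge_energy(rgb_to_chromalum(out).lum)
            worst_ee = max(worst_ee, abs(ee - ee0) / ee0)
    return {
        "max_luminance_deviation": worst_lum,
        "max_edge_energy_rel_dev": worst_ee,
        "bank_size": len(bank),
    }


def slope_recovery_coverage(
    n_rep: int = 100,
    n_observers: int = 25,
    n_images: int = 30,
    seed: int = 0,
    beta: float = 0.3,
) -> float:
    """End-to-end loop: synthetic corpus → metric → simulated ratings →
    LMM; fraction of replicates whose 95% CI covers the generative
    slope."""
    covered = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_rep):
            _, metrics = make_synthetic_corpus(
                n_images, seed=seed + 1000 + r, size=48
            )
            table = simulate_ratings(
                metrics, ObserverModel(beta=beta),
                n_observers=n_observers, seed=seed + 50_000 + r,
            )
            fit = fit_discomfort_lmm(table, ["metric"])
            lo, hi = fit.fe_conf_int["metric"]
            covered += lo <= beta <= hi
    return covered / n_rep


def lrt_type1_rate(
    n_rep: int = 200,
    n_observers: int = 20,
    n_images: int = 30,
    seed: int = 0,
) -> float:
    """Rejection rate at p < 0.05 of the fixed-effect LRT under a true
    null (β = 0; the observer random slope is retained in both models,
    the interior df = 1 test)."""
    rej = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_rep):
            rng = np.random.default_rng(seed + r)
            metrics = rng.normal(0.0056, 0.0023, n_images).clip(0.0005)
            table = simulate_ratings(
                metrics, ObserverModel(beta=0.0),
                n_observers=n_observers, seed=seed + 100_000 + r,
            )
            null = fit_discomfort_lmm(table, [], random_slopes=["metric"])
            full = fit_discomfort_lmm(table, ["metric"], random_slopes=True)
            rej += likelihood_ratio_test(null, full).p < 0.05
    return rej / n_rep


def statistic_oracles() -> dict:
    """Closed-form statistics: the 3-vs-3 KS example and the 5-point
    Spearman rank examples."""
    from .discomfort_stats import ks_two_sample

    D, _ = ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
    rho_a = spearman_point([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    rho_b = spearman_point([1, 2, 3, 4, 5], [1, 2, 4, 5, 3])
    return {"ks_D_example": D, "spearman_example_d4": rho_a,
            "spearman_example_d6": rho_b}


def bootstrap_ci_coverage(
    n_rep: int = 500, n: int = 50, rho: float = 0.5, B: int = 1000,
    seed: int = 0,
) -> float:
    """Coverage of the 95% percentile-bootstrap Spearman CI on bivariate
    normal samples.  The target is the population Spearman of the
    bivariate normal, (6/π)·asin(ρ/2)."""
    rng = np.random.default_rng(seed)
    pop = 6 / np.pi * np.arcsin(rho / 2)
    cov = np.array([[1, rho], [rho, 1]])
    covered = 0
    for _ in range(n_rep):
        z = rng.multivariate_normal([0, 0], cov, size=n)
        _, lo, hi = spearman_bootstrap(
            z[:, 0], z[:, 1], B=B, seed=int(rng.integers(2**31))
        )
        covered += lo <= pop <= hi
    return covered / n_rep


def shift_behavior(seed: int = 0, n_stimuli: int = 40, B: int = 500) -> dict:
    """Shift analysis on ratings generated from rectified z at shift 0:
    ρ(δ=0) should exceed ρ(δ=+2σ), and ρ at a strongly negative shift
    should equal the plain Spearman correlation exactly."""
    rng = np.random.default_rng(seed)
    dist = corpus_distribution(rng.normal(0.0056, 0.0023, 150))
    metrics = rng.uniform(0.004, 0.018, n_stimuli)
    z0 = np.maximum(0, (metrics - dist.mu) / dist.sigma)
    ratings = 1.0 + z0 + rng.normal(0, 0.2, n_stimuli)
    curve = shift_correlation_analysis(
        metrics, ratings, dist,
        shifts=[-10 * dist.sigma, 0.0, 2 * dist.sigma],
        B=B, seed=seed,
    )
    return {
        "rho_at_zero_shift": float(curve.rho[1]),
        "rho_at_plus_two_sigma": float(curve.rho[2]),
        "rho_at_strong_negative_shift": float(curve.rho[0]),
        "plain_spearman": spearman_point(metrics, ratings),
    }


def corpus_moments(n_images: int = 200, seed: int = 0) -> dict:
    """Realized metric moments of the calibrated synthetic corpus."""
    _, metrics = make_synthetic_corpus(n_images, seed=seed, size=48)
    return {
        "mean": float(metrics.mean()),
        "median": float(np.median(metrics)),
        "sd": float(metrics.std(ddof=1)),
    }


def triple_level_stats(n_images: int = 8, seed: int = 0) -> dict:
    """Mean achieved metric per level over triples built from synthetic
    stimuli on the art-set metric scale."""
    from .stimulus_transform import build_triples

    imgs, _ = make_synthetic_corpus(
        n_images, target_mu=0.0105, target_sigma=0.0061, seed=seed, size=48
    )
    images = {f"art{i}": im for i, im in enumerate(imgs)}
    triples = build_triples(images, tolerance=0.002, resize=False)
    out = {"n_triples": len(triples)}
    for level in ("low", "medium", "high"):
        vals = [t.metric_values[level] for t in triples]
        out[f"{level}_mean"] = float(np.mean(vals)) if vals else float("nan")
        out[f"{level}_sd"] = (
            float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        )
    return out
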