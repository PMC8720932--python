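"""End-to-end analyses: ratings experiments, nature comparison, triples.

Thin orchestration over the library modules.  Each runner takes in-memory
inputs (images as arrays, ratings as DataFrames), computes every figure
of merit of the corresponding analysis, and returns a plain dict /
DataFrame report; optional helpers persist the reports as CSV/JSON with
the full configuration and seeds recorded alongside.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chroma_metric import average_chromaticity_difference
from .spectral_metric import departure_from_one_over_f, luminance_edge_energy
from .colorspace import rgb_to_chromalum
from .discomfort_stats import (
    exclude_invariant_observers,
    fit_discomfort_lmm,
    ks_two_sample,
    likelihood_ratio_test,
    spearman_bootstrap,
)
from .natural_stats import (
    corpus_distribution,
    rank_extreme_patches,
    rectified_zscores,
    shift_correlation_analysis,
)
from .stimulus_transform import (
    DEFAULT_LEVEL_TARGETS,
    build_triples,
    generate_transform_bank,
    verify_luminance_preservation,
)

__all__ = [
    "RunConfig",
    "compute_image_metrics",
    "run_experiment_analysis",
    "run_nature_comparison",
    "run_triple_generation",
    "write_report",
]


@dataclass
class RunConfig:
    """Options shared by the runners; serialized next to every output."""

    seed: int = 0
    bootstrap_B: int = 10_000
    resize: bool = True
    shift_steps: int = 25
    level_targets: tuple = DEFAULT_LEVEL_TARGETS
    triple_tolerance: float = 0.002
    bank_kwargs: dict = field(default_factory=dict)
    out_dir: str | None = None

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def compute_image_metrics(images: dict, resize: bool = True) -> pd.DataFrame:
    """Both per-image metrics for a mapping of image_id → sRGB array."""
    rows = []
    for image_id, img in images.items():
        lum = rgb_to_chromalum(img).lum
        dep, alpha = departure_from_one_over_f(lum)
        rows.append(
            {
                "image_id": image_id,
                "chroma_metric": average_chromaticity_difference(
                    img, resize=resize
                ),
                "spectral_departure": dep,
                "spectral_alpha": alpha,
                "edge_energy": luminance_edge_energy(lum),
            }
        )
    return pd.DataFrame(rows)


def _mean_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    return (
        ratings.groupby("image_id", as_index=False)["rating"]
        .mean()
        .rename(columns={"rating": "mean_rating"})
    )


def run_experiment_analysis(
    images: dict,
    ratings: pd.DataFrame,
    config: RunConfig | None = None,
    images_set2: dict | None = None,
) -> dict:
    """Ratings-experiment analysis: metric → mixed models → correlations.

    Computes both image metrics, excludes zero-variance observers, fits
    the chroma-only, spectral-only and both-covariate LMMs, runs the LRTs
    between nested pairs, reports bootstrap Spearman correlations of mean
    rating against each metric, and (when a second stimulus set is given)
    the two-sample KS comparison of the metric distributions."""
    config = config or RunConfig()
    metrics = compute_image_metrics(images, resize=config.resize)
    ratings, excluded = exclude_invariant_observers(ratings)
    table = ratings.merge(metrics, on="image_id")

    fits = {}
    fits["null"] = fit_discomfort_lmm(table, [], random_slopes=False)
    for name, cols in [
        ("chroma", ["chroma_metric"]),
        ("spectral", ["spectral_departure"]),
        ("both", ["chroma_metric", "spectral_departure"]),
    ]:
        fits[name] = fit_discomfort_lmm(table, cols)
    lrt = {
        "chroma_vs_null": likelihood_ratio_test(fits["null"], fits["chroma"]),
        "spectral_vs_null": likelihood_ratio_test(
            fits["null"], fits["spectral"]
        ),
        "both_vs_chroma": likelihood_ratio_test(fits["chroma"], fits["both"]),
        "both_vs_spectral": likelihood_ratio_test(
            fits["spectral"], fits["both"]
        ),
    }
    mr = _mean_ratings(ratings).merge(metrics, on="image_id")
    correlations = {}
    for name, col in [("chroma", "chroma_metric"),
                      ("spectral", "spectral_departure")]:
        rho, lo, hi = spearman_bootstrap(
            mr[col], mr["mean_rating"], B=config.bootstrap_B,
            seed=config.seed,
        )
        correlations[name] = {"rho": rho, "ci_lo": lo, "ci_hi": hi}
    report = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "excluded_observers": excluded,
        "metrics": metrics,
        "fits": fits,
        "lrt": lrt,
        "correlations": correlations,
        "aic": {k: v.aic for k, v in fits.items()},
        "bic": {k: v.bic for k, v in fits.items()},
    }
    if images_set2 is not None:
        m2 = compute_image_metrics(images_set2, resize=config.resize)
        D, p = ks_two_sample(metrics["chroma_metric"], m2["chroma_metric"])
        report["ks_sets"] = {"D": D, "p": p}
        report["metrics_set2"] = m2
    return report


def run_nature_comparison(
    corpus_metrics,
    stimulus_metrics,
    mean_ratings,
    config: RunConfig | None = None,
    patches=None,
    top_k: int = 10,
) -> dict:
    """Compare stimuli against the natural-scene metric distribution.

    Builds the corpus distribution, rectifies stimulus z-scores against
    it, runs the shift analysis of the Spearman correlation with mean
    discomfort, and (optionally) ranks extreme patches."""
    config = config or RunConfig()
    dist = corpus_distribution(corpus_metrics)
    z = rectified_zscores(stimulus_metrics, dist)
    shifts = np.linspace(
        -3 * dist.sigma, 3 * dist.sigma, config.shift_steps
    )
    curve = shift_correlation_analysis(
        stimulus_metrics, mean_ratings, dist, shifts=shifts,
        B=config.bootstrap_B, seed=config.seed,
    )
    rho_raw, lo_raw, hi_raw = spearman_bootstrap(
        stimulus_metrics, mean_ratings, B=config.bootstrap_B,
        seed=config.seed,
    )
    report = {
        "version": __version__,
        "config_hash": config.digest(),
        "corpus_mu": dist.mu,
        "corpus_sigma": dist.sigma,
        "corpus_median": float(np.median(dist.samples)),
        "rectified_z": z,
        "shift_curve": curve,
        "raw_spearman": {"rho": rho_raw, "ci_lo": lo_raw, "ci_hi": hi_raw},
        "distribution": dist,
    }
    if patches is not None:
        top, bottom = rank_extreme_patches(patches, k=top_k)
        report["top_patches"] = top
        report["bottom_patches"] = bottom
    return report


def run_triple_generation(
    images: dict, config: RunConfig | None = None, bank=None
) -> pd.DataFrame:
    """Build luminance-matched triples and emit their manifest.

    Every member is re-verified for luminance preservation against its
    base image; the manifest records the transform, achieved metric,
    clipped-pixel fraction and max luminance deviation per member."""
    config = config or RunConfig()
    if bank is None:
        bank = generate_transform_bank(**config.bank_kwargs)
    triples = build_triples(
        images,
        level_targets=config.level_targets,
        tolerance=config.triple_tolerance,
        bank=bank,
        resize=config.resize,
    )
    if not triples:
        raise ValueError("no complete triples could be built")
    rows = []
    for t in triples:
        base = images[t.base_id]
        for level in ("low", "medium", "high"):
            rows.append(
                {
                    "base_id": t.base_id,
                    "level": level,
                    "theta": t.specs[level].theta,
                    "s": t.specs[level].s,
                    "metric": t.metric_values[level],
                    "clipped_fraction": t.clipped_fraction[level],
                    "max_lum_dev": verify_luminance_preservation(
                        base, t.members[level]
                    ),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.attrs["triples"] = triples
    return manifest


def write_report(report: dict, out_dir, stem: str = "report") -> Path:
    """Persist a runner report: DataFrames as CSV, the rest as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scalars = {}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{stem}_{key}.csv", index=False)
        elif hasattr(val, "shifts"):  # ShiftCurve
            pd.DataFrame(
                {
                    "shift": val.shifts,
                    "rho": val.rho,
                    "ci_lo": val.ci_lo,
                    "ci_hi": val.ci_hi,
                }
            ).to_csv(out / f"{stem}_{key}.csv", index=False)
        elif hasattr(val, "loglik"):  # ModelFit
            scalars[key] = {
                "fe_params": val.fe_params,
                "loglik": val.loglik,
                "aic": val.aic,
                "bic": val.bic,
            }
        elif isinstance(val, dict) and any(
            hasattr(v, "loglik") or hasattr(v, "chi2") for v in val.values()
        ):
            scalars[key] = {
                k: (
                    {"fe_params": v.fe_params, "loglik": v.loglik,
                     "aic": v.aic, "bic": v.bic, "n_params": v.n_params}
                    if hasattr(v, "loglik")
                    else {"chi2": v.chi2, "df": v.df, "p": v.p}
                )
                for k, v in val.items()
            }
        elif isinstance(val, np.ndarray):
            scalars[key] = val.tolist()
        elif hasattr(val, "samples"):  # NaturalDistribution
            scalars[key] = {"mu": val.mu, "sigma": val.sigma,
                            "n": int(val.samples.size)}
        elif isinstance(val, list) and val and hasattr(val[0], "metric"):
            scalars[key] = [asdict(p) for p in val]
        else:
            scalars[key] = val
    path = out / f"{stem}.json"
    with open(path, "w") as fh:
        json.dump(scalars, fh, indent=2, default=str)
    return path
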