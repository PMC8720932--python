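"""Luminance-matched triples and the level-effect mixed model.

Applies the default 350-transform bank to a subset of the Set-1-like
stimuli, assembles low/medium/high triples at the three target metric
levels (0.0035 / 0.0115 / 0.0190), verifies luminance preservation,
simulates observers rating every member, fits the level-factor mixed
model (observer random intercept + triple variance component) and runs
the Tukey-adjusted pairwise level contrasts.  Writes
results/triples/manifest.csv, level_model.json and contrasts.csv.
"""

import json

import numpy as np
import pandas as pd

from chromastress.chroma_metric import average_chromaticity_difference
from chromastress.discomfort_stats import fit_level_lmm, \
    tukey_level_contrasts
from chromastress.pipeline import RunConfig, run_triple_generation

from common import RESULTS, stimulus_set

N_BASES = 12  # transform bank x bases is the expensive step
LEVEL_EFFECT = {"low": 0.0, "medium": 0.27, "high": 0.29}


def simulate_triple_ratings(manifest, n_observers=30, seed=17):
    """Observers rate every triple member; discomfort rises with level."""
    rng = np.random.default_rng(seed)
    rows = []
    for o in range(n_observers):
        a_o = 1.9 + rng.normal(0, 0.4)
        for _, row in manifest.iterrows():
            latent = (
                a_o + LEVEL_EFFECT[row["level"]] + rng.normal(0, 0.6)
            )
            rows.append(
                (
                    f"obs{o:03d}",
                    f"{row['base_id']}_{row['level']}",
                    row["level"],
                    row["base_id"],
                    int(np.clip(np.rint(latent), 1, 5)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["observer_id", "image_id", "level", "triple", "rating"],
    )


def main() -> None:
    out = RESULTS / "triples"
    out.mkdir(parents=True, exist_ok=True)
    images, _ = stimulus_set("set1")
    subset = dict(list(images.items())[:N_BASES])
    cfg = RunConfig(resize=False, triple_tolerance=0.002)
    manifest = run_triple_generation(subset, cfg)
    manifest.to_csv(out / "manifest.csv", index=False)
    by_level = manifest.groupby("level")["metric"]
    print(
        f"{manifest['base_id'].nunique()} complete triples; level means "
        + ", ".join(
            f"{lvl} {by_level.mean()[lvl]:.4f}"
            for lvl in ("low", "medium", "high")
        )
        + f"; max luminance deviation {manifest['max_lum_dev'].max():.2e}"
    )

    ratings = simulate_triple_ratings(manifest)
    fit = fit_level_lmm(ratings, triple_col="triple")
    contrasts = tukey_level_contrasts(fit)
    contrasts.to_csv(out / "contrasts.csv", index=False)
    with open(out / "level_model.json", "w") as fh:
        json.dump(
            {
                "fe_params": fit.fe_params,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "bic": fit.bic,
            },
            fh,
            indent=2,
        )
    print("level effects:", {k: round(v, 3) for k, v in fit.fe_params.items()})
    for _, row in contrasts.iterrows():
        print(
            f"  {row['contrast']}: z = {row['z']:.2f}, "
            f"adjusted p = {row['p_adj']:.3f}"
        )


if __name__ == "__main__":
    main()
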