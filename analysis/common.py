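"""Shared deterministic inputs for the analysis drivers.

Images are regenerated from fixed seeds on every call (cheap and
byte-identical), so no binary artifacts need to be stored; the drivers
persist only text tables under results/.
"""

from pathlib import Path

import numpy as np

from chromastress.synthetic_data import (
    ObserverModel,
    make_synthetic_corpus,
    simulate_ratings,
)

SEED = 20211220
RESULTS = Path(__file__).resolve().parent.parent / "results"

#: metric mean/SD and size of the two stimulus sets, and the
#: slopes of the simulated observer populations rating them
SET_SPECS = {
    "set1": {"mu": 0.0105, "sigma": 0.0061, "n": 50, "beta": 0.34,
             "img_seed": 101, "rating_seed": 201},
    "set2": {"mu": 0.0079, "sigma": 0.0053, "n": 50, "beta": 0.22,
             "img_seed": 102, "rating_seed": 202},
}
CORPUS_SEED = 303
N_CORPUS = 200


def stimulus_set(name: str):
    """(images dict, metric array) for one stimulus set."""
    spec = SET_SPECS[name]
    imgs, metrics = make_synthetic_corpus(
        spec["n"], target_mu=spec["mu"], target_sigma=spec["sigma"],
        seed=spec["img_seed"], size=64,
    )
    images = {f"img{i:03d}": im for i, im in enumerate(imgs)}
    return images, metrics


def stimulus_ratings(name: str, metrics):
    spec = SET_SPECS[name]
    return simulate_ratings(
        metrics, ObserverModel(beta=spec["beta"]),
        n_observers=60, seed=spec["rating_seed"],
    )


def natural_corpus():
    """Metric values of the calibrated synthetic scene corpus."""
    _, metrics = make_synthetic_corpus(N_CORPUS, seed=CORPUS_SEED, size=64)
    return np.asarray(metrics)
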