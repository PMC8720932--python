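"""Generate the synthetic study inputs and summarize them.

Two stimulus "sets" of abstract-art-like images (metric scales matching
Set 1: mean 0.0105, and Set 2: mean 0.0079), simulated observer ratings
for each (60 observers, ordinal 1-5), and a natural-scene-like corpus of
200 images calibrated to the reference distribution (mean 0.0056,
SD 0.0023).  Writes the metric and rating tables under results/inputs/.
"""

import numpy as np
import pandas as pd

from common import RESULTS, SET_SPECS, natural_corpus, stimulus_ratings, \
    stimulus_set


def main() -> None:
    out = RESULTS / "inputs"
    out.mkdir(parents=True, exist_ok=True)

    for name in SET_SPECS:
        images, metrics = stimulus_set(name)
        pd.DataFrame(
            {"image_id": list(images), "chroma_metric": metrics}
        ).to_csv(out / f"{name}_metrics.csv", index=False)
        ratings = stimulus_ratings(name, metrics)
        ratings.to_csv(out / f"{name}_ratings.csv", index=False)
        print(
            f"{name}: {len(images)} images, metric mean "
            f"{metrics.mean():.4f} sd {metrics.std(ddof=1):.4f}, "
            f"{ratings['observer_id'].nunique()} observers, "
            f"rating mean {ratings['rating'].mean():.2f}"
        )

    corpus = natural_corpus()
    pd.DataFrame({"metric": corpus}).to_csv(
        out / "corpus_metrics.csv", index=False
    )
    print(
        f"corpus: {corpus.size} scenes, metric mean {corpus.mean():.4f} "
        f"median {np.median(corpus):.4f} sd {corpus.std(ddof=1):.4f}"
    )


if __name__ == "__main__":
    main()
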