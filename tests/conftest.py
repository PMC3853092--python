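import numpy as np
import pandas as pd
import pytest

from hcsneurons.synthetic import generate_scene, sample_scene_specs


@pytest.fixture(scope="session")
def separated_scene():
    """Factory: noiseless, well-separated scene + ground truth for a seed."""

    def make(seed: int, soma_count: int = 10, shape=(512, 512)):
        rng = np.random.default_rng(seed)
        somata, neurites = sample_scene_specs(
            rng, shape=shape, soma_count=soma_count, separated=True
        )
        img, truth = generate_scene(somata, neurites, shape, noise_sd=0.0, seed=seed)
        return img, truth, somata, neurites

    return make


@pytest.fixture(scope="session")
def dose_table():
    """Factory: balanced per-image feature table with configurable dose trends.

    ``trends`` maps feature name -> callable of x = log10(dose); Gaussian
    noise of the given sd is added per image.
    """

    def make(trends, images_per_dose=36, noise_sd=1.0, seed=0,
             doses=(0, 10, 50, 100, 200, 1000)):
        from hcsneurons.dose_stats import log_dose_x

        rng = np.random.default_rng(seed)
        rows = []
        for d in doses:
            x = log_dose_x(d)
            for _ in range(images_per_dose):
                row = {"dose_ng_per_ml": d}
                for name, fn in trends.items():
                    row[name] = fn(x) + rng.normal(0.0, noise_sd)
                rows.append(row)
        return pd.DataFrame(rows)

    return make
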