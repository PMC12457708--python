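import numpy as np
import pandas as pd
import pytest

import matechoice as mc


@pytest.fixture(scope="session")
def small_config() -> mc.SimConfig:
    """A reduced 2-block study that keeps every design feature."""
    return mc.SimConfig(
        n_blocks=2,
        n_noncomp_trials_per_cell=(6, 6),
        n_comp_vials_per_cell=(8, 10),
        block_effects=(0.0, 0.2),
        n_fitness_reps=4,
        n_viability_reps=4,
        n_wings_per_strain=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config) -> mc.SimStudy:
    return mc.simulate_study(small_config, 11)


@pytest.fixture(scope="session")
def default_params() -> tuple[mc.SimConfig, mc.TrueParams]:
    cfg = mc.SimConfig()
    return cfg, mc.draw_strain_effects(cfg, 5)


def make_competitive_vials(
    n: int, seed: int, strains=("s01", "s02", "s03", "s04")
) -> pd.DataFrame:
    """Mated competition vials with uniformly random winners."""
    rng = np.random.default_rng(seed)
    win = rng.integers(0, 4, size=n)
    return pd.DataFrame(
        {
            "block": "b1",
            "status": "virgin",
            "context": "V+C+",
            "vial": [f"v{i}" for i in range(n)],
            "female_strain": "s01",
            "male_black": strains[0],
            "male_blue": strains[1],
            "male_green": strains[2],
            "male_red": strains[3],
            "winner_strain": [strains[w] for w in win],
            "winner_color": [("black", "blue", "green", "red")[w] for w in win],
            "latency_min": 30.0,
            "mated": True,
        }
    )
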