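"""Memoized heavy simulation runs shared by the acceptance tests.

Each runner executes the full pipeline at the study conditions (25 frames
per 0.25 s cycle, default geometry statistics); caching keeps the suite
from re-solving identical cycles across test functions.
"""

from functools import lru_cache

from trabflow.geometry import generate_ventricle
from trabflow.scenarios import (cell_effect_experiment,
                                motion_decomposition_experiment,
                                trabeculation_effect_experiment)
from trabflow.stokes import FluidProperties, solve_cycle


@lru_cache(maxsize=None)
def viscosity_pair(seed: int = 0, resolution: float = 1.0):
    """One synthetic ventricle cycle solved at plasma and blood viscosity."""
    mb = generate_ventricle(seed=seed)
    plasma = solve_cycle(mb, FluidProperties.plasma(), resolution=resolution)
    blood = solve_cycle(mb, FluidProperties.blood(), resolution=resolution)
    return mb, plasma, blood


@lru_cache(maxsize=None)
def motion_table():
    return motion_decomposition_experiment(seeds=range(6))


@lru_cache(maxsize=None)
def cells_table():
    return cell_effect_experiment(seeds=(0, 2))


@lru_cache(maxsize=None)
def trabeculation_table():
    return trabeculation_effect_experiment(seeds=range(4), resolution=1.2)
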