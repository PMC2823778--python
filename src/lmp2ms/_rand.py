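"""Substream random-number management.

Every stochastic stage draws from its own generator obtained by combining a
single user seed with a fixed, named stream index through
``numpy.random.SeedSequence`` spawn keys.  Stages are therefore independently
reproducible: changing the number of draws in one stage never perturbs
another.
"""

from __future__ import annotations

import numpy as np

# Fixed stream indices; append only, never renumber.
STREAMS = {
    "population.sex": 0,
    "population.genotype": 1,
    "population.a02": 2,
    "population.drb115": 3,
    "population.status": 4,
    "population.onset_age": 5,
    "population.cohort": 6,
    "digestion.batch": 10,
    "digestion.noise": 11,
    "permutation": 20,
    "monte_carlo_tables": 21,
}


def substream(seed: int, stream: str) -> np.random.Generator:
    """Return the generator for a named substream of ``seed``."""
    try:
        key = STREAMS[stream]
    except KeyError:
        raise KeyError(f"unknown random substream {stream!r}") from None
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
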