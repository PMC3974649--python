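"""Luria-Delbruck fluctuation-assay simulation.

Parallel cultures grow from single cells to ``final_cells``; mutations
(GCR events) arise during growth at ``rate`` per cell division, and each
mutant clone then expands deterministically with the culture.  A mutation
occurring when the population has size ``s`` therefore leaves ``N // s``
mutant cells at plating.  The number of mutations per culture is Poisson
with mean ``rate * N`` (one division per cell born), and the division at
which each occurs is uniform — which produces the characteristic heavy-
tailed ("jackpot") mutant-count distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_RATE = 1e-4
MIN_CELLS = 10_000


@dataclass
class FluctuationExperiment:
    counts: list[int]  # mutant count per culture
    cells_per_culture: int
    true_rate: float | None = None  # simulation-only

    def __post_init__(self):
        if len(self.counts) < 1:
            raise ValueError("at least one culture is required")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("mutant counts must be non-negative integers")


def simulate_fluctuation_assay(
    rate: float, n_cultures: int, final_cells: int, seed: int = 0
) -> FluctuationExperiment:
    """Simulate per-culture mutant counts under the Luria-Delbruck process."""
    if not 0 <= rate <= MAX_RATE:
        raise ValueError(f"rate must be in [0, {MAX_RATE}]")
    if final_cells < MIN_CELLS:
        raise ValueError(f"final_cells must be at least {MIN_CELLS}")
    if n_cultures < 1:
        raise ValueError("at least one culture is required")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_cultures):
        m = rng.poisson(rate * final_cells)
        total = 0
        if m:
            s = rng.integers(1, final_cells + 1, size=m)
            total = int(np.sum(final_cells // s))
        counts.append(total)
    return FluctuationExperiment(
        counts=counts, cells_per_culture=final_cells, true_rate=rate
    )
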