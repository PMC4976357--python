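"""End-to-end convenience drivers used by the analysis scripts and checks."""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .matrix import CountMatrix
from .normalize import equalize_depth, filter_rrna
from .permfdr import DEResult, run_differential_expression
from .simdata import SimulationTruth, simulate_counts

__all__ = ["screen_simulated", "realized_fdp", "fdp_calibration"]


def screen_simulated(
    config: SimConfig, level: float = 0.5, transform: str = "log2p1"
) -> tuple[DEResult, SimulationTruth, CountMatrix]:
    """Simulate, filter rRNA, equalize depth, run the permutation-FDR screen."""
    matrix, truth = simulate_counts(config)
    matrix = filter_rrna(matrix)
    matrix = equalize_depth(matrix, seed=config.seed)
    result = run_differential_expression(matrix, level=level, transform=transform)
    return result, truth, matrix


def realized_fdp(putative: list[str], truth: SimulationTruth) -> float:
    """Fraction of the putative list not planted as DE; NaN for an empty list."""
    if not putative:
        return float("nan")
    false = sum(1 for g in putative if g not in truth.de_genes)
    return false / len(putative)


def fdp_calibration(
    config: SimConfig, n_seeds: int, level: float = 0.5, base_seed: int = 0
) -> dict:
    """Mean realized false-discovery proportion of the level-``level`` list.

    Runs the full simulate->normalize->screen pipeline across ``n_seeds``
    seeded replicates (seeds ``base_seed .. base_seed + n_seeds - 1``) and
    averages the realized FDP over the replicates with a non-empty putative
    list. Returns summary statistics including list sizes.
    """
    fdps: list[float] = []
    sizes: list[int] = []
    empty = 0
    for k in range(n_seeds):
        cfg = SimConfig(**{**config.to_dict(), "seed": int(base_seed + k) % (2**31)})
        result, truth, _ = screen_simulated(cfg, level=level)
        fdp = realized_fdp(result.putative_set, truth)
        sizes.append(len(result.putative_set))
        if np.isnan(fdp):
            empty += 1
        else:
            fdps.append(fdp)
    return {
        "mean_fdp": float(np.mean(fdps)) if fdps else float("nan"),
        "sd_fdp": float(np.std(fdps, ddof=1)) if len(fdps) > 1 else float("nan"),
        "n_seeds": n_seeds,
        "n_empty_lists": empty,
        "mean_list_size": float(np.mean(sizes)),
        "level": level,
    }
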