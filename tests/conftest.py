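"""Shared fixtures: simulated exchange experiments and small structures."""

from __future__ import annotations

import numpy as np
import pytest

from dimerswap import exchange, synthetic
from dimerswap.structcomp import Residue, StructureModel


def theta_from_scenario(
    scenario: synthetic.ExchangeScenario,
    time_grid: np.ndarray | None = None,
    config: exchange.ExchangeConfig | None = None,
) -> float:
    """End-to-end theta_res of a simulated exchange scenario."""
    grid = synthetic.default_time_grid() if time_grid is None else time_grid
    mix, comp_a, comp_b = synthetic.simulate_exchange_pair(scenario, grid)
    mix, comp_a, comp_b = exchange.resample_to_common_grid(mix, comp_a, comp_b)
    residual = exchange.residual_chromatogram(mix, comp_a, comp_b)
    total = exchange.sum_chromatogram(comp_a, comp_b)
    return exchange.theta_res(residual, total, config)


@pytest.fixture
def time_grid() -> np.ndarray:
    return synthetic.default_time_grid()


def helix_coords(n: int, radius: float = 2.3, rise: float = 1.5) -> np.ndarray:
    """Non-degenerate helical C-alpha-like trace of n points."""
    t = np.arange(n) * 100.0 * np.pi / 180.0
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])


def make_structure(
    numbers, coords, chain: str = "A", label: str = "", extra_atoms=None
) -> StructureModel:
    residues = []
    for k, (num, xyz) in enumerate(zip(numbers, coords)):
        atoms = {"CA": np.asarray(xyz, dtype=float)}
        if extra_atoms:
            for name, offset in extra_atoms:
                atoms[name] = np.asarray(xyz, dtype=float) + offset
        residues.append(Residue(int(num), "ALA", atoms))
    return StructureModel(chains={chain: residues}, label=label)
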