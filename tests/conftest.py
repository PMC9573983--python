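"""Shared fixtures: small pedigrees and fast simulation configurations."""

from __future__ import annotations

import math

import numpy as np
import pytest

from shrimpqg.pedigree import PedigreeRecord, build_pedigree
from shrimpqg.synthetic_data import SimulationConfig


@pytest.fixture
def trio_pedigree():
    """Sire, dam and one offspring."""
    return build_pedigree(
        [PedigreeRecord("S1"), PedigreeRecord("D1"), PedigreeRecord("X", "S1", "D1")]
    )


@pytest.fixture
def fullsib_mating_pedigree():
    """Offspring of a full-sib mating (inbreeding F = 0.25)."""
    return build_pedigree(
        [
            PedigreeRecord("S"),
            PedigreeRecord("D"),
            PedigreeRecord("B1", "S", "D"),
            PedigreeRecord("B2", "S", "D"),
            PedigreeRecord("X", "B1", "B2"),
        ]
    )


def random_pedigree(n_founders: int, n_nonfounders: int, seed: int):
    """Random multi-generation pedigree (parents always earlier animals)."""
    rng = np.random.default_rng(seed)
    records = [PedigreeRecord(f"F{i}") for i in range(n_founders)]
    males = [f"F{i}" for i in range(0, n_founders, 2)]
    females = [f"F{i}" for i in range(1, n_founders, 2)]
    for i in range(n_nonfounders):
        name = f"N{i}"
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        records.append(PedigreeRecord(name, sire, dam))
        if rng.random() < 0.5:
            males.append(name)
        else:
            females.append(name)
    return build_pedigree(records)


def small_sim_config(
    seed: int,
    sigma2_A: float = 1.0,
    sigma2_e: float = 1.5,
    n_progeny: int = 60,
    n_ponds: int = 3,
) -> SimulationConfig:
    """Single-trait config on a small mating design (fast fits)."""
    return SimulationConfig(
        n_sires=8,
        n_dams=8,
        n_families=10,
        n_progeny=n_progeny,
        n_ponds=n_ponds,
        trait_names=["t"],
        G=np.array([[sigma2_A]]),
        E=np.array([[sigma2_e]]),
        pond_effect_sd={"t": 0.3 * math.sqrt(sigma2_A + sigma2_e)},
        seed=seed,
    )
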