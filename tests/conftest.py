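from __future__ import annotations

import numpy as np
import pytest

from imprintscan.bisulfite import AlignParams, Amplicon, BisulfiteClone
from imprintscan.synthetic import SimulationScenario, default_amplicon


@pytest.fixture(scope="session")
def amplicon() -> Amplicon:
    """The study-scale default amplicon: 160 bp, 12 CpGs, one A/G SNP."""
    return default_amplicon(seed=1)


@pytest.fixture
def toy_params() -> AlignParams:
    """Alignment parameters relaxed for short synthetic reads."""
    return AlignParams(min_read_length=5, identity_floor=0.0)


def amplicon_from_sequence(sequence: str, snps=(), strand_mode="top") -> Amplicon:
    """Wrap an arbitrary DNA string as an amplicon, auto-detecting CpGs."""
    positions = tuple(
        i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"
    )
    return Amplicon("toy", sequence, positions, tuple(snps), strand_mode)


def make_clone(
    calls: str,
    clone_id: str = "s|c0",
    multiplicity: int = 1,
    allele: str = "unassigned",
    sample_id: str = "s",
) -> BisulfiteClone:
    """A clone carrying only methylation calls, for classification tests."""
    return BisulfiteClone(
        clone_id=clone_id,
        sample_id=sample_id,
        raw_sequence=clone_id,  # distinct per clone; content irrelevant here
        cpg_calls=calls,
        conversion_efficiency=1.0,
        multiplicity=multiplicity,
        allele=allele,
    )


def zero_noise_scenario(
    scenario_id: str = "zn",
    maternal: float = 1.0,
    paternal: float = 0.0,
    n_molecules: int = 20,
    seed: int = 0,
    **kwargs,
) -> SimulationScenario:
    params = dict(
        scenario_id=scenario_id,
        maternal_meth_prob=maternal,
        paternal_meth_prob=paternal,
        conversion_failure_rate=0.0,
        inappropriate_conversion_rate=0.0,
        seq_error_rate=0.0,
        n_molecules=n_molecules,
        pcr_duplicate_rate=0.0,
        contamination_fraction=0.0,
        seed=seed,
    )
    params.update(kwargs)
    return SimulationScenario(**params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
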