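"""Shared fixtures: a process-wide similarity calibration and small studies."""

import numpy as np
import pytest

from sigmotif.pwm import PWM
from sigmotif.similarity import default_calibration
from sigmotif.simulate import (
    CofactorSpec,
    PlantedMotifSpec,
    SyntheticStudySpec,
    generate_study,
    sample_pwm,
)


@pytest.fixture(scope="session")
def calibration():
    """One similarity calibration per test session (seeded, cached)."""
    return default_calibration()


@pytest.fixture(scope="session")
def small_study():
    """A single-cancer-type synthetic study used across tests.

    Sized so every stage has workable signal: 6 signatures of 60 genes,
    a 1000-gene scanned universe, a fairly sharp planted motif, and a
    designated miRNA overlapping half of the true target genes.
    """
    spec = SyntheticStudySpec(
        cancer_types=(("leukemia", 6, 60),),
        universe_size=1000,
        planted_motifs=(PlantedMotifSpec(ic=1.7),),
        cofactor=CofactorSpec(ic=1.8, co_plant_rate=0.7),
        mirna_background=0.1,
        seed=11,
    )
    return generate_study(spec)


@pytest.fixture(scope="session")
def sharp_pwm():
    """A high-information 10-column PWM for deterministic scanning tests."""
    return sample_pwm(10, 1.9, np.random.default_rng(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def pwm_from_rows(rows) -> PWM:
    return PWM(np.asarray(rows, dtype=float))
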