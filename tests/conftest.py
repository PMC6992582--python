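import pytest

import euplokit as ek


@pytest.fixture(scope="session")
def coefs():
    return ek.default_coefficients()


@pytest.fixture(scope="session")
def small_cohort():
    """300 patients from the default spec; shared read-only fixture."""
    return ek.generate_cohort(ek.CohortSpec(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def midsize_cohort():
    """1,464 patients (the validation-study size) from the default spec."""
    return ek.generate_cohort(ek.CohortSpec(n_patients=1464, seed=7))


def brute_force_mii(p: float, pi: float) -> int:
    """Independent oracle: iterate N upward until 1-(1-p)**N clears pi.

    Uses the same 1e-9 relative boundary tolerance as the implementation
    contract (an exact >= comparison is wrong at representable boundaries,
    e.g. p=0.9, pi=0.99 where (1-p)**2 rounds just above 0.01).
    """
    n = 0
    while 1.0 - (1.0 - p) ** n < pi * (1.0 - 1e-9):
        n += 1
        assert n < 10_000_000
    return n
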