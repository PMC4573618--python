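"""Shared fixtures: small synthetic bundles and independent oracles."""

import numpy as np
import pytest

from dhstf.pwm import BASES, ScoringMatrix
from dhstf.synthetic import SyntheticSpec, generate_fixture

_BASE_INDEX = {b: i for i, b in enumerate(BASES + "N")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def brute_force_max_score(sm: ScoringMatrix, sequence: str) -> float:
    """Window-enumeration oracle: every window on both strands, explicit max."""
    w5 = np.hstack([sm.weights, np.zeros((sm.length, 1))])
    length = sm.length
    best = -np.inf
    for strand_seq in (sequence.upper(), sequence.upper().translate(_COMPLEMENT)[::-1]):
        for i in range(len(strand_seq) - length + 1):
            window = np.array(
                [_BASE_INDEX[c] for c in strand_seq[i : i + length]]
            )
            best = max(best, float(w5[np.arange(length), window].sum()))
    return best


def random_sequence(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    alphabet = BASES + ("N" if with_n else "")
    return "".join(rng.choice(list(alphabet), size=length))


def small_spec(seed: int = 11, **kw) -> SyntheticSpec:
    """A fast fixture spec for unit tests (seconds, not minutes)."""
    defaults = dict(
        n_chromosomes=2,
        chrom_length=120_000,
        n_genes=40,
        n_dhs=120,
        n_pwms=12,
        planted_pwms=((0, 0.12), (1, -0.10)),
        targets_per_pwm=12,
        top_k=40,
        seed=seed,
    )
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_fixture(small_spec())


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    generate_fixture(small_spec(), out_dir=out)
    return out
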