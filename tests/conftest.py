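"""Shared fixtures and independent oracles used across the suite."""
from __future__ import annotations

import numpy as np
import pytest

from sitescout.motifs import PWM
from sitescout.seq import IUPAC_SETS, NucSequence

#: background with GC fraction 0.69 (A, C, G, T)
GC69 = np.array([0.155, 0.345, 0.345, 0.155])


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance, plain quadratic DP."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev = dp[:]
        dp[0] = i
        for j, cb in enumerate(b, 1):
            dp[j] = min(prev[j] + 1, dp[j - 1] + 1, prev[j - 1] + (ca != cb))
    return dp[-1]


def brute_force_matches(pattern: str, seq: str) -> list[int]:
    """Forward-strand IUPAC matching by per-position set membership.

    Independent of sitescout.seq.match_pattern; subject N matches only
    pattern symbol N.
    """
    w = len(pattern)
    hits = []
    for off in range(len(seq) - w + 1):
        ok = True
        for i in range(w):
            base = seq[off + i]
            sym = pattern[i]
            if base == "N":
                ok = sym == "N"
            else:
                ok = base in IUPAC_SETS[sym]
            if not ok:
                break
        if ok:
            hits.append(off)
    return hits


@pytest.fixture
def gc69():
    return GC69.copy()


@pytest.fixture
def toy_pwm():
    """Width-4 informative PWM over a uniform background."""
    freq = np.array(
        [
            [0.85, 0.05, 0.05, 0.05],
            [0.05, 0.85, 0.05, 0.05],
            [0.05, 0.05, 0.85, 0.05],
            [0.05, 0.05, 0.05, 0.85],
        ]
    )
    return PWM(freq, np.full(4, 0.25))


@pytest.fixture
def background_regions():
    """Deterministic i.i.d. GC-0.69 regions (10 x 310 bp)."""
    from sitescout.simulate import random_sequence

    rng = np.random.default_rng(123)
    return [
        NucSequence(f"bg{i:02d}", random_sequence(310, 0.69, rng))
        for i in range(10)
    ]
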