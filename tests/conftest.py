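"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: the screen
oracle is a nested loop over probes and samples, the Fisher oracle builds
binomial coefficients by Pascal's recurrence, and the digestion oracle is a
plain substring scan.
"""

from __future__ import annotations

import numpy as np
import pytest

from methscreen.array_screen import BetaMatrix, ScreenConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# -- screen oracle -----------------------------------------------------------

def brute_force_screen(matrix: BetaMatrix, mode: str, config: ScreenConfig) -> set[str]:
    """Nested-loop re-implementation of the cohort prevalence screen."""
    out: set[str] = set()
    for i, probe_id in enumerate(matrix.probe_ids):
        hits = 0
        informative = 0
        for j in range(len(matrix.sample_ids)):
            v = matrix.values[i, j]
            if np.isnan(v):
                continue
            informative += 1
            if mode == "unmethylated" and v <= config.unmeth_beta_max:
                hits += 1
            if mode == "methylated" and v >= config.meth_beta_min:
                hits += 1
        if informative == 0:
            continue
        if informative / len(matrix.sample_ids) < config.min_informative_frac:
            continue
        needed = (
            config.unmeth_sample_frac if mode == "unmethylated" else config.meth_sample_frac
        )
        if hits / informative >= needed:
            out.add(probe_id)
    return out


# -- Fisher oracle -----------------------------------------------------------

_MAX_N = 121


def _pascal(limit: int = _MAX_N) -> list[list[int]]:
    rows = [[1]]
    for n in range(1, limit):
        prev = rows[-1]
        rows.append(
            [1] + [prev[i - 1] + prev[i] for i in range(1, n)] + [1]
        )
    return rows


PASCAL = _pascal()


def fisher_oracle(a: int, n1: int, c: int, n2: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric-tail enumeration.

    Integer arithmetic throughout (binomials from Pascal's recurrence); the
    p-value is the total probability of tables at the observed margins whose
    probability does not exceed the observed table's.
    """
    k = a + c
    lo, hi = max(0, k - n2), min(k, n1)
    nums = [PASCAL[n1][x] * PASCAL[n2][k - x] for x in range(lo, hi + 1)]
    observed = nums[a - lo]
    tail = sum(n for n in nums if n <= observed)
    return min(tail / sum(nums), 1.0)


# -- digestion oracle --------------------------------------------------------

def scan_sites(seq: str, site: str) -> list[int]:
    """All (possibly overlapping) occurrences of a recognition site."""
    return [i for i in range(len(seq)) if seq.startswith(site, i)]
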