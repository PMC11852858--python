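"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from evchip.layout import LigandSpec, build_layout, default_panel

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def layout10(panel):
    """The canonical 10x10 chip: ten capture ligands + anti-OVA."""
    return build_layout(panel, 10, 10)


@pytest.fixture(scope="session")
def small_layout():
    """A 5x4 chip with two capture ligands, cheap enough for Monte-Carlo."""
    small_panel = (
        LigandSpec("Anti-CD36"),
        LigandSpec("Anti-CD44"),
        LigandSpec("Anti-OVA", "negative_control"),
    )
    return build_layout(small_panel, 5, 4)


# ---------------------------------------------------------------------------
# Independent Mann-Whitney oracle: explicit enumeration with pairwise
# win counting (no ranks), kept deliberately separate from the
# implementation under test.
# ---------------------------------------------------------------------------

def mwu_oracle_p(x, y) -> tuple[float, float]:
    """(U of x, two-sided p) by brute-force enumeration.

    U is counted directly as the number of (x_i, y_j) pairs with
    x_i > y_j plus half the tied pairs. The null distribution is the
    multiset of U values over every way of assigning the pooled
    observations to the two groups; the two-sided p-value is the
    probability of a U at least as far into either tail, using the
    distribution's symmetry about n_x n_y / 2.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n, n_x = len(pooled), len(x)
    n_y = n - n_x
    nm = n_x * n_y

    def u_of(first_idx):
        first = [pooled[i] for i in first_idx]
        rest = [pooled[i] for i in range(n) if i not in first_idx]
        wins = sum(1 for a in first for b in rest if a > b)
        ties = sum(1 for a in first for b in rest if a == b)
        return wins + 0.5 * ties

    u_obs = u_of(frozenset(range(n_x)))
    u_low = min(u_obs, nm - u_obs)
    hits = total = 0
    for comb in itertools.combinations(range(n), n_x):
        u = u_of(frozenset(comb))
        total += 1
        if u <= u_low + 1e-9 or u >= nm - u_low - 1e-9:
            hits += 1
    return u_obs, min(1.0, hits / total)
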