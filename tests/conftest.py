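"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from angioarray import (
    RenderConfig,
    build_default_layout,
    default_panel,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def layout(panel):
    return build_default_layout(panel)


@pytest.fixture(scope="session")
def noiseless_config():
    return RenderConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_truth(panel):
    """A 4-patient cohort for rendering-level tests."""
    return simulate_cohort(4, panel, seed=11)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)

def oracle_midranks(values):
    """Average-of-positions midranks, computed by explicit grouping."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and values[order[j]] == values[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def oracle_signed_rank_p(d):
    """Exhaustive two-sided signed-rank p: enumerate all 2^n sign
    assignments of the midranked |d| (zeros dropped)."""
    d = [x for x in d if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = oracle_midranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    lower = upper = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            lower += 1
        if w >= w_obs - 1e-9:
            upper += 1
    total = 2**n
    return min(1.0, 2.0 * min(lower / total, upper / total))


def oracle_disk_mean(pixels, center, radius):
    """Brute-force spot mean: scan every pixel of the image and test
    centre-in-disk membership."""
    cr, cc = center
    total = 0.0
    count = 0
    h, w = pixels.shape
    for r in range(h):
        for c in range(w):
            if (r - cr) ** 2 + (c - cc) ** 2 <= radius**2:
                total += pixels[r, c]
                count += 1
    return total / count


def oracle_spearman_mc_p(x, y, n_perm, seed):
    """Monte-Carlo permutation p for |Spearman rho| using scipy's
    spearmanr as the statistic (independent of the package's path)."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    obs = abs(spearmanr(x, y).statistic)
    y = np.asarray(y, dtype=float)
    hits = 0
    for _ in range(n_perm):
        if abs(spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-9:
            hits += 1
    return hits / n_perm
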