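"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by brute force
(exhaustive convolution, naive dynamic programming, position-by-position
matching) and never call the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from bithionin import EnzymeSet, kin_maturation
from bithionin.chem_core import DEFAULT_ISOTOPES
from bithionin.synthetic_data import GeneratorConfig, kina_like_precursor


@pytest.fixture(scope="session")
def kina():
    return kina_like_precursor()


@pytest.fixture(scope="session")
def product11(kina):
    return kin_maturation(kina, EnzymeSet.from_codes("C,D"))


@pytest.fixture(scope="session")
def product7(kina):
    return kin_maturation(kina, EnzymeSet.from_codes("C,D,H,I,J,EF,O"))


@pytest.fixture
def cfg():
    return GeneratorConfig(seed=7)


# ---------------------------------------------------------------------------
# Oracle: exhaustive atom-by-atom isotope convolution
# ---------------------------------------------------------------------------

def convolution_pattern_oracle(formula) -> dict[int, tuple[float, float]]:
    """Aggregated M+k isotope pattern by full convolution over every atom.

    Returns ``k -> (abundance, centroid mass)``; no pruning, no dynamic
    programming over elements: one convolution per atom.
    """
    # state: k -> (abundance a_k, mass moment s_k = sum of prob * mass)
    state: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for element in formula:
        isos = DEFAULT_ISOTOPES[element]
        principal = DEFAULT_ISOTOPES.principal(element)
        for _ in range(formula[element]):
            new: dict[int, tuple[float, float]] = {}
            for k, (a, s) in state.items():
                for iso in isos:
                    dk = iso.mass_number - principal.mass_number
                    a2, s2 = new.get(k + dk, (0.0, 0.0))
                    new[k + dk] = (a2 + a * iso.abundance,
                                   s2 + (s + a * iso.mass) * iso.abundance)
            state = new
    return {k: (a, s / a) for k, (a, s) in state.items() if a > 0}


# ---------------------------------------------------------------------------
# Oracle: naive affine-gap Smith-Waterman (Gotoh)
# ---------------------------------------------------------------------------

def naive_sw_score(query: str, ref: str, matrix, gap_open: float = 10.0,
                   gap_extend: float = 1.0) -> float:
    """Textbook O(nm) local alignment with gap cost open + (L-1)*extend."""
    n, m = len(query), len(ref)
    neg = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in query (consume ref)
    F = np.full((n + 1, m + 1), neg)  # gap in ref (consume query)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = matrix[query[i - 1], ref[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


# ---------------------------------------------------------------------------
# Oracle: position-by-position motif matcher
# ---------------------------------------------------------------------------

def brute_force_motif(protein: str, g_min: int = 6, g_max: int = 16):
    """Enumerate anchor matches of S-[ST]-X-X-C-X{g}-T-X{4}-C directly."""
    hits = []
    for g in range(g_min, g_max + 1):
        span = 11 + g
        for i in range(len(protein) - span + 1):
            window = protein[i:i + span]
            if (window[0] == "S" and window[1] in "ST" and window[4] == "C"
                    and window[5 + g] == "T" and window[10 + g] == "C"):
                hits.append(((i + 1, i + 2, i + 5, i + 6 + g, i + 11 + g), g))
    return sorted(hits)
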