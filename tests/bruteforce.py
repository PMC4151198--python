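"""Independent brute-force oracles used by the test suite.

Deliberately written as direct rule scans and exhaustive enumeration,
sharing no code with the package implementation.
"""

from __future__ import annotations

import random

# Standard residue monoisotopic masses (Da), frozen independently of the
# implementation's mass backend.
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER = 18.0105646863


def oracle_mass(sequence: str) -> float:
    return sum(RESIDUE_MASS[c] for c in sequence) + WATER


def oracle_sites(sequence: str, enzyme: str, proline_rule: bool) -> list[int]:
    """Cut positions by direct per-position rule scan."""
    sites = []
    for i in range(1, len(sequence)):
        prev, nxt = sequence[i - 1], sequence[i]
        if enzyme == "trypsin":
            hit = prev in "KR" and not (proline_rule and nxt == "P")
        elif enzyme == "lysc":
            hit = prev == "K" and not (proline_rule and nxt == "P")
        elif enzyme == "argc":
            hit = prev == "R" and not (proline_rule and nxt == "P")
        elif enzyme == "lysn":
            hit = nxt == "K"
        else:
            raise ValueError(enzyme)
        if hit:
            sites.append(i)
    return sites


def oracle_digest(sequence: str, enzyme: str, max_missed: int,
                  min_len: int, proline_rule: bool) -> set[tuple]:
    """All (sequence, start, end, missed) tuples by exhaustive join."""
    cuts = oracle_sites(sequence, enzyme, proline_rule)
    bounds = [0, *cuts, len(sequence)]
    peps = set()
    for i in range(len(bounds) - 1):
        for j in range(i, len(bounds) - 1):
            if j - i > max_missed:
                break
            frag = sequence[bounds[i]:bounds[j + 1]]
            if len(frag) >= min_len:
                peps.add((frag, bounds[i] + 1, bounds[j + 1], j - i))
    return peps


def random_protein(rng: random.Random, max_len: int = 200) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = rng.randint(1, max_len)
    return "".join(rng.choice(alphabet) for _ in range(n))
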