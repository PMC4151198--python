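"""Enzymatic in-silico digestion with missed-cleavage enumeration.

Implements site-specific cleavage for the four proteases commonly used to
build targeted-proteomics peptide databases (trypsin, Lys-C, Arg-C, Lys-N),
enumeration of peptides carrying up to a configurable number of missed
cleavages, and peptide monoisotopic mass / m/z computation.

Coordinates are 1-based inclusive on the parent protein throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from pyteomics import mass as _pyt_mass

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / rare codes accepted in sequences but opaque to digestion
#: (never a cleavage site) and without a defined residue mass here.
NONSTANDARD_AA = frozenset("BZXUO")

#: Full accepted sequence alphabet.
ALPHABET = STANDARD_AA | NONSTANDARD_AA

#: Monoisotopic proton mass in Da, used for m/z computation.
PROTON_MASS = 1.007276

ENZYMES = ("trypsin", "lysc", "argc", "lysn")

# C-terminal cleavage residues per enzyme; Lys-N is handled separately
# because it cleaves N-terminally to lysine.
_CTERM_RULES = {"trypsin": "KR", "lysc": "K", "argc": "R"}


@dataclass(frozen=True)
class DigestionParams:
    """Digestion settings stored alongside a peptide index.

    ``min_peptide_length`` is a database *build-time* bound (3-5 keeps the
    database small); the stricter assay-suitability window (5-22) is a
    query-time filter and lives in :class:`pepselect.selection.FilterConfig`.

    ``proline_rule`` suppresses cleavage after K/R when the next residue is
    proline (trypsin / Lys-C / Arg-C only; Lys-N cleaves N-terminally and is
    unaffected).
    """

    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    min_peptide_length: int = 3
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}; expected one of {ENZYMES}")
        if not 0 <= self.max_missed_cleavages <= 2:
            raise ValueError("max_missed_cleavages must be in [0, 2]")
        # 3-5 is the advised build range (keeps the database small), but
        # min_peptide_length=1 is legal and needed to enumerate the full
        # digest (e.g. for conservation checks).
        if self.min_peptide_length < 1:
            raise ValueError("min_peptide_length must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DigestionParams":
        return cls(**d)


@dataclass(frozen=True)
class DigestedPeptide:
    """One peptide occurrence on its parent protein (1-based inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def nonstandard(self) -> bool:
        """True if the peptide contains any non-standard residue (B,Z,X,U,O)."""
        return any(c in NONSTANDARD_AA for c in self.sequence)


def cleavage_sites(sequence: str, enzyme: str, proline_rule: bool = True) -> list[int]:
    """Return internal cut positions for ``enzyme`` on ``sequence``.

    A cut at position ``i`` (1-based) separates residues ``i`` and ``i+1``;
    the terminal residue never yields a cut. Trypsin cuts after K/R, Lys-C
    after K, Arg-C after R, Lys-N *before* K. With ``proline_rule`` the
    C-terminal enzymes skip sites followed by proline.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if enzyme not in ENZYMES:
        raise ValueError(f"unknown enzyme {enzyme!r}; expected one of {ENZYMES}")
    n = len(sequence)
    cuts: list[int] = []
    if enzyme == "lysn":
        # cut between i and i+1 whenever residue i+1 is K
        cuts = [i for i in range(1, n) if sequence[i] == "K"]
    else:
        residues = _CTERM_RULES[enzyme]
        for i in range(1, n):  # cut position i, i.e. after residue sequence[i-1]
            if sequence[i - 1] not in residues:
                continue
            if proline_rule and sequence[i] == "P":
                continue
            cuts.append(i)
    return cuts


def digest(sequence: str, params: DigestionParams) -> list[DigestedPeptide]:
    """Digest ``sequence`` and enumerate missed-cleavage peptides.

    Produces every fragment between consecutive cuts (0 missed cleavages)
    and every concatenation of up to ``max_missed_cleavages + 1`` consecutive
    fragments, excluding peptides shorter than ``min_peptide_length``.
    Output is sorted by (start, end). Peptides containing non-standard
    residues are retained; callers filter on :attr:`DigestedPeptide.nonstandard`.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    cuts = cleavage_sites(sequence, params.enzyme, params.proline_rule)
    bounds = [0, *cuts, len(sequence)]  # 0-based fragment boundaries
    nfrag = len(bounds) - 1
    out: list[DigestedPeptide] = []
    for j in range(nfrag):
        for k in range(params.max_missed_cleavages + 1):
            if j + k + 1 > nfrag:
                break
            lo, hi = bounds[j], bounds[j + k + 1]
            if hi - lo < params.min_peptide_length:
                continue
            out.append(DigestedPeptide(sequence[lo:hi], lo + 1, hi, k))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass in Da (residue sum + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - STANDARD_AA
    if bad:
        raise ValueError(
            f"mass undefined for non-standard residues {sorted(bad)} in {sequence!r}"
        )
    return _pyt_mass.fast_mass(sequence)


def mz(mass: float, charge: int) -> float:
    """m/z in Th of a peptide of neutral monoisotopic ``mass`` at ``charge``."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge
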