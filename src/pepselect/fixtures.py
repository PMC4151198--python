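"""Synthetic two-species proteome pairs with planted ground truth.

Emulates the xenograft scenario — a proteome of interest (tumor species)
mixed with a host/background proteome — by building proteins as
concatenations of distinct tryptic-style fragments (each ending in K or R,
no internal cleavage site, never starting with proline so the proline rule
cannot merge fragments). A chosen set of fragments is planted exactly once
in the foreground and never in the background (the true surrogate
candidates); a chosen fraction is copied into background proteins (shared
peptides that must be rejected). Annotation features are placed at a
configurable density. Output is written as UniProt flat text and FASTA with
a JSON ground-truth sidecar, and the labels are verified by brute-force
digestion before returning, so every other module is testable without any
database download.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .ingest import ProteinRecord, SequenceFeature, map_feature_key

# residues used in fragment bodies: the 20 standard minus K/R (reserved for
# fragment termini) and minus P at fragment starts (proline-rule safety).
_BODY_AA = "ACDEFGHILMNQSTVWY"  # no K, R, P
_BODY_AA_P = _BODY_AA + "P"

_KIND_TO_KEY = {
    "ptm": "MOD_RES",
    "glyco": "CARBOHYD",
    "variant_snp": "VARIANT",
    "conflict": "CONFLICT",
    "signal_peptide": "SIGNAL",
    "isoform_variable": "VAR_SEQ",
}

_FEATURE_KINDS = tuple(_KIND_TO_KEY)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic proteome pair.

    ``shared_fragment_fraction`` is the fraction of foreground tryptic
    fragments copied into background proteins; ``n_planted_unique``
    fragments are guaranteed unique in the foreground and absent from the
    background. ``feature_density`` is features per 100 residues per kind.
    """

    n_proteins_fg: int = 20
    n_proteins_bg: int = 20
    mean_protein_length: int = 360
    shared_fragment_fraction: float = 0.3
    n_planted_unique: int = 30
    feature_density: float = 0.5
    seed: int = 0
    inject_proline_sites: bool = False  # add K/R-P motifs inside fragments
    inject_nonstandard: bool = False    # replace a few residues with X/B/Z

    def __post_init__(self) -> None:
        if min(self.n_proteins_fg, self.n_proteins_bg,
               self.n_planted_unique) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.shared_fragment_fraction <= 1.0:
            raise ValueError("shared_fragment_fraction must be in [0, 1]")
        if self.feature_density < 0:
            raise ValueError("feature_density must be >= 0")


@dataclass
class FixtureTruth:
    """Ground-truth peptide labels for one generated pair.

    Labels partition the foreground 0-missed-cleavage peptide set:
    ``planted_unique`` (1 fg occurrence, 0 bg), ``planted_shared``
    (present in bg), ``incidental`` (everything else).
    """

    planted_unique: list[str] = field(default_factory=list)
    planted_shared: list[str] = field(default_factory=list)
    incidental: list[str] = field(default_factory=list)
    fg_occurrences: dict[str, int] = field(default_factory=dict)
    bg_occurrences: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        return cls(**json.loads(text))


def _brute_force_fragments(sequence: str) -> list[str]:
    """Independent tryptic scan (proline rule on, 0 missed cleavages)."""
    frags, start = [], 0
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            frags.append(sequence[start:i + 1])
            start = i + 1
    frags.append(sequence[start:])
    return frags


def _random_fragment(rng: random.Random, spec: FixtureSpec) -> str:
    n = rng.randint(5, 19)
    body = "".join(rng.choice(_BODY_AA_P if i else _BODY_AA) for i in range(n - 1))
    frag = body + rng.choice("KR")
    if spec.inject_proline_sites and n >= 8 and rng.random() < 0.3:
        # K/R followed by P: not a cleavage site under the proline rule
        pos = rng.randint(1, n - 4)
        frag = frag[:pos] + rng.choice("KR") + "P" + frag[pos + 2:]
    if spec.inject_nonstandard and rng.random() < 0.1:
        pos = rng.randint(0, n - 2)
        frag = frag[:pos] + rng.choice("BZXUO") + frag[pos + 1:]
    return frag


def _distinct_fragments(rng: random.Random, spec: FixtureSpec, count: int,
                        taboo: set[str]) -> list[str]:
    out: list[str] = []
    seen = set(taboo)
    attempts = 0
    while len(out) < count:
        frag = _random_fragment(rng, spec)
        attempts += 1
        if attempts > 100 * count + 1000:
            raise ValueError("cannot generate enough distinct fragments")
        if frag in seen:
            continue
        seen.add(frag)
        out.append(frag)
    return out


def _place_features(rng: random.Random, sequence: str,
                    density: float) -> list[SequenceFeature]:
    n = len(sequence)
    feats: list[SequenceFeature] = []
    for kind in _FEATURE_KINDS:
        expected = density * n / 100.0
        k = int(expected) + (1 if rng.random() < expected % 1.0 else 0)
        for _ in range(k):
            if kind == "signal_peptide":
                start, end = 1, min(n, rng.randint(12, 24))
            elif kind in ("conflict", "isoform_variable"):
                start = rng.randint(1, n)
                end = min(n, start + rng.randint(0, 5))
            else:
                start = end = rng.randint(1, n)
            feats.append(SequenceFeature(
                kind=kind, start=start, end=end,
                description=f"synthetic {kind}",
                source_key=_KIND_TO_KEY[kind],
            ))
    feats.sort(key=lambda f: (f.start, f.end, f.kind))
    return feats


def _assemble(rng: random.Random, spec: FixtureSpec, fragments: list[str],
              n_proteins: int, prefix: str, organism: str,
              taxon_id: int, taboo: set[str]) -> list[ProteinRecord]:
    """Distribute fragments round-robin-randomly over n_proteins records."""
    order = fragments[:]
    rng.shuffle(order)
    bins: list[list[str]] = [[] for _ in range(n_proteins)]
    for i, frag in enumerate(order):
        bins[i % n_proteins].append(frag)
    records = []
    for i, frags in enumerate(bins, 1):
        if not frags:  # every protein needs a sequence
            frags = _distinct_fragments(rng, spec, 1, taboo)
            taboo.update(frags)
        seq = "".join(frags)
        records.append(ProteinRecord(
            accession=f"{prefix}{i:04d}",
            name=f"Synthetic protein {prefix}{i:04d}",
            organism=organism,
            sequence=seq,
            source="uniprot_dat",
            taxon_id=taxon_id,
            features=_place_features(rng, seq, spec.feature_density),
            reviewed=True,
        ))
    return records


def generate_records(spec: FixtureSpec
                     ) -> tuple[list[ProteinRecord], list[ProteinRecord], FixtureTruth]:
    """Generate the proteome pair in memory; deterministic given the seed."""
    rng = random.Random(spec.seed)
    if spec.n_proteins_fg == 0 or spec.n_proteins_bg == 0:
        raise ValueError("need at least one protein per proteome")
    frags_per_protein = max(2, round(spec.mean_protein_length / 12))
    slots = spec.n_proteins_fg * frags_per_protein
    p = spec.n_planted_unique
    # Distinct fg fragments D split into planted (1 fg copy, absent bg),
    # shared (1 fg copy, copied to bg) and filler (2 fg copies, so it is
    # never foreground-unique): solves slots = p + s + 2f with
    # s = shared_fraction * D, making the planted set exactly the
    # unique-and-absent peptides.
    if p > slots:
        raise ValueError(
            f"n_planted_unique={p} exceeds the {slots} foreground "
            "fragment slots")
    denom = 2.0 - spec.shared_fragment_fraction
    n_distinct = max(p, round((slots + p) / denom))
    n_shared = round(spec.shared_fragment_fraction * n_distinct)
    n_filler = n_distinct - p - n_shared
    if n_filler < 0 or p > n_distinct:
        raise ValueError(
            "infeasible spec: n_planted_unique and shared_fragment_fraction "
            "together exceed the foreground fragment budget")

    distinct = _distinct_fragments(rng, spec, n_distinct, set())
    planted = set(distinct[:p])
    shared = set(distinct[p:p + n_shared])
    filler = distinct[p + n_shared:]
    fg_fragments = distinct[:p + n_shared] + filler + filler  # filler twice

    n_bg_frags = max(spec.n_proteins_bg * frags_per_protein, len(shared))
    bg_own = _distinct_fragments(rng, spec, n_bg_frags - len(shared),
                                 set(distinct))
    bg_fragments = sorted(shared) + bg_own

    taboo = set(fg_fragments) | set(bg_fragments)
    fg_records = _assemble(rng, spec, fg_fragments, spec.n_proteins_fg,
                           "SYNF", "Synthetica neoplastica (synthetic tumor)",
                           900001, taboo)
    bg_records = _assemble(rng, spec, bg_fragments, spec.n_proteins_bg,
                           "SYNB", "Synthetica hospes (synthetic host)",
                           900002, taboo)

    truth = _compute_truth(fg_records, bg_records, planted, shared)
    return fg_records, bg_records, truth


def _compute_truth(fg_records, bg_records, planted: set[str],
                   shared: set[str]) -> FixtureTruth:
    """Label fg peptides by brute-force digestion and verify the plant."""
    fg_counts: dict[str, int] = {}
    bg_counts: dict[str, int] = {}
    for rec in fg_records:
        for frag in _brute_force_fragments(rec.sequence):
            fg_counts[frag] = fg_counts.get(frag, 0) + 1
    for rec in bg_records:
        for frag in _brute_force_fragments(rec.sequence):
            bg_counts[frag] = bg_counts.get(frag, 0) + 1
    truth = FixtureTruth(fg_occurrences=fg_counts, bg_occurrences=bg_counts)
    for pep in sorted(fg_counts):
        if pep in planted:
            if fg_counts[pep] != 1 or bg_counts.get(pep, 0) != 0:
                raise AssertionError(
                    f"planted-unique fragment {pep} violated: "
                    f"fg={fg_counts[pep]}, bg={bg_counts.get(pep, 0)}")
            truth.planted_unique.append(pep)
        elif pep in shared:
            if bg_counts.get(pep, 0) < 1:
                raise AssertionError(f"shared fragment {pep} absent from bg")
            truth.planted_shared.append(pep)
        else:
            if fg_counts[pep] < 2 and bg_counts.get(pep, 0) == 0:
                raise AssertionError(
                    f"incidental fragment {pep} is foreground-unique and "
                    "absent from bg; it would masquerade as planted")
            truth.incidental.append(pep)
    return truth


# -- rendering ------------------------------------------------------------

def _wrap_sequence(seq: str) -> list[str]:
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        blocks = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append("     " + blocks)
    return lines


def render_uniprot_flat(records: list[ProteinRecord]) -> str:
    """Render records as UniProt flat text that parses back identically."""
    out: list[str] = []
    for r in records:
        status = "Reviewed" if r.reviewed else "Unreviewed"
        n = len(r.sequence)
        out.append(f"ID   {r.accession}_SYN         {status};         {n} AA.")
        out.append(f"AC   {r.accession};")
        out.append(f"DE   RecName: Full={r.name};")
        out.append(f"OS   {r.organism}.")
        if r.taxon_id is not None:
            out.append(f"OX   NCBI_TaxID={r.taxon_id};")
        for f in r.features:
            loc = str(f.start) if f.start == f.end else f"{f.start}..{f.end}"
            out.append(f"FT   {f.source_key:<15} {loc}")
            if f.description:
                out.append(f'FT                   /note="{f.description}"')
        out.append(f"SQ   SEQUENCE   {n} AA;  0 MW;  0000000000000000 CRC64;")
        out.extend(_wrap_sequence(r.sequence))
        out.append("//")
    return "\n".join(out) + ("\n" if records else "")


def render_fasta(records: list[ProteinRecord]) -> str:
    """Render records as UniProt-dialect FASTA (sequences only, no features)."""
    out: list[str] = []
    for r in records:
        db = "sp" if r.reviewed else "tr"
        header = f">{db}|{r.accession}|{r.accession}_SYN {r.name}"
        if r.organism:
            header += f" OS={r.organism}"
        if r.taxon_id is not None:
            header += f" OX={r.taxon_id}"
        out.append(header)
        out.extend(r.sequence[i:i + 60] for i in range(0, len(r.sequence), 60))
    return "\n".join(out) + ("\n" if records else "")


def generate_proteome_pair(spec: FixtureSpec, out_dir: str | Path
                           ) -> tuple[Path, Path, FixtureTruth]:
    """Write fg/bg proteomes (flat text + FASTA) and the truth sidecar.

    Returns the two flat-text paths and the verified :class:`FixtureTruth`;
    byte-identical outputs for identical specs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fg_records, bg_records, truth = generate_records(spec)
    fg_path = out_dir / "fg.dat"
    bg_path = out_dir / "bg.dat"
    fg_path.write_text(render_uniprot_flat(fg_records), encoding="utf-8")
    bg_path.write_text(render_uniprot_flat(bg_records), encoding="utf-8")
    (out_dir / "fg.fasta").write_text(render_fasta(fg_records), encoding="utf-8")
    (out_dir / "bg.fasta").write_text(render_fasta(bg_records), encoding="utf-8")
    (out_dir / "truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
    return fg_path, bg_path, truth
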