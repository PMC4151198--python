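"""Persistent peptide index: peptide → occurrences with annotation flags.

The index is a single-file SQLite database (the persistence format of the
original desktop tools in this niche) holding the digested peptides of one
proteome, each occurrence's coordinates and missed-cleavage count, and the
protein-level annotation features remapped to the peptide level as boolean
flags. Exact-match lookup over the stored digest answers "how many hits does
this peptide sequence have in this proteome?" — the primitive behind
surrogate-peptide uniqueness queries.
"""

from __future__ import annotations

import json
import sqlite3
import time
from dataclasses import dataclass, asdict

from .digestion import (
    DigestionParams,
    NONSTANDARD_AA,
    digest,
    monoisotopic_mass,
)
from .ingest import ProteinRecord, SequenceFeature

_FLAG_NAMES = (
    "has_ptm",
    "has_variant",
    "has_conflict",
    "in_signal",
    "isoform_variable",
    "nonstandard",
)

# feature kind → occurrence flag; "other" features are stored with the
# protein but raise no flag.
_KIND_TO_FLAG = {
    "ptm": "has_ptm",
    "glyco": "has_ptm",
    "variant_snp": "has_variant",
    "conflict": "has_conflict",
    "signal_peptide": "in_signal",
    "isoform_variable": "isoform_variable",
}


@dataclass(frozen=True)
class AnnotationFlags:
    """Peptide-level annotation flags for one occurrence."""

    has_ptm: bool = False
    has_variant: bool = False
    has_conflict: bool = False
    in_signal: bool = False
    isoform_variable: bool = False
    nonstandard: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def annotate_occurrence(start: int, end: int, sequence: str,
                        features: list[SequenceFeature]) -> AnnotationFlags:
    """Compute flags for a peptide occurrence on its parent protein.

    A flag is true iff at least one feature of the corresponding kind
    overlaps [start, end] (1-based inclusive interval intersection);
    ``nonstandard`` depends only on the peptide sequence.
    """
    if not 1 <= start <= end:
        raise ValueError(f"invalid interval ({start}, {end})")
    vals = dict.fromkeys(_FLAG_NAMES, False)
    for f in features:
        flag = _KIND_TO_FLAG.get(f.kind)
        if flag and f.start <= end and f.end >= start:
            vals[flag] = True
    vals["nonstandard"] = any(c in NONSTANDARD_AA for c in sequence)
    return AnnotationFlags(**vals)


_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE proteins (
    accession TEXT PRIMARY KEY,
    name TEXT, organism TEXT, length INTEGER, sequence TEXT
);
CREATE TABLE peptides (
    match_key TEXT PRIMARY KEY,
    sequence TEXT, length INTEGER, mass REAL,
    total_occurrences INTEGER, distinct_proteins INTEGER
);
CREATE TABLE occurrences (
    match_key TEXT, sequence TEXT, accession TEXT,
    start INTEGER, end INTEGER, missed_cleavages INTEGER,
    has_ptm INTEGER, has_variant INTEGER, has_conflict INTEGER,
    in_signal INTEGER, isoform_variable INTEGER, nonstandard INTEGER
);
CREATE INDEX idx_occ_key ON occurrences (match_key);
CREATE INDEX idx_occ_acc ON occurrences (accession);
"""


class IndexCompatibilityError(ValueError):
    """Two indexes compared in a dual-proteome query disagree on settings."""


class PeptideIndex:
    """A built peptide database over one proteome.

    Create with :func:`build_index` or :meth:`open`; persists as a single
    SQLite file via :meth:`save`. ``collapse_il`` folds isobaric I/L into one
    symbol for matching (recorded in metadata and required to match between
    compared indexes).
    """

    def __init__(self, conn: sqlite3.Connection):
        self._conn = conn
        self._conn.row_factory = sqlite3.Row

    # -- construction -------------------------------------------------

    @classmethod
    def build(cls, records: list[ProteinRecord], params: DigestionParams,
              label: str, path: str = ":memory:", collapse_il: bool = False,
              source: str = "", timestamp: float | None = None) -> "PeptideIndex":
        if not records:
            raise ValueError("empty record list")
        accs = [r.accession for r in records]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in record list")
        conn = sqlite3.connect(path)
        conn.executescript(_SCHEMA)
        idx = cls(conn)
        meta = {
            "label": label,
            "source": source,
            "dialect": records[0].source,
            "params": json.dumps(params.to_dict()),
            "collapse_il": json.dumps(collapse_il),
            "created": time.strftime(
                "%Y-%m-%dT%H:%M:%SZ",
                time.gmtime(time.time() if timestamp is None else timestamp),
            ),
        }
        conn.executemany("INSERT INTO meta VALUES (?, ?)", meta.items())
        conn.executemany(
            "INSERT INTO proteins VALUES (?, ?, ?, ?, ?)",
            ((r.accession, r.name, r.organism, len(r.sequence), r.sequence)
             for r in records),
        )
        for r in records:
            rows = []
            for pep in digest(r.sequence, params):
                flags = annotate_occurrence(pep.start, pep.end, pep.sequence,
                                            r.features)
                rows.append((
                    idx._match_key_raw(pep.sequence, collapse_il), pep.sequence,
                    r.accession, pep.start, pep.end, pep.missed_cleavages,
                    *(int(getattr(flags, f)) for f in _FLAG_NAMES),
                ))
            conn.executemany(
                "INSERT INTO occurrences VALUES (?,?,?,?,?,?,?,?,?,?,?,?)", rows
            )
        conn.execute(
            """INSERT INTO peptides
               SELECT match_key, MIN(sequence), LENGTH(MIN(sequence)), NULL,
                      COUNT(*), COUNT(DISTINCT accession)
               FROM occurrences GROUP BY match_key"""
        )
        # peptide mass; NULL where non-standard residues leave it undefined
        for row in conn.execute(
            "SELECT match_key, sequence FROM peptides"
        ).fetchall():
            seq = row["sequence"]
            if any(c in NONSTANDARD_AA for c in seq):
                continue
            conn.execute(
                "UPDATE peptides SET mass = ? WHERE match_key = ?",
                (monoisotopic_mass(seq), row["match_key"]),
            )
        conn.commit()
        return idx

    @classmethod
    def open(cls, path: str) -> "PeptideIndex":
        conn = sqlite3.connect(path)
        try:
            conn.execute("SELECT key FROM meta LIMIT 1")
        except sqlite3.DatabaseError as exc:
            raise ValueError(f"{path} is not a peptide index") from exc
        return cls(conn)

    def save(self, path: str) -> None:
        """Persist to ``path`` (single SQLite file)."""
        dest = sqlite3.connect(path)
        with dest:
            self._conn.backup(dest)
        dest.close()

    def close(self) -> None:
        self._conn.close()

    # -- metadata ------------------------------------------------------

    @property
    def metadata(self) -> dict:
        return {row["key"]: row["value"]
                for row in self._conn.execute("SELECT key, value FROM meta")}

    @property
    def params(self) -> DigestionParams:
        return DigestionParams.from_dict(json.loads(self.metadata["params"]))

    @property
    def collapse_il(self) -> bool:
        return json.loads(self.metadata.get("collapse_il", "false"))

    @property
    def label(self) -> str:
        return self.metadata.get("label", "")

    @staticmethod
    def _match_key_raw(sequence: str, collapse_il: bool) -> str:
        if collapse_il:
            return sequence.replace("I", "J").replace("L", "J")
        return sequence

    def match_key(self, sequence: str) -> str:
        return self._match_key_raw(sequence, self.collapse_il)

    def check_compatible(self, other: "PeptideIndex") -> None:
        """Raise unless dual-proteome comparison with ``other`` is sound."""
        a, b = self.params, other.params
        mismatches = []
        if a.enzyme != b.enzyme:
            mismatches.append(f"enzyme ({a.enzyme} vs {b.enzyme})")
        if a.max_missed_cleavages != b.max_missed_cleavages:
            mismatches.append(
                f"max_missed_cleavages ({a.max_missed_cleavages} vs "
                f"{b.max_missed_cleavages})")
        if self.collapse_il != other.collapse_il:
            mismatches.append("I/L collapse setting")
        if mismatches:
            raise IndexCompatibilityError(
                "indexes built with different digestion settings: "
                + "; ".join(mismatches))

    # -- queries -------------------------------------------------------

    def count_hits(self, sequence: str) -> tuple[int, int]:
        """(total_occurrences, distinct_proteins) for an exact peptide match."""
        row = self._conn.execute(
            "SELECT total_occurrences, distinct_proteins FROM peptides "
            "WHERE match_key = ?", (self.match_key(sequence),)
        ).fetchone()
        return (row[0], row[1]) if row else (0, 0)

    def protein(self, accession: str) -> sqlite3.Row | None:
        return self._conn.execute(
            "SELECT * FROM proteins WHERE accession = ?", (accession,)
        ).fetchone()

    def proteins_by_name(self, name_query: str) -> list[sqlite3.Row]:
        """Case-insensitive substring match on the protein name."""
        like = f"%{name_query.lower()}%"
        return self._conn.execute(
            "SELECT * FROM proteins WHERE LOWER(name) LIKE ? ORDER BY accession",
            (like,),
        ).fetchall()

    def occurrences_for_protein(self, accession: str) -> list[sqlite3.Row]:
        """All digest-peptide occurrences of one protein with hit counts."""
        return self._conn.execute(
            """SELECT o.*, p.mass, p.total_occurrences, p.distinct_proteins,
                      pr.name AS protein_name
               FROM occurrences o
               JOIN peptides p ON p.match_key = o.match_key
               JOIN proteins pr ON pr.accession = o.accession
               WHERE o.accession = ?
               ORDER BY o.start, o.end""",
            (accession,),
        ).fetchall()

    def occurrences_for_peptide(self, sequence: str) -> list[sqlite3.Row]:
        return self._conn.execute(
            """SELECT o.*, p.mass, p.total_occurrences, p.distinct_proteins,
                      pr.name AS protein_name
               FROM occurrences o
               JOIN peptides p ON p.match_key = o.match_key
               JOIN proteins pr ON pr.accession = o.accession
               WHERE o.match_key = ?
               ORDER BY o.accession, o.start""",
            (self.match_key(sequence),),
        ).fetchall()

    def all_peptides(self) -> list[str]:
        return [r[0] for r in
                self._conn.execute("SELECT sequence FROM peptides ORDER BY sequence")]

    def n_proteins(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM proteins").fetchone()[0]

    def n_peptides(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM peptides").fetchone()[0]

    def n_occurrences(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM occurrences").fetchone()[0]


def build_index(records: list[ProteinRecord], params: DigestionParams,
                label: str, **kwargs) -> PeptideIndex:
    """Digest ``records`` and build a queryable :class:`PeptideIndex`."""
    return PeptideIndex.build(records, params, label, **kwargs)
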