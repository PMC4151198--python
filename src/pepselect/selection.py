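"""Surrogate-peptide queries, filtering, and CSV export.

A surrogate peptide stands in for its parent protein in a targeted
(SRM/PRM) assay, so it must identify that protein unambiguously: unique
within the proteome of interest and — in mixed-species samples such as
xenografts — absent from the host/background proteome. This module answers
accession / protein-name / peptide-sequence queries against one or two
peptide indexes, applies the advised assay-design filters (length 5-22,
no Met/Cys, no annotated PTM/variant/conflict/signal positions, optional
precursor m/z window), and exports the candidate table as CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

from .digestion import mz as _mz
from .index_store import AnnotationFlags, IndexCompatibilityError, PeptideIndex

_FLAG_REASONS = {
    "has_ptm": "modified residue (PTM)",
    "has_variant": "sequence variant (SNP)",
    "has_conflict": "sequence conflict",
    "in_signal": "signal peptide",
    "isoform_variable": "isoform-variable region",
    "nonstandard": "nonstandard residue",
}

DEFAULT_EXCLUDE_FLAGS = frozenset(
    {"has_ptm", "has_variant", "has_conflict", "in_signal", "nonstandard"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Assay-suitability filters applied to candidate rows.

    Defaults implement the advised values for surrogate selection: peptide
    length 5-22 residues, no chemically labile Cys/Met, no missed cleavages,
    no annotated modification/variant/conflict/signal positions, unique in
    the foreground (exactly one occurrence) and absent from the background.
    ``mz_window`` is off by default; when set, a peptide passes if ANY
    charge in the configured set puts its precursor inside the window
    (400-1600 Th at 2+/3+ suits a triple-quadrupole platform).
    ``unique_scope`` may be relaxed from "occurrences" to "proteins" to
    accept a peptide repeated inside a single protein.
    """

    min_length: int = 5
    max_length: int = 22
    excluded_residues: frozenset[str] = frozenset({"M", "C"})
    max_missed_cleavages: int = 0
    require_unique_fg: bool = True
    unique_scope: str = "occurrences"  # or "proteins"
    max_bg_occurrences: int = 0
    exclude_flags: frozenset[str] = DEFAULT_EXCLUDE_FLAGS
    mz_window: tuple[float, float, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.max_bg_occurrences < 0:
            raise ValueError("max_bg_occurrences must be >= 0")
        if self.unique_scope not in ("occurrences", "proteins"):
            raise ValueError("unique_scope must be 'occurrences' or 'proteins'")
        unknown = set(self.exclude_flags) - set(_FLAG_REASONS)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")
        object.__setattr__(self, "excluded_residues",
                           frozenset(self.excluded_residues))
        object.__setattr__(self, "exclude_flags", frozenset(self.exclude_flags))


#: Uniqueness-only configuration: no length/residue/flag constraints, used
#: when recovering planted ground truth or exploring without assay filters.
UNIQUENESS_ONLY = FilterConfig(
    min_length=1, max_length=10**9, excluded_residues=frozenset(),
    max_missed_cleavages=2, exclude_flags=frozenset(),
)


@dataclass
class SelectionRow:
    """One candidate peptide occurrence with hit counts and filter outcome."""

    protein_accession: str | None
    protein_name: str | None
    peptide_sequence: str
    start: int | None
    end: int | None
    length: int
    missed_cleavages: int | None
    mass: float | None
    fg_total_occurrences: int
    fg_distinct_proteins: int
    bg_total_occurrences: int | None = None
    flags: AnnotationFlags = field(default_factory=AnnotationFlags)
    passed_filters: bool = False
    rejection_reasons: list[str] = field(default_factory=list)


class QueryResult(list):
    """List of :class:`SelectionRow` with batch-mode warnings attached."""

    def __init__(self, rows=(), warnings=None):
        super().__init__(rows)
        self.warnings: list[str] = list(warnings or [])


def _row_from_occurrence(occ) -> SelectionRow:
    flags = AnnotationFlags(
        **{f: bool(occ[f]) for f in (
            "has_ptm", "has_variant", "has_conflict",
            "in_signal", "isoform_variable", "nonstandard")}
    )
    return SelectionRow(
        protein_accession=occ["accession"],
        protein_name=occ["protein_name"],
        peptide_sequence=occ["sequence"],
        start=occ["start"],
        end=occ["end"],
        length=occ["end"] - occ["start"] + 1,
        missed_cleavages=occ["missed_cleavages"],
        mass=occ["mass"],
        fg_total_occurrences=occ["total_occurrences"],
        fg_distinct_proteins=occ["distinct_proteins"],
        flags=flags,
    )


def _reasons(row: SelectionRow, f: FilterConfig) -> list[str]:
    """Rejection reasons in a fixed order; empty list means pass."""
    reasons: list[str] = []
    if row.length < f.min_length:
        reasons.append(f"length < {f.min_length}")
    elif row.length > f.max_length:
        reasons.append(f"length > {f.max_length}")
    for aa in sorted(f.excluded_residues):
        if aa in row.peptide_sequence:
            reasons.append(f"excluded residue {aa}")
    if row.missed_cleavages is not None and \
            row.missed_cleavages > f.max_missed_cleavages:
        reasons.append(f"missed cleavages > {f.max_missed_cleavages}")
    for flag in ("has_ptm", "has_variant", "has_conflict", "in_signal",
                 "isoform_variable", "nonstandard"):
        if flag in f.exclude_flags and getattr(row.flags, flag):
            reasons.append(_FLAG_REASONS[flag])
    if f.require_unique_fg:
        count = (row.fg_total_occurrences if f.unique_scope == "occurrences"
                 else row.fg_distinct_proteins)
        if count != 1:
            reasons.append("not unique in foreground")
    if row.bg_total_occurrences is not None and \
            row.bg_total_occurrences > f.max_bg_occurrences:
        reasons.append("present in background")
    if f.mz_window is not None:
        low, high, charges = f.mz_window
        if row.mass is None or not any(
                low <= _mz(row.mass, z) <= high for z in charges):
            reasons.append("m/z outside window")
    return reasons


def apply_filters(rows: list[SelectionRow],
                  filters: FilterConfig) -> list[SelectionRow]:
    """Populate ``rejection_reasons``/``passed_filters`` on every row.

    Reasons are recomputed from scratch, so the operation is idempotent and
    independent of input row order. Rows are returned (same objects) in
    input order; callers drop or keep rejected rows themselves.
    """
    for row in rows:
        row.rejection_reasons = _reasons(row, filters)
        row.passed_filters = not row.rejection_reasons
    return rows


def _sorted(rows: list[SelectionRow]) -> list[SelectionRow]:
    return sorted(rows, key=lambda r: (r.protein_accession or "",
                                       r.start or 0, r.missed_cleavages or 0,
                                       r.peptide_sequence))


def _finish(rows, filters, keep_rejected, warnings) -> QueryResult:
    apply_filters(rows, filters)
    if not keep_rejected:
        rows = [r for r in rows if r.passed_filters]
    return QueryResult(_sorted(rows), warnings)


def query_accession(index: PeptideIndex, accessions: list[str],
                    filters: FilterConfig | None = None,
                    keep_rejected: bool = False) -> QueryResult:
    """All digest peptides of the given proteins, with foreground hit counts.

    A single unknown accession is fatal; in batch mode (more than one
    accession) unknown accessions become warnings on the result.
    """
    filters = filters or FilterConfig()
    batch = len(accessions) > 1
    rows: list[SelectionRow] = []
    warnings: list[str] = []
    for acc in accessions:
        occs = index.occurrences_for_protein(acc)
        if not occs:
            msg = f"unknown accession {acc!r} in index {index.label!r}"
            if batch:
                warnings.append(msg)
                continue
            raise KeyError(msg)
        rows.extend(_row_from_occurrence(o) for o in occs)
    return _finish(rows, filters, keep_rejected, warnings)


def query_name(index: PeptideIndex, name_query: str,
               filters: FilterConfig | None = None,
               keep_rejected: bool = False) -> QueryResult:
    """Case-insensitive substring match on protein names, expanded to rows."""
    if not name_query:
        raise ValueError("empty name query")
    matches = [p["accession"] for p in index.proteins_by_name(name_query)]
    if not matches:
        return QueryResult()
    rows: list[SelectionRow] = []
    for acc in matches:
        rows.extend(_row_from_occurrence(o)
                    for o in index.occurrences_for_protein(acc))
    return _finish(rows, filters or FilterConfig(), keep_rejected, [])


def query_sequences(index: PeptideIndex, sequences: list[str],
                    filters: FilterConfig | None = None,
                    keep_rejected: bool = True) -> QueryResult:
    """One row per (sequence, occurrence); absent sequences get a zero-hit row."""
    filters = filters or FilterConfig()
    rows: list[SelectionRow] = []
    for seq in sequences:
        seq = seq.upper()
        occs = index.occurrences_for_peptide(seq)
        if not occs:
            rows.append(SelectionRow(
                protein_accession=None, protein_name=None,
                peptide_sequence=seq, start=None, end=None, length=len(seq),
                missed_cleavages=None, mass=None,
                fg_total_occurrences=0, fg_distinct_proteins=0,
            ))
        else:
            rows.extend(_row_from_occurrence(o) for o in occs)
    return _finish(rows, filters, keep_rejected, [])


def select_surrogates(fg_index: PeptideIndex, bg_index: PeptideIndex,
                      accessions: list[str],
                      filters: FilterConfig | None = None,
                      keep_rejected: bool = False) -> QueryResult:
    """Dual-proteome surrogate selection.

    Queries ``accessions`` in the foreground index, attaches the number of
    exact-match hits of each peptide in the background (host) index, and
    applies the filters; with defaults a peptide passes only if it occurs
    exactly once in the foreground and never in the background. Both indexes
    must share enzyme, missed-cleavage and I/L-collapse settings.
    """
    fg_index.check_compatible(bg_index)
    filters = filters or FilterConfig()
    result = query_accession(fg_index, accessions, filters, keep_rejected=True)
    for row in result:
        row.bg_total_occurrences = bg_index.count_hits(row.peptide_sequence)[0]
    return _finish(list(result), filters, keep_rejected, result.warnings)


# -- CSV export -----------------------------------------------------------

_BASE_COLUMNS = [
    "protein_accession", "protein_name", "peptide_sequence", "start", "end",
    "length", "missed_cleavages", "mass", "fg_total_occurrences",
    "fg_distinct_proteins", "bg_total_occurrences",
    "has_ptm", "has_variant", "has_conflict", "in_signal",
    "isoform_variable", "nonstandard", "passed_filters", "rejection_reasons",
]
_FLAG_COLS = ["has_ptm", "has_variant", "has_conflict", "in_signal",
              "isoform_variable", "nonstandard"]
_INT_COLS = {"start", "end", "length", "missed_cleavages",
             "fg_total_occurrences", "fg_distinct_proteins",
             "bg_total_occurrences"}


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # round-trips exactly
    return str(value)


def export_csv(rows: list[SelectionRow], destination) -> None:
    """Write rows as RFC-4180 CSV (UTF-8, fixed column order).

    In single-proteome mode (every row's background count is null) the
    background column is omitted. ``destination`` is a path or text handle.
    """
    single = all(r.bg_total_occurrences is None for r in rows)
    columns = [c for c in _BASE_COLUMNS
               if not (single and c == "bg_total_occurrences")]

    def _write(fh) -> None:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(columns)
        for r in rows:
            rec = {
                **{c: getattr(r, c) for c in _BASE_COLUMNS
                   if c not in _FLAG_COLS and c != "rejection_reasons"},
                **{c: getattr(r.flags, c) for c in _FLAG_COLS},
                "rejection_reasons": "; ".join(r.rejection_reasons),
            }
            w.writerow([_cell(rec[c]) for c in columns])

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            _write(fh)


def read_csv(source) -> list[SelectionRow]:
    """Read back a CSV written by :func:`export_csv` (exact round trip)."""

    def _read(fh) -> list[SelectionRow]:
        reader = csv.reader(fh)
        header = next(reader)
        rows = []
        for rec in reader:
            d = dict(zip(header, rec))

            def opt(key, conv=str):
                v = d.get(key, "")
                return conv(v) if v != "" else None

            flags = AnnotationFlags(**{c: d[c] == "true" for c in _FLAG_COLS})
            rows.append(SelectionRow(
                protein_accession=opt("protein_accession"),
                protein_name=opt("protein_name"),
                peptide_sequence=d["peptide_sequence"],
                start=opt("start", int), end=opt("end", int),
                length=int(d["length"]),
                missed_cleavages=opt("missed_cleavages", int),
                mass=opt("mass", float),
                fg_total_occurrences=int(d["fg_total_occurrences"]),
                fg_distinct_proteins=int(d["fg_distinct_proteins"]),
                bg_total_occurrences=opt("bg_total_occurrences", int),
                flags=flags,
                passed_filters=d["passed_filters"] == "true",
                rejection_reasons=(d["rejection_reasons"].split("; ")
                                   if d["rejection_reasons"] else []),
            ))
        return rows

    if hasattr(source, "read"):
        return _read(source)
    with open(source, encoding="utf-8", newline="") as fh:
        return _read(fh)


def read_batch_file(path: str) -> list[str]:
    """Read a batch query file: one accession/peptide per line, '#' comments."""
    items = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                items.append(line)
    return items
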