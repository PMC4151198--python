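"""Proteome file ingestion: UniProt flat text, GenPept, FASTA.

Parses whole-proteome protein databases into :class:`ProteinRecord` objects
carrying their sequence-annotation features (PTM sites, variants/SNPs,
sequence conflicts, signal peptides, isoform-variable regions), the
information later remapped onto individual peptides in the index.

Entry-level parsing is delegated to Biopython (``Bio.SwissProt`` for the
UniProt flat format, ``Bio.SeqIO`` for GenPept and FASTA); this module
splits multi-entry streams so a malformed entry is skipped and reported
rather than aborting the whole file, and maps the parsed structures onto
the domain types. Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

from Bio import SeqIO, SwissProt

from .digestion import ALPHABET

FEATURE_KINDS = (
    "ptm",
    "glyco",
    "variant_snp",
    "conflict",
    "signal_peptide",
    "isoform_variable",
    "other",
)

# Fixed, versioned mapping from raw feature keys to feature kinds.
# Unknown keys map to "other" and are retained, never dropped.
UNIPROT_KEY_MAP = {
    "MOD_RES": "ptm",
    "LIPID": "ptm",
    "CROSSLNK": "ptm",
    "CARBOHYD": "glyco",
    "VARIANT": "variant_snp",
    "CONFLICT": "conflict",
    "SIGNAL": "signal_peptide",
    "VAR_SEQ": "isoform_variable",
}

# site_type keywords refining GenPept "Site" features.
_GENPEPT_PTM_WORDS = (
    "phosphorylation",
    "acetylation",
    "methylation",
    "amidation",
    "sulfatation",
    "sulfation",
    "modified",
    "lipid",
    "myristoylation",
    "palmitoylation",
    "hydroxylation",
)
_GENPEPT_GLYCO_WORDS = ("glycosylation",)

# GenPept keys describing the record itself rather than a sequence annotation.
_GENPEPT_STRUCTURAL_KEYS = frozenset({"source", "Protein", "CDS", "gene"})


def map_feature_key(source_key: str) -> str:
    """Deterministically map a raw feature key to a feature kind.

    UniProt feature-table keys are matched exactly; GenPept Site features use
    a composed key ``"Site/<site_type>"`` classified by keyword.
    """
    if source_key in UNIPROT_KEY_MAP:
        return UNIPROT_KEY_MAP[source_key]
    if source_key.startswith("Site/"):
        qual = source_key[5:].lower()
        if any(w in qual for w in _GENPEPT_GLYCO_WORDS):
            return "glyco"
        if any(w in qual for w in _GENPEPT_PTM_WORDS):
            return "ptm"
        return "other"
    return "other"


@dataclass(frozen=True)
class SequenceFeature:
    """One annotated interval on a protein (1-based inclusive)."""

    kind: str
    start: int
    end: int
    description: str = ""
    source_key: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid feature interval ({self.start}, {self.end})")


@dataclass
class ProteinRecord:
    """One protein entry from a proteome database file."""

    accession: str
    name: str
    organism: str
    sequence: str
    source: str  # uniprot_dat | genpept_gpff | fasta
    taxon_id: int | None = None
    features: list[SequenceFeature] = field(default_factory=list)
    reviewed: bool | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("empty accession")
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: invalid sequence characters {sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"{self.accession}: feature {f.source_key} ({f.start},{f.end}) "
                    f"outside sequence of length {n}"
                )


class ParseError(ValueError):
    """Structural corruption that aborts parsing of a file."""


class DuplicateAccessionError(ParseError):
    """Two entries in one file share a primary accession."""


@dataclass
class ParseReport:
    """Per-file account of parsed and skipped entries."""

    parsed: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)  # (line no, reason)

    def skip(self, line: int, reason: str) -> None:
        self.skipped.append((line, reason))

    def render(self) -> str:
        lines = [f"parsed: {self.parsed}", f"skipped: {len(self.skipped)}"]
        for lineno, reason in self.skipped:
            lines.append(f"  line {lineno}: {reason}")
        return "\n".join(lines) + "\n"


def _split_entries(stream) -> list[tuple[int, str]]:
    """Split a flat-file stream at ``//`` terminators.

    Returns (first line number, entry text) pairs; raises :class:`ParseError`
    if non-blank content remains after the last terminator (unterminated
    final entry).
    """
    entries: list[tuple[int, str]] = []
    buf: list[str] = []
    start_line = 1
    lineno = 0
    for lineno, line in enumerate(stream, 1):
        if line.rstrip("\n").rstrip() == "//":
            buf.append("//\n")
            entries.append((start_line, "".join(buf)))
            buf = []
            start_line = lineno + 1
        else:
            if not buf and not line.strip():
                start_line = lineno + 1
                continue
            buf.append(line)
    if any(line.strip() for line in buf):
        raise ParseError(f"unterminated final entry starting at line {start_line}")
    return entries


def _check_duplicates(records: list[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.accession in seen:
            raise DuplicateAccessionError(f"duplicate accession {r.accession}")
        seen.add(r.accession)


_RECNAME_RE = re.compile(r"RecName: Full=([^;{]+)")
_SUBNAME_RE = re.compile(r"SubName: Full=([^;{]+)")


def parse_uniprot_flat(stream, report: ParseReport | None = None) -> list[ProteinRecord]:
    """Parse UniProt flat-text entries (.dat/.txt) into records.

    Feature-table keys are mapped through the fixed key map; the primary
    accession is the first AC listed. Malformed entries are skipped and
    recorded in ``report``; a duplicate primary accession is an error.
    """
    report = report if report is not None else ParseReport()
    records: list[ProteinRecord] = []
    for start_line, text in _split_entries(stream):
        try:
            sp = SwissProt.read(io.StringIO(text))
            if not sp.accessions:
                raise ValueError("missing accession")
            if not sp.sequence:
                raise ValueError("missing sequence")
            m = _RECNAME_RE.search(sp.description) or _SUBNAME_RE.search(sp.description)
            name = m.group(1).strip() if m else sp.entry_name
            features = []
            for ft in sp.features:
                loc = ft.location
                try:
                    fstart, fend = int(loc.start) + 1, int(loc.end)
                except (TypeError, ValueError):
                    continue  # unknown/fuzzy positions carry no usable interval
                note = ft.qualifiers.get("note", "")
                features.append(
                    SequenceFeature(
                        kind=map_feature_key(ft.type),
                        start=fstart,
                        end=fend,
                        description=note if isinstance(note, str) else "; ".join(note),
                        source_key=ft.type,
                    )
                )
            taxid = int(sp.taxonomy_id[0]) if sp.taxonomy_id else None
            records.append(
                ProteinRecord(
                    accession=sp.accessions[0],
                    name=name,
                    organism=sp.organism.rstrip("."),
                    sequence=sp.sequence.upper(),
                    source="uniprot_dat",
                    taxon_id=taxid,
                    features=features,
                    reviewed=sp.data_class == "Reviewed",
                )
            )
            report.parsed += 1
        except DuplicateAccessionError:
            raise
        except Exception as exc:  # noqa: BLE001 - tolerant per entry
            report.skip(start_line, str(exc))
    _check_duplicates(records)
    return records


def parse_genpept(stream, report: ParseReport | None = None) -> list[ProteinRecord]:
    """Parse RefSeq GenPept entries (.gpff) into records.

    The accession is the VERSION accession. Site features are refined by
    their site_type qualifier through the fixed key map; structural keys
    (source, Protein, CDS) are not sequence annotations and are dropped.
    """
    report = report if report is not None else ParseReport()
    records: list[ProteinRecord] = []
    for start_line, text in _split_entries(stream):
        try:
            gb = SeqIO.read(io.StringIO(text), "genbank")
            seq = str(gb.seq).upper()
            if not seq or "N" * len(seq) == seq and len(seq) == 0:
                raise ValueError("missing sequence")
            organism = gb.annotations.get("organism", "")
            taxon_id = None
            features = []
            for ft in gb.features:
                if ft.type == "source":
                    for xref in ft.qualifiers.get("db_xref", []):
                        if xref.startswith("taxon:"):
                            taxon_id = int(xref.split(":", 1)[1])
                if ft.type in _GENPEPT_STRUCTURAL_KEYS:
                    continue
                try:
                    fstart, fend = int(ft.location.start) + 1, int(ft.location.end)
                except (TypeError, ValueError):
                    continue
                if ft.type == "Site":
                    site_type = ft.qualifiers.get("site_type", [""])[0]
                    source_key = f"Site/{site_type}"
                else:
                    source_key = ft.type
                note = ft.qualifiers.get("note", [""])[0]
                features.append(
                    SequenceFeature(
                        kind=map_feature_key(source_key),
                        start=fstart,
                        end=fend,
                        description=note,
                        source_key=source_key,
                    )
                )
            name = gb.description
            if organism and name.endswith(f" [{organism}]"):
                name = name[: -len(organism) - 3]
            records.append(
                ProteinRecord(
                    accession=gb.id,
                    name=name,
                    organism=organism,
                    sequence=seq,
                    source="genpept_gpff",
                    taxon_id=taxon_id,
                    features=features,
                    reviewed=None,
                )
            )
            report.parsed += 1
        except DuplicateAccessionError:
            raise
        except Exception as exc:  # noqa: BLE001
            report.skip(start_line, str(exc))
    _check_duplicates(records)
    return records


_UNIPROT_FASTA_RE = re.compile(r"^(sp|tr)\|([^|]+)\|(\S+)\s*(.*)$")
_OS_RE = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")
_OX_RE = re.compile(r"\bOX=(\d+)")


def parse_fasta(stream, dialect: str = "generic",
                report: ParseReport | None = None) -> list[ProteinRecord]:
    """Parse a FASTA proteome into records (no features).

    ``dialect`` controls header interpretation: ``uniprot`` expects the
    ``db|ACC|NAME`` convention, ``refseq`` and ``generic`` take the first
    whitespace-delimited token as the accession. Sequences are upper-cased
    and '*' terminators stripped; characters outside the accepted alphabet
    are an error naming the record.
    """
    if dialect not in ("uniprot", "refseq", "generic"):
        raise ValueError(f"unknown FASTA dialect {dialect!r}")
    report = report if report is not None else ParseReport()
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(stream, "fasta"):
        header = rec.description
        organism = ""
        taxon_id = None
        reviewed = None
        m = _UNIPROT_FASTA_RE.match(header) if dialect == "uniprot" else None
        if m:
            db, accession, entry_name, desc = m.groups()
            reviewed = db == "sp"
            mos = _OS_RE.search(desc)
            if mos:
                organism = mos.group(1).strip()
                desc = desc[: mos.start()].strip()
            mox = _OX_RE.search(header)
            if mox:
                taxon_id = int(mox.group(1))
            name = desc.strip() or entry_name
        else:
            parts = header.split(None, 1)
            accession = parts[0]
            name = parts[1].strip() if len(parts) > 1 else accession
        seq = str(rec.seq).upper().rstrip("*")
        records.append(
            ProteinRecord(
                accession=accession,
                name=name,
                organism=organism,
                sequence=seq,
                source="fasta",
                taxon_id=taxon_id,
                features=[],
                reviewed=reviewed,
            )
        )
        report.parsed += 1
    _check_duplicates(records)
    return records


_PARSERS = {
    "uniprot": parse_uniprot_flat,
    "genpept": parse_genpept,
}


def parse_proteome(path: str, fmt: str, dialect: str = "generic",
                   report: ParseReport | None = None) -> list[ProteinRecord]:
    """Parse a proteome file by format name (uniprot | genpept | fasta)."""
    with open(path, encoding="utf-8") as fh:
        if fmt == "fasta":
            return parse_fasta(fh, dialect=dialect, report=report)
        if fmt in _PARSERS:
            return _PARSERS[fmt](fh, report=report)
        raise ValueError(f"unknown format {fmt!r}")
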