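# Methods

## The selection model

A surrogate peptide must unambiguously identify its parent protein in an
LC-MS assay. We model a proteome as the multiset of peptides produced by
exhaustive in-silico digestion of every protein's canonical sequence, and
define the *hit count* of a peptide sequence as its number of occurrences
(protein × position pairs) in that digest. A peptide is accepted as a
surrogate candidate when

* it occurs exactly once in the foreground (proteome of interest) digest,
* it has at most `max_bg_occurrences` (default 0) exact matches in the
  background (host) digest, and
* it passes the assay-suitability filters (below).

Matching between proteomes is exact lookup of the peptide sequence against
the background's *stored digest*, not substring search of protein
sequences. Substring semantics would count peptides that tryptic digestion
of the host could never produce and would therefore understate the number
of usable candidates; database lookup reflects what a digest of the mixed
sample actually contains. Consequently both indexes must be built with the
same enzyme, the same missed-cleavage ceiling and the same I/L-collapse
setting, and `select_surrogates` refuses mismatched pairs up front.

Both the total occurrence count and the distinct-protein count are stored;
the default uniqueness test uses total occurrences, so a peptide repeated
twice inside one protein is rejected (its signal would be a mixture of two
sites and is quantitatively ambiguous). Setting
`FilterConfig.unique_scope="proteins"` relaxes this to one distinct
protein.

## Digestion

Cleavage rules: trypsin cuts C-terminally to K or R, Lys-C to K, Arg-C to
R; Lys-N cuts N-terminally to K. The proline rule (no cleavage when the
residue following a K/R site is proline) is on by default for the three
C-terminal enzymes because it is the prevailing convention in proteomics
search engines; both conventions are common in the literature, so
`DigestionParams.proline_rule` exposes the alternative. Lys-N is
unaffected (its recognition is on the N-terminal side).

Missed cleavages are enumerated exhaustively: with `c` internal cuts the
digest contains, for each `k ≤ max_missed_cleavages`, every concatenation
of `k+1` consecutive fragments — `max(0, c+1−k)` peptides. Concatenating
the 0-missed peptides in coordinate order reconstructs the protein
exactly; both properties are asserted in the test suite against a
brute-force oracle.

Non-standard letters (B, Z, X, U, O) are accepted in sequences but are
opaque: they never create a cleavage site, peptides containing them carry
a `nonstandard` flag (rejected by the default filters), and their mass is
undefined (stored as null). The protein N-terminal methionine is not
clipped before digestion; initiator-Met processing is annotation-dependent
and out of scope.

`min_peptide_length` at *build* time defaults to 3 (the 3–5 range keeps
the database compact); values down to 1 are legal because the full digest
is needed for conservation checks. The stricter 5–22 window used for assay
design is deliberately a *query-time* filter so one index serves both
exploratory and selection queries.

Masses are monoisotopic residue sums plus one water, computed via
pyteomics; m/z is `(M + z·m_p)/z` with the proton mass 1.007276 Da. The
test suite checks masses against an independently frozen residue-mass
table to 1e-4 Da.

## Annotation remapping

Protein feature-table entries are mapped to peptide-level flags by
interval intersection: an occurrence spanning `[start, end]` (1-based,
inclusive) raises a flag iff a feature of the corresponding kind overlaps
it. The feature-key map is fixed in code: MOD_RES/LIPID/CROSSLNK → ptm,
CARBOHYD → glyco (flagged together with ptm — glycosylation is a PTM),
VARIANT → variant_snp, CONFLICT → conflict, SIGNAL → signal_peptide,
VAR_SEQ → isoform_variable; unknown keys are retained as `other` (no
flag). GenPept `Site` features are classified by their `site_type`
qualifier; `source`/`Protein`/`CDS` entries describe the record, not the
sequence, and are not treated as features.

Isoforms are not expanded: only the canonical sequence is digested, and
peptides overlapping a VAR_SEQ region carry the `isoform_variable` flag so
the user can decide whether a candidate must represent all isoforms or a
specific one.

## Filters

Defaults implement the advised assay-design values: length 5–22 aa;
reject peptides containing C (incomplete reduction/alkylation) or M
(partial oxidation); 0 missed cleavages; reject occurrences overlapping
PTM, variant/SNP, conflict or signal-peptide annotations and nonstandard
peptides; require foreground uniqueness and background absence. The
optional m/z window passes a peptide if *any* charge in the configured set
(default 2+, 3+) lands inside the window; a peptide with undefined mass
cannot be placed in the window and fails the check when the window is
enabled. Rejection reasons are recomputed from scratch in a fixed order
(length, residues, missed cleavages, flags, foreground uniqueness,
background presence, m/z), making `apply_filters` idempotent and
order-independent; rejected rows can be kept with their reasons rather
than dropped, so no information is hidden from the user. Output rows are
sorted by (accession, start, missed cleavages) for determinism.

## Index persistence

The index is one SQLite file with `meta`, `proteins`, `peptides` and
`occurrences` tables and an index on the peptide match key. Digestion
parameters, the I/L-collapse flag, the source file, a proteome label and a
creation timestamp are stored in `meta`; the timestamp can be pinned
(`build --timestamp`) when byte-identical index files are wanted. CSV
bodies contain no timestamps, so identical queries on identical indexes
produce identical files. I/L collapse substitutes a joint symbol in the
match key only; stored sequences are untouched.

## Synthetic proteome pairs

The fixture generator emulates the xenograft two-proteome situation with
exact, verifiable ground truth rather than realistic biology. Proteins are
concatenations of distinct tryptic-style fragments: 5–19 residues, ending
in K or R, no internal cleavage site, never starting with P (so the
proline rule cannot merge adjacent fragments). The distinct fragment set
is partitioned into

* **planted unique** — placed exactly once in the foreground, absent from
  the background: the true surrogate candidates;
* **shared** — a configurable fraction of fragments copied into background
  proteins: peptides that must be rejected for background presence;
* **filler** — placed twice in the foreground so they are never
  foreground-unique. Without this, any fragment that merely happened not
  to be shared would pass uniqueness-only selection and the planted set
  could not equal the recovered set exactly.

With this construction, uniqueness-only selection (no length/residue/flag
constraints, 0 missed cleavages) must return exactly the planted-unique
set — precision = recall = 1 — and the generator verifies the labels by an
internal brute-force digestion before returning. Features are placed
uniformly at a configurable density (default 0.5 features per 100 residues
per kind; signal peptides at the N-terminus). Optional switches inject
K/R-P motifs (exercising the proline rule) and non-standard letters
(exercising `nonstandard` flagging). Output is rendered as UniProt flat
text and FASTA and is byte-deterministic given the seed and parameters.

What the fixtures do *not* model: inter-species homology gradients
(near-identical peptides differing by point mutations), realistic amino
acid composition (the uniform alphabet makes M/C-containing peptides more
common than in real proteomes), isoform structure, or database-release
effects. Passing the planted-truth tests therefore demonstrates the
correctness of the counting and selection machinery, not the biological
yield of candidates on real proteomes, which depends entirely on the
databases supplied.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic proteomes of
4–20 proteins (~100–360 residues each), 20 proteome pairs spanning
shared-fragment fractions 0–1, 1000 random proteins for the digestion
oracle sweep, and 100 random peptides for mass checks — sizes at which the
brute-force oracles are exact and fast while exercising every code path;
the pipeline itself streams per protein and scales to full proteomes.
Mass agreement is asserted to 1e-4 Da (the precision of the frozen
reference table); m/z is exact closed form. Ties in output ordering are
broken by peptide sequence. Degenerate inputs: empty sequences, empty
record lists, unknown enzymes, inverted intervals and infeasible fixture
specs raise `ValueError`; unknown accessions are fatal for single queries
and warnings in batch mode; malformed entries in a multi-entry file are
skipped and reported while structural corruption (an unterminated final
entry) aborts the parse.

## Known limitations

No cleavage-efficiency prediction, no LC-MS detectability scoring, no SRM
transition selection — these are downstream steps the selection output
feeds into. No incremental index updates (rebuild on change), no merged
multi-proteome indexes, no XML input dialects, and no network retrieval:
inputs are local files.
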