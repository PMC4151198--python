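"""Queries, filter semantics, dual-proteome selection, CSV round trip."""

import io
from dataclasses import replace

import pytest

from pepselect import (
    AnnotationFlags,
    DigestionParams,
    FilterConfig,
    IndexCompatibilityError,
    ProteinRecord,
    SelectionRow,
    SequenceFeature,
    apply_filters,
    build_index,
    export_csv,
    query_accession,
    query_name,
    query_sequences,
    read_csv,
    select_surrogates,
)
from pepselect.selection import UNIQUENESS_ONLY, read_batch_file

P0 = DigestionParams(enzyme="trypsin", max_missed_cleavages=0,
                     min_peptide_length=3)
RELAXED = replace(UNIQUENESS_ONLY, max_missed_cleavages=0)


def rec(acc, seq, features=(), name="protein"):
    return ProteinRecord(accession=acc, name=name, organism="Synthetic",
                         sequence=seq, source="fasta",
                         features=list(features))


def mkrow(seq="AAAAAK", fg=1, fgp=1, bg=None, length=None, mc=0, mass=600.0,
          flags=None):
    return SelectionRow(
        protein_accession="A1", protein_name="protein", peptide_sequence=seq,
        start=1, end=len(seq), length=length or len(seq),
        missed_cleavages=mc, mass=mass, fg_total_occurrences=fg,
        fg_distinct_proteins=fgp, bg_total_occurrences=bg,
        flags=flags or AnnotationFlags(),
    )


# -- query operations ------------------------------------------------------

def test_query_accession_basic():
    idx = build_index([rec("A1", "AAAKGGGR")], P0, "t")
    filt = FilterConfig(min_length=3, excluded_residues=frozenset())
    rows = query_accession(idx, ["A1"], filt)
    assert {r.peptide_sequence for r in rows} == {"AAAK", "GGGR"}
    assert all(r.fg_total_occurrences == 1 and r.passed_filters for r in rows)


def test_query_accession_methionine_rejected_with_reason():
    idx = build_index([rec("A1", "MAAKGGGR")], P0, "t")
    filt = FilterConfig(min_length=3)
    rows = query_accession(idx, ["A1"], filt, keep_rejected=True)
    bad = next(r for r in rows if r.peptide_sequence == "MAAK")
    assert not bad.passed_filters
    assert "excluded residue M" in bad.rejection_reasons


def test_query_accession_single_unknown_is_fatal_batch_warns():
    idx = build_index([rec("A1", "AAAKGGGR")], P0, "t")
    with pytest.raises(KeyError):
        query_accession(idx, ["NOPE"], RELAXED)
    result = query_accession(idx, ["A1", "NOPE"], RELAXED)
    assert {r.peptide_sequence for r in result} == {"AAAK", "GGGR"}
    assert len(result.warnings) == 1 and "NOPE" in result.warnings[0]


def test_query_name_substring_and_empty_cases():
    idx = build_index([rec("A1", "AAAKGGGR", name="Keratin-like"),
                       rec("A2", "CCCKDDDR", name="Keratin associated"),
                       rec("A3", "EEEKFFFR", name="Unrelated")], P0, "t")
    rows = query_name(idx, "kerat", RELAXED)
    assert {r.protein_accession for r in rows} == {"A1", "A2"}
    assert query_name(idx, "ZZZ", RELAXED) == []
    with pytest.raises(ValueError):
        query_name(idx, "", RELAXED)


def test_query_sequences_rows_per_occurrence_and_absent():
    idx = build_index([rec("A1", "AAAKGGGR"), rec("A2", "CCCKGGGR")], P0, "t")
    rows = query_sequences(idx, ["AAAK", "GGGR", "ABSENTK"], RELAXED)
    by_seq = {}
    for r in rows:
        by_seq.setdefault(r.peptide_sequence, []).append(r)
    assert len(by_seq["AAAK"]) == 1
    assert by_seq["AAAK"][0].fg_total_occurrences == 1
    assert len(by_seq["GGGR"]) == 2
    assert all(r.fg_total_occurrences == 2 and r.fg_distinct_proteins == 2
               for r in by_seq["GGGR"])
    absent = by_seq["ABSENTK"][0]
    assert absent.fg_total_occurrences == 0
    assert absent.protein_accession is None


def test_query_sequences_uppercases_input():
    idx = build_index([rec("A1", "AAAKGGGR")], P0, "t")
    rows = query_sequences(idx, ["aaak"], RELAXED)
    assert rows[0].fg_total_occurrences == 1


# -- dual-proteome selection ----------------------------------------------

def test_select_surrogates_planted_pass_and_shared_reject():
    fg = [rec("F1", "AAADEFKGGGR")]     # AAADEFK unique; GGGR shared
    bg = [rec("B1", "CCCWEFKGGGR")]
    fgi, bgi = build_index(fg, P0, "fg"), build_index(bg, P0, "bg")
    rows = select_surrogates(fgi, bgi, ["F1"], RELAXED, keep_rejected=True)
    by_seq = {r.peptide_sequence: r for r in rows}
    assert by_seq["AAADEFK"].passed_filters
    assert (by_seq["AAADEFK"].fg_total_occurrences,
            by_seq["AAADEFK"].bg_total_occurrences) == (1, 0)
    assert not by_seq["GGGR"].passed_filters
    assert by_seq["GGGR"].rejection_reasons == ["present in background"]


def test_select_surrogates_rejects_mismatched_indexes():
    fgi = build_index([rec("F1", "AAAKGGGR")], P0, "fg")
    bgi = build_index([rec("B1", "AAAKGGGR")],
                      DigestionParams(enzyme="lysn", max_missed_cleavages=0,
                                      min_peptide_length=3), "bg")
    with pytest.raises(IndexCompatibilityError):
        select_surrogates(fgi, bgi, ["F1"], RELAXED)


def test_background_reduces_candidates_subset(fg_index, bg_index,
                                              proteome_pair):
    """Passing set with background ⊆ passing set without background."""
    fg, _, _ = proteome_pair
    accs = [r.accession for r in fg]
    solo = {(r.protein_accession, r.peptide_sequence, r.start)
            for r in query_accession(fg_index, accs, RELAXED)}
    dual = {(r.protein_accession, r.peptide_sequence, r.start)
            for r in select_surrogates(fg_index, bg_index, accs, RELAXED)}
    assert dual <= solo


def test_planted_truth_recovery(fg_index, bg_index, proteome_pair):
    fg, _, truth = proteome_pair
    rows = select_surrogates(fg_index, bg_index,
                             [r.accession for r in fg], RELAXED)
    assert sorted({r.peptide_sequence for r in rows}) == \
        sorted(truth.planted_unique)


# -- filter semantics ------------------------------------------------------

def test_filter_length_bounds():
    rows = apply_filters([mkrow("AAEK"), mkrow("A" * 22 + "K")],
                         FilterConfig())
    assert rows[0].rejection_reasons == ["length < 5"]
    assert rows[1].rejection_reasons == ["length > 22"]
    ok = apply_filters([mkrow("AADEK"), mkrow("A" * 21 + "K")],
                       FilterConfig())
    assert all(r.passed_filters for r in ok)


def test_filter_flag_reasons():
    for flag, reason in [("has_conflict", "sequence conflict"),
                         ("has_ptm", "modified residue (PTM)"),
                         ("has_variant", "sequence variant (SNP)"),
                         ("in_signal", "signal peptide"),
                         ("nonstandard", "nonstandard residue")]:
        row = mkrow(flags=AnnotationFlags(**{flag: True}))
        apply_filters([row], FilterConfig())
        assert row.rejection_reasons == [reason], flag


def test_filter_uniqueness_and_background():
    rows = [mkrow(fg=2, fgp=2), mkrow(bg=3)]
    apply_filters(rows, FilterConfig())
    assert rows[0].rejection_reasons == ["not unique in foreground"]
    assert rows[1].rejection_reasons == ["present in background"]
    # relaxing uniqueness to distinct-protein scope
    rows2 = [mkrow(fg=2, fgp=1)]
    apply_filters(rows2, FilterConfig(unique_scope="proteins"))
    assert rows2[0].passed_filters


def test_filter_mz_window_any_charge_passes():
    filt = FilterConfig(mz_window=(400.0, 1600.0, (2, 3)))
    ok = mkrow(mass=2400.0)     # 2+: 1201, inside
    low = mkrow(mass=500.0)     # 2+: 251, 3+: 168 → outside
    nomass = mkrow(mass=None)
    apply_filters([ok, low, nomass], filt)
    assert ok.passed_filters
    assert "m/z outside window" in low.rejection_reasons
    assert "m/z outside window" in nomass.rejection_reasons


def test_apply_filters_idempotent_and_order_independent():
    rows = [mkrow("AAEK"), mkrow(fg=2), mkrow()]
    once = apply_filters(list(rows), FilterConfig())
    reasons1 = [r.rejection_reasons for r in once]
    twice = apply_filters(once, FilterConfig())
    assert [r.rejection_reasons for r in twice] == reasons1
    rev = apply_filters(list(reversed(rows)), FilterConfig())
    assert [r.rejection_reasons for r in rev] == list(reversed(reasons1))


@pytest.mark.parametrize("tighten", [
    {"min_length": 8}, {"max_length": 10},
    {"excluded_residues": frozenset("MCA")}, {"max_missed_cleavages": 0},
    {"max_bg_occurrences": 0},
])
def test_tightening_any_bound_never_adds_passing_rows(fg_index, bg_index,
                                                      proteome_pair,
                                                      tighten):
    fg, _, _ = proteome_pair
    accs = [r.accession for r in fg]
    base = FilterConfig(min_length=5, max_length=30,
                        excluded_residues=frozenset("M"),
                        max_missed_cleavages=1, max_bg_occurrences=2,
                        exclude_flags=frozenset())
    tight = replace(base, **tighten)
    loose_set = {(r.peptide_sequence, r.start) for r in
                 select_surrogates(fg_index, bg_index, accs, base)}
    tight_set = {(r.peptide_sequence, r.start) for r in
                 select_surrogates(fg_index, bg_index, accs, tight)}
    assert tight_set <= loose_set


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(min_length=0)
    with pytest.raises(ValueError):
        FilterConfig(min_length=10, max_length=5)
    with pytest.raises(ValueError):
        FilterConfig(max_bg_occurrences=-1)
    with pytest.raises(ValueError):
        FilterConfig(exclude_flags=frozenset({"bogus"}))


# -- CSV export ------------------------------------------------------------

def test_export_csv_empty_is_header_only():
    buf = io.StringIO()
    export_csv([], buf)
    lines = buf.getvalue().splitlines()
    assert len(lines) == 1
    assert lines[0].startswith("protein_accession,")


def test_export_csv_n_rows_n_plus_one_lines():
    rows = [mkrow(f"AAAE{i}K".replace(str(i), "G" * i)) for i in range(4)]
    buf = io.StringIO()
    export_csv(rows, buf)
    assert len(buf.getvalue().splitlines()) == 5


def test_export_csv_quoting_and_round_trip(tmp_path):
    row = mkrow("AAADEFK", bg=2)
    row.protein_name = "Keratin, type I"
    apply_filters([row], FilterConfig())
    path = tmp_path / "out.csv"
    export_csv([row], path)
    text = path.read_text()
    assert '"Keratin, type I"' in text
    back = read_csv(path)
    assert back == [row]


def test_export_csv_single_proteome_omits_bg_column(tmp_path):
    path = tmp_path / "out.csv"
    export_csv([mkrow()], path)
    header = path.read_text().splitlines()[0]
    assert "bg_total_occurrences" not in header
    (row,) = read_csv(path)
    assert row.bg_total_occurrences is None


def test_export_csv_round_trips_selection_output(tmp_path, fg_index,
                                                 bg_index, proteome_pair):
    fg, _, _ = proteome_pair
    rows = select_surrogates(fg_index, bg_index,
                             [fg[0].accession], FilterConfig(),
                             keep_rejected=True)
    path = tmp_path / "sel.csv"
    export_csv(list(rows), path)
    assert read_csv(path) == list(rows)


def test_read_batch_file_skips_comments(tmp_path):
    p = tmp_path / "batch.txt"
    p.write_text("# header\nACC1\nACC2  # trailing\n\nACC3\n")
    assert read_batch_file(str(p)) == ["ACC1", "ACC2", "ACC3"]
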