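# pepselect

Peptide-database building and surrogate-peptide selection for targeted
proteomics of mixed-species samples.

In bottom-up proteomics a protein is monitored through a few *surrogate
peptides*. For a peptide to stand in for its protein unambiguously it must
be **proteotypic**: a unique representative of that protein within the
proteome of interest. In xenograft samples — human tumor tissue grown in a
mouse or rat host — every sample mixes two proteomes, so a usable surrogate
must additionally be **absent from the host (background) proteome**:

```
pass(p)  ⇔  hits_fg(p) = 1  ∧  hits_bg(p) = 0  ∧  assay filters
```

where `hits_X(p)` is the number of occurrences (protein × position) of the
tryptic peptide `p` in the in-silico digest of proteome `X`, and the
advised assay filters are: length 5–22 aa, no Cys/Met (chemically labile),
0 missed cleavages, no annotated PTM / SNP variant / sequence-conflict /
signal-peptide positions, optionally a precursor m/z window (e.g. 400–1600
Th at charges 2+/3+ for a triple quadrupole).

`pepselect` builds the peptide databases behind this query:

* **ingest** — parse whole proteomes from UniProt flat text (`.dat`/`.txt`),
  RefSeq GenPept (`.gpff`) or FASTA, including the per-protein feature
  table (PTM sites, variants/SNPs, conflicts, signal peptides,
  isoform-variable regions).
* **digestion** — in-silico digestion with trypsin, Lys-C, Arg-C or Lys-N,
  0–2 missed cleavages, optional proline rule, peptide monoisotopic mass
  and m/z.
* **index_store** — a single-file SQLite peptide index: peptide →
  occurrences with coordinates, missed-cleavage counts and the protein
  annotations remapped to the peptide level as flags.
* **selection** — queries by accession, protein name or peptide sequence
  (single or batch), dual-proteome surrogate selection, the advised
  filters with per-row rejection reasons, CSV export.
* **fixtures** — synthetic two-species proteome pairs with planted
  unique/shared peptides and machine-readable ground truth, so the whole
  pipeline is testable without downloading a proteome.

## Worked example

Generate a synthetic tumor/host proteome pair, index both with identical
digestion settings, and select surrogate candidates for one protein:

```sh
pepselect fixtures --seed 7 --fg-proteins 5 --bg-proteins 5 \
    --mean-length 120 --planted-unique 10 --out-dir demo
pepselect build --in demo/fg.dat --format uniprot --enzyme trypsin \
    --missed 2 --min-len 3 --label tumor --out demo/fg.idx
pepselect build --in demo/bg.dat --format uniprot --enzyme trypsin \
    --missed 2 --min-len 3 --label host --out demo/bg.idx
pepselect select --fg demo/fg.idx --bg demo/bg.idx \
    --accession SYNF0004 --defaults --keep-rejected
```

Selected columns of the CSV this prints:

```
peptide_sequence,length,fg_total_occurrences,bg_total_occurrences,passed_filters,rejection_reasons
AEYFR,5,2,0,false,not unique in foreground
ICPFR,5,1,0,false,excluded residue C; sequence conflict
LHQVQQDIEIWK,12,1,1,false,present in background
DTTDK,5,1,0,true,
```

Reading the rows: `AEYFR` occurs twice in the tumor proteome, so it cannot
identify one protein; `ICPFR` is unique and host-absent but contains a
cysteine and overlaps an annotated sequence conflict; `LHQVQQDIEIWK` is
unique in the tumor proteome but also occurs once in the host digest —
exactly the peptide class a single-proteome workflow would wrongly accept.
`DTTDK` passes every filter (1 foreground hit, 0 background hits) and is
the surrogate candidate. `pepselect info demo/fg.idx` prints the stored
digestion parameters; `select` refuses to compare indexes built with
different enzyme, missed-cleavage or I/L-collapse settings.

The same pipeline is available as a library (`pepselect.build_index`,
`pepselect.select_surrogates`, ...), which is what the CLI calls.

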