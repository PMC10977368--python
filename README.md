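# skipdesign

Design and in-silico validation of splice-switching antisense
oligonucleotides (AONs) that knock a gene down by **exon skipping**.

When an AON base-pairs over the splicing signals of an internal exon, the
spliceosome drops that exon from the mature mRNA. If the exon length is not a
multiple of 3 (an *out-of-frame* exon), the downstream reading frame shifts,
a premature termination codon (PTC) appears, and the transcript is typically
degraded by nonsense-mediated decay (NMD) — a clean knockdown strategy for
secreted regulators such as the insulin-like growth factor binding proteins
IGFBP1/IGFBP3. `skipdesign` implements the complete desk workflow around that
idea, for researchers who design such AONs and want every selection step
explicit, scriptable and testable:

- **gene_model** — GFF3/GTF + FASTA parsing, spliced mRNA assembly, exon
  reading-frame classification (`length mod 3`), exon-skip simulation with
  PTC detection and the 50-nt NMD junction rule, target-region extraction
  (exon + 50 nt intronic flanks).
- **folding** — per-base accessibility ("ss-count") profiles from an ensemble
  of nested secondary structures (stacking-weighted dynamic program with G:U
  pairing; suboptimal structures by pair-exclusion refolds).
- **splice_signals** — exonic splicing enhancer/silencer (ESE/ESS) scanning
  with log-odds PWMs and hexamer sets (a synthetic, user-replaceable library
  ships with the package).
- **hybridization** — nearest-neighbor thermodynamics (Xia 1998 RNA:RNA
  table): GC%, Tm, AON:target binding ΔG, self- and cross-dimer screens.
- **aon_design** — sliding-window enumeration (18–30 nt), hard pass/fail
  filters, and a weighted composite ranking of openness, ESE density and
  thermodynamics.
- **insilico_assay** — nested RT-PCR product prediction (wild-type vs skipped
  band sizes), a textual virtual gel, and reference-gene-normalized qPCR
  ratios.
- **expression_counts** — average-CPM gene filtering for count matrices.
- **synthetic_data** — seeded fixture generators: toy genes with planted
  open/ESE-rich windows, paper-like Igfbp1/Igfbp3 fixtures, and
  negative-binomial count matrices.

## Worked example

Generate a synthetic gene that mirrors the Igfbp1 design context — a 185-nt
out-of-frame exon 2 with the published nested-PCR primer landing sites — and
run the pipeline on it:

```bash
skipdesign make-fixture --kind igfbp1-like --seed 7 --out fx
skipdesign skip-simulate --gff fx/igfbp1_like.gff3 --fasta fx/chr_igfbp1_like.fa --exon 2
```

```
transcript_id  skipped_exon_index  mrna_length  frameshift  product_frame_mod  ptc_mrna_offset  nmd_predicted  used_longest_orf_fallback
igfbp1_like    2                   360          True        2                  161              True           False
```

Skipping the 185-nt exon (185 mod 3 = 2) shifts the frame; translation from
the annotated start codon hits a stop 11 nt past the new exon 1/exon 3
junction, ≥ 50 nt upstream of the last junction, so NMD is predicted — the
knockdown mechanism in one row. The same library call predicts the gel:
in-silico nested RT-PCR on the wild-type and skipped transcripts returns
inner products of **425 bp** and **240 bp** (and 422/195 bp for the
igfbp3-like fixture), the band sizes that distinguish full-length from
skipped mRNA.

Thermodynamic screening of the 20-mer AON `CUUCCAUUUCUUGAGGUCGG` against a
co-administered partner:

```bash
skipdesign oligo-thermo --seq CUUCCAUUUCUUGAGGUCGG --vs AACUUGGAAUCGGUCACUCG
```

```
gc      0.500
tm_c    66.58
self_dimer_dg   -2.42
cross_dimer_dg  -3.63
```

GC is exactly 50%, the predicted duplex Tm is ~67 °C, and both dimer screens
are weak (|ΔG| < 10 kcal/mol) — the oligo passes the default hard filters.
Running the full designer on the fixture
(`skipdesign design --gff fx/igfbp1_like.gff3 --fasta fx/chr_igfbp1_like.fa
--exon 2`) ranks that exact antisense window among the top candidates, with
per-candidate openness, ESE density, ΔG, Tm and pass/fail flags in the
report.

## Notes

- The shipped ESE/ESS motif library is a synthetic consensus-derived
  stand-in (see `skipdesign/data/`); swap in your own matrices via the
  documented plain-text format for production scans.
- The folder is a stacking-weighted nested-structure model, not a full
  thermodynamic ensemble; an external folding engine can be plugged in
  behind the same `fold_mfe` / `ss_count_profile` contract.
- Off-target transcriptome-wide searches and chemistry-specific backbone
  corrections are out of scope (see `docs/methods.md`).
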