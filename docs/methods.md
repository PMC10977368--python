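# Methods

This note records the models, defaults and design choices behind
`skipdesign`, in the order the pipeline runs.

## Gene models and exon-skip simulation

Coordinates are 0-based half-open internally; GFF3/GTF input (1-based
inclusive, `Parent=` and `transcript_id` dialects via gffutils) is converted
on parse. Exons are stored in transcription order, so minus-strand splicing
arithmetic is identical to plus-strand arithmetic after the coordinate flip;
a round-trip property test holds the two representations to byte-identical
target regions.

Only internal exons are skippable: terminal exons lack the two flanking
splice sites an AON-induced skip requires. An exon is *out-of-frame* iff its
length is not a multiple of 3. `simulate_exon_skip` removes the exon from
the spliced mRNA, restarts translation at the annotated start codon (or the
longest ATG-initiated ORF when no CDS is annotated — flagged in the report),
and reports the first in-frame stop whose codon reaches past the new
junction. Codons containing N translate as unknown and never count as stops.

NMD is called by the standard 50-nt rule: a PTC at least 50 nt upstream of
the final exon–exon junction of the *skipped* transcript. The rule is
reported, not enforced — it is a well-characterized heuristic, and the
knockdown claim rests on the frameshift itself. Note a consequence used
throughout the fixtures: in a 3-exon gene the skip of exon 2 leaves a single
junction and the PTC always lies downstream of it, so NMD is never predicted;
the default fixtures therefore carry 4 exons, as the real Igfbp1/Igfbp3
genes do.

Target regions are the exon plus up to 50 nt of each *intronic* flank
(pre-mRNA, sense strand). A shorter neighbouring intron, or a terminal exon
side, truncates the flank and the truncation is recorded.

## Secondary structure and the ss-count profile

AON accessibility is summarized as per-base openness: the fraction of an
ensemble of predicted structures in which a base is unpaired. The folder is
a deliberately transparent stand-in for a thermodynamic engine: a
Nussinov-style dynamic program over nested structures with Watson–Crick and
G:U pairs, minimum hairpin loop 3, scoring

    sum of pair weights (GC = 3, AU = 2, GU = 1) + 1 per stacked pair.

The stacking bonus pushes optima toward helices rather than isolated pairs,
qualitatively matching energy-model folds while keeping the optimum
verifiable: the DP is tested against exhaustive enumeration of every nested
structure for n ≤ 12 (1000 random cases).

Suboptimal structures come from pair-exclusion refolds: forbid one base pair
of the optimal structure and refold, keeping distinct structures scoring at
least 95% of the optimum, to a default ensemble of k = 10 (refolds capped at
3k). With k = 1 the profile degenerates to the MFE unpaired indicator. The
procedure is fully deterministic. T is silently transcribed to U on input.
Pseudoknots and a full nearest-neighbor loop model are out of scope; the
`fold_mfe`/`ss_count_profile` contract is the plug-in point for an external
engine.

## ESE/ESS scanning

Exon recognition is promoted by exonic splicing enhancers, so candidate AON
windows are ranked partly by enhancer density. Scanning supports log-odds
PWMs (every window scoring ≥ the matrix threshold is reported) and exact
hexamer sets, on the sense strand only. Density counts hits whose *start*
falls in a window, divided by window length — simple and shift-equivariant;
note that overlapping occurrences (e.g. a GA-rich tandem repeat) each count,
which is how a 20-nt window can contain 5 hexamer starts.

The shipped library is **synthetic**: consensus-derived SR-protein-like
matrices and GA-rich enhancer / UAG-class silencer hexamer sets, modelled on
the published motif-class vocabularies but not reproducing any published
matrix. It exists so the pipeline and its tests run self-contained; the
plain-text format (`>name kind threshold` + 4 base rows; one 6-mer per line)
is the supported path for real libraries.

## Hybridization thermodynamics

Duplex stability uses the Watson–Crick RNA:RNA nearest-neighbor parameters
of Xia et al. (1998), shipped as a tab-delimited table with a provenance
line and swappable by file. 2'-O-methyl phosphorothioate AONs hybridizing to
pre-mRNA are approximated as RNA:RNA; no backbone-specific corrections are
applied. Defaults: strand concentration 1 µM, [Na+] 100 mM (a 16.6·log10
salt adjustment from the 1 M reference), ΔG at 37 °C. Tm uses the two-state
formula with x = 4 for heteroduplexes, x = 1 plus the symmetry entropy
correction for self-complementary sequences, and per-terminal A:U penalties.

Dimer and binding searches are ungapped: the best antiparallel alignment
over all offsets, summing stacks over consecutive complementary positions
plus initiation and terminal terms. ΔG is clamped to 0 when no alignment is
stabilizing (a single isolated pair never is). Ungapped search keeps the
screen exact and oracle-checkable (term-by-term summation reproduces the DP
on short oligos; the perfect complement is verified to minimize ΔG over all
competitors exhaustively at short lengths).

## Candidate ranking

All windows of 18–30 nt (the standard splice-switching AON span; other
lengths require an explicit override) are enumerated over the target region.
Hard filters with defaults: GC in [0.30, 0.70], Tm in [40, 95] °C,
self-/cross-dimer ΔG ≥ −10 kcal/mol, mean openness ≥ 0.5 ("partly open"),
ESE density ≥ 0. Failing candidates stay in the report with per-criterion
flags; survivors get a composite score: weighted sum of min-max-normalized
metrics — openness 0.3, net enhancer density (ESE − ESS) 0.3, and 0.4 of
thermodynamics split evenly (binding ΔG rewarded when strong; self/cross
dimer stability, GC deviation and Tm deviation from the band midpoints
penalized; 0.08 each). When a metric is constant across candidates its
normalized value is 0.5. Ties break to the 5'-most window; ranking is
deterministic and input-order invariant. The weights operationalize a
qualitative "partly open and ESE-rich" selection and are explicit
configuration, not claimed constants. Cross-dimer screening runs against a
user-supplied list of co-administered AONs; candidates report their
exon/flank overlap since a window may legitimately span a splice site.

## In-silico RT-PCR and qPCR

Primer matching is exact by default (an optional mismatch budget never
relaxes the 3'-terminal base): published primers are exact designs, and
exactness keeps products deterministic. Forward sites are occurrences of the
forward primer, reverse sites occurrences of the reverse primer's reverse
complement; all orientation-correct combinations with non-overlapping
footprints are reported, with a multiplicity warning when a primer lands
more than once. Nested semantics search the inner pair within each outer
product. Product length includes both primer footprints, so predicted sizes
compare directly to gel bands: wild-type minus skipped equals the skipped
exon length whenever both primers anneal outside it.

qPCR relative expression is E_t^(−Cq_t) divided by the geometric mean of
E_r^(−Cq_r) over reference genes, optionally normalized to a calibrator
sample; efficiencies are inputs in (1, 2] (estimating them from fluorescence
curves is out of scope). With equal efficiencies the ratio is invariant to a
constant Cq shift.

## CPM filtering

CPM = count / library size × 10⁶. A gene is retained when its mean CPM
across all samples is strictly above the threshold (default 5); a per-group
mean option exists because the averaging convention is a genuine free
choice. log2CPM uses a 0.5 pseudo-count. Differential-expression model
fitting, PCA and enrichment are deliberately not implemented.

## Synthetic fixtures

`make_toy_gene` assembles a plus-strand gene (default four exons, 80-nt
introns) on an A-rich background (A 0.68 / C 0.15 / T 0.12 / G 0.05) that is
open by construction; the only strongly paired element in the target exon is
a planted GC hairpin, and the only enhancer signal is a planted tandem-repeat
hexamer window (5 overlapping GAAGAA starts in 20 nt by default). The
generator scrubs accidental copies of the planted hexamer outside the
window, plants a start codon and a stop cassette (`TTAATTAATTAA`, stops in
all three frames) in the exon after the target, and repairs the background
so the wild-type ORF is clean — choosing the reading frame so that no
planted primer/AON sequence contains an in-frame stop. Everything is
verified by independent string searches (site uniqueness, amplicon lengths,
hexamer counts, translation scan); a background draw that collides with a
primer site is redrawn from a deterministically derived seed. Fixed seed ⇒
byte-identical GFF3/FASTA output.

The paper-like fixtures place the published Igfbp1/Igfbp3 primer pairs so the
inner wild-type/skipped products are exactly 425/240 bp (185-nt exon 2) and
422/195 bp (227-nt exon 2), and plant the reverse complement of each published
AON inside exon 2. They emulate the published design *context* — band
geometry, frame consequences, primer/AON sequences — not the real genomic
sequence, so tests passing on them demonstrate pipeline correctness, not
recovery of the Ensembl transcripts.

Count matrices are negative-binomial (dispersion 0.05, two groups of 3),
with log-uniform base means spanning 0.01–500 so a realistic fraction of
genes falls below the average-CPM filter, and a configurable fraction of
genes carrying a ±1 log2 fold-change.

## Problem sizes and numerical notes

The ss-count DP is O(n³) per fold with an O(n) vectorized inner maximum;
design studies use single-length (20-nt) enumeration over ~160-nt regions
and k = 10 ensembles, which keeps a 20-fixture recovery study under a
minute. Metric normalization is min-max per cohort; ΔG ties in duplex search
break toward more pairs, then the 5'-most span. Degenerate inputs (empty
sequences, zero-length windows, zero library sizes, empty motif libraries,
all-failing candidate sets) raise typed errors or return explicitly empty
reports with failure tallies.

## Known limitations

- The folder ranks accessibility; it does not predict free energies, and its
  suboptimal ensemble is a structural perturbation, not a Boltzmann sample.
- The synthetic motif library is a stand-in; motif-level conclusions about
  real exons require a real library.
- No off-target search, no NMD-efficiency model, no band-intensity
  (percent-skipping) prediction — gel densitometry is a wet-lab measurement.
- Thermodynamics ignore phosphorothioate/2'-O-methyl corrections and
  hairpin-vs-duplex competition within the AON.
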