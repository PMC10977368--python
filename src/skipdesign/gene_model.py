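"""Gene models, reading-frame logic and exon-skipping simulation.

This module holds the substrate of the whole design pipeline: transcripts
parsed from GFF3/GTF annotation plus genomic FASTA, the spliced mRNA they
produce, and the consequence of removing one internal exon from that mRNA.

Knockdown by exon skipping rests on a single arithmetic fact: removing an
exon whose length is not a multiple of three shifts the downstream reading
frame, which almost always creates a premature termination codon (PTC) and
marks the transcript for nonsense-mediated decay (NMD).  ``simulate_exon_skip``
makes that consequence explicit and auditable.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open.  GFF3/GTF input (1-based
inclusive) is converted on parse.  Exons are stored in *transcription* order,
so on the minus strand exon 1 is the genomically last exon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Premature stops at least this far upstream of the last exon-exon junction
#: are predicted to trigger nonsense-mediated decay (the classic 50-nt rule).
NMD_JUNCTION_RULE_NT = 50


class AnnotationError(ValueError):
    """Raised when annotation text cannot be resolved into transcripts."""


class SequenceError(ValueError):
    """Raised when coordinates fall outside the supplied sequences."""


def reverse_complement(seq: str) -> str:
    """DNA reverse complement (N-safe, case-preserved as uppercase)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """A set of named nucleotide sequences (chromosomes or contigs)."""

    records: Mapping[str, str]

    def __post_init__(self):
        seen = set()
        for name, seq in self.records.items():
            if name in seen:
                raise SequenceError(f"duplicate sequence id {name!r}")
            seen.add(name)
            bad = set(seq.upper()) - _VALID_BASES
            if bad:
                raise SequenceError(
                    f"sequence {name!r} contains invalid characters {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, source) -> "GenomeSequence":
        """Load from a FASTA path, open handle, or raw FASTA text."""
        from io import StringIO

        from Bio import SeqIO

        if isinstance(source, str) and source.lstrip().startswith(">"):
            handle = StringIO(source)
        else:
            handle = source
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
        if not records:
            raise SequenceError("no FASTA records found")
        return cls(records)

    def fetch(self, seq_id: str, start: int, end: int) -> str:
        if seq_id not in self.records:
            raise SequenceError(f"unknown sequence id {seq_id!r}")
        seq = self.records[seq_id]
        if start < 0 or end > len(seq) or start >= end:
            raise SequenceError(
                f"span [{start}, {end}) outside sequence {seq_id!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end].upper()

    def __getitem__(self, seq_id: str) -> str:
        if seq_id not in self.records:
            raise SequenceError(f"unknown sequence id {seq_id!r}")
        return self.records[seq_id]


@dataclass(frozen=True)
class Exon:
    """One exon, 0-based half-open genomic span, 1-based transcript ordinal."""

    seq_id: str
    start: int
    end: int
    index: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"exon {self.index}: start {self.start} must be < end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Transcript:
    """An ordered exon chain with CDS offsets on the spliced mRNA.

    ``cds_start``/``cds_end`` are 0-based half-open offsets into the spliced
    sequence; ``cds_end`` includes the stop codon when the annotation does.
    Either may be ``None`` for non-coding or unannotated transcripts.
    """

    id: str
    strand: str
    exons: tuple[Exon, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id!r} has no exons")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"transcript {self.id!r}: exons [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) overlap"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.cds_start is not None:
            if not 0 <= self.cds_start < self.cds_end <= self.spliced_length:
                raise ValueError(
                    f"CDS [{self.cds_start},{self.cds_end}) outside spliced "
                    f"mRNA of length {self.spliced_length}"
                )

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self.exons)

    def exon_spliced_span(self, exon_index: int) -> tuple[int, int]:
        """Half-open span of a (1-based) exon on the spliced mRNA."""
        self._check_index(exon_index)
        off = sum(len(e) for e in self.exons[: exon_index - 1])
        return off, off + len(self.exons[exon_index - 1])

    def junction_offsets(self) -> tuple[int, ...]:
        """Spliced-mRNA offsets of each exon-exon junction."""
        offs, acc = [], 0
        for e in self.exons[:-1]:
            acc += len(e)
            offs.append(acc)
        return tuple(offs)

    def _check_index(self, exon_index: int) -> None:
        if not 1 <= exon_index <= len(self.exons):
            raise ValueError(
                f"exon index {exon_index} out of range 1..{len(self.exons)} "
                f"for transcript {self.id!r}"
            )


@dataclass(frozen=True)
class TargetRegion:
    """The pre-mRNA window an AON is designed against: one exon plus flanks.

    ``sequence`` is the sense strand of the transcript (DNA alphabet).
    ``flank`` is the *requested* flank; the achieved per-side flanks are in
    ``flank_lengths`` and may be shorter where the neighbouring intron (or the
    transcript end) is shorter — recorded in ``truncated``.
    """

    sequence: str
    flank: int
    exon_span: tuple[int, int]
    flank_lengths: tuple[int, int]
    truncated: tuple[bool, bool]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def exon_sequence(self) -> str:
        return self.sequence[self.exon_span[0] : self.exon_span[1]]


@dataclass(frozen=True)
class SkipReport:
    """Consequence of removing one internal exon from a transcript."""

    transcript_id: str
    skipped_exon_index: int
    mrna: str
    frameshift: bool
    product_frame_mod: int
    ptc_mrna_offset: int | None
    nmd_predicted: bool
    used_longest_orf_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "skipped_exon_index": self.skipped_exon_index,
            "mrna_length": len(self.mrna),
            "frameshift": self.frameshift,
            "product_frame_mod": self.product_frame_mod,
            "ptc_mrna_offset": self.ptc_mrna_offset,
            "nmd_predicted": self.nmd_predicted,
            "used_longest_orf_fallback": self.used_longest_orf_fallback,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        keys = list(d)
        return (
            "\t".join(keys)
            + "\n"
            + "\t".join("" if d[k] is None else str(d[k]) for k in keys)
            + "\n"
        )


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def parse_annotation(annotation_text: str, genome: GenomeSequence) -> list[Transcript]:
    """Parse GFF3 or GTF text into :class:`Transcript` objects.

    Both attribute dialects are accepted (GFF3 ``Parent=`` and GTF
    ``transcript_id ""``).  Exon lines whose parent transcript cannot be
    resolved raise :class:`AnnotationError` naming the orphan line, as does a
    reference to a sequence id absent from ``genome``.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            annotation_text,
            dbfn=":memory:",
            from_string=True,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises several exception types
        raise AnnotationError(f"could not parse annotation: {exc}") from exc

    transcript_ids = {
        f.id for f in db.features_of_type(("mRNA", "transcript"))
    }
    if not transcript_ids:
        raise AnnotationError("annotation contains no mRNA/transcript features")

    # Orphan detection: every exon must resolve to a known transcript parent.
    for ex in db.features_of_type(("exon", "CDS")):
        parents = ex.attributes.get("Parent") or ex.attributes.get("transcript_id")
        if not parents or not set(parents) & transcript_ids:
            raise AnnotationError(
                f"{ex.featuretype} line without a resolvable transcript parent: "
                f"{str(ex)!r}"
            )

    transcripts = []
    for tf in db.features_of_type(("mRNA", "transcript")):
        if tf.seqid not in genome.records:
            raise AnnotationError(
                f"transcript {tf.id!r} references unknown sequence id {tf.seqid!r}"
            )
        strand = tf.strand if tf.strand in ("+", "-") else "+"
        exon_feats = sorted(
            db.children(tf, featuretype="exon"),
            key=lambda f: f.start,
            reverse=(strand == "-"),
        )
        if not exon_feats:
            raise AnnotationError(f"transcript {tf.id!r} has no exon children")
        exons = tuple(
            # GFF/GTF are 1-based inclusive; internal is 0-based half-open.
            Exon(seq_id=f.seqid, start=f.start - 1, end=f.end, index=i + 1)
            for i, f in enumerate(exon_feats)
        )
        cds_feats = list(db.children(tf, featuretype="CDS"))
        cds_start = cds_end = None
        if cds_feats:
            t_tmp = Transcript(id=tf.id, strand=strand, exons=exons)
            spans = sorted((f.start - 1, f.end) for f in cds_feats)
            g_first = spans[0][0] if strand == "+" else spans[-1][1] - 1
            g_last = spans[-1][1] - 1 if strand == "+" else spans[0][0]
            cds_start = _genomic_to_spliced(t_tmp, g_first)
            cds_end = _genomic_to_spliced(t_tmp, g_last) + 1
        transcripts.append(
            Transcript(
                id=tf.id, strand=strand, exons=exons,
                cds_start=cds_start, cds_end=cds_end,
            )
        )
    logger.info("parsed %d transcript(s)", len(transcripts))
    return transcripts


def _genomic_to_spliced(t: Transcript, gpos: int) -> int:
    """Map a genomic position (0-based) onto the spliced mRNA."""
    acc = 0
    for e in t.exons:
        if e.start <= gpos < e.end:
            within = gpos - e.start if t.strand == "+" else e.end - 1 - gpos
            return acc + within
        acc += len(e)
    raise SequenceError(
        f"genomic position {gpos} not exonic in transcript {t.id!r}"
    )


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------

def spliced_sequence(t: Transcript, genome: GenomeSequence) -> str:
    """Concatenate exon sequences in transcription order (sense strand)."""
    parts = []
    for e in t.exons:
        piece = genome.fetch(e.seq_id, e.start, e.end)
        parts.append(piece if t.strand == "+" else reverse_complement(piece))
    return "".join(parts)


def classify_exon_frame(exon_length: int) -> str:
    """``"out_of_frame"`` iff the length is not a multiple of 3."""
    if exon_length <= 0:
        raise ValueError(f"exon length must be positive, got {exon_length}")
    return "in_frame" if exon_length % 3 == 0 else "out_of_frame"


def _translate_first_stop(mrna: str, start: int, min_offset: int = 0) -> int | None:
    """Offset of the first in-frame stop codon at or past ``min_offset``.

    Codons containing N never count as stops.
    """
    for pos in range(start, len(mrna) - 2, 3):
        codon = mrna[pos : pos + 3].upper()
        if codon in _STOP_CODONS and pos >= min_offset:
            return pos
    return None


def _longest_orf_start(mrna: str) -> int | None:
    """Start offset of the longest ATG-initiated open reading frame."""
    best = None
    best_len = -1
    for i in range(len(mrna) - 2):
        if mrna[i : i + 3].upper() != "ATG":
            continue
        stop = _translate_first_stop(mrna, i)
        length = (stop - i) if stop is not None else (len(mrna) - i)
        if length > best_len:
            best, best_len = i, length
    return best


def simulate_exon_skip(
    t: Transcript, exon_index: int, genome: GenomeSequence
) -> SkipReport:
    """Remove one internal exon and report the reading-frame consequences.

    Translation starts at the annotated start codon of the wild-type CDS
    (longest-ORF fallback when no CDS is annotated, flagged in the report) and
    scans for the first in-frame stop at or past the new skip junction.  NMD is
    called by the 50-nt junction rule; it is a reported heuristic, not a
    mechanism claim.
    """
    t._check_index(exon_index)
    if exon_index in (1, len(t.exons)):
        raise ValueError(
            f"cannot skip terminal exon {exon_index} of transcript {t.id!r}: "
            "terminal exons lack two flanking splice sites"
        )
    wt = spliced_sequence(t, genome)
    ex_start, ex_end = t.exon_spliced_span(exon_index)
    ex_len = ex_end - ex_start
    mrna = wt[:ex_start] + wt[ex_end:]
    frameshift = classify_exon_frame(ex_len) == "out_of_frame"

    used_fallback = False
    if t.cds_start is not None:
        cds_start = t.cds_start
        if ex_start <= cds_start < ex_end:
            # start codon removed with the exon: no translation possible
            return SkipReport(
                transcript_id=t.id,
                skipped_exon_index=exon_index,
                mrna=mrna,
                frameshift=frameshift,
                product_frame_mod=ex_len % 3,
                ptc_mrna_offset=None,
                nmd_predicted=False,
            )
        start = cds_start if cds_start < ex_start else cds_start - ex_len
    else:
        start = _longest_orf_start(mrna)
        used_fallback = True

    ptc = None
    if start is not None:
        # first in-frame stop whose codon reaches past the skip junction
        ptc = _translate_first_stop(mrna, start, min_offset=max(start, ex_start - 2))

    junctions = _skipped_junctions(t, exon_index)
    nmd = (
        ptc is not None
        and bool(junctions)
        and (junctions[-1] - ptc) >= NMD_JUNCTION_RULE_NT
    )
    return SkipReport(
        transcript_id=t.id,
        skipped_exon_index=exon_index,
        mrna=mrna,
        frameshift=frameshift,
        product_frame_mod=ex_len % 3,
        ptc_mrna_offset=ptc,
        nmd_predicted=nmd,
        used_longest_orf_fallback=used_fallback,
    )


def _skipped_junctions(t: Transcript, skipped: int) -> tuple[int, ...]:
    """Exon-exon junction offsets on the skipped mRNA."""
    lengths = [len(e) for i, e in enumerate(t.exons, start=1) if i != skipped]
    offs, acc = [], 0
    for L in lengths[:-1]:
        acc += L
        offs.append(acc)
    return tuple(offs)


def skipped_fasta(t: Transcript, report: SkipReport) -> str:
    """Render the skipped transcript as a FASTA record."""
    header = f">{t.id}|skip_exon_{report.skipped_exon_index}"
    body = "\n".join(
        report.mrna[i : i + 60] for i in range(0, len(report.mrna), 60)
    )
    return f"{header}\n{body}\n"


# ---------------------------------------------------------------------------
# Target region extraction
# ---------------------------------------------------------------------------

def extract_target_region(
    t: Transcript, exon_index: int, genome: GenomeSequence, flank: int = 50
) -> TargetRegion:
    """Exon plus up to ``flank`` nt of each flanking intron, sense strand.

    Flanks are intronic pre-mRNA; a short neighbouring intron, or a terminal
    exon side with no intron at all, truncates the flank (recorded).
    """
    t._check_index(exon_index)
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    exon = t.exons[exon_index - 1]

    genomic_order = sorted(t.exons, key=lambda e: e.start)
    gi = genomic_order.index(exon)
    left_intron = (
        exon.start - genomic_order[gi - 1].end if gi > 0 else 0
    )
    right_intron = (
        genomic_order[gi + 1].start - exon.end if gi < len(genomic_order) - 1 else 0
    )
    left = min(flank, left_intron)
    right = min(flank, right_intron)
    window = genome.fetch(exon.seq_id, exon.start - left, exon.end + right)

    if t.strand == "+":
        up, down = left, right
    else:
        window = reverse_complement(window)
        up, down = right, left
    return TargetRegion(
        sequence=window,
        flank=flank,
        exon_span=(up, up + len(exon)),
        flank_lengths=(up, down),
        truncated=(up < flank, down < flank),
    )


def transcripts_by_longest_cds(transcripts: Iterable[Transcript]) -> list[Transcript]:
    """Sort candidates so the longest annotated CDS comes first (the default
    isoform choice when the user does not name one)."""
    def cds_len(t: Transcript) -> int:
        return (t.cds_end - t.cds_start) if t.cds_start is not None else -1

    return sorted(transcripts, key=cds_len, reverse=True)
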