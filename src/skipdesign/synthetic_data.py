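"""Synthetic gene-model fixtures for plant-and-recover testing.

Every stage of the design pipeline is exercised on generated data: toy
multi-exon genes with a frame-disrupting internal exon, a planted "partly
open and ESE-rich" window, planted hairpin stems (the only structured
regions in an otherwise A-rich, hence open, background), primer landing
sites engineered to yield chosen nested-PCR product sizes, and
negative-binomial count matrices with two groups of replicates.

The paper-like fixtures mirror the published Igfbp1/Igfbp3 design context:
a 185 nt (resp. 227 nt) out-of-frame exon 2 whose nested RT-PCR products are
425/240 bp (resp. 422/195 bp) with the published primer pairs.  The genomic
sequences are synthetic; only the published primer/AON sequences and the band
geometry are real study inputs.

Seeds are mandatory; a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_counts import CountMatrix
from .gene_model import GenomeSequence, Transcript, parse_annotation, reverse_complement

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
#: stop codons in all three frames within 12 nt; terminates the reading frame
#: of both the wild-type and the frameshifted skipped transcript
STOP_CASSETTE = "TTAATTAATTAA"

# --- published study inputs -------------------------------------------------
# Splice-switching AONs (2'-O-methyl phosphorothioate, 5'->3')
IGFBP1_AON = "CUUCCAUUUCUUGAGGUCGG"
IGFBP3_AON = "AACUUGGAAUCGGUCACUCG"
CONTROL_AON = "UUCAAGUUUAUCUUGCUCUUC"

# Nested RT-PCR primer pairs (5'->3'): (forward, reverse)
IGFBP1_INNER_PRIMERS = ("GTCCTTCCAGATTGGCGTGG", "GTTGGGCTGCAGCTAATCTC")
IGFBP1_OUTER_PRIMERS = ("CCTCAAGAAATGGAAGGAGCCC", "TCATCTCCTGCTTTCTGTTGGG")
IGFBP3_INNER_PRIMERS = ("GGAGCAGTACCCGCTGAG", "CACAGTTTGGGATGTGGACG")
IGFBP3_OUTER_PRIMERS = ("GACAGAATACGGTCCCTGCC", "CCCTTCTTGTCACAGTTTGGG")

# Gel band sizes (bp) the fixtures are built to reproduce
IGFBP1_PRODUCTS = {"wt_inner": 425, "skip_inner": 240}
IGFBP3_PRODUCTS = {"wt_inner": 422, "skip_inner": 195}

# A-rich background: open (unpairable runs) and ESE-poor by construction
_BACKGROUND_P = {"A": 0.68, "C": 0.15, "T": 0.12, "G": 0.05}


class FixtureError(ValueError):
    pass


class _RetryableFixtureError(FixtureError):
    """Bad luck with the random background (e.g. a duplicated primer site);
    redrawing from a derived seed fixes it deterministically."""


@dataclass
class PrimerPlan:
    """Where the nested primer pairs land and what they must amplify."""

    inner: tuple[str, str]
    outer: tuple[str, str]
    inner_fwd_spliced_start: int
    inner_wt_product: int
    outer_fwd_spliced_start: int
    outer_wt_product: int
    expect_skip_products: bool = True


@dataclass
class FixtureSpec:
    """Everything the generator plants, plus the mandatory seed."""

    seed: int
    exon_lengths: tuple[int, ...] = (90, 59, 120, 60)
    target_exon: int = 2
    intron_length: int = 80
    leader: int = 30
    trailer: int = 30
    seq_id: str = "chrT"
    transcript_id: str = "toy_tx"
    atg_exon1_offset: int = 10
    ese_hexamer: str | None = "GAAGAA"
    ese_window_exon_offset: int = 22
    ese_window_len: int = 20
    stem_exon_offset: int | None = 0
    stem_arm: str = "GCGGCG"
    stem_loop_len: int = 4
    primers: PrimerPlan | None = None
    aon_antisense: str | None = None  # RNA 5'->3'; target window planted
    aon_exon_offset: int = 50

    def __post_init__(self):
        if self.seed is None:
            raise FixtureError("a seed is mandatory")
        if not 1 < self.target_exon < len(self.exon_lengths):
            raise FixtureError(
                f"target exon {self.target_exon} must be internal in a "
                f"{len(self.exon_lengths)}-exon gene"
            )
        tlen = self.exon_lengths[self.target_exon - 1]
        if self.ese_hexamer is not None:
            if self.ese_window_exon_offset + self.ese_window_len > tlen:
                raise FixtureError("ESE window does not fit in the target exon")
        if self.primers is not None and self.primers.expect_skip_products:
            # primer sites inside the skipped exon contradict skip products
            spans = self._primer_spliced_spans()
            t_lo = sum(self.exon_lengths[: self.target_exon - 1])
            t_hi = t_lo + tlen
            for label, (s, e) in spans.items():
                if s < t_hi and e > t_lo:
                    raise FixtureError(
                        f"contradictory spec: primer site {label!r} "
                        f"[{s},{e}) lies in the target exon [{t_lo},{t_hi}) "
                        "but a skipped product is expected"
                    )

    def _primer_spliced_spans(self) -> dict[str, tuple[int, int]]:
        p = self.primers
        if p is None:
            return {}
        spans = {
            "inner_fwd": (
                p.inner_fwd_spliced_start,
                p.inner_fwd_spliced_start + len(p.inner[0]),
            ),
            "outer_fwd": (
                p.outer_fwd_spliced_start,
                p.outer_fwd_spliced_start + len(p.outer[0]),
            ),
        }
        inner_end = p.inner_fwd_spliced_start + p.inner_wt_product
        outer_end = p.outer_fwd_spliced_start + p.outer_wt_product
        spans["inner_rev"] = (inner_end - len(p.inner[1]), inner_end)
        spans["outer_rev"] = (outer_end - len(p.outer[1]), outer_end)
        return spans


@dataclass
class ToyGeneTruth:
    """Ground truth for every planted feature, for plant-and-recover tests."""

    seq_id: str
    transcript_id: str
    exon_genomic_spans: list[tuple[int, int]]
    target_exon: int
    target_exon_length: int
    cds_spliced: tuple[int, int]
    ese: dict | None
    stem: dict | None
    primer_sites: dict
    product_sizes: dict
    aon: dict | None
    expected_skip: dict

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ToyGene:
    gff3: str
    fasta: str
    truth: ToyGeneTruth
    spec: FixtureSpec

    def genome(self) -> GenomeSequence:
        return GenomeSequence.from_fasta(self.fasta)

    def transcript(self) -> Transcript:
        return parse_annotation(self.gff3, self.genome())[0]

    def write(self, outdir) -> dict[str, Path]:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gff3": outdir / f"{self.spec.transcript_id}.gff3",
            "fasta": outdir / f"{self.spec.seq_id}.fa",
            "truth": outdir / f"{self.spec.transcript_id}.truth.json",
        }
        paths["gff3"].write_text(self.gff3)
        paths["fasta"].write_text(self.fasta)
        paths["truth"].write_text(json.dumps(self.truth.to_dict(), indent=2))
        if self.spec.primers is not None:
            p = self.spec.primers
            paths["primers"] = outdir / f"{self.spec.transcript_id}.primers.tsv"
            paths["primers"].write_text(
                f"{p.outer[0]}\t{p.outer[1]}\touter\n"
                f"{p.inner[0]}\t{p.inner[1]}\tinner\n"
            )
        return paths


def _draw_background(rng: np.random.Generator, n: int) -> list[str]:
    bases = np.array(list(_BACKGROUND_P))
    probs = np.array(list(_BACKGROUND_P.values()))
    return list(rng.choice(bases, size=n, p=probs))


def make_toy_gene(spec: FixtureSpec) -> ToyGene:
    """Assemble a toy gene whose planted features match ``spec`` exactly.

    The generator validates its own output with independent string searches
    (primer site uniqueness, hexamer occurrence counts, amplicon lengths,
    reading-frame scan) and raises :class:`FixtureError` on any mismatch.
    A background draw that happens to duplicate a primer landing site is
    redrawn from a seed derived deterministically from ``spec.seed``.
    """
    last: Exception | None = None
    for attempt in range(10):
        try:
            return _make_toy_gene_once(spec, spec.seed + attempt * 1_000_003)
        except _RetryableFixtureError as exc:
            last = exc
    raise FixtureError(f"fixture generation failed after 10 redraws: {last}")


def _make_toy_gene_once(spec: FixtureSpec, seed: int) -> ToyGene:
    rng = np.random.default_rng(seed)

    exon_g: list[tuple[int, int]] = []
    pos = spec.leader
    for L in spec.exon_lengths:
        exon_g.append((pos, pos + L))
        pos += L + spec.intron_length
    glen = pos - spec.intron_length + spec.trailer

    genome = _draw_background(rng, glen)
    planted = [False] * glen

    exon_spliced_start = [
        sum(spec.exon_lengths[:i]) for i in range(len(spec.exon_lengths))
    ]

    def spliced_to_genomic(spos: int) -> int:
        for i, (gs, ge) in enumerate(exon_g):
            off = spos - exon_spliced_start[i]
            if 0 <= off < spec.exon_lengths[i]:
                return gs + off
        raise FixtureError(f"spliced position {spos} not exonic")

    def plant(seq: str, spliced_start: int, label: str) -> None:
        for k, ch in enumerate(seq):
            g = spliced_to_genomic(spliced_start + k)
            if planted[g] and genome[g] != ch:
                raise FixtureError(
                    f"plant {label!r} conflicts with an earlier plant at "
                    f"genomic {g}"
                )
            genome[g] = ch
            planted[g] = True

    t_idx = spec.target_exon - 1
    t_spl = exon_spliced_start[t_idx]
    t_len = spec.exon_lengths[t_idx]

    # primer landing sites
    primer_sites = spec._primer_spliced_spans()
    if spec.primers is not None:
        p = spec.primers
        plant(p.inner[0], primer_sites["inner_fwd"][0], "inner_fwd")
        plant(p.outer[0], primer_sites["outer_fwd"][0], "outer_fwd")
        plant(
            reverse_complement(p.inner[1]), primer_sites["inner_rev"][0], "inner_rev"
        )
        plant(
            reverse_complement(p.outer[1]), primer_sites["outer_rev"][0], "outer_rev"
        )

    # AON target window inside the target exon (sense strand)
    aon_truth = None
    if spec.aon_antisense is not None:
        target_window = reverse_complement(spec.aon_antisense.replace("U", "T"))
        a_start = t_spl + spec.aon_exon_offset
        plant(target_window, a_start, "aon_target")
        aon_truth = {
            "spliced_span": (a_start, a_start + len(target_window)),
            "exon_offset": spec.aon_exon_offset,
            "antisense": spec.aon_antisense,
            "target_window": target_window,
        }

    # hairpin stem: the only strongly paired element in the target exon
    stem_truth = None
    if spec.stem_exon_offset is not None:
        hairpin = (
            spec.stem_arm
            + "A" * spec.stem_loop_len
            + reverse_complement(spec.stem_arm)
        )
        plant(hairpin, t_spl + spec.stem_exon_offset, "stem")
        stem_truth = {
            "exon_offset": spec.stem_exon_offset,
            "length": len(hairpin),
        }

    # ESE-rich window: tandem hexamer repeat
    ese_truth = None
    if spec.ese_hexamer is not None:
        hex_dna = spec.ese_hexamer.replace("U", "T")
        reps = -(-spec.ese_window_len // len(hex_dna))  # ceil
        window = (hex_dna * reps)[: spec.ese_window_len]
        e_start = t_spl + spec.ese_window_exon_offset
        plant(window, e_start, "ese_window")
        expected_hits = sum(
            1
            for s in range(spec.ese_window_len - len(hex_dna) + 1)
            if window[s : s + len(hex_dna)] == hex_dna
        )
        ese_truth = {
            "exon_offset": spec.ese_window_exon_offset,
            "length": spec.ese_window_len,
            "hexamer": spec.ese_hexamer,
            "expected_hits": expected_hits,
        }

    # start codon and a stop cassette in the exon after the target
    if spec.primers is None:
        plant("ATG", spec.atg_exon1_offset, "start_codon")
        cds_start = spec.atg_exon1_offset
    else:
        cds_start = _plant_atg_for_primers(spec, plant, primer_sites)
    cassette_spl = exon_spliced_start[t_idx + 1] + 10
    plant(STOP_CASSETTE, cassette_spl, "stop_cassette")

    # scrub accidental ESE hexamers outside the planted window
    if spec.ese_hexamer is not None:
        _scrub_hexamer(genome, planted, spec.ese_hexamer.replace("U", "T"))

    # repair: no in-frame stop between the start codon and the cassette
    cds_end = _repair_orf(
        genome, planted, spec, exon_g, exon_spliced_start, cds_start, cassette_spl
    )

    gseq = "".join(genome)
    spliced = "".join(gseq[gs:ge] for gs, ge in exon_g)
    skipped = (
        spliced[:t_spl] + spliced[t_spl + t_len :]
    )

    # independent verification of planted features
    product_sizes = _verify_products(spec, spliced, skipped)
    if spec.ese_hexamer is not None:
        _verify_hexamers(spec, gseq, ese_truth, spliced_to_genomic, t_spl)

    expected_skip = _expected_skip(
        spec, spliced, skipped, cds_start, t_spl, t_len, exon_spliced_start
    )

    gff3 = _render_gff3(spec, exon_g, cds_start, cds_end, exon_spliced_start)
    fasta = _render_fasta(spec.seq_id, gseq)
    truth = ToyGeneTruth(
        seq_id=spec.seq_id,
        transcript_id=spec.transcript_id,
        exon_genomic_spans=exon_g,
        target_exon=spec.target_exon,
        target_exon_length=t_len,
        cds_spliced=(cds_start, cds_end),
        ese=ese_truth,
        stem=stem_truth,
        primer_sites=primer_sites,
        product_sizes=product_sizes,
        aon=aon_truth,
        expected_skip=expected_skip,
    )
    return ToyGene(gff3=gff3, fasta=fasta, truth=truth, spec=spec)


def _plant_atg_for_primers(spec, plant, primer_sites) -> int:
    """Place the start codon so no planted element carries an in-frame stop.

    Tries each ATG already present in (or plantable just upstream of) the
    forward-primer region, then checks every planted element upstream of the
    stop cassette for in-frame stop triplets.
    """
    p = spec.primers
    elements = {
        "outer_fwd": (primer_sites["outer_fwd"][0], p.outer[0]),
        "inner_fwd": (primer_sites["inner_fwd"][0], p.inner[0]),
    }
    if spec.aon_antisense is not None:
        t_spl = sum(spec.exon_lengths[: spec.target_exon - 1])
        window = reverse_complement(spec.aon_antisense.replace("U", "T"))
        elements["aon_target"] = (t_spl + spec.aon_exon_offset, window)

    # candidate starts: ATG inside the outer forward primer, else planted
    # right after it
    candidates = []
    o_start, o_seq = elements["outer_fwd"]
    for k in range(len(o_seq) - 2):
        if o_seq[k : k + 3] == "ATG":
            candidates.append(("existing", o_start + k))
    fwd_end = primer_sites["outer_fwd"][1]
    gap = primer_sites["inner_fwd"][0] - fwd_end
    for d in range(max(0, gap - 2)):
        candidates.append(("plant", fwd_end + d))

    for mode, start in candidates:
        ok = True
        for label, (e_start, e_seq) in elements.items():
            if e_start < start:  # element upstream of CDS: frame irrelevant
                head = max(0, start - e_start)
            else:
                head = 0
            for k in range(head, len(e_seq) - 2):
                pos = e_start + k
                if (pos - start) % 3 == 0 and e_seq[k : k + 3] in _STOPS:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            if mode == "plant":
                # the inner forward primer may begin with the G of ATG
                nxt = primer_sites["inner_fwd"][0]
                seq = "ATG"[: nxt - start] if nxt - start < 3 else "ATG"
                if nxt - start < 3:
                    inner_first = p.inner[0][: 3 - len(seq)]
                    if seq + inner_first != "ATG":
                        continue
                plant(seq, start, "start_codon")
            return start
    raise FixtureError(
        "could not place a start codon avoiding in-frame stops in planted "
        "elements"
    )


def _scrub_hexamer(genome: list[str], planted: list[bool], hex_dna: str) -> None:
    g = "".join(genome)
    pos = g.find(hex_dna)
    while pos != -1:
        free = [k for k in range(pos, pos + len(hex_dna)) if not planted[k]]
        if free:
            genome[free[0]] = "C"
            g = "".join(genome)
            pos = g.find(hex_dna, pos)
        else:
            pos = g.find(hex_dna, pos + 1)  # the planted window itself


def _repair_orf(
    genome, planted, spec, exon_g, exon_spliced_start, cds_start, cassette_spl
) -> int:
    def spliced_seq() -> str:
        g = "".join(genome)
        return "".join(g[gs:ge] for gs, ge in exon_g)

    def spliced_to_genomic(spos: int) -> int:
        for i, (gs, ge) in enumerate(exon_g):
            off = spos - exon_spliced_start[i]
            if 0 <= off < spec.exon_lengths[i]:
                return gs + off
        raise FixtureError(f"spliced position {spos} not exonic")

    for _ in range(500):
        s = spliced_seq()
        stop_at = None
        for pos in range(cds_start, len(s) - 2, 3):
            if s[pos : pos + 3] in _STOPS:
                stop_at = pos
                break
        if stop_at is None:
            raise FixtureError("no stop codon reachable; cassette missing?")
        if stop_at >= cassette_spl:
            return stop_at + 3
        free = [
            k for k in range(stop_at, stop_at + 3)
            if not planted[spliced_to_genomic(k)]
        ]
        if not free:
            raise FixtureError(
                f"in-frame stop at spliced {stop_at} lies fully inside "
                "planted sequence"
            )
        genome[spliced_to_genomic(free[0])] = "C"
    raise FixtureError("ORF repair did not converge")


def _verify_products(spec, spliced: str, skipped: str) -> dict:
    sizes: dict[str, int] = {}
    if spec.primers is None:
        return sizes
    p = spec.primers
    for name, template in (("wt", spliced), ("skip", skipped)):
        for round_name, (fwd, rev) in (("outer", p.outer), ("inner", p.inner)):
            f_sites = _all_indices(template, fwd)
            r_sites = _all_indices(template, reverse_complement(rev))
            if len(f_sites) != 1 or len(r_sites) != 1:
                raise _RetryableFixtureError(
                    f"{round_name} primers must land uniquely on the {name} "
                    f"template (found {len(f_sites)} fwd, {len(r_sites)} rev)"
                )
            sizes[f"{name}_{round_name}"] = (
                r_sites[0] + len(rev) - f_sites[0]
            )
    if sizes["wt_inner"] != p.inner_wt_product:
        raise FixtureError(
            f"wild-type inner product {sizes['wt_inner']} != planned "
            f"{p.inner_wt_product}"
        )
    t_len = spec.exon_lengths[spec.target_exon - 1]
    if p.expect_skip_products and (
        sizes["wt_inner"] - sizes["skip_inner"] != t_len
    ):
        raise FixtureError("skip product size does not differ by the exon length")
    return sizes


def _all_indices(s: str, sub: str) -> list[int]:
    out, pos = [], s.find(sub)
    while pos != -1:
        out.append(pos)
        pos = s.find(sub, pos + 1)
    return out


def _verify_hexamers(spec, gseq, ese_truth, spliced_to_genomic, t_spl) -> None:
    hex_dna = spec.ese_hexamer.replace("U", "T")
    w_start = spliced_to_genomic(t_spl + spec.ese_window_exon_offset)
    w_end = w_start + spec.ese_window_len
    inside = outside = 0
    for pos in _all_indices(gseq, hex_dna):
        if w_start <= pos and pos + len(hex_dna) <= w_end:
            inside += 1
        else:
            outside += 1
    if inside != ese_truth["expected_hits"] or outside != 0:
        raise FixtureError(
            f"hexamer plant verification failed: {inside} inside "
            f"(expected {ese_truth['expected_hits']}), {outside} outside"
        )


def _expected_skip(
    spec, spliced, skipped, cds_start, t_spl, t_len, exon_spliced_start
) -> dict:
    """Independent (plain string scan) prediction of the skip consequences."""
    frameshift = t_len % 3 != 0
    ptc = None
    for pos in range(cds_start, len(skipped) - 2, 3):
        if skipped[pos : pos + 3] in _STOPS and pos >= t_spl - 2:
            ptc = pos
            break
    lengths = [
        L for i, L in enumerate(spec.exon_lengths, start=1)
        if i != spec.target_exon
    ]
    junctions = list(np.cumsum(lengths[:-1]))
    nmd = ptc is not None and bool(junctions) and junctions[-1] - ptc >= 50
    return {
        "frameshift": frameshift,
        "ptc_mrna_offset": ptc,
        "nmd_predicted": bool(nmd),
        "skipped_length": len(skipped),
    }


def _render_gff3(spec, exon_g, cds_start, cds_end, exon_spliced_start) -> str:
    gene_id = f"{spec.transcript_id}_gene"
    g_lo = exon_g[0][0] + 1
    g_hi = exon_g[-1][1]
    lines = [
        "##gff-version 3",
        f"{spec.seq_id}\tskipdesign\tgene\t{g_lo}\t{g_hi}\t.\t+\t.\tID={gene_id}",
        f"{spec.seq_id}\tskipdesign\tmRNA\t{g_lo}\t{g_hi}\t.\t+\t.\t"
        f"ID={spec.transcript_id};Parent={gene_id}",
    ]
    for i, (gs, ge) in enumerate(exon_g, start=1):
        lines.append(
            f"{spec.seq_id}\tskipdesign\texon\t{gs + 1}\t{ge}\t.\t+\t.\t"
            f"ID={spec.transcript_id}.exon{i};Parent={spec.transcript_id}"
        )
    # map the spliced CDS interval onto genomic exon pieces
    for i, (gs, ge) in enumerate(exon_g):
        e_lo = exon_spliced_start[i]
        e_hi = e_lo + (ge - gs)
        lo = max(cds_start, e_lo)
        hi = min(cds_end, e_hi)
        if lo < hi:
            g_start = gs + (lo - e_lo)
            g_end = gs + (hi - e_lo)
            lines.append(
                f"{spec.seq_id}\tskipdesign\tCDS\t{g_start + 1}\t{g_end}\t.\t+\t0\t"
                f"ID={spec.transcript_id}.cds{i + 1};Parent={spec.transcript_id}"
            )
    return "\n".join(lines) + "\n"


def _render_fasta(seq_id: str, seq: str, width: int = 60) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{seq_id}\n{body}\n"


# ---------------------------------------------------------------------------
# Paper-like fixtures
# ---------------------------------------------------------------------------

_PAPERLIKE = {
    "igfbp1-like": dict(
        exon_lengths=(150, 185, 150, 60),
        inner=IGFBP1_INNER_PRIMERS,
        outer=IGFBP1_OUTER_PRIMERS,
        inner_fwd_start=30,
        inner_wt_product=IGFBP1_PRODUCTS["wt_inner"],
        outer_fwd_start=5,
        outer_wt_product=475,
        aon=IGFBP1_AON,
    ),
    "igfbp3-like": dict(
        exon_lengths=(150, 227, 150, 60),
        inner=IGFBP3_INNER_PRIMERS,
        outer=IGFBP3_OUTER_PRIMERS,
        inner_fwd_start=30,
        inner_wt_product=IGFBP3_PRODUCTS["wt_inner"],
        outer_fwd_start=5,
        outer_wt_product=471,
        aon=IGFBP3_AON,
    ),
}


def make_paperlike_fixture(gene: str, seed: int = 7) -> ToyGene:
    """A gene emulating the published Igfbp1/Igfbp3 design context.

    ``gene`` is ``"igfbp1-like"`` or ``"igfbp3-like"``.  The 185 nt / 227 nt
    out-of-frame exon 2, the published nested primer pairs and the published AON
    target window are planted so that in-silico nested PCR yields the
    published 425/240 bp resp. 422/195 bp wild-type/skipped bands.
    """
    if gene not in _PAPERLIKE:
        raise FixtureError(
            f"unknown paper-like gene {gene!r}; choose from {sorted(_PAPERLIKE)}"
        )
    cfg = _PAPERLIKE[gene]
    spec = FixtureSpec(
        seed=seed,
        exon_lengths=cfg["exon_lengths"],
        target_exon=2,
        intron_length=80,
        seq_id=f"chr_{gene.replace('-', '_')}",
        transcript_id=gene.replace("-", "_"),
        ese_hexamer=None,
        stem_exon_offset=None,
        primers=PrimerPlan(
            inner=cfg["inner"],
            outer=cfg["outer"],
            inner_fwd_spliced_start=cfg["inner_fwd_start"],
            inner_wt_product=cfg["inner_wt_product"],
            outer_fwd_spliced_start=cfg["outer_fwd_start"],
            outer_wt_product=cfg["outer_wt_product"],
        ),
        aon_antisense=cfg["aon"],
        aon_exon_offset=50,
    )
    return make_toy_gene(spec)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def make_count_matrix(
    n_genes: int = 1000,
    n_per_group: int = 3,
    lfc: float = 1.0,
    frac_de: float = 0.1,
    dispersion: float = 0.05,
    base_mean_range: tuple[float, float] = (0.01, 500.0),
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts for two groups of replicates.

    A fraction ``frac_de`` of genes carries a log2 fold-change of ``lfc`` in
    the treated group.  Base means are log-uniform down to near zero so a
    realistic share of genes falls below an average-CPM filter.  Returns the
    matrix plus a truth table with each gene's base mean and assigned log2
    fold-change.
    """
    rng = np.random.default_rng(seed)
    base = np.exp(
        rng.uniform(np.log(base_mean_range[0]), np.log(base_mean_range[1]), n_genes)
    )
    is_de = rng.random(n_genes) < frac_de
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    gene_lfc = np.where(is_de, lfc * signs, 0.0)

    means_ctrl = base
    means_trt = base * 2.0 ** gene_lfc
    n_nb = 1.0 / dispersion

    def draw(means):
        cols = []
        for _ in range(n_per_group):
            p = n_nb / (n_nb + means)
            cols.append(rng.negative_binomial(n_nb, p))
        return np.column_stack(cols)

    counts = np.column_stack([draw(means_ctrl), draw(means_trt)])
    samples = [f"ctrl_{i + 1}" for i in range(n_per_group)] + [
        f"trt_{i + 1}" for i in range(n_per_group)
    ]
    genes = [f"gene_{i + 1}" for i in range(n_genes)]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    groups = {s: ("ctrl" if s.startswith("ctrl") else "trt") for s in samples}
    truth = pd.DataFrame(
        {"base_mean": base, "log2_fc": gene_lfc, "is_de": is_de}, index=genes
    )
    return CountMatrix(counts=df, groups=groups), truth
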