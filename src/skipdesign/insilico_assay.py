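"""In-silico RT-PCR, nested PCR and reference-gene-normalized qPCR.

Exon skipping is read out on a gel: primers in the exons flanking the target
amplify both transcripts, so the wild-type band and the skipped band differ
by exactly the skipped exon's length.  This module predicts those amplicons.
Primer matching is exact by default (an optional mismatch budget is allowed
anywhere except the 3'-terminal base); product length includes both primer
footprints, so predicted bp are directly comparable to ladder-calibrated gel
bands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


class AssayError(ValueError):
    pass


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'."""

    forward: str
    reverse: str
    label: str = ""

    def __post_init__(self):
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            s = seq.upper().replace("U", "T")
            if len(s) < 10:
                raise AssayError(f"{name} primer must be >= 10 nt, got {len(s)}")
            if set(s) - set("ACGTN"):
                raise AssayError(f"{name} primer has non-nucleotide characters")
        object.__setattr__(self, "forward", self.forward.upper().replace("U", "T"))
        object.__setattr__(self, "reverse", self.reverse.upper().replace("U", "T"))


@dataclass(frozen=True)
class PcrProduct:
    template_id: str
    start: int  # forward primer 5' position on the template
    end: int  # reverse primer 5' position + 1 (template coordinates)
    round: str  # "outer" or "inner"
    multi_site: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise AssayError("product must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_sites(template: str, query: str, max_mismatches: int) -> list[int]:
    """Start positions where ``query`` anneals; the 3' base must always match
    and is taken as the last character of ``query`` as written."""
    sites = []
    if max_mismatches == 0:
        pos = template.find(query)
        while pos != -1:
            sites.append(pos)
            pos = template.find(query, pos + 1)
        return sites
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    for pos in range(len(t) - len(q) + 1):
        window = t[pos : pos + len(q)]
        mm = int((window != q).sum())
        if mm <= max_mismatches and window[-1] == q[-1]:
            sites.append(pos)
    return sites


def pcr_products(
    template: str,
    outer: PrimerPair,
    inner: PrimerPair | None = None,
    template_id: str = "template",
    max_mismatches: int = 0,
) -> list[PcrProduct]:
    """Predict amplicons; nested semantics when an inner pair is given.

    Forward sites are occurrences of the forward primer on the template;
    reverse sites are occurrences of the reverse complement of the reverse
    primer.  All orientation-correct combinations with positive length are
    reported; a primer with multiple sites flags its products ``multi_site``.
    When an inner pair is given, inner products are searched *within* each
    outer product and reported in outer-template coordinates.
    """
    template = template.upper().replace("U", "T")
    if not template:
        raise AssayError("empty template")
    products = _round_products(template, outer, "outer", template_id, max_mismatches)
    if inner is None:
        return products
    nested: list[PcrProduct] = []
    for outer_prod in products:
        sub = template[outer_prod.start : outer_prod.end]
        for p in _round_products(sub, inner, "inner", template_id, max_mismatches):
            nested.append(
                PcrProduct(
                    template_id=template_id,
                    start=outer_prod.start + p.start,
                    end=outer_prod.start + p.end,
                    round="inner",
                    multi_site=p.multi_site or outer_prod.multi_site,
                )
            )
    combined = products + nested
    # deduplicate inner products found in overlapping outer parents
    seen, unique = set(), []
    for p in combined:
        key = (p.start, p.end, p.round)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def _round_products(
    template: str,
    pair: PrimerPair,
    round_name: str,
    template_id: str,
    max_mismatches: int,
) -> list[PcrProduct]:
    fwd_sites = _find_sites(template, pair.forward, max_mismatches)
    rev_sites = _find_sites(template, _revcomp_dna(pair.reverse), max_mismatches)
    multi = len(fwd_sites) > 1 or len(rev_sites) > 1
    if multi:
        logger.warning(
            "%s primer pair %r has multiple annealing sites "
            "(%d forward, %d reverse); reporting all products",
            round_name, pair.label or pair.forward[:8], len(fwd_sites), len(rev_sites),
        )
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(pair.reverse)
            if r >= f + len(pair.forward):  # non-overlapping footprints
                products.append(
                    PcrProduct(
                        template_id=template_id, start=f, end=end,
                        round=round_name, multi_site=multi,
                    )
                )
    return products


def products_tsv(products: list[PcrProduct]) -> str:
    lines = ["template\tstart\tend\tlength\tround"]
    for p in products:
        lines.append(f"{p.template_id}\t{p.start}\t{p.end}\t{p.length}\t{p.round}")
    return "\n".join(lines) + "\n"


def virtual_gel(products: list[PcrProduct], lane_width: int = 40) -> str:
    """A textual gel: one band per product, largest at the top."""
    if not products:
        return "(no products)\n"
    lines = []
    for p in sorted(products, key=lambda p: -p.length):
        bar = "=" * max(4, int(lane_width * p.length / max(q.length for q in products)))
        lines.append(f"{p.length:>6} bp  {bar}  [{p.round}] {p.template_id}")
    return "\n".join(lines) + "\n"


def qpcr_relative(
    target_cq,
    reference_cqs: dict[str, float] | dict[str, list[float]],
    e_target: float = 2.0,
    e_references: dict[str, float] | None = None,
    calibrator_target_cq: float | None = None,
    calibrator_reference_cqs: dict[str, float] | None = None,
) -> float:
    """Relative expression normalized to the geometric mean of reference genes.

    ratio = E_t^(-Cq_t) / geomean_r(E_r^(-Cq_r)), optionally divided by the
    same quantity for a calibrator sample.  Amplification efficiencies are
    inputs (per-cycle fold change, in (1, 2]); replicate Cq values for a gene
    are averaged first.
    """
    if not reference_cqs:
        raise AssayError("at least one reference gene Cq is required")
    e_references = e_references or {}

    def eff(name: str) -> float:
        e = e_references.get(name, 2.0)
        if not 1.0 < e <= 2.0:
            raise AssayError(f"efficiency for {name!r} must be in (1, 2], got {e}")
        return e

    if not 1.0 < e_target <= 2.0:
        raise AssayError(f"target efficiency must be in (1, 2], got {e_target}")

    def mean_cq(v) -> float:
        if v is None:
            raise AssayError("missing Cq value")
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        if arr.size == 0 or np.any(np.isnan(arr)):
            raise AssayError("missing Cq value")
        return float(arr.mean())

    def sample_quantity(t_cq, r_cqs) -> float:
        log_t = -mean_cq(t_cq) * math.log(e_target)
        log_refs = [
            -mean_cq(cq) * math.log(eff(name)) for name, cq in r_cqs.items()
        ]
        return math.exp(log_t - sum(log_refs) / len(log_refs))

    ratio = sample_quantity(target_cq, reference_cqs)
    if calibrator_target_cq is not None:
        if not calibrator_reference_cqs:
            raise AssayError("calibrator requires reference Cq values")
        ratio /= sample_quantity(calibrator_target_cq, calibrator_reference_cqs)
    return ratio


def parse_primer_pairs(text: str) -> list[PrimerPair]:
    """Read primers from FASTA (paired records in order) or 2-column text."""
    text = text.strip()
    pairs = []
    if text.startswith(">"):
        from io import StringIO

        from Bio import SeqIO

        recs = list(SeqIO.parse(StringIO(text), "fasta"))
        if len(recs) % 2 != 0:
            raise AssayError("FASTA primer input must contain pairs of records")
        for i in range(0, len(recs), 2):
            pairs.append(
                PrimerPair(
                    forward=str(recs[i].seq),
                    reverse=str(recs[i + 1].seq),
                    label=recs[i].id,
                )
            )
    else:
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) < 2:
                raise AssayError(f"primer line needs two columns: {ln!r}")
            label = parts[2] if len(parts) > 2 else ""
            pairs.append(PrimerPair(forward=parts[0], reverse=parts[1], label=label))
    if not pairs:
        raise AssayError("no primer pairs found")
    return pairs
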