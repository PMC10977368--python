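"""Exonic splicing enhancer/silencer (ESE/ESS) motif scanning.

Splice-switching AONs work best when they occlude the cis-elements the
spliceosome uses to recognise the target exon, so the designer scans the exon
for ESE motifs (position weight matrices in log-odds form, plus exact hexamer
sets) and prefers windows dense in enhancer hits.

The motif library shipped with the package (``data/motif_matrices_synthetic.tsv``
and the hexamer lists next to it) is a *synthetic* stand-in: consensus-derived
SR-protein-like matrices and GA-rich enhancer / UAG-class silencer hexamers,
not a reproduction of any published matrix set.  The plain-text format below
lets users drop in their own matrices (ESEfinder, HSF exports, ...):

    >name kind threshold          e.g.  >SRSF1_like ESE 2.5
    A  <w floats>
    C  <w floats>
    G  <w floats>
    U  <w floats>

Hexamer sets are one 6-mer per line; ``#`` lines are comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .folding import to_rna

logger = logging.getLogger(__name__)

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifMatrix:
    """A log-odds PWM with a minimum reportable score."""

    name: str
    kind: str  # "ESE" or "ESS"
    threshold: float
    matrix: np.ndarray  # shape (4, width): rows A, C, G, U

    def __post_init__(self):
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 2:
            raise MotifError(
                f"motif {self.name!r}: matrix must be 4 x width>=2, "
                f"got {self.matrix.shape}"
            )
        if self.kind not in ("ESE", "ESS"):
            raise MotifError(f"motif {self.name!r}: kind must be ESE or ESS")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def score_window(self, window: str) -> float:
        """Sum of per-position log-odds; windows containing N score -inf."""
        total = 0.0
        for pos, base in enumerate(window):
            row = _BASE_ROW.get(base)
            if row is None:
                return float("-inf")
            total += self.matrix[row, pos]
        return total


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    score: float
    kind: str


@dataclass(frozen=True)
class MotifLibrary:
    matrices: tuple[MotifMatrix, ...]
    hexamer_sets: dict[str, frozenset[str]]  # name -> 6-mers (RNA alphabet)
    hexamer_kinds: dict[str, str]  # set name -> ESE/ESS

    def __post_init__(self):
        for name, hexes in self.hexamer_sets.items():
            for h in hexes:
                if len(h) != 6 or set(h) - set("ACGU"):
                    raise MotifError(f"set {name!r}: {h!r} is not an RNA 6-mer")
            if name not in self.hexamer_kinds:
                raise MotifError(f"hexamer set {name!r} has no ESE/ESS kind")

    @property
    def empty(self) -> bool:
        return not self.matrices and not self.hexamer_sets


def parse_motif_matrices(text: str) -> tuple[MotifMatrix, ...]:
    """Parse the documented ``>name kind threshold`` block format."""
    matrices = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise MotifError(f"expected '>' header, got {header!r}")
        try:
            name, kind, thr = header[1:].split()
        except ValueError as exc:
            raise MotifError(f"malformed header {header!r}") from exc
        rows = {}
        for j in range(1, 5):
            parts = lines[i + j].split()
            rows[parts[0].upper()] = [float(x) for x in parts[1:]]
        try:
            mat = np.array([rows[b] for b in "ACGU"], dtype=float)
        except KeyError as exc:
            raise MotifError(f"motif {name!r}: missing base row {exc}") from exc
        matrices.append(
            MotifMatrix(name=name, kind=kind, threshold=float(thr), matrix=mat)
        )
        i += 5
    return tuple(matrices)


def parse_hexamer_set(text: str) -> frozenset[str]:
    hexes = set()
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        hexes.add(to_rna(ln))
    return frozenset(hexes)


def load_default_library() -> MotifLibrary:
    """The packaged synthetic ESE/ESS library (see module docstring)."""
    pkg = resources.files("skipdesign.data")
    matrices = parse_motif_matrices(
        (pkg / "motif_matrices_synthetic.tsv").read_text()
    )
    ese = parse_hexamer_set((pkg / "ese_hexamers_synthetic.txt").read_text())
    ess = parse_hexamer_set((pkg / "ess_hexamers_synthetic.txt").read_text())
    return MotifLibrary(
        matrices=matrices,
        hexamer_sets={"ESE_hexamers": ese, "ESS_hexamers": ess},
        hexamer_kinds={"ESE_hexamers": "ESE", "ESS_hexamers": "ESS"},
    )


def scan_motifs(
    sequence: str,
    matrices: tuple[MotifMatrix, ...] = (),
    hexamer_sets: dict[str, frozenset[str]] | None = None,
    hexamer_kinds: dict[str, str] | None = None,
) -> list[MotifHit]:
    """Report every PWM window scoring >= its threshold and every exact
    hexamer occurrence, sorted by start then motif name.

    Scanning is on the sense (exonic) strand only, since splicing enhancers
    act on the pre-mRNA itself.
    """
    hexamer_sets = hexamer_sets or {}
    hexamer_kinds = hexamer_kinds or {}
    if not matrices and not hexamer_sets:
        raise MotifError("empty motif library")
    rna = to_rna(sequence)
    min_width = min(
        [m.width for m in matrices] + ([6] if hexamer_sets else [])
    )
    if len(rna) < min_width:
        raise MotifError(
            f"sequence length {len(rna)} shorter than smallest motif "
            f"width {min_width}"
        )
    hits: list[MotifHit] = []
    for m in matrices:
        for s in range(len(rna) - m.width + 1):
            score = m.score_window(rna[s : s + m.width])
            if score >= m.threshold:
                hits.append(MotifHit(motif=m.name, start=s, score=score, kind=m.kind))
    for set_name, hexes in hexamer_sets.items():
        kind = hexamer_kinds.get(set_name, "ESE")
        for s in range(len(rna) - 5):
            word = rna[s : s + 6]
            if word in hexes:
                hits.append(
                    MotifHit(motif=f"{set_name}:{word}", start=s, score=1.0, kind=kind)
                )
    hits.sort(key=lambda h: (h.start, h.motif))
    logger.debug("scan found %d hit(s) on %d nt", len(hits), len(rna))
    return hits


def scan_library(sequence: str, library: MotifLibrary) -> list[MotifHit]:
    return scan_motifs(
        sequence,
        matrices=library.matrices,
        hexamer_sets=library.hexamer_sets,
        hexamer_kinds=library.hexamer_kinds,
    )


def ese_density(
    hits: list[MotifHit], window_start: int, window_len: int, kind: str = "ESE"
) -> float:
    """Hits of the given kind whose *start* lies in the window, per nt."""
    if window_len <= 0:
        raise ValueError(f"window length must be positive, got {window_len}")
    if window_start < 0:
        raise ValueError(f"window start must be >= 0, got {window_start}")
    count = sum(
        1
        for h in hits
        if h.kind == kind and window_start <= h.start < window_start + window_len
    )
    return count / window_len
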