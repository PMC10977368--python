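"""Nearest-neighbor hybridization thermodynamics for AON screening.

GC%, melting temperature, AON:target binding free energy and self/cross-dimer
screens, all computed from a dinucleotide-stack nearest-neighbor (NN) table.
The default table is the RNA:RNA Watson-Crick set of Xia et al. (1998),
shipped as ``data/nn_rna_xia1998.tsv`` with a provenance line; 2'-O-methyl
phosphorothioate AONs hybridizing to pre-mRNA are approximated as RNA:RNA
duplexes, and the table is swappable by file for other chemistries.

Dimer and binding searches are *ungapped*: the best antiparallel complementary
alignment of one strand against the other is found by sliding every offset and
summing NN stacks over consecutive Watson-Crick pairs.  This matches common
oligo-dimer screens and keeps the computation exact and oracle-checkable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

from .folding import to_rna

logger = logging.getLogger(__name__)

GAS_CONSTANT = 1.987  # cal/(mol*K)
REFERENCE_CELSIUS = 37.0
DEFAULT_STRAND_CONC_M = 1e-6
DEFAULT_SODIUM_M = 0.1

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


class ThermoError(ValueError):
    pass


@dataclass(frozen=True)
class NNParameterTable:
    """Per-stack enthalpy/entropy with initiation and correction terms."""

    stacks: dict[str, tuple[float, float]]  # XY -> (dH kcal/mol, dS cal/mol/K)
    initiation: tuple[float, float]
    terminal_au: tuple[float, float]
    symmetry: tuple[float, float]
    provenance: str

    def __post_init__(self):
        expected = {a + b for a in "ACGU" for b in "ACGU"}
        missing = expected - set(self.stacks)
        if missing:
            raise ThermoError(f"NN table missing stacks: {sorted(missing)}")
        if not self.provenance:
            raise ThermoError("NN table must carry a provenance tag")

    @classmethod
    def from_tsv(cls, text: str, provenance: str | None = None) -> "NNParameterTable":
        stacks = {}
        init = term_au = sym = None
        prov = provenance or ""
        for ln in text.splitlines():
            if ln.startswith("#"):
                if not prov and "provenance" in ln:
                    prov = ln.lstrip("# ").strip()
                continue
            parts = ln.split()
            if len(parts) != 3 or parts[0] == "stack":
                continue
            key, dh, ds = parts[0], float(parts[1]), float(parts[2])
            if key == "INIT":
                init = (dh, ds)
            elif key == "TERM_AU":
                term_au = (dh, ds)
            elif key == "SYM":
                sym = (dh, ds)
            else:
                stacks[to_rna(key)] = (dh, ds)
        if init is None or term_au is None or sym is None:
            raise ThermoError("NN table missing INIT/TERM_AU/SYM rows")
        return cls(
            stacks=stacks, initiation=init, terminal_au=term_au,
            symmetry=sym, provenance=prov or "unspecified",
        )


@dataclass(frozen=True)
class DuplexResult:
    """Best ungapped duplex between two strands.

    ``delta_g`` is kcal/mol at 37 degC (0 when no stabilizing duplex exists);
    ``paired_span`` gives the half-open window on strand ``a`` between the
    first and last paired bases of the best alignment.
    """

    delta_g: float
    tm: float | None
    paired_span: tuple[int, int] | None
    mismatches: int
    n_pairs: int


def _load_default_table() -> NNParameterTable:
    text = (resources.files("skipdesign.data") / "nn_rna_xia1998.tsv").read_text()
    return NNParameterTable.from_tsv(text)


_DEFAULT_TABLE: NNParameterTable | None = None


def default_nn_table() -> NNParameterTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = _load_default_table()
    return _DEFAULT_TABLE


def gc_content(sequence: str) -> float:
    """(#G + #C) / length; T and U are equivalent (neither counted)."""
    if not sequence:
        raise ThermoError("empty sequence")
    rna = to_rna(sequence)
    bad = set(rna) - set("ACGUN")
    if bad:
        raise ThermoError(f"invalid bases: {sorted(bad)}")
    return (rna.count("G") + rna.count("C")) / len(rna)


def _is_self_complementary(rna: str) -> bool:
    return all(_WC.get(b) == c for b, c in zip(rna, reversed(rna)))


def _perfect_duplex_sums(
    rna: str, params: NNParameterTable
) -> tuple[float, float]:
    """dH, dS for the duplex of ``rna`` with its perfect complement."""
    dh, ds = params.initiation
    for i in range(len(rna) - 1):
        sdh, sds = params.stacks[rna[i : i + 2]]
        dh += sdh
        ds += sds
    for end in (rna[0], rna[-1]):
        if end in "AU":
            dh += params.terminal_au[0]
            ds += params.terminal_au[1]
    if _is_self_complementary(rna):
        dh += params.symmetry[0]
        ds += params.symmetry[1]
    return dh, ds


def melting_temperature(
    dh: float,
    ds: float,
    self_complementary: bool,
    conc: float = DEFAULT_STRAND_CONC_M,
    salt: float = DEFAULT_SODIUM_M,
) -> float:
    """Two-state Tm (degC) with a 16.6 log10[Na+] salt adjustment."""
    x = 1.0 if self_complementary else 4.0
    tm_k = (dh * 1000.0) / (ds + GAS_CONSTANT * math.log(conc / x))
    return tm_k - 273.15 + 16.6 * math.log10(salt)


def tm_nearest_neighbor(
    sequence: str,
    params: NNParameterTable | None = None,
    conc: float = DEFAULT_STRAND_CONC_M,
    salt: float = DEFAULT_SODIUM_M,
) -> float:
    """Tm of the sequence hybridized to its perfect complement."""
    params = params or default_nn_table()
    rna = to_rna(sequence)
    if len(rna) < 2:
        raise ThermoError(f"need >= 2 nt for a nearest-neighbor Tm, got {len(rna)}")
    if set(rna) - set("ACGU"):
        raise ThermoError("Tm requires an unambiguous A/C/G/U sequence")
    dh, ds = _perfect_duplex_sums(rna, params)
    return melting_temperature(
        dh, ds, self_complementary=_is_self_complementary(rna), conc=conc, salt=salt
    )


def delta_g_at(dh: float, ds: float, celsius: float = REFERENCE_CELSIUS) -> float:
    return dh - (celsius + 273.15) * (ds / 1000.0)


def duplex_score(
    a: str,
    b: str,
    params: NNParameterTable | None = None,
    conc: float = DEFAULT_STRAND_CONC_M,
    salt: float = DEFAULT_SODIUM_M,
) -> DuplexResult:
    """Best ungapped antiparallel duplex of ``a`` against ``b``.

    Self-dimer screen: ``duplex_score(a, a)``.  AON:target binding energy:
    ``duplex_score(aon, target_window)``.  ``delta_g`` is 0 when no alignment
    is stabilizing (which requires at least two consecutive pairs).
    """
    params = params or default_nn_table()
    ra, rb = to_rna(a), to_rna(b)
    if not ra or not rb:
        raise ThermoError("both sequences must be nonempty")
    rb_rev = rb[::-1]  # antiparallel: a[i] faces reversed b

    best = None  # (dG, dh, ds, span, mismatches, n_pairs, selfcomp)
    for d in range(-(len(rb_rev) - 1), len(ra)):
        paired = []
        for i in range(len(ra)):
            j = i - d
            if 0 <= j < len(rb_rev):
                if _WC.get(ra[i]) == rb_rev[j]:
                    paired.append(i)
        if len(paired) < 2:
            continue
        dh, ds = params.initiation
        n_stacks = 0
        pairset = set(paired)
        for i in paired:
            if i + 1 in pairset:
                sdh, sds = params.stacks[ra[i : i + 2]]
                dh += sdh
                ds += sds
                n_stacks += 1
        if n_stacks == 0:
            continue
        for end in (paired[0], paired[-1]):
            if ra[end] in "AU":
                dh += params.terminal_au[0]
                ds += params.terminal_au[1]
        selfcomp = ra == rb and _alignment_symmetric(ra, rb_rev, d)
        if selfcomp:
            dh += params.symmetry[0]
            ds += params.symmetry[1]
        dg = delta_g_at(dh, ds)
        span = (paired[0], paired[-1] + 1)
        mm = sum(1 for i in range(*span) if i not in pairset)
        key = (dg, -len(paired), span[0])
        if best is None or key < best[0]:
            best = (key, dg, dh, ds, span, mm, len(paired), selfcomp)

    if best is None or best[1] >= 0:
        return DuplexResult(
            delta_g=0.0, tm=None, paired_span=None, mismatches=0, n_pairs=0
        )
    _, dg, dh, ds, span, mm, n_pairs, selfcomp = best
    tm = melting_temperature(dh, ds, self_complementary=selfcomp, conc=conc, salt=salt)
    return DuplexResult(
        delta_g=dg, tm=tm, paired_span=span, mismatches=mm, n_pairs=n_pairs
    )


def _alignment_symmetric(ra: str, rb_rev: str, d: int) -> bool:
    """Whether a self-alignment is its own mirror (palindromic register)."""
    return len(ra) == len(rb_rev) and d == 0 and _is_self_complementary(ra)


def binding_delta_g(
    aon: str, target_window: str, params: NNParameterTable | None = None
) -> float:
    """AON:target binding free energy (kcal/mol at 37 degC)."""
    return duplex_score(aon, target_window, params=params).delta_g
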