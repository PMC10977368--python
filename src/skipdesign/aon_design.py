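"""Candidate enumeration, filtering and ranking for splice-switching AONs.

The selection procedure: slide antisense windows of 18-30 nt across the
target region (exon plus intronic flanks), annotate each window with
structural accessibility (mean ss-count openness), enhancer density, GC%,
Tm, AON:target binding energy and self/cross-dimer stability, apply hard
pass/fail filters, and rank the survivors by a weighted composite of
min-max-normalized metrics.  "Partly open and ESE-rich" is operationalized
as: mean openness >= 0.5 (default) and enhancer density rewarded in the
composite; the weights are explicit configuration, not claimed cut-offs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from .folding import SSCountProfile, ss_count_profile, to_rna
from .gene_model import TargetRegion, Transcript, GenomeSequence, extract_target_region, reverse_complement
from .hybridization import (
    NNParameterTable,
    default_nn_table,
    duplex_score,
    gc_content,
    tm_nearest_neighbor,
)
from .splice_signals import MotifHit, MotifLibrary, ese_density, load_default_library, scan_library

logger = logging.getLogger(__name__)

AON_LENGTH_FLOOR = 18
AON_LENGTH_CEIL = 30


class DesignError(ValueError):
    pass


@dataclass
class DesignConfig:
    """All designer knobs with desk-tested defaults.

    Length bounds outside 18-30 nt require ``allow_length_override`` — that
    range is the standard span of splice-switching AON chemistries.  Weights:
    0.3 openness, 0.3 enhancer density, 0.4 thermodynamics split evenly over
    binding energy, self-dimer, cross-dimer, GC deviation and Tm deviation.
    """

    length_min: int = 18
    length_max: int = 30
    allow_length_override: bool = False
    gc_min: float = 0.3
    gc_max: float = 0.7
    tm_min: float = 40.0
    tm_max: float = 95.0
    max_self_dimer_dg: float = 10.0  # fail if self-dimer dG < -10 kcal/mol
    max_cross_dimer_dg: float = 10.0
    min_mean_openness: float = 0.5
    min_ese_density: float = 0.0
    weight_openness: float = 0.3
    weight_ese: float = 0.3
    weight_binding: float = 0.08
    weight_self_dimer: float = 0.08
    weight_cross_dimer: float = 0.08
    weight_gc: float = 0.08
    weight_tm: float = 0.08
    ensemble_size: int = 10
    suboptimal_tolerance: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.length_min > self.length_max:
            raise DesignError("length_min must be <= length_max")
        for L in (self.length_min, self.length_max):
            if not (AON_LENGTH_FLOOR <= L <= AON_LENGTH_CEIL) and not self.allow_length_override:
                raise DesignError(
                    f"AON length {L} outside the standard {AON_LENGTH_FLOOR}-"
                    f"{AON_LENGTH_CEIL} nt range for splice-switching AONs; "
                    "set allow_length_override to force"
                )
        for name in (
            "weight_openness", "weight_ese", "weight_binding",
            "weight_self_dimer", "weight_cross_dimer", "weight_gc", "weight_tm",
        ):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, text: str) -> "DesignConfig":
        import yaml

        data = yaml.safe_load(text) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(asdict(self), sort_keys=False)


@dataclass
class AonCandidate:
    """One antisense window with every metric the ranking consumes."""

    start: int  # window start on the TargetRegion
    length: int
    target_window: str  # sense strand, DNA alphabet
    antisense: str  # 5'->3' RNA alphabet (reverse complement of window)
    gc: float | None = None
    tm: float | None = None
    binding_dg: float | None = None
    self_dimer_dg: float | None = None
    cross_dimer_dg: float | None = None
    mean_openness: float | None = None
    ese_density: float | None = None
    ess_density: float | None = None
    exon_overlap_nt: int | None = None
    passes: dict = field(default_factory=dict)
    composite_score: float | None = None

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def passed_all(self) -> bool:
        return all(self.passes.values()) if self.passes else False


@dataclass
class DesignReport:
    """Ranked candidates plus per-stage and per-criterion bookkeeping."""

    ranked: list[AonCandidate]
    failed: list[AonCandidate]
    failure_counts: dict[str, int]
    stage_counts: dict[str, int]

    @property
    def top(self) -> AonCandidate | None:
        return self.ranked[0] if self.ranked else None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rank, c in enumerate(self.ranked + self.failed, start=1):
            row = {
                "rank": rank if c.passed_all else None,
                "start": c.start,
                "end": c.end,
                "length": c.length,
                "antisense_2omeps": to_2omeps(c.antisense),
                "gc": c.gc,
                "tm": c.tm,
                "binding_dg": c.binding_dg,
                "self_dimer_dg": c.self_dimer_dg,
                "cross_dimer_dg": c.cross_dimer_dg,
                "mean_openness": c.mean_openness,
                "ese_density": c.ese_density,
                "ess_density": c.ess_density,
                "exon_overlap_nt": c.exon_overlap_nt,
                "composite_score": c.composite_score,
                "pass": c.passed_all,
            }
            row.update({f"pass_{k}": v for k, v in c.passes.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        df = self.to_dataframe()
        return json.dumps(
            {
                "stage_counts": self.stage_counts,
                "failure_counts": self.failure_counts,
                "candidates": json.loads(df.to_json(orient="records")),
            },
            indent=2,
        )


def to_2omeps(antisense: str) -> str:
    """Render an antisense sequence in 2'-O-methyl phosphorothioate display
    form: RNA alphabet, uppercase.  Idempotent."""
    up = antisense.upper()
    bad = set(up) - set("ACGTU")
    if bad:
        raise DesignError(f"non-nucleotide characters: {sorted(bad)}")
    return up.replace("T", "U")


def antisense_of(window: str) -> str:
    """The AON sequence hybridizing a sense-strand window: reverse complement
    rendered in the RNA alphabet."""
    return to_2omeps(reverse_complement(window.upper().replace("U", "T")))


def enumerate_candidates(
    region: TargetRegion, cfg: DesignConfig
) -> list[AonCandidate]:
    """All sliding windows of each allowed length, ordered by (start, length)."""
    n = len(region)
    if n <= cfg.length_min:
        raise DesignError(
            f"region length {n} not longer than minimum AON length "
            f"{cfg.length_min}"
        )
    out = []
    for start in range(0, n - cfg.length_min + 1):
        for L in range(cfg.length_min, cfg.length_max + 1):
            if start + L > n:
                break
            window = region.sequence[start : start + L]
            out.append(
                AonCandidate(
                    start=start,
                    length=L,
                    target_window=window,
                    antisense=antisense_of(window),
                )
            )
    logger.info("enumerated %d candidate window(s)", len(out))
    return out


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.5] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def score_and_rank(
    candidates: list[AonCandidate],
    profile: SSCountProfile,
    hits: list[MotifHit],
    cfg: DesignConfig,
    co_aons: list[str] | None = None,
    params: NNParameterTable | None = None,
    exon_span: tuple[int, int] | None = None,
) -> DesignReport:
    """Annotate every candidate, apply hard filters, rank the survivors.

    Composite = weighted sum of min-max-normalized metrics over the passing
    set: openness and net enhancer density rewarded; strong binding rewarded;
    stable self/cross dimers and GC/Tm deviation from the band midpoint
    penalized.  Stable sort; ties broken by the 5'-most window start.
    """
    params = params or default_nn_table()
    co_rna = [to_2omeps(a) for a in (co_aons or [])]
    gc_mid = (cfg.gc_min + cfg.gc_max) / 2
    tm_mid = (cfg.tm_min + cfg.tm_max) / 2

    for c in candidates:
        if c.end > len(profile):
            raise DesignError(
                f"candidate window [{c.start},{c.end}) outside the profile "
                f"of length {len(profile)}"
            )
        c.gc = gc_content(c.antisense)
        c.tm = tm_nearest_neighbor(c.antisense, params=params)
        c.binding_dg = duplex_score(
            c.antisense, to_rna(c.target_window), params=params
        ).delta_g
        c.self_dimer_dg = duplex_score(c.antisense, c.antisense, params=params).delta_g
        c.cross_dimer_dg = (
            min(duplex_score(c.antisense, other, params=params).delta_g for other in co_rna)
            if co_rna
            else 0.0
        )
        c.mean_openness = profile.mean_openness(c.start, c.end)
        c.ese_density = ese_density(hits, c.start, c.length, kind="ESE")
        c.ess_density = ese_density(hits, c.start, c.length, kind="ESS")
        if exon_span is not None:
            lo = max(c.start, exon_span[0])
            hi = min(c.end, exon_span[1])
            c.exon_overlap_nt = max(0, hi - lo)
        c.passes = {
            "gc": cfg.gc_min <= c.gc <= cfg.gc_max,
            "tm": cfg.tm_min <= c.tm <= cfg.tm_max,
            "self_dimer": c.self_dimer_dg >= -cfg.max_self_dimer_dg,
            "cross_dimer": c.cross_dimer_dg >= -cfg.max_cross_dimer_dg,
            "openness": c.mean_openness >= cfg.min_mean_openness,
            "ese": c.ese_density >= cfg.min_ese_density,
        }

    passing = [c for c in candidates if c.passed_all]
    failed = [c for c in candidates if not c.passed_all]
    failure_counts: dict[str, int] = {}
    for c in failed:
        for k, ok in c.passes.items():
            if not ok:
                failure_counts[k] = failure_counts.get(k, 0) + 1
    stage_counts = {
        "enumerated": len(candidates),
        "passing": len(passing),
        "failed": len(failed),
    }
    logger.info("design stages: %s", stage_counts)

    if not passing:
        return DesignReport(
            ranked=[], failed=failed,
            failure_counts=failure_counts, stage_counts=stage_counts,
        )

    open_n = _minmax([c.mean_openness for c in passing])
    ese_n = _minmax([c.ese_density - c.ess_density for c in passing])
    bind_n = _minmax([-c.binding_dg for c in passing])  # stronger binding up
    self_n = _minmax([c.self_dimer_dg for c in passing])  # less stable up
    cross_n = _minmax([c.cross_dimer_dg for c in passing])
    gc_dev = _minmax([abs(c.gc - gc_mid) for c in passing])
    tm_dev = _minmax([abs(c.tm - tm_mid) for c in passing])
    for c, o, e, b, s, x, g, t in zip(
        passing, open_n, ese_n, bind_n, self_n, cross_n, gc_dev, tm_dev
    ):
        c.composite_score = (
            cfg.weight_openness * o
            + cfg.weight_ese * e
            + cfg.weight_binding * b
            + cfg.weight_self_dimer * s
            + cfg.weight_cross_dimer * x
            + cfg.weight_gc * (1 - g)
            + cfg.weight_tm * (1 - t)
        )
    passing.sort(key=lambda c: (-c.composite_score, c.start, c.length))
    return DesignReport(
        ranked=passing, failed=failed,
        failure_counts=failure_counts, stage_counts=stage_counts,
    )


def run_design(
    transcript: Transcript,
    genome: GenomeSequence,
    exon_index: int,
    cfg: DesignConfig | None = None,
    library: MotifLibrary | None = None,
    co_aons: list[str] | None = None,
    flank: int = 50,
) -> tuple[DesignReport, TargetRegion]:
    """Full design pass for one target exon: extract region, fold, scan, rank."""
    cfg = cfg or DesignConfig()
    library = library or load_default_library()
    region = extract_target_region(transcript, exon_index, genome, flank=flank)
    profile = ss_count_profile(
        region.sequence,
        ensemble_size=cfg.ensemble_size,
        tolerance=cfg.suboptimal_tolerance,
    )
    hits = scan_library(region.sequence, library)
    candidates = enumerate_candidates(region, cfg)
    report = score_and_rank(
        candidates, profile, hits, cfg, co_aons=co_aons, exon_span=region.exon_span
    )
    return report, region
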