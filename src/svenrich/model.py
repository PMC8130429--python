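"""Core domain types for somatic structural-variant enrichment.

A structural variant (SV) joins two distant reference loci into a novel
breakpoint junction. Each junction is represented by two :class:`Breakend`
objects, each carrying the reference flank that is *retained* in the derived
allele: ``Side.LEFT`` means the sequence up to and including ``pos`` is
joined into the derived allele, ``Side.RIGHT`` means the sequence from
``pos`` onward is.

Coordinates are 1-based throughout the in-memory model (VCF convention);
annotation tracks use 0-based half-open intervals (BED convention) and are
converted at the interface.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional


class Side(str, enum.Enum):
    """Which reference flank of a breakend is retained in the derived allele."""

    LEFT = "left"
    RIGHT = "right"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SVClass(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    INS = "INS"
    TRA = "TRA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and canonicalize mitochondrial names to ``MT``."""
    m = _CHROM_RE.match(chrom)
    core = m.group(2) if m else chrom
    if core.upper() in {"M", "MT"}:
        return "MT"
    return core


def chrom_sort_key(chrom: str) -> tuple:
    """Fixed chromosome ordering: 1..22, X, Y, MT, then others lexicographic."""
    core = normalize_chrom(chrom)
    if core.isdigit():
        return (0, int(core), "")
    special = {"X": 23, "Y": 24, "MT": 25}
    if core.upper() in special:
        return (0, special[core.upper()], "")
    return (1, 0, core)


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int  # 1-based
    side: Side

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("breakend chromosome must be non-empty")

    @property
    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos)


@dataclass
class BreakpointCall:
    """One SV junction: two breakends plus caller evidence and annotations.

    ``caller_features`` holds numeric evidence from the upstream SV caller
    (supporting read count, mapping qualities, read lengths, quality score);
    ``annotations`` holds distances added by the annotation stage and the
    classifier's score/label. ``length`` is defined only for intrachromosomal
    calls; interchromosomal translocations (TRA) have no length.
    """

    id: str
    end_a: Breakend
    end_b: Breakend
    sv_class: SVClass
    filter_flags: frozenset = frozenset()
    caller_features: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.filter_flags = frozenset(self.filter_flags)
        intra = self.end_a.chrom == self.end_b.chrom
        if self.sv_class is SVClass.TRA and intra:
            raise ValueError(f"{self.id}: TRA requires two different chromosomes")
        if self.sv_class is not SVClass.TRA and not intra:
            raise ValueError(f"{self.id}: interchromosomal call must be TRA")

    @property
    def length(self) -> Optional[int]:
        """SV length in bp; ``None`` for interchromosomal translocations."""
        if self.sv_class is SVClass.TRA:
            return None
        return abs(self.end_b.pos - self.end_a.pos)

    @property
    def junction_key(self) -> tuple:
        """Canonical identity of the junction (ends sorted, orientation kept)."""
        c = canonicalize(self)
        return (
            c.end_a.chrom, c.end_a.pos, c.end_a.side,
            c.end_b.chrom, c.end_b.pos, c.end_b.side,
        )

    @property
    def is_canonical(self) -> bool:
        return self.end_a.sort_key <= self.end_b.sort_key


def canonicalize(call: BreakpointCall) -> BreakpointCall:
    """Return the call with ends ordered by (chromosome, position).

    Idempotent; the retained-side flags travel with their breakends, so the
    junction topology is unchanged.
    """
    if call.is_canonical:
        return call
    return replace(call, end_a=call.end_b, end_b=call.end_a)


def infer_sv_class(end_a: Breakend, end_b: Breakend) -> SVClass:
    """Classify a canonically ordered breakend pair by its orientation.

    Intrachromosomal (left, right) joins delete the intervening segment,
    (right, left) joins duplicate it tandemly, and like-sided joins invert it.
    """
    if end_a.chrom != end_b.chrom:
        return SVClass.TRA
    pair = (end_a.side, end_b.side)
    if pair == (Side.LEFT, Side.RIGHT):
        return SVClass.DEL
    if pair == (Side.RIGHT, Side.LEFT):
        return SVClass.DUP
    return SVClass.INV


@dataclass
class GenomeTrack:
    """Named set of genomic intervals (0-based half-open), e.g. simple repeats."""

    name: str  # one of {"simple_repeat", "gap", "segmental_duplication"}
    intervals: list = field(default_factory=list)  # [(chrom, start, end), ...]

    TRACK_NAMES = ("simple_repeat", "gap", "segmental_duplication")

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.name}: interval {chrom}:{start}-{end} has start >= end"
                )

    def by_chrom(self) -> Mapping[str, list]:
        out: dict = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return out


@dataclass
class PipelineConfig:
    """Tunable constants of the enrichment pipeline.

    Defaults follow the published protocol: mini-amplicons of 30-230 bp,
    Top-20 selection by SV size, a 96% precision / 99.5% recall classifier
    operating point, 40x dilution per ng of pre-amplified cfDNA and a 28 uL
    digital-PCR chip input volume.
    """

    top_n: int = 20
    product_size_range: tuple = (30, 230)
    operating_precision: float = 0.96
    operating_recall: float = 0.995
    overlap_window: int = 100
    preamp_dilution_per_ng: float = 40.0
    chip_input_volume: float = 28.0
    excluded_chromosomes: frozenset = frozenset({"Y", "MT"})
    flank_length: int = 500
    no_element_distance: int = 100_000_000  # sentinel when a track is empty on a chromosome

    def __post_init__(self) -> None:
        lo, hi = self.product_size_range
        if not (0 < lo < hi):
            raise ValueError("product_size_range must satisfy 0 < min < max")
        for name in ("top_n", "overlap_window", "flank_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.operating_precision <= 1 and 0 < self.operating_recall <= 1):
            raise ValueError("operating point fractions must lie in (0, 1]")
        self.excluded_chromosomes = frozenset(
            normalize_chrom(c) for c in self.excluded_chromosomes
        )


def sort_calls(calls: Iterable[BreakpointCall]) -> list:
    """Deterministic genomic ordering of canonical calls."""
    return sorted(calls, key=lambda c: (c.end_a.sort_key, c.end_b.sort_key, c.id))
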