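"""Deterministic enrichment filters: pre-filter, panel-of-normal blacklist
and size ranking.

These are the cumulative steps that, together with the classifier, enrich a
raw long-read SV call set for patient-specific somatic junctions without
matched germline data. Stage-level bookkeeping (:class:`StageCounts`) tracks
how many calls — and, when truth labels are available, how many somatic
calls — survive each step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import (
    Breakend,
    BreakpointCall,
    PipelineConfig,
    SVClass,
    Side,
    canonicalize,
    normalize_chrom,
)


@dataclass
class StageCounts:
    """Call accounting for one pipeline stage (conservation: in = out + removed)."""

    stage: str
    calls_in: int
    calls_out: int
    somatic_in: Optional[int] = None
    somatic_out: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.calls_out <= self.calls_in):
            raise ValueError(f"{self.stage}: calls_out must lie in [0, calls_in]")

    @property
    def removed(self) -> int:
        return self.calls_in - self.calls_out


def _count_somatic(calls, labels):
    if labels is None:
        return None
    return sum(1 for c in calls if labels.get(c.id, False))


def stage_counts(stage: str, calls_in, calls_out, labels=None) -> StageCounts:
    return StageCounts(
        stage=stage,
        calls_in=len(calls_in),
        calls_out=len(calls_out),
        somatic_in=_count_somatic(calls_in, labels),
        somatic_out=_count_somatic(calls_out, labels),
    )


def write_stage_counts(counts: Iterable[StageCounts], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["stage", "calls_in", "calls_out", "somatic_in", "somatic_out"])
        for c in counts:
            w.writerow([c.stage, c.calls_in, c.calls_out,
                        "" if c.somatic_in is None else c.somatic_in,
                        "" if c.somatic_out is None else c.somatic_out])


@dataclass(frozen=True)
class DbEntry:
    """One panel-of-normal junction, canonically ordered."""

    sample_id: str
    end_a: Breakend
    end_b: Breakend

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("database entry requires a sample_id")
        if self.end_a.sort_key > self.end_b.sort_key:
            a, b = self.end_a, self.end_b
            object.__setattr__(self, "end_a", b)
            object.__setattr__(self, "end_b", a)


@dataclass
class CallDatabase:
    """Panel-of-normal breakpoint collection with per-sample provenance.

    ``use_orientation=False`` disables retained-side matching in overlap
    tests, for databases derived from callers with lossy orientation.
    """

    name: str  # "sharc_db" or "ref_db"
    entries: list = field(default_factory=list)
    source: str = ""
    use_orientation: bool = True

    @classmethod
    def from_calls(cls, name: str, calls: Iterable[BreakpointCall], **kw) -> "CallDatabase":
        entries = [
            DbEntry(c.sample_id, canonicalize(c).end_a, canonicalize(c).end_b)
            for c in calls
        ]
        return cls(name=name, entries=entries, **kw)

    def write_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sample_id", "chrom_a", "pos_a", "side_a",
                        "chrom_b", "pos_b", "side_b"])
            for e in self.entries:
                w.writerow([e.sample_id, e.end_a.chrom, e.end_a.pos, e.end_a.side.value,
                            e.end_b.chrom, e.end_b.pos, e.end_b.side.value])

    @classmethod
    def read_tsv(cls, path: str, name: str, **kw) -> "CallDatabase":
        entries = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                entries.append(DbEntry(
                    row["sample_id"],
                    Breakend(row["chrom_a"], int(row["pos_a"]), Side(row["side_a"])),
                    Breakend(row["chrom_b"], int(row["pos_b"]), Side(row["side_b"])),
                ))
        return cls(name=name, entries=entries, source=path, **kw)


def prefilter(calls: Iterable[BreakpointCall],
              config: Optional[PipelineConfig] = None,
              labels: Optional[Mapping[str, bool]] = None) -> tuple:
    """Keep only PASS calls, drop insertions and calls touching excluded
    chromosomes (Y / MT by default). Order is preserved.

    A call passes iff its FILTER set is exactly {PASS}; a missing filter
    ('.') counts as non-PASS.
    """
    config = config or PipelineConfig()
    calls = list(calls)
    excluded = config.excluded_chromosomes
    kept = [
        c for c in calls
        if c.filter_flags == frozenset({"PASS"})
        and normalize_chrom(c.end_a.chrom) not in excluded
        and normalize_chrom(c.end_b.chrom) not in excluded
        and c.sv_class is not SVClass.INS
    ]
    return kept, stage_counts("prefilter", calls, kept, labels)


def overlaps(call: BreakpointCall, entry: DbEntry, window: int,
             match_orientation: bool = True) -> bool:
    """True when both breakends of ``call`` lie within ``window`` bp of the
    entry's breakends on the same chromosome pair (and, by default, with the
    same retained-side orientation). Symmetric in its two arguments."""
    if window < 0:
        raise ValueError("window must be >= 0")
    c = canonicalize(call)
    if (c.end_a.chrom, c.end_b.chrom) != (entry.end_a.chrom, entry.end_b.chrom):
        return False
    if abs(c.end_a.pos - entry.end_a.pos) > window:
        return False
    if abs(c.end_b.pos - entry.end_b.pos) > window:
        return False
    if match_orientation and (c.end_a.side, c.end_b.side) != (entry.end_a.side, entry.end_b.side):
        return False
    return True


def blacklist_filter(calls: Iterable[BreakpointCall],
                     databases: Iterable[CallDatabase],
                     exclude_sample: str = "",
                     window: int = 100,
                     labels: Optional[Mapping[str, bool]] = None) -> tuple:
    """Remove calls matching any panel-of-normal entry from another sample.

    Entries whose ``sample_id`` equals ``exclude_sample`` are ignored, so a
    sample present in the panel does not blacklist itself.
    """
    calls = list(calls)
    databases = list(databases)
    known = {"sharc_db", "ref_db"}
    for db in databases:
        if db.name not in known:
            raise ValueError(f"unknown database name {db.name!r} (expected one of {sorted(known)})")
    # bucket entries by chromosome pair for linear-time scans
    buckets: dict = {}
    for db in databases:
        for e in db.entries:
            if e.sample_id == exclude_sample:
                continue
            buckets.setdefault((e.end_a.chrom, e.end_b.chrom), []).append(
                (e, db.use_orientation))
    kept = []
    for call in calls:
        c = canonicalize(call)
        hits = buckets.get((c.end_a.chrom, c.end_b.chrom), ())
        if not any(overlaps(c, e, window, match_orientation=use_or)
                   for e, use_or in hits):
            kept.append(call)
    return kept, stage_counts("blacklist", calls, kept, labels)


def rank_and_select(calls: Iterable[BreakpointCall], top_n: int = 20) -> tuple:
    """Rank calls by descending SV length and select the Top-N.

    Interchromosomal translocations have no defined length, so they are
    placed after all sized calls in the full ranked list and never enter the
    Top-N (they remain available for manual selection). Ties are broken by
    (chromosome, position) ascending.
    """
    sized, tra = [], []
    for call in calls:
        (tra if call.sv_class is SVClass.TRA else sized).append(canonicalize(call))
    sized.sort(key=lambda c: (-c.length, c.end_a.sort_key, c.end_b.sort_key, c.id))
    tra.sort(key=lambda c: (c.end_a.sort_key, c.end_b.sort_key, c.id))
    full = sized + tra
    return sized[:top_n], full
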