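"""End-to-end enrichment: prefilter -> annotate -> classify -> blacklist -> rank."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .annotate import annotate_calls
from .classify import ClassifierModel, classify
from .filters import (
    CallDatabase,
    blacklist_filter,
    prefilter,
    rank_and_select,
    stage_counts,
)
from .model import BreakpointCall, GenomeTrack, PipelineConfig


def run_enrichment(calls: Sequence[BreakpointCall],
                   tracks: Mapping[str, GenomeTrack],
                   model: Optional[ClassifierModel],
                   databases: Iterable[CallDatabase],
                   sample_id: str = "",
                   config: Optional[PipelineConfig] = None,
                   labels: Optional[Mapping[str, bool]] = None) -> tuple:
    """Run the full filtering cascade on a raw call set.

    ``labels`` (call id -> is_somatic) is optional truth used only for
    stage accounting. Returns ``(top_n, full_ranked, stage_counts_list)``;
    the full ranked list retains translocations after all sized calls.
    """
    config = config or PipelineConfig()
    counts = []

    kept, sc = prefilter(calls, config, labels)
    counts.append(sc)

    annotated = annotate_calls(kept, tracks, config)

    if model is not None:
        scored = classify(model, annotated)
        classified = [c for c in scored if c.annotations.get("rf_label")]
        counts.append(stage_counts("rf_classifier", scored, classified, labels))
    else:
        classified = annotated

    kept2, sc = blacklist_filter(classified, databases, exclude_sample=sample_id,
                                 window=config.overlap_window, labels=labels)
    counts.append(sc)

    top, full = rank_and_select(kept2, config.top_n)
    counts.append(stage_counts(f"top_{config.top_n}", full, top, labels))
    return top, full, counts


def somatic_fraction(calls: Sequence[BreakpointCall],
                     labels: Mapping[str, bool]) -> float:
    """Fraction of calls whose truth label is somatic; 0 for an empty list."""
    if not calls:
        return 0.0
    return sum(1 for c in calls if labels.get(c.id, False)) / len(calls)
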