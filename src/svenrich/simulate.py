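"""Seeded synthetic data for every pipeline stage.

Real inputs to the pipeline — a reference genome, UCSC annotation tracks, a
raw long-read SV call set dominated by artifacts, panel-of-normal
databases and digital-PCR chip exports — are all emulated here at desk
scale so the complete workflow is testable without downloads.

The default scenario mirrors the structure of a low-coverage nanopore tumor
call set: a small minority of somatic junctions with strong read support
placed away from repeats, germline junctions shared with the
panel-of-normal databases, and a large majority of false-positive calls
with weak support clustered near repeat elements. Somatic calls are
constructed to be absent from the panel of normals; germline calls are
injected into it with position jitter so window-overlap matching is
exercised non-trivially. All outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import TruthLabelSet
from .filters import CallDatabase, DbEntry
from .model import (
    Breakend,
    BreakpointCall,
    GenomeTrack,
    SVClass,
    Side,
    canonicalize,
)

_SIDES_BY_CLASS = {
    SVClass.DEL: (Side.LEFT, Side.RIGHT),
    SVClass.DUP: (Side.RIGHT, Side.LEFT),
    SVClass.INV: (Side.LEFT, Side.LEFT),
    SVClass.INS: (Side.LEFT, Side.RIGHT),
}


@dataclass
class FeatureParams:
    """Class-conditional caller-feature distributions (lognormal/Poisson
    families). ``support`` is 2 + Poisson(support_rate), matching a 2-read
    caller threshold."""

    support_rate: float
    mapq_mean: float
    mapq_sd: float
    read_length_log_mean: float
    read_length_log_sd: float
    score_mean: float
    score_sd: float


@dataclass
class SimScenario:
    """Parameters of one synthetic study; defaults are the package's
    standard desk-scale conditions."""

    seed: int = 0
    # genome
    contig_lengths: Mapping[str, int] = field(default_factory=lambda: {
        "chr1": 500_000, "chr2": 500_000, "chr3": 500_000, "chr4": 500_000,
        "chrY": 50_000, "chrMT": 16_000,
    })
    gc: float = 0.41
    # annotation tracks (expected counts per 100 kb and length ranges, bp)
    repeat_density: float = 20.0
    repeat_length: tuple = (50, 500)
    gap_density: float = 0.4
    gap_length: tuple = (1_000, 10_000)
    segdup_density: float = 1.0
    segdup_length: tuple = (1_000, 20_000)
    # call-set composition
    n_somatic: int = 20
    n_germline: int = 50
    n_fp: int = 500
    somatic_length: tuple = (50_000, 400_000)
    germline_length: tuple = (1_000, 50_000)
    fp_length: tuple = (60, 10_000)
    tra_fraction: float = 0.1
    ins_fraction_fp: float = 0.1
    ins_fraction_germline: float = 0.1
    fp_nonpass_fraction: float = 0.3
    fp_excluded_chrom_fraction: float = 0.1
    fp_near_repeat_bp: int = 200
    somatic_repeat_clearance: int = 2_000
    # class-conditional features
    true_features: FeatureParams = field(default_factory=lambda: FeatureParams(
        support_rate=8.0, mapq_mean=55.0, mapq_sd=4.0,
        read_length_log_mean=np.log(8_000), read_length_log_sd=0.4,
        score_mean=0.85, score_sd=0.08))
    fp_features: FeatureParams = field(default_factory=lambda: FeatureParams(
        support_rate=0.5, mapq_mean=25.0, mapq_sd=6.0,
        read_length_log_mean=np.log(4_000), read_length_log_sd=0.6,
        score_mean=0.30, score_sd=0.10))
    # panel of normals
    n_pon_samples: int = 10
    pon_fraction_germline: float = 0.9
    pon_fraction_fp: float = 0.8
    pon_decoys_per_sample: int = 20
    overlap_window: int = 100
    # classifier truth set
    n_truth: int = 1_500
    truth_positive_fraction: float = 0.5
    # digital PCR
    vaf_trajectory: tuple = (8.0, 4.0, 1.0, 0.0, 2.0, 12.0)
    wt_per_ul: float = 50.0
    n_droplets: int = 21_000
    eluate_used: float = 40.0
    eluate_total: float = 80.0
    plasma_volume_ml: float = 4.0
    chip_input_volume: float = 28.0

    def __post_init__(self) -> None:
        for chrom, length in self.contig_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length contig {chrom!r}")
        for v in self.vaf_trajectory:
            if not (0 <= v <= 100):
                raise ValueError("VAF trajectory values must lie in [0, 100]")
        if min(self.n_somatic, self.n_germline, self.n_fp) < 0:
            raise ValueError("call counts must be non-negative")

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v

        return plain(dataclasses.asdict(self))


# ---------------------------------------------------------------------------
# reference and tracks

def simulate_reference(scenario: SimScenario) -> dict:
    """Deterministic random genome: {contig: sequence} at the configured
    GC content (P(G) = P(C) = gc/2)."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    gc = scenario.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    out = {}
    for chrom, length in scenario.contig_lengths.items():
        idx = rng.choice(4, size=length, p=probs)
        out[chrom] = "".join(bases[idx])
    return out


def write_fasta(reference: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_tracks(scenario: SimScenario) -> dict:
    """Simple-repeat, gap and segmental-duplication tracks with Poisson
    element counts per contig and uniform element placement."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    specs = {
        "simple_repeat": (scenario.repeat_density, scenario.repeat_length),
        "gap": (scenario.gap_density, scenario.gap_length),
        "segmental_duplication": (scenario.segdup_density, scenario.segdup_length),
    }
    tracks = {}
    for name, (density, (lo, hi)) in specs.items():
        intervals = []
        for chrom, length in scenario.contig_lengths.items():
            n = rng.poisson(density * length / 100_000)
            for _ in range(n):
                el_len = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, max(1, length - el_len)))
                intervals.append((chrom, start, start + el_len))
        tracks[name] = GenomeTrack(name=name, intervals=sorted(intervals))
    return tracks


# ---------------------------------------------------------------------------
# call sets

def _draw_features(rng, params: FeatureParams) -> dict:
    return {
        "support": float(2 + rng.poisson(params.support_rate)),
        "mapq": float(np.clip(rng.normal(params.mapq_mean, params.mapq_sd), 0, 60)),
        "read_length": float(rng.lognormal(params.read_length_log_mean,
                                           params.read_length_log_sd)),
        "score": float(np.clip(rng.normal(params.score_mean, params.score_sd), 0, 1)),
    }


def _min_repeat_distance(pos_list, repeat_positions) -> int:
    if not len(repeat_positions):
        return 10**9
    arr = np.asarray(repeat_positions)
    return int(min(np.abs(arr - p).min() for p in pos_list))


def _place_intra(rng, contigs, lengths, length_range, margin=1_000):
    lo, hi = length_range
    for _ in range(1_000):
        chrom = contigs[rng.integers(len(contigs))]
        clen = lengths[chrom]
        sv_len = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if clen - sv_len - 2 * margin <= margin:
            continue
        pos_a = int(rng.integers(margin, clen - sv_len - margin))
        return chrom, pos_a, pos_a + sv_len
    raise ValueError("could not place call: requested calls exceed genome capacity")


def _make_call(call_id, chrom_a, pos_a, chrom_b, pos_b, sv_class, rng,
               features, filters=("PASS",), sample_id="") -> BreakpointCall:
    chrom_a, chrom_b = str(chrom_a), str(chrom_b)
    if sv_class is SVClass.TRA:
        side_a = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
        side_b = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
    else:
        side_a, side_b = _SIDES_BY_CLASS[sv_class]
    call = BreakpointCall(
        id=call_id,
        end_a=Breakend(chrom_a, pos_a, side_a),
        end_b=Breakend(chrom_b, pos_b, side_b),
        sv_class=sv_class,
        filter_flags=frozenset(filters),
        caller_features=features,
        sample_id=sample_id,
    )
    return canonicalize(call)


def simulate_callset(scenario: SimScenario,
                     reference: Optional[Mapping[str, str]] = None,
                     tracks: Optional[Mapping[str, GenomeTrack]] = None,
                     sample_id: str = "tumor") -> tuple:
    """Generate the tumor call set, its truth labels and the PON databases.

    Returns ``(calls, labels, (sharc_db, ref_db))`` where ``labels`` maps
    call id to one of {"somatic", "germline", "fp"}. Somatic junctions are
    guaranteed to have no panel-of-normal entry within the overlap window;
    germline (and most false-positive) junctions are injected into the
    databases under other sample ids with uniform jitter of up to half the
    window on each breakend.
    """
    tracks = tracks if tracks is not None else simulate_tracks(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    lengths = dict(scenario.contig_lengths)
    main_contigs = [c for c in lengths
                    if c not in ("chrY", "chrMT") and lengths[c] >= 100_000]
    excl_contigs = [c for c in lengths if c in ("chrY", "chrMT")]
    capacity = sum(lengths[c] for c in main_contigs)
    if (scenario.n_somatic + scenario.n_germline + scenario.n_fp) * 2_000 > capacity:
        raise ValueError("requested calls exceed genome capacity")

    repeat_pos = {}
    for chrom, start, end in tracks["simple_repeat"].intervals:
        repeat_pos.setdefault(chrom, []).append((start + end) // 2)

    calls, labels = [], {}
    pon_sources = []  # (call, pon_fraction) to inject into databases
    somatic_ends = {}  # chrom -> [pos, ...] for decoy avoidance

    # somatic: large, strong support, away from simple repeats, never in PON
    n_som_tra = int(round(scenario.n_somatic * scenario.tra_fraction))
    for i in range(scenario.n_somatic):
        feats = _draw_features(rng, scenario.true_features)
        for _ in range(200):
            if i < n_som_tra and len(main_contigs) > 1:
                ca, cb = rng.choice(main_contigs, size=2, replace=False)
                pa = int(rng.integers(1_000, lengths[ca] - 1_000))
                pb = int(rng.integers(1_000, lengths[cb] - 1_000))
                cls = SVClass.TRA
            else:
                ca, pa, pb = _place_intra(rng, main_contigs, lengths,
                                          scenario.somatic_length)
                cb = ca
                cls = SVClass(["DEL", "DUP", "INV"][int(rng.integers(3))])
            clearance = min(
                _min_repeat_distance([pa], repeat_pos.get(ca, [])),
                _min_repeat_distance([pb], repeat_pos.get(cb, [])))
            if clearance >= scenario.somatic_repeat_clearance:
                break
        call = _make_call(f"som_{i:04d}", ca, pa, cb, pb, cls, rng, feats,
                          sample_id=sample_id)
        calls.append(call)
        labels[call.id] = "somatic"
        somatic_ends.setdefault(call.end_a.chrom, []).append(call.end_a.pos)
        somatic_ends.setdefault(call.end_b.chrom, []).append(call.end_b.pos)

    # germline: mid-sized, strong support, shared with the panel of normals
    for i in range(scenario.n_germline):
        feats = _draw_features(rng, scenario.true_features)
        if rng.random() < scenario.ins_fraction_germline:
            ca, pa, pb = _place_intra(rng, main_contigs, lengths, (100, 1_000))
            cls = SVClass.INS
        else:
            ca, pa, pb = _place_intra(rng, main_contigs, lengths,
                                      scenario.germline_length)
            cls = SVClass(["DEL", "DUP", "INV"][int(rng.integers(3))])
        call = _make_call(f"grm_{i:04d}", ca, pa, ca, pb, cls, rng, feats,
                          sample_id=sample_id)
        calls.append(call)
        labels[call.id] = "germline"
        pon_sources.append((call, scenario.pon_fraction_germline))

    # false positives: weak support, near repeats, often non-PASS
    n_fp_tra = int(round(scenario.n_fp * scenario.tra_fraction))
    for i in range(scenario.n_fp):
        feats = _draw_features(rng, scenario.fp_features)
        filters = ("PASS",)
        if rng.random() < scenario.fp_nonpass_fraction:
            filters = (["LowQual", "Gap", "SVcluster"][int(rng.integers(3))],)
        on_excl = excl_contigs and rng.random() < scenario.fp_excluded_chrom_fraction
        if rng.random() < scenario.ins_fraction_fp:
            ca, pa, pb = _place_intra(rng, main_contigs, lengths, (100, 1_000))
            cls = SVClass.INS
            cb = ca
        elif on_excl:
            cb = excl_contigs[int(rng.integers(len(excl_contigs)))]
            ca = main_contigs[int(rng.integers(len(main_contigs)))]
            pa = int(rng.integers(1_000, lengths[ca] - 1_000))
            pb = int(rng.integers(1_000, lengths[cb] - 1_000))
            cls = SVClass.TRA
        elif i < n_fp_tra and len(main_contigs) > 1:
            ca, cb = rng.choice(main_contigs, size=2, replace=False)
            pa = _near_repeat(rng, ca, lengths, repeat_pos, scenario)
            pb = _near_repeat(rng, cb, lengths, repeat_pos, scenario)
            cls = SVClass.TRA
        else:
            ca, pa, pb = _place_intra(rng, main_contigs, lengths, scenario.fp_length)
            cb = ca
            shift = pa - _near_repeat(rng, ca, lengths, repeat_pos, scenario)
            pa, pb = max(1, pa - shift), max(2, pb - shift)
            if pa == pb:
                pb += 1
            cls = SVClass(["DEL", "DUP", "INV"][int(rng.integers(3))])
        call = _make_call(f"fpc_{i:04d}", ca, pa, cb, pb, cls, rng, feats,
                          filters=filters, sample_id=sample_id)
        calls.append(call)
        labels[call.id] = "fp"
        pon_sources.append((call, scenario.pon_fraction_fp))

    sharc_db, ref_db = _build_pon(scenario, rng, pon_sources, somatic_ends,
                                  main_contigs, lengths)
    return calls, labels, (sharc_db, ref_db)


def _near_repeat(rng, chrom, lengths, repeat_pos, scenario) -> int:
    positions = repeat_pos.get(chrom)
    if positions:
        center = positions[int(rng.integers(len(positions)))]
        pos = center + int(rng.integers(-scenario.fp_near_repeat_bp,
                                        scenario.fp_near_repeat_bp + 1))
        return int(np.clip(pos, 1_000, lengths[chrom] - 1_000))
    return int(rng.integers(1_000, lengths[chrom] - 1_000))


def _build_pon(scenario, rng, pon_sources, somatic_ends, main_contigs, lengths):
    """Panel-of-normal databases: jittered copies of germline/FP junctions
    under other sample ids, plus random decoy junctions kept clear of every
    somatic breakend."""
    pon_samples = [f"pon_{i:02d}" for i in range(scenario.n_pon_samples)]
    half = max(1, scenario.overlap_window // 2)
    guard_inject = 2 * scenario.overlap_window

    def clear_of_somatic(c) -> bool:
        for end in (c.end_a, c.end_b):
            near = somatic_ends.get(end.chrom, [])
            if near and min(abs(p - end.pos) for p in near) <= guard_inject:
                return False
        return True

    sharc_entries, ref_entries = [], []
    for call, fraction in pon_sources:
        if rng.random() >= fraction:
            continue
        c = canonicalize(call)
        if not clear_of_somatic(c):
            # keep the somatic-absence guarantee: never seed the panel near
            # a somatic breakend
            continue
        n_carriers = 1 + int(rng.integers(0, 3))
        carriers = rng.choice(pon_samples, size=min(n_carriers, len(pon_samples)),
                              replace=False)
        for sample in carriers:
            ja = int(rng.integers(-half, half + 1))
            jb = int(rng.integers(-half, half + 1))
            entry = DbEntry(
                str(sample),
                Breakend(c.end_a.chrom, max(1, c.end_a.pos + ja), c.end_a.side),
                Breakend(c.end_b.chrom, max(1, c.end_b.pos + jb), c.end_b.side),
            )
            (sharc_entries if rng.random() < 0.7 else ref_entries).append(entry)

    guard = 2 * scenario.overlap_window
    for sample in pon_samples:
        for _ in range(scenario.pon_decoys_per_sample):
            for _ in range(100):
                chrom = main_contigs[int(rng.integers(len(main_contigs)))]
                pa = int(rng.integers(1_000, lengths[chrom] - 60_000))
                pb = pa + int(rng.integers(500, 50_000))
                near = somatic_ends.get(chrom, [])
                if near and min(min(abs(p - pa), abs(p - pb)) for p in near) <= guard:
                    continue
                cls = SVClass(["DEL", "DUP", "INV"][int(rng.integers(3))])
                sa, sb = _SIDES_BY_CLASS[cls]
                entry = DbEntry(str(sample), Breakend(chrom, pa, sa),
                                Breakend(chrom, pb, sb))
                (sharc_entries if rng.random() < 0.5 else ref_entries).append(entry)
                break
    sharc_db = CallDatabase(name="sharc_db", entries=sharc_entries,
                            source="synthetic nanopore panel")
    ref_db = CallDatabase(name="ref_db", entries=ref_entries,
                          source="synthetic short-read controls",
                          use_orientation=False)
    return sharc_db, ref_db


# ---------------------------------------------------------------------------
# classifier truth set

def simulate_truthset(scenario: SimScenario) -> TruthLabelSet:
    """Labeled training set with class-conditional feature distributions.

    True calls carry strong read evidence and large repeat distances; false
    calls weak evidence near repeats. Annotation distances are drawn
    directly (lognormal), so the set is self-contained for training.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 4]))
    n_pos = int(round(scenario.n_truth * scenario.truth_positive_fraction))
    n_neg = scenario.n_truth - n_pos
    items = []
    order = [True] * n_pos + [False] * n_neg
    for i, is_true in enumerate(order):
        params = scenario.true_features if is_true else scenario.fp_features
        feats = _draw_features(rng, params)
        # distances reflect track sparsity: simple repeats are dense (near
        # for artifacts, a few kb away for real junctions) while gaps and
        # segmental duplications are sparse, so even artifacts are usually
        # tens of kb from them
        if is_true:
            dists = [rng.lognormal(np.log(5_000), 0.8),
                     rng.lognormal(np.log(100_000), 1.0),
                     rng.lognormal(np.log(30_000), 1.0)]
        else:
            dists = [rng.lognormal(np.log(60), 1.0)]
            for far in (100_000, 30_000):
                if rng.random() < 0.2:
                    dists.append(rng.lognormal(np.log(200), 1.0))
                else:
                    dists.append(rng.lognormal(np.log(far), 1.0))
        pos_a = int(rng.integers(10_000, 10_000_000))
        length = int(rng.integers(200, 100_000))
        cls = SVClass(["DEL", "DUP", "INV"][int(rng.integers(3))])
        sa, sb = _SIDES_BY_CLASS[cls]
        call = BreakpointCall(
            id=f"truth_{i:05d}",
            end_a=Breakend("chr1", pos_a, sa),
            end_b=Breakend("chr1", pos_a + length, sb),
            sv_class=cls,
            filter_flags=frozenset({"PASS"}),
            caller_features=feats,
            annotations={
                "dist_simple_repeat": float(dists[0]),
                "dist_gap": float(dists[1]),
                "dist_segmental_duplication": float(dists[2]),
            },
        )
        items.append((call, is_true))
    return TruthLabelSet(items)


# ---------------------------------------------------------------------------
# digital PCR

def simulate_dpcr(scenario: SimScenario) -> pd.DataFrame:
    """Chip-level dPCR measurement table along the configured VAF trajectory.

    Molecule counts are Poisson draws whose expectations satisfy
    vaf(mutant, wt) = truth; a zero truth VAF yields exactly zero mutant
    counts. One row per timepoint with the full :class:`~svenrich.quant.DpcrCounts`
    field set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 5]))
    rows = []
    for t, true_vaf in enumerate(scenario.vaf_trajectory):
        w = scenario.wt_per_ul
        m_expected = 0.0 if true_vaf == 0 else w * true_vaf / (100.0 - true_vaf)
        volume = scenario.chip_input_volume
        m = rng.poisson(m_expected * volume) / volume
        wt_up = rng.poisson(w * volume) / volume
        wt_down = rng.poisson(w * volume) / volume
        rows.append({
            "patient": "sim", "timepoint": t, "assay": "SV-A",
            "true_vaf": true_vaf,
            "mutant_per_ul": float(m),
            "wt_up_per_ul": float(wt_up),
            "wt_down_per_ul": float(wt_down),
            "chip_input_volume": volume,
            "eluate_used": scenario.eluate_used,
            "eluate_total": scenario.eluate_total,
            "plasma_volume": scenario.plasma_volume_ml,
            "n_droplets": int(rng.normal(scenario.n_droplets,
                                         scenario.n_droplets * 0.05)),
        })
    return pd.DataFrame(rows)
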