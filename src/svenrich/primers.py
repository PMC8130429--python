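"""Breakpoint-junction template construction and primer/probe design.

A somatic SV creates a junction absent from the germline genome. To
validate and later quantify it, a template for the derived allele is
rebuilt from the reference: the retained flank of breakend A (reverse
complemented when its right flank is the retained one) joined to the
retained flank of breakend B. A junction-spanning (mutant) primer pair is
then picked so the amplicon crosses the junction, and wild-type partner
pairs are derived for the reference continuation on each side, each sharing
one primer with the mutant pair.

The picker is a self-contained nearest-neighbor-thermodynamics engine:
candidates of 18-27 nt with Tm 57-63 C (optimum 60) and 20-80% GC are
scored by Tm deviation, pair Tm difference and product-size deviation
within the configured 30-230 bp mini-amplicon range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .model import Breakend, BreakpointCall, PipelineConfig, SVClass, Side, canonicalize

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class JunctionTemplate:
    """Reconstructed derived-allele sequence around one junction.

    ``junction_offset`` is the number of template bases contributed by side
    A, i.e. the 0-based index where side B starts. ``intervals`` records the
    0-based half-open reference interval each half maps back to, and
    ``revcomp_flags`` whether that half was reverse complemented.
    """

    sequence: str
    junction_offset: int
    call_id: str
    flank_length: int
    sides: tuple = (Side.LEFT, Side.RIGHT)
    intervals: tuple = ()        # ((chrom, start, end), (chrom, start, end))
    revcomp_flags: tuple = (False, False)

    def __post_init__(self) -> None:
        if not (1 <= self.junction_offset < len(self.sequence)):
            raise ValueError("junction_offset must split the template in two non-empty halves")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError("template must use the DNA alphabet")


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """0-based half-open fetch tolerant of pyfaidx objects and plain dicts."""
    if hasattr(reference, "keys") and not hasattr(reference, "faidx"):
        seq = reference[chrom][start:end]
    else:
        if chrom not in reference:
            raise KeyError(f"contig {chrom!r} missing from reference")
        seq = str(reference[chrom][start:end])
    return str(seq).upper()


def _contig_length(reference, chrom: str) -> int:
    if hasattr(reference, "faidx"):
        return len(reference[chrom])
    return len(reference[chrom])


def build_junction_template(reference, call: BreakpointCall,
                            flank_length: int = 500) -> JunctionTemplate:
    """Reconstruct the derived-allele sequence crossing the junction.

    Side A retained-left flanks end at ``pos_a`` and read forward;
    retained-right flanks start at ``pos_a`` and are reverse complemented so
    the template always reads 5'->3' into the junction. Side B is the
    mirror case. Flanks are truncated at contig edges.
    """
    if call.sv_class is SVClass.INS:
        raise ValueError("insertions carry novel sequence; no reference template exists")
    c = canonicalize(call)
    halves = []
    for which, end in (("a", c.end_a), ("b", c.end_b)):
        contig_len = _contig_length(reference, end.chrom)
        if end.pos > contig_len:
            raise ValueError(
                f"breakend {end.chrom}:{end.pos} beyond contig end ({contig_len} bp)")
        if end.side is Side.LEFT:
            start, stop = max(0, end.pos - flank_length), end.pos
            seq = _fetch(reference, end.chrom, start, stop)
            rc = which == "b"  # left-retained flank on side B enters the junction reversed
        else:
            start, stop = end.pos - 1, min(contig_len, end.pos - 1 + flank_length)
            seq = _fetch(reference, end.chrom, start, stop)
            rc = which == "a"
        halves.append(((end.chrom, start, stop), revcomp(seq) if rc else seq, rc))
    (iv_a, seq_a, rc_a), (iv_b, seq_b, rc_b) = halves
    if not seq_a or not seq_b:
        raise ValueError(f"{c.id}: empty flank at a contig edge")
    return JunctionTemplate(
        sequence=seq_a + seq_b,
        junction_offset=len(seq_a),
        call_id=c.id,
        flank_length=flank_length,
        sides=(c.end_a.side, c.end_b.side),
        intervals=(iv_a, iv_b),
        revcomp_flags=(rc_a, rc_b),
    )


# ---------------------------------------------------------------------------
# primer picking

@dataclass(frozen=True)
class Primer:
    sequence: str
    start: int   # 0-based template coordinate of the 5'-most template base
    end: int     # half-open; reverse primers anneal to template[start:end]
    strand: int  # +1 forward, -1 reverse
    tm: float


@dataclass
class PrimerAssay:
    """One junction assay: mutant (junction-spanning) pair, optional
    wild-type partners and probes, with per-amplicon product sizes."""

    call_id: str
    sv_forward: Primer
    sv_reverse: Primer
    product_size: int
    score: float
    wt_up: Optional[Primer] = None        # partner for the shared sv primer on side A
    wt_up_product: Optional[int] = None
    wt_down: Optional[Primer] = None      # partner for the shared sv primer on side B
    wt_down_product: Optional[int] = None
    probes: dict = field(default_factory=dict)  # {"SV": seq, "WT-U": seq, "WT-D": seq}
    notes: list = field(default_factory=list)


@dataclass
class PickerSettings:
    """Internal primer-engine parameters (nearest-neighbor Tm, standard
    50 mM Na+ salt correction)."""

    min_length: int = 18
    max_length: int = 27
    min_tm: float = 57.0
    max_tm: float = 63.0
    opt_tm: float = 60.0
    min_gc: float = 20.0
    max_gc: float = 80.0
    product_size_range: tuple = (30, 230)
    size_weight: float = 0.02   # penalty per bp of product-size deviation from midpoint
    probe_tm_offset: float = 8.0
    max_candidates_per_strand: int = 4000


def primer_tm(seq: str) -> float:
    return float(_mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def _gc(seq: str) -> float:
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def _candidates(template: str, lo: int, hi: int, strand: int,
                settings: PickerSettings) -> list:
    """Primer candidates whose annealing site lies in template[lo:hi)."""
    out = []
    n = len(template)
    lo, hi = max(0, lo), min(n, hi)
    for start in range(lo, hi):
        for length in range(settings.min_length, settings.max_length + 1):
            end = start + length
            if end > hi:
                break
            site = template[start:end].upper()
            if "N" in site:
                continue
            gc = _gc(site)
            if not (settings.min_gc <= gc <= settings.max_gc):
                continue
            seq = site if strand > 0 else revcomp(site)
            tm = primer_tm(seq)
            if not (settings.min_tm <= tm <= settings.max_tm):
                continue
            out.append(Primer(seq, start, end, strand, tm))
            if len(out) >= settings.max_candidates_per_strand:
                return out
    return out


def pair_score(fwd: Primer, rev: Primer, product: int,
               settings: PickerSettings) -> float:
    lo, hi = settings.product_size_range
    midpoint = (lo + hi) / 2
    return (abs(fwd.tm - settings.opt_tm) + abs(rev.tm - settings.opt_tm)
            + abs(fwd.tm - rev.tm)
            + settings.size_weight * abs(product - midpoint))


def _best_pairs(fwds: Sequence[Primer], revs: Sequence[Primer],
                settings: PickerSettings, max_pairs: int) -> list:
    lo, hi = settings.product_size_range
    scored = []
    for f in fwds:
        for r in revs:
            if r.start < f.end:  # primers must not overlap
                continue
            product = r.end - f.start
            if not (lo <= product <= hi):
                continue
            scored.append((pair_score(f, r, product, settings), f.start, r.end, f, r, product))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    return scored[:max_pairs]


def design_breakpoint_primers(template: JunctionTemplate,
                              config: Optional[PipelineConfig] = None,
                              settings: Optional[PickerSettings] = None,
                              max_pairs: int = 5) -> list:
    """Design junction-spanning (mutant) primer pairs on a template.

    The forward primer lies entirely left of the junction, the reverse
    primer entirely right of it, so every amplicon crosses the breakpoint.
    Returns assays ranked by score (best first); empty when no pair is
    feasible (short template, masked or low-complexity flanks).
    """
    config = config or PipelineConfig()
    settings = settings or PickerSettings(product_size_range=config.product_size_range)
    lo, hi = settings.product_size_range
    if len(template.sequence) < lo:
        return []
    jo = template.junction_offset
    # only the window within max product size of the junction can matter
    fwds = _candidates(template.sequence, jo - hi, jo, +1, settings)
    fwds = [f for f in fwds if f.end <= jo]
    revs = _candidates(template.sequence, jo, jo + hi, -1, settings)
    revs = [r for r in revs if r.start >= jo]
    assays = []
    for score, _, _, f, r, product in _best_pairs(fwds, revs, settings, max_pairs):
        assays.append(PrimerAssay(
            call_id=template.call_id, sv_forward=f, sv_reverse=r,
            product_size=product, score=score,
        ))
    return assays


def _wildtype_template(reference, end: Breakend, flank_length: int,
                       retained_first: bool) -> JunctionTemplate:
    """Reference locus around one breakend, oriented like the mutant template.

    For a retained-left breakend the window reads forward; for a
    retained-right one it is reverse complemented, so the retained flank
    occupies the same template coordinates as in the mutant template.
    ``retained_first`` is True for side A (retained flank before the
    junction) and False for side B.
    """
    contig_len = _contig_length(reference, end.chrom)
    if end.side is Side.LEFT:
        start = max(0, end.pos - flank_length)
        stop = min(contig_len, end.pos + flank_length)
        seq = _fetch(reference, end.chrom, start, stop)
        offset = end.pos - start
        rc = not retained_first
        if rc:
            seq, offset = revcomp(seq), len(seq) - offset
    else:
        start = max(0, end.pos - 1 - flank_length)
        stop = min(contig_len, end.pos - 1 + flank_length)
        seq = _fetch(reference, end.chrom, start, stop)
        offset = end.pos - 1 - start
        rc = retained_first
        if rc:
            seq, offset = revcomp(seq), len(seq) - offset
    return JunctionTemplate(
        sequence=seq, junction_offset=offset, call_id="wt",
        flank_length=flank_length,
        intervals=((end.chrom, start, stop),) * 2,
        revcomp_flags=(rc, rc),
    )


def design_wildtype_partners(reference, call: BreakpointCall, assay: PrimerAssay,
                             config: Optional[PipelineConfig] = None,
                             settings: Optional[PickerSettings] = None) -> PrimerAssay:
    """Complete a mutant assay with wild-type upstream/downstream partners.

    The wild-type upstream (WT-U) amplicon reuses the mutant primer on side
    A plus one new primer on the reference continuation past breakend A; the
    downstream (WT-D) amplicon mirrors this for side B — each wild-type
    amplicon shares exactly one primer with the mutant pair. A side whose
    continuation is repetitive or low-complexity is omitted with a note, so
    single-sided assays are possible.
    """
    config = config or PipelineConfig()
    settings = settings or PickerSettings(product_size_range=config.product_size_range)
    c = canonicalize(call)
    template = build_junction_template(reference, c, config.flank_length)
    jo = template.junction_offset

    # WT-U: reference continuation past end_a; shared primer = sv_forward
    wt_u = _wildtype_template(reference, c.end_a, config.flank_length, retained_first=True)
    shift_u = wt_u.junction_offset - jo
    f = assay.sv_forward
    f_u = Primer(f.sequence, f.start + shift_u, f.end + shift_u, +1, f.tm)
    revs = _candidates(wt_u.sequence, wt_u.junction_offset,
                       wt_u.junction_offset + settings.product_size_range[1], -1, settings)
    revs = [r for r in revs if r.start >= wt_u.junction_offset]
    pairs = _best_pairs([f_u], revs, settings, 1)
    if pairs:
        _, _, _, _, r, product = pairs[0]
        assay.wt_up, assay.wt_up_product = r, product
    else:
        assay.notes.append("WT-U omitted: no feasible partner primer (repetitive flank)")

    # WT-D: reference continuation before end_b; shared primer = sv_reverse
    wt_d = _wildtype_template(reference, c.end_b, config.flank_length, retained_first=False)
    shift_d = wt_d.junction_offset - jo
    r0 = assay.sv_reverse
    r_d = Primer(r0.sequence, r0.start + shift_d, r0.end + shift_d, -1, r0.tm)
    lo_w = max(0, wt_d.junction_offset - settings.product_size_range[1])
    fwds = _candidates(wt_d.sequence, lo_w, wt_d.junction_offset, +1, settings)
    fwds = [fc for fc in fwds if fc.end <= wt_d.junction_offset]
    pairs = _best_pairs(fwds, [r_d], settings, 1)
    if pairs:
        _, _, _, fw, _, product = pairs[0]
        assay.wt_down, assay.wt_down_product = fw, product
    else:
        assay.notes.append("WT-D omitted: no feasible partner primer (repetitive flank)")
    return assay


def design_probes(template: JunctionTemplate, assay: PrimerAssay,
                  settings: Optional[PickerSettings] = None) -> PrimerAssay:
    """Optional hydrolysis probes: the mutant probe spans the junction, at a
    Tm about 8 C above the primers."""
    settings = settings or PickerSettings()
    probe_settings = PickerSettings(
        min_length=settings.min_length, max_length=settings.max_length + 3,
        min_tm=settings.min_tm + settings.probe_tm_offset - 2,
        max_tm=settings.max_tm + settings.probe_tm_offset + 2,
        opt_tm=settings.opt_tm + settings.probe_tm_offset,
        product_size_range=settings.product_size_range,
    )
    jo = template.junction_offset
    inner_lo, inner_hi = assay.sv_forward.end, assay.sv_reverse.start
    cands = _candidates(template.sequence, inner_lo, inner_hi, +1, probe_settings)
    spanning = [p for p in cands if p.start < jo < p.end]
    if spanning:
        best = min(spanning, key=lambda p: (abs(p.tm - probe_settings.opt_tm), p.start))
        assay.probes["SV"] = best.sequence
    else:
        assay.notes.append("SV probe omitted: no junction-spanning candidate")
    return assay


def write_assays_tsv(assays: Sequence[PrimerAssay], path: str) -> None:
    """TSV export: one row per primer/probe with role, position, Tm, product size."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["call_id", "role", "sequence", "start", "tm", "product_size"])
        for a in assays:
            rows = [
                ("SV-F", a.sv_forward, a.product_size),
                ("SV-R", a.sv_reverse, a.product_size),
            ]
            if a.wt_up:
                rows.append(("WT-U", a.wt_up, a.wt_up_product))
            if a.wt_down:
                rows.append(("WT-D", a.wt_down, a.wt_down_product))
            for role, p, size in rows:
                w.writerow([a.call_id, role, p.sequence, p.start, f"{p.tm:.2f}", size])
            for role, seq in sorted(a.probes.items()):
                w.writerow([a.call_id, f"probe-{role}", seq, "", "", ""])
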