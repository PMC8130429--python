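"""Readers and writers for the pipeline's file formats.

VCF handling supports both dialects emitted by long-read SV callers:
breakend (BND) records with bracket ALTs, written as mate pairs, and
symbolic ALTs (``<DEL>``, ``<DUP>``, ``<INV>``, ``<INS>``) with an ``END``
INFO key. Mate pairs are collapsed to a single :class:`BreakpointCall` on
read. Annotation distances and caller features survive a round trip through
INFO keys.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Optional

import pysam

from .model import (
    Breakend,
    BreakpointCall,
    GenomeTrack,
    SVClass,
    Side,
    canonicalize,
    infer_sv_class,
    sort_calls,
)


class VcfParseError(ValueError):
    """Malformed record in an SV VCF, reported with its line context."""


# t[m[ / t]m] / ]m]t / [m[t  -- the four breakend ALT forms
_BND_RE = re.compile(
    r"^(?P<lead>[A-Za-z.*]*)"
    r"(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)(?P<b2>[\[\]])"
    r"(?P<trail>[A-Za-z.*]*)$"
)

# INFO keys used for round-tripping internal fields
_ANNOT_PREFIX = "DIST_"
_FEATURE_PREFIX = "CF_"
_ANNOT_KEYS = {
    "dist_simple_repeat": "DIST_REPEAT",
    "dist_gap": "DIST_GAP",
    "dist_segmental_duplication": "DIST_SEGDUP",
}
_ANNOT_KEYS_INV = {v: k for k, v in _ANNOT_KEYS.items()}


def _decode_bnd_alt(alt: str) -> tuple:
    """Decode a bracketed breakend ALT.

    Returns ``(side_here, mate_chrom, mate_pos, mate_side)``. Sequence before
    the bracket means the reference flank left of this position is retained;
    sequence after means the right flank is. An opening bracket ``[`` points
    at a mate whose right flank joins the junction, ``]`` at a mate whose
    left flank does.
    """
    m = _BND_RE.match(alt)
    if not m or m.group("b1") != m.group("b2"):
        raise ValueError(f"not a breakend ALT: {alt!r}")
    lead, trail = m.group("lead"), m.group("trail")
    if bool(lead) == bool(trail):
        raise ValueError(f"breakend ALT must carry sequence on exactly one side: {alt!r}")
    side_here = Side.LEFT if lead else Side.RIGHT
    mate_side = Side.RIGHT if m.group("b1") == "[" else Side.LEFT
    return side_here, m.group("chrom"), int(m.group("pos")), mate_side


def _encode_bnd_alt(ref: str, side_here: Side, mate: Breakend) -> str:
    bracket = "[" if mate.side is Side.RIGHT else "]"
    mate_str = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
    if side_here is Side.LEFT:
        return f"{ref}{mate_str}"
    return f"{mate_str}{ref}"


_SYMBOLIC_SIDES = {
    SVClass.DEL: (Side.LEFT, Side.RIGHT),
    SVClass.DUP: (Side.RIGHT, Side.LEFT),
    SVClass.INV: (Side.LEFT, Side.LEFT),
    SVClass.INS: (Side.LEFT, Side.RIGHT),
}


def _info_to_maps(info) -> tuple:
    caller_features: dict = {}
    annotations: dict = {}
    for key, value in info.items():
        if key in ("SVTYPE", "END", "MATEID", "SVLEN", "SIDES"):
            continue
        if isinstance(value, tuple):
            value = value[0]
        if key in _ANNOT_KEYS_INV:
            annotations[_ANNOT_KEYS_INV[key]] = float(value)
        elif key.startswith(_ANNOT_PREFIX):
            annotations[key[len(_ANNOT_PREFIX):].lower()] = float(value)
        elif key.startswith(_FEATURE_PREFIX):
            caller_features[key[len(_FEATURE_PREFIX):].lower()] = float(value)
    return caller_features, annotations


def read_sv_vcf(path: str, sample_id: str = "") -> list:
    """Load an SV VCF into canonical :class:`BreakpointCall` objects.

    BND mate pairs are merged to one call per junction (the mate whose own
    coordinate is the canonical lower end is kept); unmatched mates are kept
    as single records with a warning. The FILTER column is preserved
    verbatim.
    """
    calls: list = []
    seen_junctions: dict = {}
    bnd_keys: set = set()
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf):
            if not rec.alts:
                continue
            alt = rec.alts[0]
            filters = frozenset(rec.filter.keys())
            svtype = rec.info.get("SVTYPE")
            try:
                if alt.startswith("<"):
                    is_bnd = False
                    call = _decode_symbolic(rec, alt, filters, sample_id)
                elif svtype == "BND" or any(b in alt for b in "[]"):
                    is_bnd = True
                    call = _decode_bnd_record(rec, alt, filters, sample_id)
                else:
                    raise ValueError(f"unsupported ALT {alt!r}")
            except ValueError as exc:
                raise VcfParseError(
                    f"{path}: record {i + 1} at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
            key = call.junction_key
            if is_bnd:
                bnd_keys.add(key)
            if key in seen_junctions:
                seen_junctions[key] += 1
                continue
            seen_junctions[key] = 1
            calls.append(call)
    n_unpaired = sum(1 for key in bnd_keys if seen_junctions[key] == 1)
    if n_unpaired:
        warnings.warn(
            f"{path}: {n_unpaired} breakend record(s) without a mate; kept as single calls",
            stacklevel=2,
        )
    return calls


def _decode_symbolic(rec, alt: str, filters, sample_id: str) -> BreakpointCall:
    svtype = alt.strip("<>")
    try:
        sv_class = SVClass(svtype)
    except ValueError as exc:
        raise ValueError(f"unknown symbolic ALT {alt!r}") from exc
    end = rec.stop  # pysam: INFO END, or pos+len(ref)-1
    side_a, side_b = _SYMBOLIC_SIDES[sv_class]
    try:
        sides = rec.info.get("SIDES")
    except (KeyError, ValueError):  # SIDES absent from the header
        sides = None
    if sides:
        if isinstance(sides, tuple):
            sides = ",".join(sides)
        a, b = sides.split(",")
        side_a, side_b = Side(a), Side(b)
    caller_features, annotations = _info_to_maps(rec.info)
    call = BreakpointCall(
        id=rec.id or f"{rec.chrom}_{rec.pos}_{svtype}",
        end_a=Breakend(rec.chrom, rec.pos, side_a),
        end_b=Breakend(rec.chrom, max(end, 1), side_b),
        sv_class=sv_class,
        filter_flags=filters,
        caller_features=caller_features,
        annotations=annotations,
        sample_id=sample_id,
    )
    return canonicalize(call)


def _decode_bnd_record(rec, alt: str, filters, sample_id: str) -> BreakpointCall:
    side_here, mate_chrom, mate_pos, mate_side = _decode_bnd_alt(alt)
    end_a = Breakend(rec.chrom, rec.pos, side_here)
    end_b = Breakend(mate_chrom, mate_pos, mate_side)
    caller_features, annotations = _info_to_maps(rec.info)
    base_id = re.sub(r"_[12]$", "", rec.id) if rec.id else f"{rec.chrom}_{rec.pos}_BND"
    call = BreakpointCall(
        id=base_id,
        end_a=end_a,
        end_b=end_b,
        sv_class=infer_sv_class(end_a, end_b),
        filter_flags=filters,
        caller_features=caller_features,
        annotations=annotations,
        sample_id=sample_id,
    )
    return canonicalize(call)


def _build_header(calls: Iterable[BreakpointCall], contig_lengths: Optional[dict]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="Second breakend position">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length in bp">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend record">')
    header.add_line('##INFO=<ID=SIDES,Number=1,Type=String,Description="Retained sides of the two breakends">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP,Description="Tandem duplication">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    info_keys: set = set()
    filter_keys: set = set()
    chroms: dict = {}
    for call in calls:
        for name in call.annotations:
            info_keys.add(_ANNOT_KEYS.get(name, _ANNOT_PREFIX + name.upper()))
        for name in call.caller_features:
            info_keys.add(_FEATURE_PREFIX + name.upper())
        filter_keys.update(call.filter_flags)
        for end in (call.end_a, call.end_b):
            chroms[end.chrom] = max(chroms.get(end.chrom, 0), end.pos)
    for key in sorted(info_keys):
        header.add_line(f'##INFO=<ID={key},Number=1,Type=Float,Description="svenrich field">')
    for key in sorted(filter_keys - {"PASS"}):
        header.add_line(f'##FILTER=<ID={key},Description="caller filter">')
    if contig_lengths:
        chroms.update(contig_lengths)
    from .model import chrom_sort_key

    for chrom in sorted(chroms, key=chrom_sort_key):
        length = contig_lengths.get(chrom) if contig_lengths else None
        header.contigs.add(chrom, length=length or chroms[chrom] + 1000)
    return header


def _set_common_info(rec, call: BreakpointCall) -> None:
    if call.filter_flags:
        for f in sorted(call.filter_flags):
            rec.filter.add(f)
    for name, value in sorted(call.annotations.items()):
        rec.info[_ANNOT_KEYS.get(name, _ANNOT_PREFIX + name.upper())] = float(value)
    for name, value in sorted(call.caller_features.items()):
        rec.info[_FEATURE_PREFIX + name.upper()] = float(value)


def write_sv_vcf(calls: Iterable[BreakpointCall], path: str,
                 contig_lengths: Optional[dict] = None) -> None:
    """Write calls as VCF: symbolic records for intrachromosomal SVs, BND
    mate pairs for translocations. ``read_sv_vcf(write_sv_vcf(calls))``
    reproduces breakends, class, filters, annotations and caller features."""
    calls = [canonicalize(c) for c in calls]
    header = _build_header(calls, contig_lengths)
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sort_calls(calls):
            if call.sv_class is SVClass.TRA:
                for this, mate, suffix in (
                    (call.end_a, call.end_b, "_1"),
                    (call.end_b, call.end_a, "_2"),
                ):
                    rec = out.new_record(
                        contig=this.chrom, start=this.pos - 1, stop=this.pos,
                        alleles=("N", _encode_bnd_alt("N", this.side, mate)),
                        id=call.id + suffix,
                    )
                    rec.info["SVTYPE"] = "BND"
                    rec.info["MATEID"] = call.id + ("_2" if suffix == "_1" else "_1")
                    _set_common_info(rec, call)
                    out.write(rec)
            else:
                rec = out.new_record(
                    contig=call.end_a.chrom, start=call.end_a.pos - 1,
                    stop=call.end_b.pos,
                    alleles=("N", f"<{call.sv_class.value}>"),
                    id=call.id,
                )
                rec.info["SVTYPE"] = call.sv_class.value
                rec.info["SVLEN"] = call.length
                rec.info["SIDES"] = f"{call.end_a.side.value},{call.end_b.side.value}"
                _set_common_info(rec, call)
                out.write(rec)


def read_bed_track(path: str, name: str) -> GenomeTrack:
    """Read a BED3+ file into a :class:`GenomeTrack` (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return GenomeTrack(name=name, intervals=intervals)


def write_bed_track(track: GenomeTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
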