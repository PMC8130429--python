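"""Junction templates and primer design: construction oracles, remapping,
product-size and junction-spanning postconditions."""

import itertools

import numpy as np
import pytest

from svenrich.model import Breakend, BreakpointCall, SVClass, Side
from svenrich.primers import (
    PickerSettings,
    build_junction_template,
    design_breakpoint_primers,
    design_wildtype_partners,
    pair_score,
    primer_tm,
    revcomp,
    _candidates,
)

TOY = {"chr1": "AAAACCCCGGGGTTTT"}


def mkcall(call_id, chrom_a, pos_a, side_a, chrom_b, pos_b, side_b):
    ea, eb = Breakend(chrom_a, pos_a, side_a), Breakend(chrom_b, pos_b, side_b)
    from svenrich.model import infer_sv_class
    return BreakpointCall(call_id, ea, eb, infer_sv_class(ea, eb))


class TestJunctionTemplate:
    def test_deletion_join_manual_oracle(self):
        call = mkcall("d", "chr1", 4, Side.LEFT, "chr1", 13, Side.RIGHT)
        t = build_junction_template(TOY, call, flank_length=4)
        assert t.sequence == "AAAATTTT"
        assert t.junction_offset == 4

    def test_inversion_join_reverse_complements_second_flank(self):
        call = mkcall("i", "chr1", 4, Side.LEFT, "chr1", 12, Side.LEFT)
        t = build_junction_template(TOY, call, flank_length=4)
        assert t.sequence == "AAAA" + revcomp("GGGG")  # AAAACCCC
        assert t.junction_offset == 4

    def test_right_right_join(self):
        call = mkcall("i2", "chr1", 5, Side.RIGHT, "chr1", 13, Side.RIGHT)
        t = build_junction_template(TOY, call, flank_length=4)
        # side A right flank CCCC reverse complemented + side B right flank TTTT
        assert t.sequence == revcomp("CCCC") + "TTTT"

    def test_flank_truncated_at_contig_edges(self):
        call = mkcall("d", "chr1", 2, Side.LEFT, "chr1", 15, Side.RIGHT)
        t = build_junction_template(TOY, call, flank_length=10)
        assert t.sequence == "AA" + "TT"
        assert t.junction_offset == 2

    def test_breakend_beyond_contig_rejected(self):
        call = mkcall("d", "chr1", 4, Side.LEFT, "chr1", 999, Side.RIGHT)
        with pytest.raises(ValueError, match="beyond contig"):
            build_junction_template(TOY, call, flank_length=4)

    def test_insertion_has_no_reference_template(self):
        call = BreakpointCall("x", Breakend("chr1", 4, Side.LEFT),
                              Breakend("chr1", 8, Side.RIGHT), SVClass.INS)
        with pytest.raises(ValueError, match="novel sequence"):
            build_junction_template(TOY, call, 4)

    def test_remapping_recovers_source_intervals(self, random_reference):
        """Splitting at the junction and undoing recorded reverse
        complements must reproduce the two reference intervals exactly."""
        rng = np.random.default_rng(77)
        contigs = list(random_reference)
        for i in range(300):
            ca, cb = (contigs[0], contigs[0]) if rng.random() < 0.7 else contigs
            pa = int(rng.integers(600, 29_000))
            pb = int(rng.integers(600, 29_000))
            if ca == cb:
                pa, pb = sorted((pa, pb))
                if pb - pa < 2:
                    continue
            sa = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
            sb = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
            ea, eb = Breakend(ca, pa, sa), Breakend(cb, pb, sb)
            from svenrich.model import infer_sv_class
            call = BreakpointCall(f"f{i}", ea, eb, infer_sv_class(ea, eb))
            t = build_junction_template(random_reference, call,
                                        flank_length=int(rng.integers(20, 500)))
            halves = (t.sequence[:t.junction_offset], t.sequence[t.junction_offset:])
            for half, (chrom, start, end), rc in zip(halves, t.intervals,
                                                     t.revcomp_flags):
                source = random_reference[chrom][start:end]
                assert (revcomp(half) if rc else half) == source


@pytest.fixture(scope="module")
def template(random_reference):
    call = mkcall("d", "chr1", 8_000, Side.LEFT, "chr1", 22_000, Side.RIGHT)
    return build_junction_template(random_reference, call, flank_length=400)


class TestPrimerDesign:
    def test_products_span_junction_within_size_range(self, template):
        assays = design_breakpoint_primers(template)
        assert assays
        for a in assays:
            assert 30 <= a.product_size <= 230
            assert a.sv_forward.end <= template.junction_offset <= a.sv_reverse.start
            assert a.product_size == a.sv_reverse.end - a.sv_forward.start

    def test_primers_occur_once_in_amplicon_context(self, template):
        for a in design_breakpoint_primers(template):
            amplicon = template.sequence[a.sv_forward.start:a.sv_reverse.end]
            assert amplicon.count(a.sv_forward.sequence) == 1
            assert amplicon.count(revcomp(a.sv_reverse.sequence)) == 1

    def test_short_template_yields_empty_list(self):
        call = mkcall("d", "chr1", 8, Side.LEFT, "chr1", 14, Side.RIGHT)
        t = build_junction_template(TOY, call, flank_length=8)
        assert design_breakpoint_primers(t) == []

    def test_determinism(self, template):
        a1 = design_breakpoint_primers(template)
        a2 = design_breakpoint_primers(template)
        assert [(x.sv_forward, x.sv_reverse) for x in a1] == \
               [(x.sv_forward, x.sv_reverse) for x in a2]

    def test_best_pair_matches_exhaustive_enumeration(self, random_reference):
        """Oracle: enumerate every candidate window pair under the same
        score and compare with the picker's choice."""
        call = mkcall("d", "chr1", 2_000, Side.LEFT, "chr1", 12_000, Side.RIGHT)
        t = build_junction_template(random_reference, call, flank_length=120)
        settings = PickerSettings()
        assays = design_breakpoint_primers(t, settings=settings, max_pairs=1)
        jo = t.junction_offset
        best = None
        n = len(t.sequence)
        for f_start in range(0, jo):
            for f_len in range(settings.min_length, settings.max_length + 1):
                f_end = f_start + f_len
                if f_end > jo:
                    break
                fseq = t.sequence[f_start:f_end]
                if not self._ok(fseq, settings):
                    continue
                f_tm = primer_tm(fseq)
                if not (settings.min_tm <= f_tm <= settings.max_tm):
                    continue
                for r_start in range(jo, n):
                    for r_len in range(settings.min_length, settings.max_length + 1):
                        r_end = r_start + r_len
                        if r_end > n:
                            break
                        product = r_end - f_start
                        if not (settings.product_size_range[0] <= product
                                <= settings.product_size_range[1]):
                            continue
                        rseq = revcomp(t.sequence[r_start:r_end])
                        if not self._ok(rseq, settings):
                            continue
                        r_tm = primer_tm(rseq)
                        if not (settings.min_tm <= r_tm <= settings.max_tm):
                            continue
                        from svenrich.primers import Primer
                        score = pair_score(Primer(fseq, f_start, f_end, 1, f_tm),
                                           Primer(rseq, r_start, r_end, -1, r_tm),
                                           product, settings)
                        key = (score, f_start, r_end)
                        if best is None or key < best[0]:
                            best = (key, fseq, rseq)
        if assays:
            assert best is not None
            assert (assays[0].sv_forward.sequence,
                    assays[0].sv_reverse.sequence) == (best[1], best[2])
        else:
            assert best is None

    @staticmethod
    def _ok(seq, settings):
        if "N" in seq:
            return False
        gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        return settings.min_gc <= gc <= settings.max_gc


class TestWildtypePartners:
    def test_both_sides_share_exactly_one_primer(self, random_reference):
        call = mkcall("d", "chr1", 8_000, Side.LEFT, "chr1", 22_000, Side.RIGHT)
        t = build_junction_template(random_reference, call, flank_length=400)
        assay = design_breakpoint_primers(t)[0]
        assay = design_wildtype_partners(random_reference, call, assay)
        assert assay.wt_up is not None and assay.wt_down is not None
        # WT-U shares the forward primer; its partner differs from the mutant reverse
        assert assay.wt_up.sequence != assay.sv_reverse.sequence
        assert assay.wt_down.sequence != assay.sv_forward.sequence
        assert 30 <= assay.wt_up_product <= 230
        assert 30 <= assay.wt_down_product <= 230

    def test_low_complexity_flank_gives_single_sided_assay(self, random_reference):
        # poly-A continuation upstream of end_b: no WT-D partner primer exists
        seq = random_reference["chr1"]
        doctored = {"chr1": seq[:22_000] + "A" * 3_000 + seq[25_000:]}
        call = mkcall("d", "chr1", 8_000, Side.LEFT, "chr1", 25_001, Side.RIGHT)
        t = build_junction_template(doctored, call, flank_length=400)
        assays = design_breakpoint_primers(t)
        if not assays:  # mutant pair itself may be infeasible on poly-A flank
            pytest.skip("no mutant pair on doctored reference")
        assay = design_wildtype_partners(doctored, call, assays[0])
        assert (assay.wt_up is None) or (assay.wt_down is None)
        assert any("omitted" in n for n in assay.notes)
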