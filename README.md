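# svenrich

Enrichment of **patient-specific somatic structural variants (SVs)** from
low-coverage long-read sequencing call sets — without matched germline data —
plus breakpoint-junction PCR assay design and digital-PCR quantification of
circulating tumor DNA (ctDNA).

## Who this is for

A single nanopore flow cell of tumor DNA (1–5x coverage) yields thousands of
raw SV calls of which typically well under 1% are somatic; the rest are
sequencing artifacts and germline variants. `svenrich` implements the
computational side of turning that raw call set into a handful of validated,
patient-specific breakpoint junctions usable as liquid-biopsy biomarkers:

1. **Pre-filter** — keep `PASS` calls, drop insertions and calls touching
   chromosome Y or MT.
2. **Annotation** — distance of each junction to the nearest simple repeat,
   assembly gap and segmental duplication (interval index over BED tracks).
3. **Random-forest classification** — true/false labels at a
   precision–recall operating point (default 96% precision / 99.5% recall)
   selected on a 100-round bootstrap curve over a 90%–10% re-partition of
   the training portion of a 2/3–1/3 split.
4. **Panel-of-normal blacklist** — remove junctions matching any entry of
   two breakpoint databases (long-read panel + short-read germline
   controls) within ±100 bp per breakend, excluding the query sample itself.
5. **Ranking** — order by SV length and select the Top-20 for PCR
   validation; interchromosomal translocations have no length and stay in
   the full ranked output only.
6. **Assay design** — rebuild the derived-allele junction template from the
   reference, pick junction-spanning (mutant) primer pairs with 30–230 bp
   mini-amplicons and wild-type partner pairs that each share one primer
   with the mutant pair.
7. **Quantification** — qPCR triage of primer sets (exclude if >1 product,
   Cq separation < 5 cycles, or tumor Cq > 20) and dPCR math:

   VAF = m / (m + w) × 100%,  MM/mL = m × V_chip / ((V_used/V_total) × V_plasma)

   with m, w the mutant / wild-type molecules per µL in the chip and V_chip
   the 28 µL chip input.

Every stage is backed by a seeded synthetic-data generator (reference
genome, annotation tracks, labeled call sets, panel-of-normal databases,
dPCR chip tables), so the complete workflow runs and is tested without any
external downloads.

## Worked example

```sh
svenrich simulate --seed 7 --out-dir fixtures
svenrich train    --seed 7 --out model.joblib
svenrich enrich \
    --vcf fixtures/calls.vcf \
    --simple-repeat fixtures/simple_repeat.bed \
    --gap fixtures/gap.bed \
    --segdup fixtures/segmental_duplication.bed \
    --model model.joblib \
    --sharc-db fixtures/sharc_db.tsv --ref-db fixtures/ref_db.tsv \
    --sample-id tumor --labels fixtures/labels.tsv \
    --out-dir run
```

`train` prints the held-out metrics of the classifier (1500 labeled calls,
2/3–1/3 split, 100 bootstrap rounds):

```json
{
  "precision": 0.9765625,
  "recall": 1.0,
  "accuracy": 0.988,
  "threshold": 0.01
}
```

`enrich` logs the per-stage call accounting (total and, because a truth
label table was supplied, somatic counts):

```
[prefilter]     570 -> 346 (somatic 20 -> 20)
[rf_classifier] 346 ->  69 (somatic 20 -> 20)
[blacklist]      69 ->  23 (somatic 20 -> 20)
[top_20]         23 ->  20 (somatic 20 -> 18)
```

Reading: the raw synthetic call set is 3.5% somatic (20/570); the cascade
removes non-PASS/insertion/Y-MT calls, then artifact calls, then germline
calls shared with the panel of normals, without losing a single somatic
junction, and the final Top-20 is 90% somatic (two somatic translocations
have no length and therefore stay out of the Top-20). `run/top_n.tsv` holds
the ranked selection, `run/ranked.vcf` the full annotated ranking, and
`run/manifest.json` enough to reproduce the run byte-for-byte
(`svenrich enrich --from-manifest run/manifest.json --out-dir rerun`).

Primer assays and dPCR quantification:

```sh
svenrich primers  --reference fixtures/reference.fa --vcf run/ranked.vcf --out assays.tsv
svenrich quantify --table fixtures/dpcr.tsv --out quant.tsv
```

`assays.tsv` lists, per junction, the mutant pair (SV-F/SV-R) and wild-type
partners (WT-U/WT-D) with positions, melting temperatures and product sizes
(all within 30–230 bp); `quant.tsv` reports the VAF against each wild-type
side (plus their mean) and mutant molecules per mL plasma, e.g. a simulated
timepoint with true VAF 8% yields `vaf_up 8.07, vaf_down 7.97, 61 MM/mL`.

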