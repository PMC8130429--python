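"""qPCR triage of breakpoint primer sets and digital-PCR quantification.

Junction-spanning assays amplify only the rearranged (mutant) allele, so
mutant and wild-type molecule concentrations from a digital-PCR chip give
the variant allele frequency (VAF) directly, and — together with the
eluate and plasma accounting — the absolute number of mutant molecules per
millilitre of plasma:

    VAF = m / (m + w) x 100%
    MM/mL = m x V_chip / ((eluate_used / eluate_total) x plasma_volume)

with m, w in molecules/uL in the chip and V_chip the chip input volume
(28 uL). Concentrations are taken as exported by the chip analysis
software; a Poisson back-calculation from droplet counts is offered as an
optional helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class QpcrResult:
    """One qPCR validation of a breakpoint primer set.

    ``cq_germline`` is ``None`` when the germline reaction never crossed the
    threshold (the desired outcome for a somatic junction); ``n_products``
    counts distinct melt-curve peaks.
    """

    primer_set: str
    cq_tumor: float
    cq_germline: Optional[float] = None
    n_products: int = 1

    def __post_init__(self) -> None:
        if self.cq_tumor <= 0:
            raise ValueError("cq_tumor must be positive")
        if self.cq_germline is not None and self.cq_germline <= 0:
            raise ValueError("cq_germline must be positive when present")
        if self.n_products < 0:
            raise ValueError("n_products must be >= 0")


def qpcr_triage(result: QpcrResult,
                max_cq_tumor: float = 20.0,
                min_cq_separation: float = 5.0) -> tuple:
    """Decide whether a primer set qualifies for digital PCR.

    Excluded when any of: more than one PCR product, germline-tumor Cq
    separation below 5 cycles, or tumor Cq above 20. Returns
    ``(decision, reasons)`` with every violated rule listed; an undetected
    germline passes the separation rule (infinite separation) with a note.
    """
    reasons = []
    if result.n_products > 1:
        reasons.append(f">1 PCR product ({result.n_products})")
    if result.cq_germline is None:
        separation = math.inf
        notes = ["germline not amplified; separation rule passed"]
    else:
        separation = result.cq_germline - result.cq_tumor
        notes = []
    if separation < min_cq_separation:
        reasons.append(
            f"Cq_germline - Cq_tumor = {separation:.3g} < {min_cq_separation:g}")
    if result.cq_tumor > max_cq_tumor:
        reasons.append(f"Cq_tumor = {result.cq_tumor:g} > {max_cq_tumor:g}")
    decision = "exclude" if reasons else "include"
    return decision, reasons + notes


@dataclass
class DpcrCounts:
    """Chip-level molecule concentrations and sample accounting for one assay."""

    mutant_per_ul: float
    wt_up_per_ul: Optional[float] = None
    wt_down_per_ul: Optional[float] = None
    chip_input_volume: float = 28.0  # uL loaded into the chip
    eluate_used: float = 0.0         # uL of the cfDNA eluate used
    eluate_total: float = 0.0        # uL total eluate from isolation
    plasma_volume: float = 1.0       # mL plasma the eluate came from
    n_droplets: int = 0

    def __post_init__(self) -> None:
        for name in ("mutant_per_ul", "chip_input_volume", "eluate_used",
                     "eluate_total", "n_droplets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("wt_up_per_ul", "wt_down_per_ul"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.wt_up_per_ul is None and self.wt_down_per_ul is None:
            raise ValueError("at least one wild-type concentration is required")
        if self.eluate_total and self.eluate_used > self.eluate_total:
            raise ValueError("eluate_used must not exceed eluate_total")
        if self.plasma_volume <= 0:
            raise ValueError("plasma_volume must be positive")


def vaf(mutant_per_ul: float, wt_per_ul: float) -> float:
    """Variant allele frequency in percent: 100 x m / (m + w)."""
    if mutant_per_ul < 0 or wt_per_ul < 0:
        raise ValueError("concentrations must be non-negative")
    total = mutant_per_ul + wt_per_ul
    if total == 0:
        raise ValueError("VAF undefined: mutant and wild-type both zero")
    return 100.0 * mutant_per_ul / total


def vaf_per_side(counts: DpcrCounts) -> dict:
    """VAF against each available wild-type side, plus their mean when both
    sides were assayed (sides are the primary outputs; the mean is a
    labeled convenience)."""
    out: dict = {}
    sides = []
    if counts.wt_up_per_ul is not None:
        out["vaf_up"] = vaf(counts.mutant_per_ul, counts.wt_up_per_ul)
        sides.append(out["vaf_up"])
    if counts.wt_down_per_ul is not None:
        out["vaf_down"] = vaf(counts.mutant_per_ul, counts.wt_down_per_ul)
        sides.append(out["vaf_down"])
    if len(sides) == 2:
        out["vaf_mean"] = float(np.mean(sides))
    return out


def mutant_molecules_per_ml(counts: DpcrCounts) -> float:
    """Absolute mutant molecules per mL plasma.

    m x chip_input_volume / ((eluate_used / eluate_total) x plasma_volume).
    """
    if counts.eluate_used == 0 or counts.eluate_total == 0:
        raise ValueError("eluate volumes must be positive to scale to plasma")
    eluate_fraction = counts.eluate_used / counts.eluate_total
    return (counts.mutant_per_ul * counts.chip_input_volume
            / (eluate_fraction * counts.plasma_volume))


def preamp_dilution_factor(input_ng: float, per_ng: float = 40.0) -> float:
    """Dilution applied to pre-amplified cfDNA: 40x per ng of input."""
    if input_ng <= 0:
        raise ValueError("pre-amplification input must be positive")
    return per_ng * input_ng


def log_zero_adjust(values: Sequence[float]) -> np.ndarray:
    """Shift values by +1 so zeros survive a log axis (axes relabel as v-1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError("log-zero adjustment requires non-negative values")
    return arr + 1.0


@dataclass
class ConcordanceResult:
    spearman_rho: float
    slope: float
    intercept: float
    rho_defined: bool = True


def concordance(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """Spearman rank correlation (average ranks on ties) plus OLS slope and
    intercept of y on x, as used to compare paired VAF measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("concordance requires two equal-length series with n >= 3")
    if np.all(x == x[0]):
        # vertical fan: neither rank correlation nor a slope of y on x exists
        return ConcordanceResult(math.nan, math.nan, math.nan, rho_defined=False)
    reg = stats.linregress(x, y)
    if np.all(y == y[0]):
        return ConcordanceResult(math.nan, float(reg.slope), float(reg.intercept),
                                 rho_defined=False)
    rho = stats.spearmanr(x, y).statistic
    return ConcordanceResult(float(rho), float(reg.slope), float(reg.intercept))


def molecules_per_ul_from_droplets(n_positive: int, n_total: int,
                                   droplet_volume_nl: float = 0.59) -> float:
    """Optional Poisson back-calculation from droplet counts.

    lambda = -ln(1 - p/n) molecules per droplet, converted to molecules/uL
    by the droplet volume (default 0.59 nL, a typical crystal dPCR
    partition).
    """
    if not (0 <= n_positive <= n_total) or n_total <= 0:
        raise ValueError("need 0 <= n_positive <= n_total with n_total > 0")
    if n_positive == n_total:
        raise ValueError("all partitions positive: concentration saturated")
    lam = -math.log(1.0 - n_positive / n_total)
    return lam / (droplet_volume_nl * 1e-3)
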