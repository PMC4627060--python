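"""Screening arithmetic and the polyclonal 96-well founder model.

After co-electroporation, the outgrowth culture is distributed across a
96-well plate instead of being plated.  With N kanamycin-resistant
founder cells spread over W wells, the number of founders seeding a
well is well modeled as Poisson with rate lambda = N / W (the observed
131-463 colonies per experiment give lambda ~ 1.4-4.8, i.e. the
expected "~1-4 founders per well").  Each founder independently
carries the co-targeted loxP with probability f (the per-colony
co-targeting frequency, 0.24-6.2% in the initial single-colony screen
and far higher in later projects).  A well types loxP-positive when it
received at least one co-targeted founder, hence

    P(positive well) = 1 - exp(-lambda * f)

and the inverse maps a well-level positive fraction back to a
per-colony frequency:  f_hat = -ln(1 - k/W) / lambda.  PCR sensitivity
and within-well competition are ignored (the protocol cultures wells
long enough for kanR bacteria to dominate before screening).

The module also reproduces the published screening tables from their
raw counts and the pooled-BAC risk arithmetic (~10% of library clones
are incorrect; pooling two independent clones gives ~1% risk that both
are bad).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PlateScreen",
    "FreqSummary",
    "frequency_summary",
    "founders_per_well",
    "predict_positive_well_fraction",
    "estimate_cotargeting_freq",
    "pooled_bac_failure_risk",
    "simulate_plates",
    "INITIAL_SCREEN",
    "WELL_SCREEN",
]


@dataclass
class PlateScreen:
    """One 96-well (or partial-plate) CoSBR screen."""

    colonies: int
    wells: int
    positives: int
    cotargeting_freq: float | None = None

    def __post_init__(self) -> None:
        if self.wells <= 0:
            raise ValueError("wells must be positive")
        if not (0 <= self.positives <= self.wells):
            raise ValueError("positives must lie in [0, wells]")
        if self.cotargeting_freq is not None and not (0 <= self.cotargeting_freq <= 1):
            raise ValueError("cotargeting_freq must lie in [0, 1]")

    @property
    def founder_rate(self) -> float:
        return founders_per_well(self.colonies, self.wells)


@dataclass
class FreqSummary:
    """k/n with both published display conventions."""

    k: int
    n: int
    fraction: float
    percent_2sf: str   # two significant figures, e.g. "6.2", "0.65"
    percent_whole: str  # nearest whole percent, e.g. "36"


def frequency_summary(k: int, n: int) -> FreqSummary:
    """Exact fraction plus two-significant-figure and whole-percent display."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    frac = k / n
    pct = 100 * frac
    two_sf = "0" if k == 0 else f"{pct:.2g}"
    whole = str(int(math.floor(pct + 0.5)))
    return FreqSummary(k, n, frac, two_sf, whole)


def founders_per_well(colonies: int, wells: int) -> float:
    """Poisson founder rate lambda = colonies / wells."""
    if wells <= 0:
        raise ValueError("wells must be positive")
    if colonies < 0:
        raise ValueError("colonies must be non-negative")
    return colonies / wells


def predict_positive_well_fraction(lam: float, f: float) -> float:
    """P(a well is loxP-positive) under the Poisson founder model.

    Founders ~ Poisson(lam), each independently co-targeted with
    probability f; a well is positive when it received >= 1 co-targeted
    founder, so the co-targeted founders are Poisson(lam*f) and
    P(positive) = 1 - exp(-lam*f).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not (0 <= f <= 1):
        raise ValueError("f must lie in [0, 1]")
    return 1.0 - math.exp(-lam * f)


def estimate_cotargeting_freq(
    screen: PlateScreen, conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Invert the founder model: per-colony frequency from well counts.

    Returns ``(f_hat, (lo, hi))`` with f_hat = -ln(1 - k/W)/lambda
    clamped to [0, 1] and a confidence interval obtained by transforming
    an exact (Clopper-Pearson) binomial interval on k/W.  A saturated
    plate (all wells positive) leaves f unidentifiable and errors.
    """
    lam = screen.founder_rate
    if lam <= 0:
        raise ValueError("founder rate must be positive to estimate f")
    k, w = screen.positives, screen.wells
    if k == w:
        raise ValueError("all wells positive: f is unidentifiable (saturated plate)")

    def to_f(p: float) -> float:
        return min(1.0, max(0.0, -math.log1p(-p) / lam))

    alpha = 1 - conf_level
    lo_p = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, w - k + 1)
    hi_p = stats.beta.ppf(1 - alpha / 2, k + 1, w - k)
    return to_f(k / w), (to_f(lo_p), to_f(min(hi_p, 1 - 1e-12)))


def pooled_bac_failure_risk(per_clone_bad: float, n_clones: int) -> float:
    """Risk that every clone in a pool is incorrect (independent clones)."""
    if not (0 <= per_clone_bad <= 1):
        raise ValueError("per_clone_bad must lie in [0, 1]")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    return per_clone_bad**n_clones


def simulate_plates(
    lam: float, f: float, wells: int, n_plates: int, rng: np.random.Generator
) -> np.ndarray:
    """Positive-well counts for simulated plates under the founder model.

    Each well draws Poisson(lam) founders; each founder is co-targeted
    with probability f; the well scores positive if any founder is.
    """
    founders = rng.poisson(lam, size=(n_plates, wells))
    cotargeted = rng.binomial(founders, f)
    return (cotargeted > 0).sum(axis=1)


# ---------------------------------------------------------------------------
# Published CoSBR screening data (inputs for reproduction)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenRow:
    gene: str
    clone: str
    orientation: str  # gene transcription relative to the insert's T7->Sp6 arrow
    oligo: str        # "lagging" | "leading"
    colonies: int
    loxp_positive: int
    printed_pct: str
    printed_consistent: bool = True


#: Initial single-colony CoSBR screen: per-colony co-targeting frequencies
#: for five genes / eight BAC clones with lagging- and leading-strand
#: oligos.  The Tnfsf15 lagging row is internally inconsistent in the
#: original table (6/143 recomputes to 4.2%, not the printed 3.5%) and is
#: flagged accordingly.
INITIAL_SCREEN: tuple[ScreenRow, ...] = (
    ScreenRow("Casp1", "RP23-78A8", "Sp6_to_T7", "lagging", 369, 23, "6.2"),
    ScreenRow("Casp1", "RP23-78A8", "Sp6_to_T7", "leading", 225, 7, "3.1"),
    ScreenRow("Casp1", "RP23-101E5", "T7_to_Sp6", "lagging", 131, 2, "1.5"),
    ScreenRow("Casp1", "RP23-101E5", "T7_to_Sp6", "leading", 154, 1, "0.65"),
    ScreenRow("Nnmt", "RP23-268F15", "T7_to_Sp6", "lagging", 318, 15, "4.7"),
    ScreenRow("Nnmt", "RP23-268F15", "T7_to_Sp6", "leading", 248, 3, "1.2"),
    ScreenRow("Nnmt", "RP23-280F20", "T7_to_Sp6", "lagging", 224, 1, "0.45"),
    ScreenRow("Nnmt", "RP23-280F20", "T7_to_Sp6", "leading", 148, 0, "0"),
    ScreenRow("Tnfsf15", "RP23-162E5", "T7_to_Sp6", "lagging", 143, 6, "3.5", False),
    ScreenRow("Tnfsf15", "RP23-162E5", "T7_to_Sp6", "leading", 178, 0, "0"),
    ScreenRow("Keap1", "RP23-311A18", "T7_to_Sp6", "lagging", 357, 4, "1.1"),
    ScreenRow("Keap1", "RP23-311A18", "T7_to_Sp6", "leading", 345, 4, "1.2"),
    ScreenRow("Usp10", "RP23-371H2", "Sp6_to_T7", "lagging", 428, 9, "2.1"),
    ScreenRow("Usp10", "RP23-371H2", "Sp6_to_T7", "leading", 463, 8, "1.7"),
    ScreenRow("Usp10", "RP23-1P14", "Sp6_to_T7", "lagging", 422, 1, "0.24"),
    ScreenRow("Usp10", "RP23-1P14", "Sp6_to_T7", "leading", 414, 8, "1.9"),
)


@dataclass(frozen=True)
class WellRow:
    gene: str
    clone: str
    stage: str  # "wells" | "retrievals" | "error_free"
    k: int
    n: int
    printed_pct: str


#: Liquid-culture 96-well protocol results (95 screening wells per plate;
#: two wells of each plate hold controls): loxP-positive well fractions,
#: loxP-positive retrievals, and error-free loxP rates.
WELL_SCREEN: tuple[WellRow, ...] = (
    WellRow("Cdh11", "RP23-60C23", "wells", 34, 95, "36"),
    WellRow("Cdh11", "RP23-60C23", "retrievals", 6, 21, "29"),
    WellRow("Cdh11", "RP23-60C23", "error_free", 6, 6, "100"),
    WellRow("Cdh11", "RP23-35E14", "wells", 2, 95, "2"),
    WellRow("S100A8", "RP23-6E18", "wells", 60, 95, "63"),
    WellRow("S100A8", "RP23-6E18", "retrievals", 6, 17, "35"),
    WellRow("S100A8", "RP23-6E18", "error_free", 5, 6, "83"),
    WellRow("S100A8", "RP23-189H20/229K18", "wells", 51, 95, "54"),
)
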