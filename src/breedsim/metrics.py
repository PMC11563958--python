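"""Performance indicators: realized gain, accuracy, variance, allele fates.

Realized genetic gain is the OLS regression slope of the yearly mean true
genetic value of the Stage-1 (parent-recycling) population on the year
index, with every replicate's series centered to zero at Year 0.  Two
horizons are reported: the first 15 years (medium-term) and all 30 years
(long-term).  Prediction accuracy is the Pearson correlation between the
selection scores (GEBVs, or phenotypes for purely phenotypic selection)
and the true genetic values of the candidates at the recycling decision
point.  Genetic variance is the variance of true main-effect genetic
values among the Stage-1 lines; GEI deviations are excluded from this
statistic.  Favorable-allele accounting classifies each QTL by the
frequency of the allele whose additive contribution is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Population
from .trait import TraitArchitecture, genetic_values

__all__ = [
    "GainEstimate",
    "genetic_gain",
    "prediction_accuracy",
    "favorable_allele_frequency",
    "allele_summary",
    "breeders_equation_gain",
    "summarize_recycling_population",
]


@dataclass(frozen=True)
class GainEstimate:
    """OLS regression of centered mean genetic value on breeding year."""

    slope: float
    intercept: float
    horizon: int
    rate_percent: float = np.nan  # slope / reference mean x 100

    def with_reference_mean(self, ref_mean: float) -> "GainEstimate":
        return GainEstimate(self.slope, self.intercept, self.horizon,
                            rate_percent=100.0 * self.slope / ref_mean)


def genetic_gain(series, horizon: int) -> GainEstimate:
    """Least-squares gain per year over years 0..horizon inclusive.

    ``series`` holds the yearly mean genetic values indexed from Year 0.
    """
    y = np.asarray(series, dtype=np.float64)
    if horizon + 1 > y.size:
        raise ValueError(f"horizon {horizon} exceeds the {y.size - 1}-year series")
    x = np.arange(horizon + 1, dtype=np.float64)
    slope, intercept = np.polyfit(x, y[: horizon + 1], 1)
    return GainEstimate(slope=float(slope), intercept=float(intercept),
                        horizon=horizon)


def prediction_accuracy(scores, true_gvs) -> float:
    """Pearson correlation of selection scores with true genetic values."""
    scores = np.asarray(scores, dtype=np.float64)
    true_gvs = np.asarray(true_gvs, dtype=np.float64)
    if scores.size != true_gvs.size:
        raise ValueError("score and genetic-value vectors must align")
    if scores.size < 3:
        raise ValueError("at least three lines are required")
    if np.ptp(scores) == 0 or np.ptp(true_gvs) == 0:
        return np.nan
    return float(np.corrcoef(scores, true_gvs)[0, 1])


def favorable_allele_frequency(pop: Population,
                               arch: TraitArchitecture) -> np.ndarray:
    """Per-QTL frequency of the allele with positive additive effect.

    QTL with an exactly zero additive effect have no favorable allele and
    are returned as NaN (they are excluded from summaries).
    """
    freq1 = pop.allele_frequency(arch.qtl_idx)
    a = arch.additive_effects
    fav = np.where(a > 0, freq1, 1.0 - freq1)
    return np.where(a == 0, np.nan, fav)


def allele_summary(freqs) -> dict:
    """Classify favorable-allele frequencies over the QTL panel.

    Returns percentages of QTL with the favorable allele lost (= 0),
    fixed (= 1), nearly fixed (> 0.90) and rare (< 0.10); ``nearly
    fixed`` includes fixed QTL and ``rare`` includes lost ones, matching
    the base-population summary convention.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    freqs = freqs[~np.isnan(freqs)]
    if freqs.size and (freqs.min() < 0 or freqs.max() > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    n = freqs.size
    pct = lambda k: 100.0 * k / n if n else np.nan
    n_lost = int((freqs == 0).sum())
    n_fixed = int((freqs == 1).sum())
    return {
        "pct_lost": pct(n_lost),
        "pct_fixed": pct(n_fixed),
        "pct_nearly_fixed": pct(int((freqs > 0.90).sum())),
        "pct_rare": pct(int((freqs < 0.10).sum())),
        "n_segregating": n - n_lost - n_fixed,
        "n_qtl": n,
    }


def breeders_equation_gain(intensity: float, accuracy: float,
                           additive_sd: float, cycle_years: float) -> float:
    """Expected gain per year: i * r * sigma_A / L."""
    if cycle_years <= 0:
        raise ValueError("cycle length must be positive")
    if min(intensity, accuracy, additive_sd) <= 0:
        raise ValueError("intensity, accuracy and sigma_A must be positive")
    return intensity * accuracy * additive_sd / cycle_years


def summarize_recycling_population(pop: Population, scores,
                                   arch: TraitArchitecture, year: int,
                                   criterion: str) -> dict:
    """One metrics row for the population at the recycling decision point."""
    gv = genetic_values(pop, arch)  # main-effect values, w = 0
    fav = favorable_allele_frequency(pop, arch)
    row = {
        "year": year,
        "n_candidates": pop.n,
        "mean_gv": float(gv.mean()),
        "var_gv": float(gv.var()),
        "accuracy": prediction_accuracy(scores, gv),
        "criterion": criterion,
    }
    row.update(allele_summary(fav))
    return row
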