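"""Mutation-rate backgrounds, the binomial enrichment test, FDR control and
the inflection-point rate threshold.

The model: within a catalogue of candidate regulatory regions, each base pair
of each sample is a Bernoulli trial with success probability equal to the
expected per-bp per-sample mutation rate. A region of length L observed in a
cohort of N samples therefore contributes n = L*N trials, and its total
mutation count k is tested against Binomial(n, background_rate) with the
exact one-sided upper tail P(X >= k).

Two background calibrations are offered. "allsamples" averages the
per-sample rates over the whole cohort and uses the same expectation for
every region. "regionsamples" averages only over the samples actually
mutated in the region under test, which protects against hypermutated
subsets of the cohort inflating or deflating the background for regions they
dominate.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .types import SampleRateTable, ThresholdResult

BACKGROUND_MODES = ("allsamples", "regionsamples")
TRIALS_CONVENTIONS = ("cohort", "mutated")

#: p-values are floored here so that -log10(q) and the (0, 1] invariant stay
#: finite even when the exact tail underflows double precision.
MIN_P = 1e-300


def per_sample_rates(
    snv_counts_in_regions: dict[str, int], total_region_bp: int
) -> SampleRateTable:
    """Per-sample mutation rate inside the merged catalogue.

    rate_s = (in-region SNV count of sample s) / (total region bp). The input
    mapping must cover every cohort sample, including those with zero
    in-region mutations.
    """
    if total_region_bp < 1:
        raise ValueError("total_region_bp must be >= 1 (empty region catalogue?)")
    rates = {s: c / total_region_bp for s, c in snv_counts_in_regions.items()}
    return SampleRateTable(rates=rates, total_region_bp=total_region_bp)


def background_rate(
    mode: str,
    rates: SampleRateTable,
    mutated_samples: Optional[Iterable[str]] = None,
) -> float:
    """Expected per-bp per-sample rate for one region under the chosen mode."""
    if mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {mode!r}; expected one of {BACKGROUND_MODES}")
    if mode == "allsamples":
        return rates.mean_rate()
    if mutated_samples is None:
        raise ValueError("regionsamples mode requires the region's mutated sample set")
    mutated = list(mutated_samples)
    if not mutated:
        raise ValueError(
            "regionsamples background is undefined for a region with no "
            "mutated samples; such regions are skipped upstream"
        )
    return rates.subset_mean(mutated)


def binomial_enrichment_test(
    k: int, region_length: int, n_samples_for_trials: int, background_rate: float
) -> float:
    """Exact one-sided upper-tail binomial p-value P(X >= k).

    X ~ Binomial(region_length * n_samples_for_trials, background_rate).
    Returns 1.0 for k = 0.
    """
    if k < 0:
        raise ValueError("mutation count k must be >= 0")
    if region_length < 1 or n_samples_for_trials < 1:
        raise ValueError("region_length and n_samples_for_trials must be >= 1")
    if not (0.0 < background_rate < 1.0):
        raise ValueError(f"background rate must lie in (0, 1), got {background_rate}")
    n_trials = region_length * n_samples_for_trials
    if k > n_trials:
        raise ValueError(f"k={k} exceeds the trial count {n_trials}")
    if k == 0:
        return 1.0
    p = float(binom.sf(k - 1, n_trials, background_rate))
    return max(p, MIN_P)


def binomial_upper_tail(k: np.ndarray, n_trials: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Vectorised P(X >= k) for X ~ Binomial(n_trials, rate); 1 where k = 0."""
    k = np.asarray(k)
    p = binom.sf(k - 1, np.asarray(n_trials), np.asarray(rate))
    return np.clip(np.where(k <= 0, 1.0, p), MIN_P, 1.0)


def adjust_multiple_testing(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    Order-preserving (q is monotone in p) and bounded in (0, 1]. An empty
    input yields an empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    raw = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def inflection_threshold(region_rates: Sequence[float]) -> ThresholdResult:
    """Hockey-stick cutoff on the ranked per-region mutation rates.

    The rates of all mutated regions are sorted ascending and both axes are
    min-max rescaled to [0, 1]; the threshold is the rate at the first ranked
    point where the rescaled curve climbs at slope >= 1 — the point where the
    curve leaves the flat bulk for the steep tail, in the spirit of the
    tangent rule used to call super-enhancers from ranked signal. The slope
    at a point is that of the segment arriving at it (backward difference;
    the first point uses the forward segment), so the selected point itself
    lies on the steep limb. A constant vector has no tail: the threshold is
    that constant and every region passes.
    """
    rates = np.asarray(sorted(region_rates), dtype=float)
    n = rates.size
    if n == 0:
        raise ValueError("inflection threshold needs at least one mutated region")
    lo, hi = rates[0], rates[-1]
    if n == 1 or hi == lo:
        return ThresholdResult(threshold_rate=float(lo), rank_at_inflection=1)

    x = np.arange(n) / (n - 1)
    y = (rates - lo) / (hi - lo)
    slopes = np.empty(n)
    slopes[1:] = np.diff(y) / np.diff(x)
    slopes[0] = slopes[1]
    # Segment slopes average to 1 over the rescaled curve, so a crossing
    # always exists; the guard covers floating-point shortfall only.
    crossing = np.flatnonzero(slopes >= 1.0 - 1e-12)
    idx = int(crossing[0]) if crossing.size else int(np.argmax(slopes))
    return ThresholdResult(threshold_rate=float(rates[idx]), rank_at_inflection=idx + 1)


def call_significant(results, q_cutoff: float = 0.05, threshold: Optional[ThresholdResult] = None):
    """Apply the significance gate: q <= q_cutoff AND rate >= threshold.

    Both comparisons are inclusive. Mutates and returns the result
    collection. Untested (zero-mutation) regions are never significant.
    """
    if not (0.0 < q_cutoff < 1.0):
        raise ValueError("q_cutoff must lie in (0, 1)")
    for r in results:
        r.passes_rate_threshold = bool(
            threshold is not None
            and r.summary.n_mutations > 0
            and r.summary.region_rate >= threshold.threshold_rate
        )
        r.significant = bool(r.tested and r.q_value <= q_cutoff and r.passes_rate_threshold)
    return results
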