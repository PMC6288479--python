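"""Posterior summaries: MAP estimates, marginal histograms, credible
intervals, prediction overlays and identifiability flags.

The maximum-posterior-density (MAP) point is the argmax of the stored
log-posteriors over the starting point and the retained chain.  Marginal
identifiability is judged with two operational heuristics mirroring the
qualitative criteria used when inspecting marginal histograms:

* *flat*: the 95% credible interval spans more than 80% of the prior
  range (the data barely narrowed the prior);
* *multimodal*: the 3-bin-smoothed histogram has more than one local
  maximum exceeding 20% of the global maximum.

Both thresholds are configurable and reported alongside the raw
marginals, so users can apply their own judgment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import HergfitError
from .fitting_io import FittingProblem
from .inference import PosteriorSample

__all__ = [
    "MarginalSummary",
    "PredictionOverlay",
    "map_estimate",
    "credible_interval",
    "marginal_histogram",
    "prediction_overlay",
    "identifiability_flags",
]


@dataclass
class MarginalSummary:
    """One parameter's marginal posterior: histogram, moments, equal-tailed
    credible interval, mode estimate, and identifiability flags."""

    parameter: str
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    std: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    mode: float
    flat: bool
    multimodal: bool


@dataclass
class PredictionOverlay:
    """Aligned (time, observed, predicted) triples with residual summary."""

    table: pd.DataFrame
    rmse: float
    residual_mean: float
    residual_std: float


def map_estimate(
    sample: PosteriorSample,
    theta0: Optional[np.ndarray] = None,
    theta0_log_posterior: Optional[float] = None,
) -> np.ndarray:
    """Maximum-posterior-density point: argmax over {theta0} ∪ chain,
    ties broken by earliest occurrence (theta0 first).

    ``theta0`` defaults to the starting point stored on the sample.
    """
    if sample.n_retained == 0:
        raise HergfitError("empty chain")
    if theta0 is None:
        theta0 = sample.theta0
        theta0_log_posterior = sample.theta0_log_posterior
    best = int(np.argmax(sample.log_posteriors))
    best_lp = float(sample.log_posteriors[best])
    if theta0 is not None and theta0_log_posterior is not None:
        if theta0_log_posterior >= best_lp:
            return np.asarray(theta0, dtype=float).copy()
    return sample.chain[best].copy()


def credible_interval(
    sample: PosteriorSample, parameter: str, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed empirical credible interval via linearly interpolated
    quantiles at (1-level)/2 and 1-(1-level)/2."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    column = sample.column(parameter)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(column, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _smooth(counts: np.ndarray, window: int = 3) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def _count_modes(counts: np.ndarray, rel_height: float, valley_fraction: float = 0.5) -> int:
    """Distinct modes of the smoothed histogram.

    Candidate modes are local maxima above ``rel_height`` × the global
    maximum; adjacent candidates are merged unless the valley between them
    drops below ``valley_fraction`` of the smaller peak (sampling noise on
    a unimodal histogram produces shoulder maxima with shallow valleys,
    which must not count as extra modes).
    """
    smoothed = _smooth(counts)
    peak = smoothed.max()
    if peak <= 0:
        return 0
    threshold = rel_height * peak
    n = smoothed.size
    candidates: list[int] = []
    i = 0
    while i < n:
        left = smoothed[i - 1] if i > 0 else -np.inf
        # treat plateaus as a single candidate
        j = i
        while j + 1 < n and smoothed[j + 1] == smoothed[i]:
            j += 1
        right = smoothed[j + 1] if j + 1 < n else -np.inf
        if smoothed[i] >= threshold and smoothed[i] > left and smoothed[i] > right:
            candidates.append(i)
        i = j + 1
    # merge shoulder peaks separated only by shallow valleys
    merged = True
    while merged and len(candidates) > 1:
        merged = False
        for k in range(len(candidates) - 1):
            a, b = candidates[k], candidates[k + 1]
            valley = smoothed[a : b + 1].min()
            if valley >= valley_fraction * min(smoothed[a], smoothed[b]):
                drop = k if smoothed[a] <= smoothed[b] else k + 1
                del candidates[drop]
                merged = True
                break
    return len(candidates)


def marginal_histogram(
    sample: PosteriorSample,
    parameter: str,
    bins: int = 50,
    ci_level: float = 0.95,
    flat_fraction: float = 0.8,
    mode_rel_height: float = 0.2,
) -> MarginalSummary:
    """Histogram + moments + credible interval + flags for one parameter.

    The histogram spans the retained-sample range; the mode estimate is
    the centre of the fullest bin.  The *flat* flag needs the prior range
    (stored on the sample by the inference pipeline); it is False when the
    range is unavailable.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    column = sample.column(parameter)
    lo, hi = float(column.min()), float(column.max())
    if lo == hi:  # degenerate: a single occupied bin
        edges = np.linspace(lo - 0.5, hi + 0.5, bins + 1)
    else:
        edges = np.linspace(lo, hi, bins + 1)
    counts, edges = np.histogram(column, bins=edges)
    centres = 0.5 * (edges[:-1] + edges[1:])
    ci_lo, ci_hi = credible_interval(sample, parameter, ci_level)

    flat = False
    if sample.free_lower is not None and sample.free_upper is not None:
        i = sample.free_names.index(parameter)
        prior_range = float(sample.free_upper[i] - sample.free_lower[i])
        flat = (ci_hi - ci_lo) > flat_fraction * prior_range

    multimodal = _count_modes(counts, mode_rel_height) > 1

    return MarginalSummary(
        parameter=parameter,
        bin_edges=edges,
        counts=counts,
        mean=float(column.mean()),
        std=float(column.std(ddof=0)),
        ci_level=ci_level,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        mode=float(centres[int(np.argmax(counts))]),
        flat=bool(flat),
        multimodal=bool(multimodal),
    )


def prediction_overlay(problem: FittingProblem, theta: np.ndarray) -> PredictionOverlay:
    """Simulate at ``theta`` and align predictions with the observations."""
    predicted = problem.simulate_currents(np.asarray(theta, dtype=float))
    residuals = problem.observed - predicted
    table = pd.DataFrame(
        {
            "time": problem.times,
            "observed": problem.observed,
            "predicted": predicted,
        }
    )
    return PredictionOverlay(
        table=table,
        rmse=float(np.sqrt(np.mean(residuals**2))),
        residual_mean=float(residuals.mean()),
        residual_std=float(residuals.std(ddof=0)),
    )


def identifiability_flags(
    sample: PosteriorSample,
    bins: int = 50,
    min_chain: int = 1000,
    flat_fraction: float = 0.8,
    mode_rel_height: float = 0.2,
) -> dict[str, dict[str, bool]]:
    """Per-parameter {flat, multimodal} flags over the whole chain."""
    if sample.n_retained < min_chain:
        raise HergfitError(
            f"chain too short for identifiability flags: "
            f"{sample.n_retained} < {min_chain}"
        )
    out = {}
    for name in sample.free_names:
        summary = marginal_histogram(
            sample,
            name,
            bins=bins,
            flat_fraction=flat_fraction,
            mode_rel_height=mode_rel_height,
        )
        out[name] = {"flat": summary.flat, "multimodal": summary.multimodal}
    return out
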