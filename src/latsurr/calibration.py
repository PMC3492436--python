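"""Type-I-error calibration of association tests under a true null.

A null model yields a valid test when, applied to pairs of lattices that
really are independent, it rejects at rate alpha for every nominal level
alpha.  This module repeats the Monte-Carlo association test on many
independently simulated reference pairs (fractional Brownian fields with
a chosen autocorrelation exponent, optionally median-binarised), then
compares observed and expected rejection rates over the whole [0, 1]
range of alpha and summarises the departure from the identity line by
the Kolmogorov-Smirnov statistic of the null p-value sample against
Uniform(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_tests import monte_carlo_test
from .null_models import NullModelSpec
from .simulate import FBFSpec, binarize_median, fbf_generate

__all__ = ["CalibrationCurve", "run_calibration", "ks_departure", "tile_lattice"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Observed vs expected type-I-error rates and the KS departure.

    ``alphas``/``observed`` form the binned calibration curve (bin width
    0.05); ``d_max`` is the KS maximum difference computed on the raw,
    unbinned p-value sample, with its asymptotic p-value ``d_max_p``.
    """

    alphas: np.ndarray
    observed: np.ndarray
    n_pairs: int
    d_max: float
    d_max_p: float
    p_values: np.ndarray

    def rate_at(self, alpha: float) -> float:
        """Observed rejection proportion at a nominal level."""
        return float(np.mean(self.p_values <= alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alphas, "observed": self.observed,
             "n_pairs": self.n_pairs}
        )


def ks_departure(pvalues: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic of p-values against Uniform(0,1).

    Monte-Carlo p-values live on a discrete lattice of multiples of
    1/n_total, which makes the asymptotic KS p-value slightly
    conservative; it is used here as a descriptive departure measure.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    res = stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def run_calibration(
    field_spec: FBFSpec,
    null: NullModelSpec,
    stat: str = "pearson_r",
    n_pairs: int = 200,
    n_surrogates: int = 99,
    seed: int = 0,
    binary: bool = False,
) -> CalibrationCurve:
    """Estimate the type-I-error calibration curve of a null model.

    ``n_pairs`` independent pairs of reference fields are simulated from
    ``field_spec`` (two independent streams per pair, implementing the
    null of independent pattern-generating processes), median-binarised
    when ``binary``, and tested with ``monte_carlo_test``.  Per-pair
    seeds are spawned deterministically from ``seed``, so the result is
    identical for a fixed master seed regardless of evaluation order.
    """
    if n_pairs < 20:
        raise ValueError("n_pairs must be >= 20")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_pairs)
    pvals = np.empty(n_pairs)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        a = fbf_generate(replace(field_spec, seed=0), rng=rng)
        b = fbf_generate(replace(field_spec, seed=0), rng=rng)
        if binary:
            a, b = binarize_median(a), binarize_median(b)
        res = monte_carlo_test(
            a, b, stat=stat, null=null, n_surrogates=n_surrogates, seed=rng
        )
        pvals[i] = res.p_value
    alphas = np.arange(1, 21) * 0.05
    observed = np.array([np.mean(pvals <= al) for al in alphas])
    d_max, d_max_p = ks_departure(pvals)
    return CalibrationCurve(alphas, observed, n_pairs, d_max, d_max_p, pvals)


def tile_lattice(values: np.ndarray, size: int) -> list[np.ndarray]:
    """Cut a large raster into non-overlapping size x size windows.

    Helper for calibrating against real gridded data; partial windows at
    the right/bottom edges are dropped.
    """
    v = np.asarray(values, dtype=float)
    tiles = []
    for i in range(0, v.shape[0] - size + 1, size):
        for j in range(0, v.shape[1] - size + 1, size):
            tiles.append(v[i : i + size, j : j + size])
    return tiles
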