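"""Summary statistics of network structure and dynamics.

Synchrony is the variance of the population-mean signal relative to the
mean per-channel variance,

    omega = var(L) / [(1/n) sum_i var(v_i)],   0 <= omega <= 1,

equal to 1 for identical channels and about 1/n for independent ones.  The
same formula applied to region-averaged voltages L_i gives the macroscale
synchrony Omega.  Variances are population-form time averages
(denominator N), matching the time-average notation of the definition.

Interspike-interval (ISI) statistics pool the consecutive spike-time
differences of every neuron across the whole network; skewness and
(non-excess) kurtosis use the population central-moment estimators
m3 / s^3 and m4 / s^4, so a Gaussian sample gives about 0 and 3.

Macroscale strength statistics describe the off-diagonal (inter-regional)
entries of R: their variance, the order-of-magnitude span
log10(max/min) over nonzero entries, and the mean number of incoming
macroscale edges (R_ij != 0) per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netgen import MacroConnectome
from .neurodyn import SpikeRaster

__all__ = [
    "SynchronyResult",
    "ISISummary",
    "MacroStats",
    "synchrony",
    "extract_isis",
    "moments",
    "isi_summary",
    "macro_stats",
    "pc_variance_fraction",
]


@dataclass(frozen=True)
class SynchronyResult:
    """Variance-ratio synchrony; ``scale`` is "neuron" (omega) or "region" (Omega)."""

    value: float
    numerator: float  # var of the channel-mean series
    denominator: float  # mean of per-channel variances
    scale: str = "neuron"


@dataclass(frozen=True)
class ISISummary:
    """Pooled ISI sample with population-form variance, skewness, kurtosis."""

    isis: np.ndarray
    variance: float
    skewness: float
    kurtosis: float
    count: int


@dataclass(frozen=True)
class MacroStats:
    """Off-diagonal statistics of the macroscale strength matrix R.

    ``oom_span`` is log10(max/min) over nonzero off-diagonal entries; when
    there are none it is reported as 0 with ``oom_span_defined=False``.
    """

    strength_variance: float
    oom_span: float
    mean_in_edges: float
    oom_span_defined: bool = True


def synchrony(channels: np.ndarray, scale: str = "neuron") -> SynchronyResult:
    """Variance-of-mean over mean-of-variances synchrony of a (T, k) array."""
    X = np.asarray(channels, dtype=float)
    if X.ndim != 2:
        raise ValueError("channels must be a (samples, channels) array")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 channels")
    per_channel = X.var(axis=0)  # population form (denominator N)
    denom = float(per_channel.mean())
    if denom == 0.0:
        raise ValueError("all channels are constant; synchrony is undefined (0/0)")
    num = float(X.mean(axis=1).var())
    return SynchronyResult(value=num / denom, numerator=num, denominator=denom, scale=scale)


def extract_isis(raster: SpikeRaster) -> np.ndarray:
    """Pooled interspike intervals: per-neuron consecutive spike-time diffs.

    Neurons with fewer than two spikes contribute nothing; the pooled
    count therefore equals (total spikes) - (number of neurons that spiked).
    """
    if raster.n_events == 0:
        return np.empty(0)
    order = np.lexsort((raster.times, raster.neuron_ids))
    ids = raster.neuron_ids[order]
    times = raster.times[order]
    diffs = np.diff(times)
    same_neuron = ids[1:] == ids[:-1]
    return diffs[same_neuron]


def moments(sample: np.ndarray) -> tuple[float, float, float]:
    """Population central-moment (variance, skewness, non-excess kurtosis).

    No small-sample bias correction: variance m2, skewness m3 / m2^1.5,
    kurtosis m4 / m2^2 (Gaussian -> 3).  Requires >= 2 points for the
    variance; skewness/kurtosis additionally require nonzero variance and
    are only meaningful for samples of at least a few dozen points.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 points for moments; got {x.size}")
    dev = x - x.mean()
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:
        raise ValueError("sample has zero variance; skewness/kurtosis undefined")
    m3 = float(np.mean(dev**3))
    m4 = float(np.mean(dev**4))
    return m2, m3 / m2**1.5, m4 / m2**2


def isi_summary(raster: SpikeRaster, *, min_count: int = 20) -> ISISummary:
    """Pooled ISI sample and its moments; errors below ``min_count`` intervals."""
    isis = extract_isis(raster)
    if isis.size < min_count:
        raise ValueError(
            f"only {isis.size} pooled ISIs; need at least {min_count} for "
            "higher-moment estimates"
        )
    var, skew, kurt = moments(isis)
    return ISISummary(
        isis=isis, variance=var, skewness=skew, kurtosis=kurt, count=isis.size
    )


def macro_stats(macro: MacroConnectome) -> MacroStats:
    """Off-diagonal strength variance, order-of-magnitude span, mean in-edges."""
    R = np.asarray(macro.R, dtype=float)
    z = R.shape[0]
    if z < 2:
        raise ValueError("need at least 2 regions for inter-regional statistics")
    off_mask = ~np.eye(z, dtype=bool)
    off = R[off_mask]
    strength_variance = float(off.var())
    nonzero = off[off != 0]
    if nonzero.size:
        oom_span = float(np.log10(nonzero.max() / nonzero.min()))
        defined = True
    else:
        oom_span = 0.0
        defined = False
    in_edges = (R != 0) & off_mask
    mean_in_edges = float(in_edges.sum(axis=1).mean())
    return MacroStats(
        strength_variance=strength_variance,
        oom_span=oom_span,
        mean_in_edges=mean_in_edges,
        oom_span_defined=defined,
    )


def pc_variance_fraction(channels: np.ndarray, k: int) -> float:
    """Fraction of total variance captured by the top-k principal components."""
    X = np.asarray(channels, dtype=float)
    if X.ndim != 2:
        raise ValueError("channels must be a (samples, channels) array")
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"component count k must lie in [1, {X.shape[1]}]")
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    total = float(eigvals.sum())
    if total == 0.0:
        raise ValueError("channels have zero total variance")
    return float(eigvals[:k].sum()) / total
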