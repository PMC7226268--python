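"""Spike-train statistics: rates, spectra, Fano factor, correlations.

The population rate r(t) is a spike histogram normalised by N and the bin
width (1 ms by default).  Single-train power spectra are full-record
periodograms of the mean-subtracted binned train, averaged over K sampled
neurons; for such a spectrum the high-frequency plateau equals the mean rate
nu and the zero-frequency limit equals nu * FF, which is how the spectral
Fano factor is extracted.  The correlation time is the integral of the
squared, normalised continuous part of the autocorrelation, evaluated in the
frequency domain (Parseval):

    tau_c = integral df (S(f) - nu)^2 / nu^4 .
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpikeData

__all__ = [
    "ActivitySeries",
    "SpectrumSummary",
    "CorrelationFunction",
    "population_rate",
    "averaged_spectrum",
    "fano_factor_counts",
    "correlation",
    "correlation_time",
]


@dataclass
class ActivitySeries:
    """Binned firing rate r(t) in Hz for a population (network or module)."""

    values: np.ndarray
    bin_width: float  # ms
    n_neurons: int
    scope: str = "network"

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.values))


@dataclass
class SpectrumSummary:
    """Averaged spike-train power spectrum with derived scalar statistics.

    nu : mean firing rate (Hz), computed from spike counts
    fano : low-frequency plateau of the spectrum divided by nu
    tau_c : correlation time (ms)
    plateau_high : high-frequency plateau (validation: should be ~nu)
    """

    freqs: np.ndarray
    power: np.ndarray
    n_averaged: int
    nu: float
    fano: float
    tau_c: float
    plateau_high: float


@dataclass
class CorrelationFunction:
    lags: np.ndarray  # ms, symmetric around 0
    values: np.ndarray
    kind: str  # "auto" | "cross"
    n_averaged: int
    n_excluded: int = 0


def population_rate(
    spikes: SpikeData,
    scope: np.ndarray | None = None,
    bin_width: float = 1.0,
) -> ActivitySeries:
    """Population firing rate r(t); ``scope`` restricts to a neuron subset.

    Satisfies sum(r) * bin_width * N = total in-scope spike count exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if scope is None:
        times = spikes.times
        n = spikes.n_neurons
        label = "network"
    else:
        scope = np.asarray(scope)
        if scope.size == 0:
            raise ValueError("empty scope")
        times = spikes.times[np.isin(spikes.neuron_ids, scope)]
        n = scope.size
        label = "subset"
    n_bins = int(round(spikes.t_total / bin_width))
    counts = np.bincount(
        np.minimum((times / bin_width).astype(np.int64), n_bins - 1),
        minlength=n_bins,
    )
    rate_hz = counts / (n * bin_width / 1000.0)
    return ActivitySeries(values=rate_hz, bin_width=bin_width, n_neurons=n, scope=label)


def _sample_neurons(spikes: SpikeData, k: int, rng: np.random.Generator) -> np.ndarray:
    k = min(k, spikes.n_neurons)
    return rng.choice(spikes.n_neurons, size=k, replace=False)


def averaged_spectrum(
    spikes: SpikeData,
    sample_size: int = 1000,
    seed: int = 0,
    low_band_hz: float = 5.0,
) -> SpectrumSummary:
    """Periodogram of K sampled neurons' spike trains, averaged.

    Each train is binned at the simulation dt, mean-subtracted, and
    transformed over the full record (no segmenting), so the frequency
    resolution is 1/T.  nu comes from spike counts; the Fano factor is the
    mean spectral power over (0, low_band_hz] divided by nu.
    """
    if spikes.n_spikes == 0:
        raise ValueError("empty raster")
    t_sec = spikes.t_total / 1000.0
    if 1.0 / t_sec > low_band_hz:
        raise ValueError(
            f"record too short: frequency resolution {1 / t_sec:.2f} Hz exceeds "
            f"the low-frequency band {low_band_hz} Hz"
        )
    rng = np.random.default_rng(seed)
    neurons = _sample_neurons(spikes, sample_size, rng)
    binned = spikes.binned(neurons, bin_ms=spikes.dt).astype(np.float64)
    nu = float(binned.sum() / len(neurons) / t_sec)
    if nu == 0:
        raise ValueError("sampled neurons emitted no spikes")
    binned -= binned.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(binned, axis=1)) ** 2 / t_sec
    power = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(binned.shape[1], d=spikes.dt / 1000.0)

    low = (freqs > 0) & (freqs <= low_band_hz)
    fano = float(power[low].mean() / nu)
    high = freqs >= 0.8 * freqs[-1]
    plateau_high = float(power[high].mean())
    summary = SpectrumSummary(
        freqs=freqs,
        power=power,
        n_averaged=len(neurons),
        nu=nu,
        fano=fano,
        tau_c=np.nan,
        plateau_high=plateau_high,
    )
    summary.tau_c = correlation_time(summary)
    return summary


def correlation_time(spectrum: SpectrumSummary) -> float:
    """Integral timescale tau_c (ms) from the averaged spectrum.

    Two-sided integral of (S(f) - nu)^2 / nu^4 over the estimated band,
    excluding the DC bin (the mean was already removed from the trains).
    """
    if not spectrum.nu > 0:
        raise ValueError("correlation time undefined for nu = 0")
    df = spectrum.freqs[1] - spectrum.freqs[0]
    integrand = (spectrum.power[1:] - spectrum.nu) ** 2 / spectrum.nu ** 4
    tau_sec = 2.0 * float(integrand.sum()) * df
    return tau_sec * 1000.0


def fano_factor_counts(spikes: SpikeData, window: float | None = None) -> float:
    """Count-based Fano factor <dn^2>/<n>.

    With ``window`` equal to the full record (default) the variance is taken
    across neurons; with a shorter window the record is tiled and each
    neuron's FF over windows is averaged across neurons.
    """
    window = spikes.t_total if window is None else window
    if window > spikes.t_total:
        raise ValueError("window exceeds record length")
    counts_per_neuron = np.bincount(spikes.neuron_ids, minlength=spikes.n_neurons)
    if window == spikes.t_total:
        mean = counts_per_neuron.mean()
        if mean == 0:
            raise ValueError("Fano factor undefined: zero mean count")
        return float(counts_per_neuron.var() / mean)
    n_win = int(spikes.t_total // window)
    widx = np.minimum((spikes.times / window).astype(np.int64), n_win - 1)
    table = np.zeros((spikes.n_neurons, n_win))
    np.add.at(table, (spikes.neuron_ids, widx), 1)
    means = table.mean(axis=1)
    ok = means > 0
    if not np.any(ok):
        raise ValueError("Fano factor undefined: zero mean count")
    return float((table[ok].var(axis=1) / means[ok]).mean())


def correlation(
    spikes: SpikeData,
    kind: str = "auto",
    sample_size: int = 1000,
    max_lag: float = 100.0,
    bin_width: float = 1.0,
    seed: int = 0,
) -> CorrelationFunction:
    """Averaged auto- or cross-correlogram of binned spike trains.

    Trains are binned at ``bin_width`` ms and mean-subtracted.  The
    autocorrelation is averaged over K sampled neurons and normalised by its
    zero-lag value; the cross-correlation is averaged over K sampled ordered
    pairs, each normalised by the geometric mean of the two zero-lag
    autocorrelations.  Spike-free trains are excluded and counted.
    """
    if kind not in ("auto", "cross"):
        raise ValueError("kind must be 'auto' or 'cross'")
    rng = np.random.default_rng(seed)
    n_lags = int(round(max_lag / bin_width))
    lags = np.arange(-n_lags, n_lags + 1) * bin_width

    if kind == "auto":
        neurons = _sample_neurons(spikes, sample_size, rng)
        binned = spikes.binned(neurons, bin_ms=bin_width).astype(np.float64)
        active = binned.sum(axis=1) > 0
        n_excluded = int(np.count_nonzero(~active))
        binned = binned[active]
        if binned.shape[0] == 0:
            raise ValueError("no active trains in sample")
        binned -= binned.mean(axis=1, keepdims=True)
        spec = np.abs(np.fft.rfft(binned, axis=1)) ** 2
        acf_full = np.fft.irfft(spec.mean(axis=0), n=binned.shape[1])
        acf = np.concatenate([acf_full[-n_lags:], acf_full[: n_lags + 1]])
        values = acf / acf[n_lags]
        return CorrelationFunction(lags, values, "auto", binned.shape[0], n_excluded)

    # cross: K random ordered pairs (x, y), correlate x with y
    n = spikes.n_neurons
    k = min(sample_size, n * (n - 1))
    xs = rng.integers(0, n, size=2 * k + 16)
    ys = rng.integers(0, n, size=2 * k + 16)
    ok = xs != ys
    pairs = np.unique(np.stack([xs[ok], ys[ok]], axis=1), axis=0)
    pairs = pairs[rng.permutation(len(pairs))[:k]]
    neurons = np.unique(pairs)
    binned = spikes.binned(neurons, bin_ms=bin_width).astype(np.float64)
    row = {int(j): i for i, j in enumerate(neurons)}
    binned -= binned.mean(axis=1, keepdims=True)
    ft = np.fft.rfft(binned, axis=1)
    norms = (np.abs(ft) ** 2).sum(axis=1)
    acc = np.zeros(2 * n_lags + 1)
    n_used = 0
    n_excluded = 0
    n_bins = binned.shape[1]
    for a, b in pairs:
        ia, ib = row[int(a)], row[int(b)]
        if norms[ia] == 0 or norms[ib] == 0:
            n_excluded += 1
            continue
        ccf_full = np.fft.irfft(ft[ia] * np.conj(ft[ib]), n=n_bins)
        ccf = np.concatenate([ccf_full[-n_lags:], ccf_full[: n_lags + 1]])
        zero_a = np.fft.irfft(np.abs(ft[ia]) ** 2, n=n_bins)[0]
        zero_b = np.fft.irfft(np.abs(ft[ib]) ** 2, n=n_bins)[0]
        acc += ccf / np.sqrt(zero_a * zero_b)
        n_used += 1
    if n_used == 0:
        raise ValueError("no active pairs in sample")
    return CorrelationFunction(lags, acc / n_used, "cross", n_used, n_excluded)
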