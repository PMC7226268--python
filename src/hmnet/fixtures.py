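"""Seeded synthetic inputs with known ground truth.

Every generator here emulates the statistical structure one of the
estimators assumes, so the estimators can be validated without running a
network simulation: homogeneous Poisson rasters (flat spectrum at the rate,
Fano factor 1, zero correlation time), the deterministic two-neuron
mutual-excitation loop used to validate the delayed-TE scan, delayed binary
copies, periodic and two-state bursting renewal-style trains with known
Fano factors, and correlated Gaussian / coupled autoregressive series whose
mutual information and transfer entropy have closed forms.

Closed-form oracles:

* bivariate Gaussian with correlation rho: MI = -1/2 log2(1 - rho^2)
* AR(1) target driven by white source, x_{t+1} = a x_t + c y_t + s eta_t
  with y_t, eta_t ~ iid N(0,1): TE = 1/2 log2(1 + c^2 / s^2)
* delayed Bernoulli(p) copy: TE at the true delay = binary entropy of p
"""

from __future__ import annotations

import math

import numpy as np

from .simulate import SpikeData

__all__ = [
    "make_two_neuron_loop",
    "make_poisson",
    "make_delayed_copy",
    "make_periodic",
    "make_bursting",
    "make_gaussian_pair",
    "make_ar_coupled",
    "gaussian_mi_bits",
    "ar_te_bits",
    "binary_entropy_bits",
]


def make_two_neuron_loop(
    delay_yx: int,
    delay_xy: int,
    n_bins: int = 5000,
    seed_pattern: tuple = ((0, "y"),),
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mutual-excitation raster for a two-neuron loop.

    Every y spike at bin t places an x spike at t + delay_yx; every x spike
    at t places a y spike at t + delay_xy.  Activity is initiated by the
    seed pattern (a sequence of ``(bin, "x"|"y")``); spike placement is
    idempotent, so collisions are harmless.  The loop's orbit is periodic
    with period ``delay_yx + delay_xy`` once every seed has propagated; the
    pre-periodic transient is trimmed so the returned ``(y, x)`` trains are
    exactly periodic.  The canonical construction is a single seed spike
    (at any bin), for which the delayed-TE argmax equals the corresponding
    connection delay regardless of where the seed sits; seed patterns that
    spawn several phase families of the orbit can introduce exact TE ties
    between neighbouring delays.
    """
    if delay_yx < 1 or delay_xy < 1:
        raise ValueError("delays must be >= 1 bin")
    if n_bins <= 4 * (delay_yx + delay_xy):
        raise ValueError("n_bins too small relative to the delays")
    if not seed_pattern:
        raise ValueError("seed pattern must contain at least one spike")
    transient = max(t0 for t0, _ in seed_pattern) + delay_yx + delay_xy
    total = n_bins + transient
    y = np.zeros(total, dtype=np.int8)
    x = np.zeros(total, dtype=np.int8)
    for t0, which in seed_pattern:
        (y if which == "y" else x)[t0] = 1
    for t in range(total):
        if y[t] and t + delay_yx < total:
            x[t + delay_yx] = 1
        if x[t] and t + delay_xy < total:
            y[t + delay_xy] = 1
    return y[transient:], x[transient:]


def make_poisson(
    n_trains: int,
    rate: float,
    t_total: float = 2000.0,
    dt: float = 0.1,
    seed: int = 0,
) -> SpikeData:
    """Homogeneous Poisson raster: iid Bernoulli(rate * dt) bins per train.

    rate in Hz, t_total and dt in ms; requires rate * dt < 1.
    """
    p = rate * dt / 1000.0
    if p >= 1:
        raise ValueError("rate * dt must be < 1 spike per bin")
    rng = np.random.default_rng(seed)
    n_bins = int(round(t_total / dt))
    if p == 0:
        ids = np.empty(0, dtype=np.int64)
        times = np.empty(0, dtype=np.float64)
    else:
        grid = rng.random((n_trains, n_bins)) < p
        ids, cols = np.nonzero(grid)
        times = cols * dt
        order = np.argsort(times, kind="stable")
        ids, times = ids[order], times[order]
    return SpikeData(
        neuron_ids=ids, times=times, n_neurons=n_trains,
        t_total=t_total, dt=dt, meta={"kind": "poisson", "rate": rate, "seed": seed},
    )


def make_delayed_copy(
    p: float, delay: int, n_bins: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Source y ~ iid Bernoulli(p); target x an exact copy shifted by ``delay``
    bins.  TE_{y->x} at the true delay equals the binary entropy of p."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n_bins) < p).astype(np.int8)
    x = np.zeros(n_bins, dtype=np.int8)
    if delay < n_bins:
        x[delay:] = y[: n_bins - delay]
    return y, x


def make_periodic(
    n_trains: int,
    isi_ms: float,
    t_total: float = 2000.0,
    dt: float = 0.1,
    seed: int = 0,
) -> SpikeData:
    """Perfectly periodic trains with random initial phases (renewal process
    with zero ISI variance; count Fano factor well below 1)."""
    rng = np.random.default_rng(seed)
    ids, times = [], []
    for j in range(n_trains):
        phase = rng.uniform(0, isi_ms)
        t = np.arange(phase, t_total, isi_ms)
        t = np.round(t / dt) * dt
        t = t[t < t_total]
        ids.append(np.full(t.size, j, dtype=np.int64))
        times.append(t)
    ids = np.concatenate(ids)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return SpikeData(
        neuron_ids=ids[order], times=times[order], n_neurons=n_trains,
        t_total=t_total, dt=dt, meta={"kind": "periodic", "isi_ms": isi_ms},
    )


def make_bursting(
    n_trains: int,
    rate_high: float,
    rate_low: float,
    switch_ms: float,
    t_total: float = 2000.0,
    dt: float = 0.1,
    seed: int = 0,
) -> SpikeData:
    """Two-state (doubly stochastic) Poisson trains alternating between a
    high-rate and a low-rate state every ``switch_ms``; random initial state
    per train.  Slow rate modulation makes the count Fano factor exceed 1."""
    rng = np.random.default_rng(seed)
    n_bins = int(round(t_total / dt))
    t_axis = np.arange(n_bins) * dt
    phase_idx = (t_axis // switch_ms).astype(np.int64) % 2
    ids, times = [], []
    for j in range(n_trains):
        start = rng.integers(0, 2)
        rate = np.where((phase_idx + start) % 2 == 0, rate_high, rate_low)
        spikes = rng.random(n_bins) < rate * dt / 1000.0
        t = t_axis[spikes]
        ids.append(np.full(t.size, j, dtype=np.int64))
        times.append(t)
    ids = np.concatenate(ids)
    times = np.concatenate(times)
    order = np.argsort(times, kind="stable")
    return SpikeData(
        neuron_ids=ids[order], times=times[order], n_neurons=n_trains,
        t_total=t_total, dt=dt,
        meta={"kind": "bursting", "rates": (rate_high, rate_low)},
    )


def make_gaussian_pair(
    rho: float, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate standard Gaussian samples with correlation rho.

    MI oracle: :func:`gaussian_mi_bits`.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho * z1 + math.sqrt(1.0 - rho * rho) * z2


def make_ar_coupled(
    a: float, c: float, n: int, sigma: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled pair: white source y_t ~ N(0,1) driving an AR(1) target,
    x_{t+1} = a x_t + c y_t + sigma eta_t.

    Returns (y, x).  TE oracle: :func:`ar_te_bits`.
    """
    if not abs(a) < 1:
        raise ValueError("AR coefficient must satisfy |a| < 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    eta = rng.standard_normal(n)
    x = np.zeros(n)
    for t in range(n - 1):
        x[t + 1] = a * x[t] + c * y[t] + sigma * eta[t]
    return y, x


def gaussian_mi_bits(rho: float) -> float:
    """MI of a bivariate Gaussian with correlation rho, in bits."""
    return -0.5 * math.log2(1.0 - rho * rho)


def ar_te_bits(c: float, sigma: float) -> float:
    """TE (bits) of the white-noise-driven AR(1) pair of
    :func:`make_ar_coupled`: 1/2 log2(1 + c^2/sigma^2)."""
    return 0.5 * math.log2(1.0 + (c / sigma) ** 2)


def binary_entropy_bits(p: float) -> float:
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)
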