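"""Spike statistics, E/I balance metrics, weight analysis and decoding.

Post-hoc analysis of simulation runs: per-neuron firing rates, CV of
interspike intervals and Fano factors; Gaussian-kernel rate traces;
cross-correlation of excitatory vs inhibitory input currents (tight
balance shows a high peak at a small non-negative lag, i.e. inhibition
trailing excitation); log-weight histograms and stimulus receptive
fields; and decoding of the stimulus instantaneous firing rate from a
neural population via the same first-spike contribution rule the
plasticity uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .network import ConfigurationError, SynapseGroup
from .plasticity import decode_population_rate

__all__ = [
    "SpikeStats",
    "spike_stats",
    "rate_trace",
    "decode_stimulus",
    "smeared_stimulus",
    "frame_correlations",
    "balance_metrics",
    "weight_analysis",
    "receptive_field_similarity",
    "minimum_isi",
]


@dataclass
class SpikeStats:
    """Population spike statistics as tidy DataFrames."""

    per_neuron: pd.DataFrame       # neuron, rate_hz, cv_isi, n_spikes
    fano: pd.DataFrame             # window_ms, neuron, fano
    excluded_cv: int               # neurons with < 3 spikes
    excluded_fano: int             # neuron/window combos with zero counts

    @property
    def mean_rate(self) -> float:
        return float(self.per_neuron["rate_hz"].mean())

    @property
    def mean_cv(self) -> float:
        return float(self.per_neuron["cv_isi"].dropna().mean())

    def mean_fano(self) -> pd.Series:
        return self.fano.groupby("window_ms")["fano"].mean()


def spike_stats(
    trains: list[np.ndarray],
    duration: float,
    windows=(50.0, 100.0, 200.0, 500.0),
) -> SpikeStats:
    """Rates, ISI coefficients of variation and Fano factors.

    ``trains`` holds one sorted spike-time array (ms) per neuron;
    ``duration`` is the recording length in ms.  CV is computed for
    neurons with at least 3 spikes (others are excluded and counted);
    the Fano factor uses non-overlapping windows tiling the recording,
    discarding the partial trailing window.
    """
    rows = []
    excluded = 0
    for k, t in enumerate(trains):
        n = t.size
        rate = n / duration * 1000.0
        if n >= 3:
            isi = np.diff(t)
            cv = float(np.std(isi) / np.mean(isi)) if np.mean(isi) > 0 \
                else np.nan
        else:
            cv = np.nan
            excluded += 1
        rows.append((k, rate, cv, n))
    per_neuron = pd.DataFrame(rows,
                              columns=["neuron", "rate_hz", "cv_isi",
                                       "n_spikes"])
    fano_rows = []
    excluded_fano = 0
    for win in windows:
        n_win = int(duration // win)
        if n_win < 2:
            continue
        edges = np.arange(n_win + 1) * win
        for k, t in enumerate(trains):
            counts, _ = np.histogram(t, bins=edges)
            m = counts.mean()
            if m == 0:
                excluded_fano += 1
                continue
            fano_rows.append((win, k, float(counts.var() / m)))
    fano = pd.DataFrame(fano_rows, columns=["window_ms", "neuron", "fano"])
    return SpikeStats(per_neuron, fano, excluded, excluded_fano)


def minimum_isi(trains: list[np.ndarray]) -> float:
    """Smallest interspike interval over all neurons (ms); inf if none."""
    best = math.inf
    for t in trains:
        if t.size >= 2:
            m = float(np.diff(t).min())
            if m < best:
                best = m
    return best


def rate_trace(train: np.ndarray, duration: float, sigma: float = 200.0,
               bin_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate over time by Gaussian-kernel smoothing (Hz).

    The spike train is binned and convolved with a Gaussian of standard
    deviation ``sigma`` ms; the time grid is padded by 4σ on both sides
    so the trace integrates to the spike count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pad = 4.0 * sigma
    edges = np.arange(-pad, duration + pad + bin_ms, bin_ms)
    counts, _ = np.histogram(train, bins=edges)
    kern_halfwidth = int(np.ceil(4.0 * sigma / bin_ms))
    kx = np.arange(-kern_halfwidth, kern_halfwidth + 1) * bin_ms
    kern = np.exp(-0.5 * (kx / sigma) ** 2)
    kern /= kern.sum()
    smooth = np.convolve(counts, kern, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, smooth / (bin_ms * 1e-3)


# ---------------------------------------------------------------------- #
# decoding


def decode_stimulus(
    group: SynapseGroup,
    post_trains: list[np.ndarray],
    v_snapshots: dict[float, np.ndarray],
    times,
    grid: tuple[int, int],
    *,
    tau_m: float,
    tau_A: float,
    C: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Decoded stimulus frames r̂^{Dβ}_j(t) on the pixel grid.

    ``group`` must have the stimulus population presynaptic (there is no
    stimulus-to-stimulus decoding); ``post_trains`` are the decoding
    population's per-neuron spike times and ``v_snapshots`` its membrane
    potentials sampled at each requested time.  Returns (times, frames)
    with frames shaped (n_times, rows, cols).
    """
    if group.pre_pop != "D":
        raise ConfigurationError("decoding expects stimulus-presynaptic "
                                 "weights")
    rows, cols = grid
    if rows * cols != group.n_pre:
        raise ConfigurationError("grid does not match the stimulus size")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    frames = np.empty((times.size, rows, cols))
    for k, t in enumerate(times):
        V = v_snapshots[float(t)]
        rhat = decode_population_rate(group, post_trains, V, float(t),
                                      tau_m=tau_m, tau_A=tau_A, C=C)
        frames[k] = rhat.reshape(rows, cols)
    return times, frames


def smeared_stimulus(
    stim_trains: list[np.ndarray],
    times,
    grid: tuple[int, int],
    tau: float,
) -> np.ndarray:
    """Exponentially smeared stimulus frames — the decoding target.

    Each pixel's spike train is low-pass filtered with e^{−Δ/τ} (the
    membrane time constant), evaluated at the requested times.
    """
    rows, cols = grid
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.zeros((times.size, rows * cols))
    for j, train in enumerate(stim_trains):
        if train.size == 0:
            continue
        for k, t in enumerate(times):
            hi = np.searchsorted(train, t, side="right")
            lo = np.searchsorted(train, t - 8.0 * tau)
            if hi > lo:
                out[k, j] = np.exp(-(t - train[lo:hi]) / tau).sum()
    return out.reshape(times.size, rows, cols)


def frame_correlations(decoded: np.ndarray,
                       target: np.ndarray) -> np.ndarray:
    """Per-frame spatial Pearson correlation over pixels with nonzero
    target variance; NaN where undefined."""
    n = decoded.shape[0]
    out = np.full(n, np.nan)
    for k in range(n):
        d = decoded[k].ravel()
        t = target[k].ravel()
        mask = t > 0
        if mask.sum() < 3 or np.std(t[mask]) == 0 or np.std(d[mask]) == 0:
            continue
        out[k] = float(np.corrcoef(d[mask], t[mask])[0, 1])
    return out


# ---------------------------------------------------------------------- #
# excitation-inhibition balance


def balance_metrics(
    t: np.ndarray,
    i_exc: np.ndarray,
    i_inh: np.ndarray,
    max_lag_ms: float = 50.0,
) -> pd.DataFrame:
    """Cross-correlation of excitatory vs inverted inhibitory current.

    For each recorded neuron, the normalised cross-correlation between
    the (mean-subtracted) excitatory current and −1 × the inhibitory
    current is computed; reported are the peak correlation and its lag,
    with positive lag meaning inhibition trails excitation.  Constant
    traces have undefined correlation and yield NaN.
    """
    if i_exc.ndim == 1:
        i_exc = i_exc[:, None]
        i_inh = i_inh[:, None]
    dt = float(np.median(np.diff(t)))
    max_shift = int(round(max_lag_ms / dt))
    rows = []
    for k in range(i_exc.shape[1]):
        e = i_exc[:, k] - i_exc[:, k].mean()
        i = -(i_inh[:, k] - i_inh[:, k].mean())
        se, si = e.std(), i.std()
        if se == 0 or si == 0:
            rows.append((k, np.nan, np.nan))
            continue
        cc = signal.correlate(i, e, mode="full")
        lags = signal.correlation_lags(i.size, e.size, mode="full")
        keep = np.abs(lags) <= max_shift
        cc = cc[keep] / (se * si * e.size)
        lags = lags[keep]
        pk = int(np.argmax(cc))
        rows.append((k, float(cc[pk]), float(lags[pk] * dt)))
    return pd.DataFrame(rows, columns=["neuron", "peak_corr", "lag_ms"])


# ---------------------------------------------------------------------- #
# weights


def weight_analysis(
    groups: dict[str, SynapseGroup],
    grid: tuple[int, int] | None = None,
    rf_group: str = "DE",
    n_bins: int = 50,
) -> dict:
    """Log-weight histograms, moment diagnostics and receptive fields.

    Returns per-group histograms of log10 weights with skewness and
    excess kurtosis of the log-weights, plus — when ``grid`` is given
    and ``rf_group`` exists — per-neuron receptive fields: each
    postsynaptic neuron's incoming stimulus weights on the pixel grid,
    max-normalised per neuron.
    """
    out: dict = {"histograms": {}, "moments": {}}
    for name, g in groups.items():
        w = g.w[g.w > 0]
        logw = np.log10(w)
        counts, edges = np.histogram(logw, bins=n_bins)
        out["histograms"][name] = (counts, edges)
        if logw.size and logw.std() > 0:
            skew = float(stats.skew(logw))
            kurt = float(stats.kurtosis(logw))
        else:  # degenerate (all-equal) weights
            skew = 0.0
            kurt = float("nan")
        out["moments"][name] = {
            "skewness": skew,
            "excess_kurtosis": kurt,
            "n": int(logw.size),
        }
    if grid is not None and rf_group in groups:
        g = groups[rf_group]
        rows, cols = grid
        fields = np.zeros((g.n_post, rows, cols))
        for i in range(g.n_post):
            sl = slice(g.pindptr[i], g.pindptr[i + 1])
            fld = np.zeros(rows * cols)
            fld[g.pre[sl]] = g.w[g.pos[sl]]
            m = fld.max()
            if m > 0:
                fld /= m
            fields[i] = fld.reshape(rows, cols)
        out["receptive_fields"] = fields
    return out


def receptive_field_similarity(fields: np.ndarray,
                               pairs: list[tuple[int, int]]) -> np.ndarray:
    """Pairwise cosine similarity of flattened normalised fields."""
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        fa = fields[a].ravel()
        fb = fields[b].ravel()
        na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
        out[k] = float(fa @ fb / (na * nb)) if na > 0 and nb > 0 else np.nan
    return out
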