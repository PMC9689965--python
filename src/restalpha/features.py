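"""Resting-state EEG features: relative power level, power spectral entropy,
Lempel-Ziv complexity.

All three features are computed per frequency band and channel on fixed
1500-sample epochs of the band-filtered signal, then averaged over a run's
epochs.  Each is invariant to positive amplitude scaling of the input:

* RPL_i = P_i / P_all with P = mean squared amplitude; P_all is the sum of
  the four band powers (the bands partition 4-50 Hz), so the four RPLs lie
  on the probability simplex and sum to 1 exactly.
* PSE = -sum p_i ln p_i of the periodogram PSD restricted to the band's
  frequency bins and normalized to sum 1; bounded by ln(n_bins), attained
  only for a flat in-band spectrum.
* LZC = C(n) * log2(n) / n where C(n) is the LZ76 pattern count of the
  epoch binarized at its median (ties binarize to 1, counter starts at 1);
  approaches ~1 for i.i.d. random binary sequences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numba import njit
from scipy.signal import periodogram

from .preprocessing import BANDS, BandDefinition, EpochSet, bandpass_array

log = logging.getLogger(__name__)

FEATURE_NAMES = ("RPL", "PSE", "LZC")

TOTAL_LOW = 4.0
TOTAL_HIGH = 50.0


def band_power(signal: np.ndarray) -> float:
    """Mean squared amplitude (1/N) * sum x(t)^2 of a 1-D signal."""
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    return float(np.mean(x * x))


def relative_power_level(
    epoch: np.ndarray,
    sample_rate: float,
    bands: tuple[BandDefinition, ...] = BANDS,
    order: int = 4,
    normalizer: str = "band_sum",
) -> dict[str, float]:
    """Per-band relative power of a single-channel epoch.

    With the default ``normalizer="band_sum"`` the total power is the sum of
    the band powers themselves (the bands partition 4-50 Hz), which makes
    the RPLs sum to 1 exactly.  ``normalizer="broadband"`` divides by the
    power of a single 4-50 Hz filtered signal instead; the two differ only
    through filter-edge effects.
    """
    powers = {
        b.name: band_power(bandpass_array(epoch, sample_rate, b, order)) for b in bands
    }
    if normalizer == "band_sum":
        total = sum(powers.values())
    elif normalizer == "broadband":
        broad = BandDefinition("broadband", TOTAL_LOW, TOTAL_HIGH)
        total = band_power(bandpass_array(epoch, sample_rate, broad, order))
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    if total == 0:
        raise ValueError("all-zero epoch: relative power undefined")
    return {name: p / total for name, p in powers.items()}


def band_psd(
    epoch: np.ndarray,
    sample_rate: float,
    band: BandDefinition | None,
):
    """Periodogram PSD, restricted to a band's frequency bins if given."""
    freqs, psd = periodogram(epoch, fs=sample_rate, window="boxcar", detrend=False)
    if band is None:
        return freqs, psd
    mask = (freqs >= band.low) & (freqs <= band.high)
    if mask.sum() < 2:
        raise ValueError(
            f"band {band.name} holds fewer than 2 periodogram bins at this resolution"
        )
    return freqs[mask], psd[mask]


def spectral_entropy(psd: np.ndarray) -> float:
    """Shannon entropy (nats) of a normalized power spectral density."""
    total = psd.sum()
    if total <= 0:
        raise ValueError("zero total band power: spectral entropy undefined")
    p = psd / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def power_spectral_entropy(
    epoch: np.ndarray,
    sample_rate: float,
    band: BandDefinition,
    order: int = 4,
    prefiltered: bool = False,
    restrict_to_band: bool = True,
) -> float:
    """PSE of one channel epoch in one band (band-filter, periodogram, entropy).

    ``restrict_to_band=False`` keeps the full spectrum of the band-filtered
    signal instead of only the in-band bins (an alternative convention; the
    out-of-band bins then contribute near-zero mass).
    """
    x = epoch if prefiltered else bandpass_array(epoch, sample_rate, band, order)
    _, psd = band_psd(x, sample_rate, band if restrict_to_band else None)
    return spectral_entropy(psd)


def n_band_bins(n_samples: int, sample_rate: float, band: BandDefinition) -> int:
    """Number of periodogram bins inside a band (the PSE upper bound is its ln)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    return int(((freqs >= band.low) & (freqs <= band.high)).sum())


# ---------------------------------------------------------------------------
# Lempel-Ziv


@njit(cache=True)
def _lz76_count(seq: np.ndarray) -> int:  # pragma: no cover - compiled
    n = seq.size
    if n == 0:
        return 0
    c = 1  # the first symbol is the first pattern; counter starts at 1
    i = 1
    while i < n:
        # longest match of seq[i:] against an occurrence starting before i
        # (the source may extend into the current phrase)
        kmax = 0
        for j in range(i):
            # a candidate can only beat kmax if it matches at offset kmax
            if i + kmax < n and seq[j + kmax] != seq[i + kmax]:
                continue
            k = 0
            while i + k < n and seq[j + k] == seq[i + k]:
                k += 1
            if k > kmax:
                kmax = k
                if i + kmax >= n:
                    break
        c += 1
        i += kmax + 1
    return c


def lz76_pattern_count(symbols) -> int:
    """LZ76 pattern count C(n) of a 0/1 sequence.

    Sequential parsing into phrases, each the shortest substring not seen in
    the prefix (sources may overlap the phrase itself); the trailing
    incomplete phrase counts.  A constant sequence gives C(n) = 2.
    """
    seq = np.ascontiguousarray(symbols, dtype=np.uint8)
    if np.any(seq > 1):
        raise ValueError("symbols must be 0/1")
    return int(_lz76_count(seq))


def binarize_epoch(epoch: np.ndarray, threshold: str = "median") -> np.ndarray:
    """Binarize at the epoch median (default) or mean: >= threshold -> 1.

    Ties map to 1, keeping the rule deterministic; the median choice makes
    the downstream complexity feature invariant to amplitude scaling.
    """
    x = np.asarray(epoch, dtype=np.float64)
    if threshold == "median":
        t = np.median(x)
    elif threshold == "mean":
        t = np.mean(x)
    else:
        raise ValueError(f"unknown binarization threshold {threshold!r}")
    return (x >= t).astype(np.uint8)


def lempel_ziv_complexity(
    epoch: np.ndarray,
    sample_rate: float | None = None,
    band: BandDefinition | None = None,
    order: int = 4,
    prefiltered: bool = True,
    threshold: str = "median",
) -> float:
    """Normalized LZ76 complexity C(n) * log2(n) / n of a single-channel epoch.

    If ``band`` is given and ``prefiltered`` is False, the epoch is
    band-filtered first.  A constant epoch binarizes to all ones and yields
    the minimal C(n) = 2.
    """
    x = np.asarray(epoch, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("epoch too short for LZ76")
    if band is not None and not prefiltered:
        if sample_rate is None:
            raise ValueError("sample_rate required to band-filter")
        x = bandpass_array(x, sample_rate, band, order)
    c = lz76_pattern_count(binarize_epoch(x, threshold))
    return c * np.log2(n) / n


# ---------------------------------------------------------------------------
# feature table


def epoch_set_features(
    epoch_set: EpochSet,
    bands: tuple[BandDefinition, ...] = BANDS,
    channels: tuple[str, ...] | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
    order: int = 4,
) -> pd.DataFrame:
    """Tidy per-channel features of one subject/state's epochs.

    The continuous-record band filtering happened upstream of epoching in
    the main pipeline; here each epoch is filtered per band (identical
    filters, edge transients only), then per-epoch features are averaged.
    Restricting ``channels``/``features`` skips work the caller won't use.
    """
    fs = epoch_set.sample_rate
    ch_idx = (
        range(len(epoch_set.channel_labels))
        if channels is None
        else [epoch_set.channel_labels.index(c) for c in channels]
    )
    ch_idx = list(ch_idx)
    ch_names = [epoch_set.channel_labels[i] for i in ch_idx]
    data = epoch_set.epochs[:, ch_idx, :]  # (epochs, channels, samples)

    rows = []
    band_powers = {}  # band -> (epochs, channels) for the RPL normalizer
    filtered = {}
    for band in bands:
        y = bandpass_array(data, fs, band, order)
        filtered[band.name] = y
        band_powers[band.name] = np.mean(y * y, axis=-1)
    total_power = sum(band_powers.values())

    for bi, band in enumerate(bands):
        y = filtered[band.name]
        if "RPL" in features:
            with np.errstate(invalid="ignore", divide="ignore"):
                rpl = band_powers[band.name] / total_power
            rpl_mean = rpl.mean(axis=0)
        if "PSE" in features:
            _, psd = periodogram(y, fs=fs, window="boxcar", detrend=False, axis=-1)
            freqs = np.fft.rfftfreq(y.shape[-1], d=1.0 / fs)
            mask = (freqs >= band.low) & (freqs <= band.high)
            p = psd[..., mask]
            p = p / p.sum(axis=-1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
            pse_mean = (-(p * logp).sum(axis=-1)).mean(axis=0)
        if "LZC" in features:
            n = y.shape[-1]
            lzc = np.empty(y.shape[:2])
            for e in range(y.shape[0]):
                for c in range(y.shape[1]):
                    lzc[e, c] = lz76_pattern_count(binarize_epoch(y[e, c]))
            lzc_mean = (lzc * np.log2(n) / n).mean(axis=0)
        for ci, ch in enumerate(ch_names):
            if "RPL" in features:
                rows.append((epoch_set.subject_id, epoch_set.state, band.name, ch, "RPL", rpl_mean[ci]))
            if "PSE" in features:
                rows.append((epoch_set.subject_id, epoch_set.state, band.name, ch, "PSE", pse_mean[ci]))
            if "LZC" in features:
                rows.append((epoch_set.subject_id, epoch_set.state, band.name, ch, "LZC", lzc_mean[ci]))
    return pd.DataFrame(
        rows, columns=["subject", "state", "band", "channel", "feature", "value"]
    )


def build_feature_table(
    epoch_sets: list[EpochSet],
    bands: tuple[BandDefinition, ...] = BANDS,
    channels: tuple[str, ...] | None = None,
    features: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Concatenate per-subject/state feature frames into the cohort table.

    Subjects missing one of the two resting states are dropped with a
    warning so the table stays complete over the retained subjects.
    """
    frames = [
        epoch_set_features(es, bands, channels, features) for es in epoch_sets
    ]
    table = pd.concat(frames, ignore_index=True)
    states_per_subject = table.groupby("subject")["state"].nunique()
    required = table["state"].nunique()
    incomplete = states_per_subject[states_per_subject < required].index
    if len(incomplete) and required > 1:
        log.warning("dropping subjects missing a resting state: %s", list(incomplete))
        table = table[~table["subject"].isin(incomplete)].reset_index(drop=True)
    return table
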