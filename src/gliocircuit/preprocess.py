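"""ECoG preprocessing: decimation, bipolar derivation, notch, band power.

The stage order is fixed — downsample -> bipolar re-reference -> notch at the
line-noise bases and their harmonics -> band-pass + Hilbert envelope power ->
trial segmentation with condition-specific trims.  All filtering is
zero-phase (forward-backward) with 1 s reflection padding, so trial markers
never shift in latency; the trims (>= 1 s everywhere) discard whatever edge
transients survive the padding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.signal as sps

from .errors import DegenerateInputError
from .recording import TRIM_SECONDS, EcogRecording, SegmentedPower

#: quality factor of each IIR notch; narrow enough to leave high-gamma content
#: between the 79-Hz harmonics intact.
NOTCH_Q = 30.0


def _pad_filtfilt_sos(sos: np.ndarray, data: np.ndarray, fs: float) -> np.ndarray:
    pad = min(int(round(fs)), data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sps.sosfiltfilt(sos, padded, axis=-1)
    return out[..., pad:-pad] if pad else out


def _pad_filtfilt_ba(b: np.ndarray, a: np.ndarray, data: np.ndarray, fs: float) -> np.ndarray:
    pad = min(int(round(fs)), data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = sps.filtfilt(b, a, padded, axis=-1)
    return out[..., pad:-pad] if pad else out


def downsample(rec: EcogRecording, fs_target: float) -> EcogRecording:
    """Anti-aliased decimation to ``fs_target``; markers rescale with it.

    Marker onsets floor and offsets ceil in the new sample units, so a trial
    never loses retained interior time to rounding.
    """
    if fs_target > rec.fs:
        raise ValueError(f"fs_target {fs_target} exceeds recording rate {rec.fs}")
    if fs_target == rec.fs:
        return rec.with_(step="downsample:identity")
    from fractions import Fraction

    frac = Fraction(fs_target / rec.fs).limit_denominator(10_000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    ratio = fs_target / rec.fs
    markers = rec.markers.copy()
    markers["onset"] = np.floor(markers["onset"] * ratio).astype(np.int64)
    markers["offset"] = np.minimum(
        np.ceil(markers["offset"] * ratio).astype(np.int64), data.shape[1]
    )
    return rec.with_(data=data, fs=float(fs_target), markers=markers,
                     step=f"downsample:{fs_target}Hz")


def bipolar_rereference(rec: EcogRecording) -> EcogRecording:
    """Adjacent-pair subtraction within each strip (1-2, 2-3, 3-4).

    A strip of m electrodes yields m-1 derived channels; any signal common to
    the whole strip (e.g. the scalp reference) cancels exactly.
    """
    rows, derived = [], []
    for strip, grp in rec.channels.groupby("strip_id", sort=False):
        grp = grp.sort_values("index_in_strip")
        if len(grp) < 2:
            raise DegenerateInputError(
                f"strip {strip!r} has {len(grp)} channel(s); bipolar derivation needs >= 2"
            )
        idx = grp.index.to_numpy()
        for k in range(len(idx) - 1):
            a, b = idx[k], idx[k + 1]
            derived.append(rec.data[a] - rec.data[b])
            rows.append({
                "channel_id": f"{rec.channels.at[a, 'channel_id']}-{rec.channels.at[b, 'channel_id']}",
                "strip_id": strip,
                "index_in_strip": k,
            })
    channels = pd.DataFrame(rows)
    return rec.with_(data=np.asarray(derived), channels=channels, step="bipolar")


def harmonic_frequencies(base: float, nyquist: float) -> list[float]:
    """All integer harmonics of ``base`` strictly below the Nyquist frequency."""
    return [base * k for k in range(1, int(np.ceil(nyquist / base))) if base * k < nyquist]


def notch_filter(rec: EcogRecording, base_freqs) -> EcogRecording:
    """Zero-phase IIR notches at every harmonic of each base below Nyquist."""
    nyq = rec.fs / 2.0
    for base in base_freqs:
        if base >= nyq:
            raise ValueError(f"notch base {base} Hz is at or above Nyquist ({nyq} Hz)")
    data = rec.data
    for base in base_freqs:
        for f0 in harmonic_frequencies(base, nyq):
            b, a = sps.iirnotch(f0, NOTCH_Q, fs=rec.fs)
            data = _pad_filtfilt_ba(b, a, data, rec.fs)
    return rec.with_(data=data, step=f"notch:{list(base_freqs)}")


def bandpass_power(rec: EcogRecording, band) -> EcogRecording:
    """Band-limited instantaneous power: |Hilbert(bandpassed x)|^2.

    Returns a recording-shaped object whose ``data`` holds the continuous
    power time series (uV^2) of each channel.
    """
    lo, hi = band
    nyq = rec.fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) must lie strictly inside (0, {nyq})")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    pad = min(int(round(rec.fs)), rec.n_samples - 1)
    padded = np.pad(rec.data, [(0, 0), (pad, pad)], mode="reflect")
    filtered = sps.sosfiltfilt(sos, padded, axis=-1)
    n = filtered.shape[-1]
    from scipy.fft import next_fast_len

    analytic = sps.hilbert(filtered, N=next_fast_len(n), axis=-1)[..., :n]
    power = np.abs(analytic) ** 2
    power = power[:, pad : pad + rec.n_samples] if pad else power[:, : rec.n_samples]
    return rec.with_(data=power, step=f"power:{lo}-{hi}Hz")


def segment_trials(power_rec: EcogRecording, band_name: str = "hg") -> SegmentedPower:
    """Cut continuous power into trials, trimming marker-error margins.

    Rest trials lose 2 s from each end, counting trials 1 s from each end, and
    switch trials a further 3 s from the start (the initial easy phase).
    """
    fs = power_rec.fs
    trials, blocks = [], []
    for row in power_rec.markers.itertuples():
        front_s, back_s = TRIM_SECONDS[row.condition]
        a = row.onset + int(round(front_s * fs))
        b = row.offset - int(round(back_s * fs))
        if b - a <= 0:
            span = (row.offset - row.onset) / fs
            raise DegenerateInputError(
                f"trial {row.trial_id!r} ({row.condition}, {span:.2f} s) shorter than "
                f"its total trim of {front_s + back_s:.1f} s"
            )
        trials.append({"trial_id": row.trial_id, "condition": row.condition,
                       "n_samples": b - a})
        blocks.append(power_rec.data[:, a:b])
    band = _band_from_provenance(power_rec.provenance)
    return SegmentedPower(
        channel_ids=power_rec.channel_ids,
        trials=pd.DataFrame(trials),
        data=blocks,
        band=band,
        band_name=band_name,
        fs=fs,
    )


def _band_from_provenance(provenance) -> tuple:
    for step in reversed(provenance):
        if step.startswith("power:"):
            lo, hi = step.split(":")[1].removesuffix("Hz").split("-")
            return (float(lo), float(hi))
    return (np.nan, np.nan)


def preprocess(rec: EcogRecording, config, band=None, band_name: str = "hg",
               skip_notch: bool = False) -> SegmentedPower:
    """Full fixed-order pipeline from raw recording to segmented band power."""
    band = tuple(band if band is not None else config.hg_band)
    rec = downsample(rec, config.fs_target)
    rec = bipolar_rereference(rec)
    if not skip_notch:
        rec = notch_filter(rec, config.notch_bases)
    rec = bandpass_power(rec, band)
    return segment_trials(rec, band_name=band_name)


def preprocess_all_bands(rec: EcogRecording, config) -> dict:
    """Segmented power for the high-gamma band and every extra analysis band.

    The common stages (downsample, bipolar, notch) run once; only the
    band-power extraction differs per band.
    """
    rec = downsample(rec, config.fs_target)
    rec = bipolar_rereference(rec)
    rec = notch_filter(rec, config.notch_bases)
    out = {}
    for name, band in config.all_bands.items():
        out[name] = segment_trials(bandpass_power(rec, band), band_name=name)
    return out
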