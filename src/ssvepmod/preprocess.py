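"""Continuous-EEG preprocessing: re-reference, filter, downsample, epoch, reject.

The fixed pipeline order is: average-mastoid re-reference -> 1 Hz FIR
high-pass -> downsample to 256 Hz -> 60 Hz notch -> 2 s epochs with 1 s
overlap per stimulation block -> +/-100 uV artifact rejection.  The surface
Laplacian and spectral steps live in :mod:`ssvepmod.csd` and
:mod:`ssvepmod.spectral`; rejection is applied on voltage epochs before the
Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "Recording",
    "EpochSet",
    "rereference_average_mastoids",
    "highpass_fir",
    "downsample",
    "notch_line",
    "epoch_blocks",
    "reject_epochs",
    "preprocess_recording",
]


@dataclass
class Marker:
    """Stimulation-block onset marker."""

    sample: int
    block_id: int
    brightness_code: int


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts.

    ``markers`` hold block onsets (sample index, block id, brightness code in
    centered units -2..2).  ``reference`` names the current reference scheme.
    """

    data: np.ndarray  # (n_channels, n_samples), uV
    sampling_rate: float
    channel_labels: list[str]
    markers: list[Marker] = field(default_factory=list)
    reference: str = "M1"
    participant: str | int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        samples = [m.sample for m in self.markers]
        if any(s2 <= s1 for s1, s2 in zip(samples, samples[1:])):
            raise ValueError("marker sample indices must be strictly increasing")
        if samples and (samples[0] < 0 or samples[-1] >= self.data.shape[1]):
            raise ValueError("marker sample index outside the record")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class EpochSet:
    """Fixed-length epochs cut from stimulation blocks.

    ``epoch_meta`` has one row per epoch with columns ``participant``,
    ``block``, ``brightness`` and ``kept`` (False iff the rejection rule
    fired).  Epochs are in uV before the Laplacian, uV/cm^2 after.
    """

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    epoch_meta: pd.DataFrame
    sampling_rate: float
    window_length: float
    channel_labels: list[str]
    units: str = "uV"

    def __post_init__(self) -> None:
        expected = int(round(self.window_length * self.sampling_rate))
        if self.epochs.ndim != 3 or self.epochs.shape[2] != expected:
            raise ValueError(
                f"epochs must be (n, channels, {expected}) for "
                f"window {self.window_length}s at {self.sampling_rate} Hz"
            )
        if len(self.epoch_meta) != self.epochs.shape[0]:
            raise ValueError("epoch_meta rows must match epoch count")

    @property
    def kept(self) -> np.ndarray:
        return self.epoch_meta["kept"].to_numpy()

    def n_kept(self) -> int:
        return int(self.kept.sum())


def rereference_average_mastoids(
    rec: Recording, mastoids: tuple[str, str] = ("M1", "M2")
) -> Recording:
    """Re-reference to the mastoid average and drop the mastoid channels."""
    for lab in mastoids:
        if lab not in rec.channel_labels:
            raise ValueError(f"mastoid channel {lab!r} missing from recording")
    m_idx = [rec.channel_labels.index(lab) for lab in mastoids]
    ref = rec.data[m_idx].mean(axis=0)
    keep = [i for i, lab in enumerate(rec.channel_labels) if lab not in mastoids]
    data = rec.data[keep] - ref
    return replace(
        rec,
        data=data,
        channel_labels=[rec.channel_labels[i] for i in keep],
        markers=list(rec.markers),
        reference="average mastoids",
    )


def highpass_fir(
    rec: Recording, cutoff: float = 1.0, transition: float = 2.0
) -> Recording:
    """Zero-phase Hamming-windowed-sinc FIR high-pass.

    The -6 dB (half-amplitude) point lands on ``cutoff``; the transition band
    spans ``cutoff +/- transition/2``.  Delegated to :func:`mne.filter.filter_data`
    with delay-compensated single-pass application.
    """
    import mne.filter

    if rec.sampling_rate <= 2 * (cutoff + transition):
        raise ValueError("sampling rate too low for the requested high-pass")
    # mne places the half-amplitude point at l_freq - l_trans_bandwidth/2.
    l_freq = cutoff + transition / 2
    n_taps = int(round(3.3 / transition * rec.sampling_rate)) | 1
    if rec.n_samples < n_taps:
        raise ValueError(
            f"record of {rec.n_samples} samples shorter than filter order {n_taps}"
        )
    data = mne.filter.filter_data(
        rec.data,
        sfreq=rec.sampling_rate,
        l_freq=l_freq,
        h_freq=None,
        l_trans_bandwidth=transition,
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    return replace(rec, data=data, markers=list(rec.markers))


def downsample(rec: Recording, target: float = 256.0) -> Recording:
    """Polyphase resampling with built-in anti-alias filtering.

    Marker indices are remapped to the nearest new sample.
    """
    if target > rec.sampling_rate:
        raise ValueError("target rate above original sampling rate")
    frac = Fraction(target / rec.sampling_rate).limit_denominator(1000)
    data = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    ratio = target / rec.sampling_rate
    markers = [
        Marker(int(round(m.sample * ratio)), m.block_id, m.brightness_code)
        for m in rec.markers
    ]
    return replace(rec, data=data, sampling_rate=target, markers=markers)


def notch_line(rec: Recording, freq: float = 60.0, q: float = 30.0) -> Recording:
    """IIR notch at the line frequency, applied forward-backward (zero phase)."""
    if freq >= rec.sampling_rate / 2:
        raise ValueError("notch frequency at or above Nyquist")
    b, a = scipy.signal.iirnotch(freq, q, fs=rec.sampling_rate)
    data = scipy.signal.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=data, markers=list(rec.markers))


def epoch_blocks(
    rec: Recording,
    window: float = 2.0,
    overlap: float = 1.0,
    block_duration: float = 20.0,
) -> EpochSet:
    """Cut overlapping epochs from each stimulation block.

    Epochs start at the block onset sample and advance by ``window - overlap``;
    the final partial window is discarded.  A 20 s block with 2 s windows and
    1 s overlap yields 19 epochs.
    """
    if not rec.markers:
        raise ValueError("recording has no block markers")
    fs = rec.sampling_rate
    win = int(round(window * fs))
    step = int(round((window - overlap) * fs))
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    blk = int(round(block_duration * fs))
    chunks, meta = [], []
    for m in rec.markers:
        end = min(m.sample + blk, rec.n_samples)
        start = m.sample
        n_ep = 0
        while start + win <= end:
            chunks.append(rec.data[:, start : start + win])
            meta.append(
                {
                    "participant": rec.participant,
                    "block": m.block_id,
                    "brightness": m.brightness_code,
                    "kept": True,
                }
            )
            start += step
            n_ep += 1
        if n_ep == 0:
            import warnings

            warnings.warn(
                f"block {m.block_id} shorter than the epoch window; zero epochs",
                stacklevel=2,
            )
    epochs = (
        np.stack(chunks)
        if chunks
        else np.empty((0, len(rec.channel_labels), win))
    )
    return EpochSet(
        epochs=epochs,
        epoch_meta=pd.DataFrame(meta, columns=["participant", "block", "brightness", "kept"]),
        sampling_rate=fs,
        window_length=window,
        channel_labels=list(rec.channel_labels),
    )


def reject_epochs(eset: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Flag epochs whose absolute voltage exceeds ``threshold`` uV anywhere.

    The rule is any-channel, any-sample strict exceedance, applied on voltage
    epochs before the Laplacian.  Counts are recorded in ``epoch_meta``.
    """
    if eset.units != "uV":
        raise ValueError("rejection threshold applies to voltage epochs (uV)")
    exceeds = np.abs(eset.epochs).max(axis=(1, 2)) > threshold
    meta = eset.epoch_meta.copy()
    meta["kept"] = ~exceeds
    return EpochSet(
        epochs=eset.epochs,
        epoch_meta=meta,
        sampling_rate=eset.sampling_rate,
        window_length=eset.window_length,
        channel_labels=eset.channel_labels,
        units=eset.units,
    )


def preprocess_recording(
    rec: Recording,
    hp_cutoff: float = 1.0,
    hp_transition: float = 2.0,
    target_rate: float = 256.0,
    line_freq: float = 60.0,
    window: float = 2.0,
    overlap: float = 1.0,
    block_duration: float = 20.0,
    reject_threshold: float = 100.0,
    mastoids: tuple[str, str] = ("M1", "M2"),
) -> EpochSet:
    """Run the fixed preprocessing chain on one continuous recording."""
    rec = rereference_average_mastoids(rec, mastoids)
    rec = highpass_fir(rec, hp_cutoff, hp_transition)
    rec = downsample(rec, target_rate)
    rec = notch_line(rec, line_freq)
    eset = epoch_blocks(rec, window, overlap, block_duration)
    return reject_epochs(eset, reject_threshold)
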