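"""Hamming-tapered periodogram PSD and 25 Hz SSVEP power extraction.

Each 2 s epoch at 256 Hz gives a 0.5 Hz bin spacing, so the 25 Hz stimulation
frequency falls exactly on a bin (no zero padding).  Per-epoch linear power at
that bin is averaged across an intensity block's kept epochs and then
converted to dB; the average-then-log order is the package default, with a
flag for the log-then-average alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.signal

from .preprocess import EpochSet

__all__ = ["psd_epoch", "ssvep_power", "build_psd_table"]


def psd_epoch(epoch: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hamming-tapered periodogram of one epoch.

    Parameters
    ----------
    epoch
        ``(..., n_samples)`` array; the taper spans the whole epoch.
    sampling_rate
        Sampling rate in Hz.

    Returns
    -------
    freqs, psd
        Frequencies (Hz) and power spectral density (power per Hz, density
        normalization) along the last axis.
    """
    epoch = np.asarray(epoch, dtype=float)
    if np.isnan(epoch).any():
        raise ValueError("epoch contains NaN samples")
    if epoch.shape[-1] % 2:
        raise ValueError("epoch length must be even")
    return scipy.signal.periodogram(
        epoch,
        fs=sampling_rate,
        window="hamming",
        detrend=False,
        scaling="density",
        axis=-1,
    )


def _bin_index(freqs: np.ndarray, f0: float) -> int:
    k = int(np.argmin(np.abs(freqs - f0)))
    if abs(freqs[k] - f0) > 1e-6:
        raise ValueError(f"{f0} Hz does not fall on a PSD bin (nearest {freqs[k]})")
    return k


def ssvep_power(
    eset: EpochSet,
    f0: float = 25.0,
    db_of_mean: bool = True,
) -> pd.DataFrame:
    """Average stimulation-frequency power per (block, channel), in dB.

    Kept epochs within each block are averaged at the ``f0`` bin in linear
    power units and then converted with ``10*log10`` (``db_of_mean=True``,
    default); ``db_of_mean=False`` averages per-epoch dB instead.  Blocks with
    zero kept epochs yield NaN.

    Returns a long DataFrame with columns ``participant``, ``block``,
    ``brightness``, ``electrode``, ``psd_db``, ``n_epochs_used``.
    """
    freqs, psd = psd_epoch(eset.epochs, eset.sampling_rate)  # (e, c, f)
    k = _bin_index(freqs, f0)
    power = psd[:, :, k]  # (epochs, channels)
    meta = eset.epoch_meta
    rows = []
    for (participant, block, brightness), idx in meta.groupby(
        ["participant", "block", "brightness"], sort=True, dropna=False
    ).groups.items():
        kept = meta.loc[idx, "kept"].to_numpy()
        sel = power[np.asarray(idx)[kept]]
        if sel.shape[0] == 0:
            db = np.full(power.shape[1], np.nan)
        elif db_of_mean:
            db = 10 * np.log10(sel.mean(axis=0))
        else:
            db = (10 * np.log10(sel)).mean(axis=0)
        for c, lab in enumerate(eset.channel_labels):
            rows.append(
                {
                    "participant": participant,
                    "block": block,
                    "brightness": brightness,
                    "electrode": lab,
                    "psd_db": db[c],
                    "n_epochs_used": int(kept.sum()),
                }
            )
    return pd.DataFrame(rows)


def build_psd_table(per_participant: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-participant SSVEP power tables into one long table.

    Keys are (participant, electrode, brightness); duplicates raise, and rows
    with NaN power (all epochs of a block rejected) are kept but flagged via
    ``missing``.
    """
    table = pd.concat(per_participant, ignore_index=True)
    dup = table.duplicated(subset=["participant", "electrode", "brightness"])
    if dup.any():
        first = table.loc[dup.idxmax(), ["participant", "electrode", "brightness"]]
        raise ValueError(f"duplicate PSD key: {tuple(first)}")
    table = table.copy()
    table["missing"] = ~np.isfinite(table["psd_db"])
    return table
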