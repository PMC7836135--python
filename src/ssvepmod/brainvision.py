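"""BrainVision triplet (.vhdr/.eeg/.vmrk) export and import.

The writer emits IEEE float-32 multiplexed binary data in microvolts with
block onsets as stimulus markers (``S  1`` .. ``S  5`` encode brightness
codes -2..2).  Reading goes through :func:`mne.io.read_raw_brainvision` and
reconstructs the package's :class:`~ssvepmod.preprocess.Recording`.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .preprocess import Marker, Recording

__all__ = ["write_brainvision", "read_brainvision"]

_STIM_OFFSET = 3  # stimulus id = brightness code + 3 -> S1..S5


def write_brainvision(rec: Recording, vhdr_path: str | Path) -> Path:
    """Write a recording as a BrainVision triplet next to ``vhdr_path``."""
    vhdr = Path(vhdr_path)
    if vhdr.suffix != ".vhdr":
        raise ValueError("path must end in .vhdr")
    stem = vhdr.stem
    eeg, vmrk = vhdr.with_suffix(".eeg"), vhdr.with_suffix(".vmrk")

    interval_us = 1e6 / rec.sampling_rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={len(rec.channel_labels)}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, m in enumerate(rec.markers, start=2):
        stim = m.brightness_code + _STIM_OFFSET
        mlines.append(f"Mk{k}=Stimulus,S{stim:>3},{m.sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr


def read_brainvision(vhdr_path: str | Path, participant=None) -> Recording:
    """Load a BrainVision triplet back into a :class:`Recording` (uV)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> uV
    markers = []
    block = 0
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        match = re.match(r"Stimulus/S\s*(\d+)", desc)
        if not match:
            continue
        block += 1
        markers.append(
            Marker(
                sample=int(round(onset * raw.info["sfreq"])),
                block_id=block,
                brightness_code=int(match.group(1)) - _STIM_OFFSET,
            )
        )
    return Recording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        markers=markers,
        participant=participant,
    )
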