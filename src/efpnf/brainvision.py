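"""BrainVision triplet reader/writer.

The study's EEG was recorded with Brain Vision tooling, so the on-disk
dialect is the BrainVision Core format: an INI-style ``.vhdr`` header, a
raw binary ``.eeg`` payload, and a ``.vmrk`` marker file.  The writer
emits multiplexed little-endian IEEE_FLOAT_32; the reader additionally
accepts INT_16 with per-channel resolution scaling.  Marker positions
are 1-based sample indices per the dialect rule.
"""

from __future__ import annotations

import configparser
import os

import numpy as np

from .synthetic import EEGRecording

_SUPPORTED_FORMATS = {"IEEE_FLOAT_32": ("<f4", 4), "INT_16": ("<i2", 2)}


def write_brainvision(recording: EEGRecording, basename: str) -> tuple:
    """Write ``basename``.vhdr/.eeg/.vmrk; returns the three paths.

    Samples are stored channel-multiplexed as little-endian float32 in
    microvolts (resolution 1).  Markers become ``Stimulus`` entries with
    1-based sample positions; a leading ``New Segment`` marker is always
    present.
    """
    base = os.path.basename(basename)
    vhdr, eeg, vmrk = (basename + ext for ext in (".vhdr", ".eeg", ".vmrk"))
    n_ch = len(recording.channel_labels)
    sampling_interval_us = 1e6 / recording.rate
    si = (f"{sampling_interval_us:.0f}" if float(sampling_interval_us).is_integer()
          else f"{sampling_interval_us!r}")
    try:
        lines = [
            "Brain Vision Data Exchange Header File Version 1.0",
            "; Written by efpnf",
            "",
            "[Common Infos]",
            "Codepage=UTF-8",
            f"DataFile={base}.eeg",
            f"MarkerFile={base}.vmrk",
            "DataFormat=BINARY",
            "DataOrientation=MULTIPLEXED",
            f"NumberOfChannels={n_ch}",
            f"SamplingInterval={si}",
            "",
            "[Binary Infos]",
            "BinaryFormat=IEEE_FLOAT_32",
            "",
            "[Channel Infos]",
        ]
        for i, ch in enumerate(recording.channel_labels, start=1):
            lines.append(f"Ch{i}={ch},,1,µV")
        with open(vhdr, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

        recording.data.T.astype("<f4").tofile(eeg)

        mlines = [
            "Brain Vision Data Exchange Marker File, Version 1.0",
            "",
            "[Common Infos]",
            "Codepage=UTF-8",
            f"DataFile={base}.eeg",
            "",
            "[Marker Infos]",
            "Mk1=New Segment,,1,1,0,00000000000000000000",
        ]
        for k, (t, label) in enumerate(recording.markers, start=2):
            pos = int(round(t * recording.rate)) + 1  # 1-based dialect rule
            mlines.append(f"Mk{k}=Stimulus,{label},{pos},1,0")
        with open(vmrk, "w", encoding="utf-8") as fh:
            fh.write("\n".join(mlines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing BrainVision triplet {basename!r}: {exc}") from exc
    return vhdr, eeg, vmrk


def _parse_ini(path: str) -> configparser.ConfigParser:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    body = "\n".join(line for line in text.splitlines()
                     if not line.startswith(("Brain Vision", ";")))
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str
    cp.read_string(body)
    return cp


def read_brainvision(basename: str) -> EEGRecording:
    """Read a BrainVision triplet written in the supported dialect subset.

    Supports BINARY/MULTIPLEXED data in IEEE_FLOAT_32 or INT_16 (scaled
    by the per-channel resolution).  Raises a format error naming the
    offending field for anything else, and on header/data size mismatch.
    """
    vhdr = basename + ".vhdr"
    cp = _parse_ini(vhdr)
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError(f"{vhdr}: unsupported DataFormat={common.get('DataFormat')}")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError(
            f"{vhdr}: unsupported DataOrientation={common.get('DataOrientation')}")
    n_ch = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])
    fmt = cp["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32")
    if fmt not in _SUPPORTED_FORMATS:
        raise ValueError(f"{vhdr}: unsupported BinaryFormat={fmt}")
    dtype, itemsize = _SUPPORTED_FORMATS[fmt]
    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        entry = cp["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        labels.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))
    eeg_path = basename + ".eeg"
    nbytes = os.path.getsize(eeg_path)
    if nbytes % (n_ch * itemsize) != 0:
        expected = nbytes // (n_ch * itemsize) + 1
        raise ValueError(
            f"{eeg_path}: truncated payload; expected a multiple of "
            f"{n_ch * itemsize} bytes per sample frame "
            f"(found {nbytes} bytes, i.e. a partial frame of sample {expected})")
    raw = np.fromfile(eeg_path, dtype=dtype).reshape(-1, n_ch).T.astype(float)
    data = raw * np.asarray(resolutions)[:, None]
    markers = []
    vmrk = basename + ".vmrk"
    if os.path.exists(vmrk):
        mp = _parse_ini(vmrk)
        for key, entry in mp["Marker Infos"].items():
            parts = entry.split(",")
            mtype, desc, pos = parts[0], parts[1], int(parts[2])
            if mtype == "New Segment":
                continue
            markers.append(((pos - 1) / rate, desc))
    return EEGRecording(data=data, rate=rate, channel_labels=labels,
                        markers=markers)


__all__ = ["write_brainvision", "read_brainvision"]
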