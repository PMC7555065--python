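"""File formats: Praat TextGrid, TSV annotation mirror, WAV, neural container.

The neural container is a raw little-endian float32 array (channels x time,
C order) next to a JSON sidecar describing the sampling rate and channel
metadata.  WAV files are written as float32 through :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .fragments import Annotation, Interval

__all__ = [
    "write_textgrid",
    "read_textgrid",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "write_wav",
    "read_wav",
    "write_neural",
    "read_neural",
]

_TIERS = ("words", "overlap", "nonspeech", "hand")


def _tier_intervals(ann: Annotation, tier: str) -> list[Interval]:
    return getattr(ann, tier)


def write_textgrid(path: str | Path, ann: Annotation, total_duration: float | None = None) -> None:
    """Write a long-format Praat TextGrid with the four annotation tiers.

    Gaps between labeled intervals are filled with empty-label intervals as
    Praat requires a full tier partition.
    """
    xmax = total_duration if total_duration is not None else max(ann.span, 1e-3)
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(_TIERS)}",
        "item []:",
    ]
    for ti, tier in enumerate(_TIERS, start=1):
        labeled = _tier_intervals(ann, tier)
        full: list[Interval] = []
        cursor = 0.0
        for iv in labeled:
            if iv.onset - cursor > 1e-9:
                full.append(Interval(cursor, iv.onset, ""))
            full.append(iv)
            cursor = iv.offset
        if xmax - cursor > 1e-9:
            full.append(Interval(cursor, xmax, ""))
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f'        name = "{tier}"',
            "        xmin = 0",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(full)}",
        ]
        for ii, iv in enumerate(full, start=1):
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {iv.onset:.6f}",
                f"            xmax = {iv.offset:.6f}",
                f'            text = "{iv.label}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_textgrid(path: str | Path) -> Annotation:
    """Parse the long TextGrid format written by :func:`write_textgrid`."""
    tiers: dict[str, list[Interval]] = {t: [] for t in _TIERS}
    current: str | None = None
    xmin = xmax = None
    label = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("name ="):
            current = line.split("=", 1)[1].strip().strip('"')
        elif line.startswith("intervals ["):
            xmin = xmax = label = None
        elif line.startswith("xmin =") and current is not None:
            xmin = float(line.split("=", 1)[1])
        elif line.startswith("xmax =") and current is not None:
            xmax = float(line.split("=", 1)[1])
        elif line.startswith("text ="):
            label = line.split("=", 1)[1].strip().strip('"')
            if current in tiers and xmin is not None and xmax is not None and label != "":
                tiers[current].append(Interval(xmin, xmax, label))
    return Annotation(**tiers)


def write_annotation_tsv(path: str | Path, ann: Annotation) -> None:
    rows = ["onset\toffset\ttier\tlabel"]
    for tier in _TIERS:
        for iv in _tier_intervals(ann, tier):
            rows.append(f"{iv.onset:.6f}\t{iv.offset:.6f}\t{tier}\t{iv.label}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_annotation_tsv(path: str | Path) -> Annotation:
    tiers: dict[str, list[Interval]] = {t: [] for t in _TIERS}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        onset, offset, tier, *rest = line.split("\t")
        label = rest[0] if rest else ""
        if tier in tiers:
            tiers[tier].append(Interval(float(onset), float(offset), label))
    return Annotation(**tiers)


def read_annotation(path: str | Path) -> Annotation:
    """Dispatch on extension: .TextGrid or .tsv."""
    p = Path(path)
    if p.suffix.lower() in {".textgrid", ".tg"}:
        return read_textgrid(p)
    return read_annotation_tsv(p)


def write_wav(path: str | Path, samples: np.ndarray, fs: int) -> None:
    wavfile.write(str(path), fs, np.asarray(samples, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    else:
        data = data.astype(np.float64)
    if data.ndim > 1:
        data = data.mean(axis=1)
    return data, int(fs)


def write_neural(path: str | Path, samples: np.ndarray, fs: float, channel_meta: list[dict]) -> None:
    """Raw float32 channels-x-time array plus a JSON sidecar (same stem)."""
    path = Path(path)
    arr = np.ascontiguousarray(samples, dtype="<f4")
    arr.tofile(path)
    sidecar = {
        "fs": fs,
        "n_channels": int(arr.shape[0]),
        "n_samples": int(arr.shape[1]),
        "dtype": "<f4",
        "order": "C",
        "channels": channel_meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_neural(path: str | Path) -> tuple[np.ndarray, float, list[dict]]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=sidecar["dtype"])
    arr = arr.reshape(sidecar["n_channels"], sidecar["n_samples"]).astype(np.float64)
    return arr, float(sidecar["fs"]), sidecar["channels"]
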