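"""Text/image formats: trace CSV, HR CSV, PNG frame directories with ROI
sidecars, and the session report JSON."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np

from ..errors import EmptyInputError, MirrorVitalsError, ParseError
from ..signal_core import FaceObservation, RGBTrace

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


# -- trace CSV ---------------------------------------------------------------

def write_trace_csv(trace: RGBTrace, path) -> None:
    """Write ``time_s,R,G,B`` at full float precision (repr round-trip)."""
    times = trace.times
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "R", "G", "B"])
        for t, (r, g, b) in zip(times, trace.values):
            writer.writerow([repr(float(t)), repr(float(r)), repr(float(g)), repr(float(b))])


def read_trace_csv(path) -> RGBTrace:
    """Parse a ``time_s,R,G,B`` CSV; malformed rows raise with line numbers."""
    times: List[float] = []
    rows: List[Tuple[float, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ParseError("empty file", line=1)
        if [h.strip() for h in header] != ["time_s", "R", "G", "B"]:
            raise ParseError(f"expected header time_s,R,G,B, got {','.join(header)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"expected 4 columns, got {len(row)}", line=lineno)
            try:
                t, r, g, b = (float(cell) for cell in row)
            except ValueError:
                raise ParseError(f"non-numeric cell in {row}", line=lineno) from None
            times.append(t)
            rows.append((r, g, b))
    if not rows:
        raise EmptyInputError(f"no samples in {path}")
    times_arr = np.asarray(times)
    if len(times_arr) > 1:
        fs = (len(times_arr) - 1) / (times_arr[-1] - times_arr[0])
    else:
        fs = 1.0
    return RGBTrace(fs=fs, values=np.asarray(rows), t0=float(times_arr[0]))


# -- HR CSV ------------------------------------------------------------------

def write_hr_csv(timestamps: Sequence[float], bpm: Sequence[float], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "bpm"])
        for t, v in zip(timestamps, bpm):
            writer.writerow([repr(float(t)), repr(float(v))])


def read_hr_csv(path) -> Tuple[np.ndarray, np.ndarray]:
    times, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["time_s", "bpm"]:
            raise ParseError("expected header time_s,bpm", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"expected 2 columns, got {len(row)}", line=lineno)
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except ValueError:
                raise ParseError(f"non-numeric cell in {row}", line=lineno) from None
    if not times:
        raise EmptyInputError(f"no samples in {path}")
    return np.asarray(times), np.asarray(values)


# -- frame directories -------------------------------------------------------

def write_frame_sequence(
    frames: Sequence[np.ndarray],
    rois: Sequence[FaceObservation],
    out_dir,
    fs: float,
) -> None:
    """Numbered 8-bit PNGs plus a JSON sidecar with per-frame ROI boxes.

    Frames are clipped to [0, 255] and quantized; the sidecar records fs so
    timestamps can be reconstructed on read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = {"fs": fs, "frames": []}
    for i, (frame, roi) in enumerate(zip(frames, rois)):
        name = f"frame_{i:06d}.png"
        img = np.clip(np.asarray(frame), 0, 255).astype(np.uint8)
        iio.imwrite(out / name, img)
        x, y, w, h = roi.box
        sidecar["frames"].append(
            {"frame_index": i, "file": name, "x": x, "y": y, "w": w, "h": h,
             "confidence": roi.confidence}
        )
    (out / "rois.json").write_text(json.dumps(sidecar, indent=1))


def read_frame_source(
    path, fs: Optional[float] = None
) -> Iterator[Tuple[float, np.ndarray, Optional[FaceObservation]]]:
    """Yield ``(timestamp, frame, roi_or_None)`` from a frame directory or
    video container.

    Directories use the ``rois.json`` sidecar when present (for fs and per
    frame ROIs); otherwise ``fs`` must be supplied and the ROI defaults to
    the full frame.  Container files are decoded through imageio when a
    suitable plugin is available.
    """
    p = Path(path)
    if not p.exists():
        raise MirrorVitalsError(f"frame source {path} does not exist")
    if p.is_dir():
        sidecar_path = p / "rois.json"
        rois_by_index = {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            fs = sidecar.get("fs", fs)
            for entry in sidecar["frames"]:
                rois_by_index[entry["frame_index"]] = FaceObservation(
                    box=(entry["x"], entry["y"], entry["w"], entry["h"]),
                    confidence=entry["confidence"],
                )
        if fs is None:
            raise MirrorVitalsError("fs required when no rois.json sidecar is present")
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise EmptyInputError(f"no image frames in {path}")
        for i, f in enumerate(files):
            frame = np.asarray(iio.imread(f), dtype=float)
            if frame.ndim == 2:
                frame = np.stack([frame] * 3, axis=-1)
            roi = rois_by_index.get(i, FaceObservation(box=(0, 0, frame.shape[1], frame.shape[0])))
            yield i / fs, frame, roi
    else:
        try:
            meta = iio.immeta(p, exclude_applied=False)
            frames = iio.imiter(p)
        except Exception as exc:
            raise MirrorVitalsError(f"cannot decode video {path}: {exc}") from exc
        rate = fs or meta.get("fps") or 30.0
        for i, frame in enumerate(frames):
            frame = np.asarray(frame, dtype=float)
            yield i / rate, frame, FaceObservation(box=(0, 0, frame.shape[1], frame.shape[0]))


# -- session report ----------------------------------------------------------

def write_session_report(path, estimates, trigger_log, config_dict, seed) -> None:
    report = {
        "config": config_dict,
        "seed": seed,
        "windows": [
            {
                "t_start": est.window[0],
                "t_end": est.window[1],
                "hr_bpm": est.hr_bpm,
                "spo2_pct": est.spo2_pct,
                "snr": est.snr if np.isfinite(est.snr) else None,
                "valid": est.valid,
                "reasons": est.reasons,
            }
            for est in estimates
        ],
        "trigger_log": trigger_log,
    }
    Path(path).write_text(json.dumps(report, indent=1))
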