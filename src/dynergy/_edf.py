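"""Minimal EDF (European Data Format) codec.

Supports the plain 16-bit EDF layout: one fixed header, one signal-header
block, and contiguous little-endian int16 data records.  Enough to round-trip
multichannel recordings for this package; no EDF+ annotations.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

_HDR = 256  # bytes in the fixed header and per-signal header block


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw.ljust(width, b" ")


def write_edf(path, data: np.ndarray, fs: float, channel_names) -> None:
    """Write ``channels x samples`` float data as 16-bit EDF.

    Values are linearly quantized per channel onto the int16 range, so the
    round trip is approximate (~1e-4 relative for well-scaled signals).
    """
    data = np.asarray(data, dtype=float)
    ns, nsamp = data.shape
    if ns != len(channel_names):
        raise ValueError("channel_names length must match data rows")
    # one record per second when the sample count allows it, else one record
    if fs == int(fs) and nsamp % int(fs) == 0:
        spr = int(fs)
        n_records = nsamp // spr
        rec_dur = 1.0
    else:
        spr = nsamp
        n_records = 1
        rec_dur = nsamp / fs

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    # guard constant channels: EDF forbids physical_min == physical_max
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header_bytes = _HDR + _HDR * ns
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate X X X X", 80))
        fh.write(_field(now.strftime("%d.%m.%y"), 8))
        fh.write(_field(now.strftime("%H.%M.%S"), 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field(f"{rec_dur:g}", 8))
        fh.write(_field(str(ns), 4))
        for name in channel_names:
            fh.write(_field(str(name), 16))
        for _ in range(ns):
            fh.write(_field("", 80))
        for _ in range(ns):
            fh.write(_field("uV", 8))
        for v in pmin:
            fh.write(_field(f"{v:.8g}"[:8], 8))
        for v in pmax:
            fh.write(_field(f"{v:.8g}"[:8], 8))
        for _ in range(ns):
            fh.write(_field(str(dmin), 8))
        for _ in range(ns):
            fh.write(_field(str(dmax), 8))
        for _ in range(ns):
            fh.write(_field("", 80))
        for _ in range(ns):
            fh.write(_field(str(spr), 8))
        for _ in range(ns):
            fh.write(_field("", 32))
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path):
    """Read a 16-bit EDF file.

    Returns ``(data, fs, channel_names)`` with data as float64
    channels x samples in physical units.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(_HDR)
        if len(hdr) < _HDR:
            raise IOError(f"{path}: truncated EDF header")
        try:
            n_records = int(hdr[236:244].decode("ascii").strip())
            rec_dur = float(hdr[244:252].decode("ascii").strip())
            ns = int(hdr[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise IOError(f"{path}: malformed EDF header") from exc

        sig_hdr = fh.read(_HDR * ns)

        # signal header is field-major: all labels, then all transducers, ...
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        pos = 0
        blocks = {}
        for key, w in zip(
            ["label", "transducer", "dim", "pmin", "pmax", "dmin", "dmax",
             "prefilter", "spr", "reserved"],
            widths,
        ):
            blk = sig_hdr[pos: pos + w * ns]
            blocks[key] = [
                blk[i * w:(i + 1) * w].decode("ascii").strip()
                for i in range(ns)
            ]
            pos += w * ns

        names = blocks["label"]
        pmin = np.array([float(v) for v in blocks["pmin"]])
        pmax = np.array([float(v) for v in blocks["pmax"]])
        dmin = np.array([float(v) for v in blocks["dmin"]])
        dmax = np.array([float(v) for v in blocks["dmax"]])
        spr = [int(v) for v in blocks["spr"]]

        raw = fh.read()

    total = sum(spr) * 2
    if len(raw) < total * n_records:
        raise IOError(f"{path}: truncated EDF data section")

    out = [np.empty(s * n_records) for s in spr]
    cursor = 0
    for r in range(n_records):
        for i, s in enumerate(spr):
            chunk = np.frombuffer(raw, dtype="<i2", count=s, offset=cursor)
            cursor += s * 2
            out[i][r * s:(r + 1) * s] = chunk
    scale = (pmax - pmin) / (dmax - dmin)
    data = np.vstack([
        (out[i] - dmin[i]) * scale[i] + pmin[i] for i in range(ns)
    ])
    if not all(s == spr[0] for s in spr):
        raise IOError(f"{path}: heterogeneous sampling rates not supported")
    fs = spr[0] / rec_dur
    if not math.isfinite(fs) or fs <= 0:
        raise IOError(f"{path}: invalid record duration")
    return data, fs, names
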