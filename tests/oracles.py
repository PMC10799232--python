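"""Independent readers and brute-force references used as test oracles.

These implementations deliberately share no code with the package writers:
the FCS reader follows the FCS 3.1 byte layout, the ROI reader the ImageJ
binary ``.roi`` layout, and the drift oracle is exhaustive cross-correlation.
"""

from __future__ import annotations

import struct
import zipfile

import numpy as np


def read_fcs(path) -> tuple[dict, np.ndarray]:
    """Parse an FCS file: (TEXT keywords, events array of shape ($TOT, $PAR))."""
    raw = open(path, "rb").read()
    version = raw[0:6].decode()
    assert version.startswith("FCS"), version
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii")
    delim = text[0]
    parts = text[1:].split(delim)
    # trailing delimiter produces one empty tail entry
    if parts and parts[-1] == "":
        parts = parts[:-1]
    keywords = dict(zip(parts[0::2], parts[1::2]))

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    if n_tot == 0:
        return keywords, np.empty((0, n_par))
    data_begin = int(raw[26:34]) or int(keywords["$BEGINDATA"])
    data_end = int(raw[34:42]) or int(keywords["$ENDDATA"])
    blob = raw[data_begin : data_end + 1]

    assert keywords["$DATATYPE"] == "F"
    byteord = keywords["$BYTEORD"]
    endian = "<" if byteord in ("1,2,3,4",) else ">"
    values = np.frombuffer(blob, dtype=f"{endian}f4")
    return keywords, values.reshape(n_tot, n_par)


def read_imagej_roi(blob: bytes) -> dict:
    """Parse one binary ImageJ ROI record (big-endian, 64-byte header)."""
    assert blob[0:4] == b"Iout", "bad ROI magic"
    version, = struct.unpack(">h", blob[4:6])
    roi_type = blob[6]
    top, left, bottom, right, n = struct.unpack(">4hH", blob[8:18])
    xs = np.frombuffer(blob[64 : 64 + 2 * n], dtype=">i2").astype(int) + left
    ys = np.frombuffer(blob[64 + 2 * n : 64 + 4 * n], dtype=">i2").astype(int) + top
    return {
        "version": version,
        "type": roi_type,
        "top": top,
        "left": left,
        "bottom": bottom,
        "right": right,
        "n": n,
        "x": xs,
        "y": ys,
    }


def read_roi_zip(path) -> dict[str, dict]:
    out = {}
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            out[name.removesuffix(".roi")] = read_imagej_roi(zf.read(name))
    return out


def brute_force_shift(reference: np.ndarray, moving: np.ndarray, max_shift: int = 10):
    """Exhaustive integer (dx, dy) maximising NCC of the aligned overlap.

    (dx, dy) is the content displacement: moving ≈ roll(reference, (dy, dx)).
    """
    best, best_score = (0, 0), -np.inf
    h, w = reference.shape
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ry0, ry1 = max(-dy, 0), h + min(-dy, 0)
            rx0, rx1 = max(-dx, 0), w + min(-dx, 0)
            my0, my1 = max(dy, 0), h + min(dy, 0)
            mx0, mx1 = max(dx, 0), w + min(dx, 0)
            a = reference[ry0:ry1, rx0:rx1].astype(float).ravel()
            b = moving[my0:my1, mx0:mx1].astype(float).ravel()
            if a.size < 16:
                continue
            a = a - a.mean()
            b = b - b.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            score = float(np.dot(a, b) / denom) if denom else -np.inf
            if score > best_score:
                best_score, best = score, (dx, dy)
    return best
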