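"""Minimal FCS 3.0 reader/writer.

Covers the dialect used throughout this project and the common variants a
clinical cytometer emits: a single dataset per file, list-mode data
(``$MODE/L``), ``$DATATYPE`` F (float32) or I (unsigned integer), byte order
little- (``1,2,3,4``) or big-endian (``4,3,2,1``), detector names in ``$PnN``,
marker (stain) names in ``$PnS`` and the acquisition spillover matrix in the
``$SPILLOVER`` keyword (``n,det_1,...,det_n,v_11,v_12,...`` row-major).

Writing always emits float32 little-endian with ``/`` as the TEXT delimiter.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

__all__ = ["FcsData", "read_fcs", "write_fcs", "format_spillover", "parse_spillover"]

_HEADER_LEN = 58
_TEXT_START = 256  # fixed TEXT offset leaves room for the 58-byte header


class FcsParseError(ValueError):
    """Raised when a file cannot be parsed as FCS 3.0."""


class FcsData:
    """Events plus the TEXT keywords of one FCS dataset."""

    def __init__(self, events: np.ndarray, channels: list[str], markers: list[str],
                 keywords: dict[str, str]):
        self.events = events
        self.channels = channels
        self.markers = markers
        self.keywords = keywords

    @property
    def spillover(self) -> tuple[np.ndarray, list[str]] | None:
        raw = self.keywords.get("$SPILLOVER") or self.keywords.get("SPILL")
        if raw is None:
            return None
        return parse_spillover(raw)


def format_spillover(matrix: np.ndarray, detectors: list[str]) -> str:
    matrix = np.asarray(matrix, dtype=float)
    n = len(detectors)
    if matrix.shape != (n, n):
        raise ValueError(f"spillover matrix shape {matrix.shape} does not match {n} detectors")
    cells = [str(n)] + list(detectors) + [repr(float(v)) for v in matrix.ravel()]
    return ",".join(cells)


def parse_spillover(text: str) -> tuple[np.ndarray, list[str]]:
    parts = [p.strip() for p in text.split(",")]
    n = int(parts[0])
    names = parts[1 : 1 + n]
    values = np.array([float(v) for v in parts[1 + n : 1 + n + n * n]], dtype=float)
    if values.size != n * n:
        raise FcsParseError(f"$SPILLOVER declares {n} detectors but carries {values.size} values")
    return values.reshape(n, n), names


def write_fcs(path: str | Path, events: np.ndarray, channels: list[str],
              markers: list[str] | None = None,
              spillover: tuple[np.ndarray, list[str]] | None = None,
              extra_keywords: dict[str, str] | None = None) -> Path:
    """Write one float32 little-endian FCS 3.0 dataset.

    ``channels`` fill ``$PnN`` (detector names); ``markers``, when given, fill
    ``$PnS``.  ``spillover`` is a ``(matrix, detector_names)`` pair stored in
    ``$SPILLOVER``.
    """
    path = Path(path)
    events = np.ascontiguousarray(events, dtype="<f4")
    n_events, n_par = events.shape
    if len(channels) != n_par:
        raise ValueError("number of channel names must match event-matrix width")
    if markers is not None and len(markers) != n_par:
        raise ValueError("number of marker names must match event-matrix width")

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_events),
    }
    top = 262144
    for i, name in enumerate(channels, start=1):
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}N"] = name
        kw[f"$P{i}R"] = str(top)
        if markers is not None:
            kw[f"$P{i}S"] = markers[i - 1]
    if spillover is not None:
        kw["$SPILLOVER"] = format_spillover(*spillover)
    if extra_keywords:
        kw.update(extra_keywords)
    # data offsets are written fixed-width so the TEXT length is stable
    kw["$BEGINDATA"] = "%012d" % 0
    kw["$ENDDATA"] = "%012d" % 0

    def render(d: dict[str, str]) -> bytes:
        out = "/"
        for k, v in d.items():
            v = str(v)
            if "/" in v:
                raise ValueError(f"keyword value for {k} may not contain the delimiter '/'")
            out += f"{k}/{v}/"
        return out.encode("ascii")

    text = render(kw)
    data_start = _TEXT_START + len(text)
    data_end = data_start + events.nbytes - 1
    kw["$BEGINDATA"] = "%012d" % data_start
    kw["$ENDDATA"] = "%012d" % data_end
    text = render(kw)
    text_end = _TEXT_START + len(text) - 1

    header = b"FCS3.0    " + b"".join(
        b"%8d" % v for v in (_TEXT_START, text_end, data_start, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (_TEXT_START - _HEADER_LEN))
        fh.write(text)
        fh.write(events.tobytes())
    return path


def _read_segment(buf: bytes, start: int, end: int, what: str) -> bytes:
    if end < start or len(buf) <= end:
        raise FcsParseError(
            f"truncated FCS file: {what} segment [{start}, {end}] exceeds file size {len(buf)}"
        )
    return buf[start : end + 1]


def read_fcs(path: str | Path) -> FcsData:
    """Read a single-dataset FCS 3.0 file (``$DATATYPE`` F or I)."""
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < _HEADER_LEN:
        raise FcsParseError(f"truncated FCS file: {len(buf)} bytes is shorter than the 58-byte header")
    version = buf[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsParseError(f"unsupported FCS version {version!r}; this reader handles FCS 3.0/3.1")
    offsets = []
    for i in range(6):
        field = buf[10 + 8 * i : 18 + 8 * i].strip() or b"0"
        offsets.append(int(field))
    text_start, text_end, data_start, data_end = offsets[:4]

    text = _read_segment(buf, text_start, text_end, "TEXT").decode("ascii", errors="replace")
    delim, body = text[0], text[1:]
    parts = body.split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    keywords = {parts[i].strip(): parts[i + 1] for i in range(0, len(parts) - 1, 2)}

    if data_start == 0:
        data_start = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    mode = keywords.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise FcsParseError(f"unsupported $MODE {mode!r}; only list mode is handled")

    bits = [int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsParseError("$DATATYPE F requires $PnB 32")
        dtype = np.dtype(endian + "f4")
        raw = _read_segment(buf, data_start, data_start + 4 * n_par * n_tot - 1, "DATA")
        events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (16, 32):
            raise FcsParseError("$DATATYPE I supported only for uniform $PnB 16 or 32")
        nbytes = bits[0] // 8
        dtype = np.dtype(f"{endian}u{nbytes}")
        raw = _read_segment(buf, data_start, data_start + nbytes * n_par * n_tot - 1, "DATA")
        events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(float)
    else:
        raise FcsParseError(f"unsupported $DATATYPE {datatype!r}; only F and I are handled")

    channels = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    markers = [keywords.get(f"$P{i}S", channels[i - 1]) for i in range(1, n_par + 1)]
    if "$SPILLOVER" not in keywords and "SPILL" not in keywords:
        warnings.warn(f"{path.name}: no $SPILLOVER keyword; assuming identity spillover")
    return FcsData(events, channels, markers, keywords)
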