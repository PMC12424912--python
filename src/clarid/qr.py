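"""QR code generation and read-back for identifier strings.

A self-contained Model-2 QR codec: byte mode, error-correction level L,
versions 1-5 (up to 106 payload characters, ample for both identifier
formats).  Symbols are rendered to PNG through Pillow and read back by grid
sampling, which assumes an upright, unrotated, high-contrast image such as
the ones this module writes — the supported round trip is
``read_qr(generate_qr(identifier)) == identifier``.

Reed-Solomon parity is computed over GF(256) with the standard polynomial
0x11D; on read-back the syndromes are verified (a clean image must check
out exactly) rather than corrected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import QRReadError, RangeError

__all__ = ["generate_qr", "read_qr"]

# ---------------------------------------------------------------------------
# GF(256) arithmetic and Reed-Solomon parity
# ---------------------------------------------------------------------------

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _rs_generator(n_parity: int) -> list[int]:
    gen = [1]
    for i in range(n_parity):
        nxt = [0] * (len(gen) + 1)
        for j, coef in enumerate(gen):
            nxt[j] ^= _gf_mul(coef, _EXP[i])
            nxt[j + 1] ^= coef
        gen = nxt
    return gen  # highest-degree coefficient first is gen[-1]? kept as built


def _rs_parity(data: list[int], n_parity: int) -> list[int]:
    gen = _rs_generator(n_parity)
    # polynomial long division; gen built low->high, reverse for division
    gen = gen[::-1]
    rem = list(data) + [0] * n_parity
    for i in range(len(data)):
        factor = rem[i]
        if factor:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], factor)
    return rem[len(data):]


def _rs_syndromes_ok(codewords: list[int], n_parity: int) -> bool:
    for i in range(n_parity):
        x = _EXP[i]
        acc = 0
        for c in codewords:
            acc = _gf_mul(acc, x) ^ c
        if acc:
            return False
    return True


# ---------------------------------------------------------------------------
# Version tables (error-correction level L, single RS block)
# ---------------------------------------------------------------------------

# version -> (total codewords, data codewords)
_VERSIONS_L = {1: (26, 19), 2: (44, 34), 3: (70, 55), 4: (100, 80), 5: (134, 108)}
# version -> alignment pattern center (v>=2); v1 has none
_ALIGN = {2: 18, 3: 22, 4: 26, 5: 30}

_EC_L_BITS = 0b01
_MASK_USED = 0  # (row + col) % 2 == 0


def _format_bits(ec_bits: int, mask: int) -> int:
    """15-bit format information: 5 data bits + BCH(15,5) remainder, masked."""
    data = (ec_bits << 3) | mask
    value = data << 10
    g = 0b10100110111
    for shift in range(14, 9, -1):
        if value & (1 << shift):
            value ^= g << (shift - 10)
    return ((data << 10) | value) ^ 0b101010000010010


_FORMAT_CODES = {(ec, m): _format_bits(ec, m) for ec in range(4) for m in range(8)}


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _function_modules(version: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (modules, is_function) with all function patterns placed."""
    size = 17 + 4 * version
    m = np.zeros((size, size), dtype=np.uint8)
    used = np.zeros((size, size), dtype=bool)

    def put(r, c, v):
        m[r, c] = v
        used[r, c] = True

    def finder(r0, c0):
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if 0 <= r < size and 0 <= c < size:
                    inside = 0 <= dr <= 6 and 0 <= dc <= 6
                    if inside and (dr in (0, 6) or dc in (0, 6) or (2 <= dr <= 4 and 2 <= dc <= 4)):
                        put(r, c, 1)
                    else:
                        put(r, c, 0)

    finder(0, 0)
    finder(0, size - 7)
    finder(size - 7, 0)

    for i in range(8, size - 8):
        v = 1 if i % 2 == 0 else 0
        if not used[6, i]:
            put(6, i, v)
        if not used[i, 6]:
            put(i, 6, v)

    if version >= 2:
        p = _ALIGN[version]
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                v = 1 if max(abs(dr), abs(dc)) != 1 else 0
                put(p + dr, p + dc, v)

    # dark module
    put(4 * version + 9, 8, 1)

    # reserve format information areas (filled later)
    for i in range(9):
        if i != 6:
            used[8, i] = True
            used[i, 8] = True
    for i in range(8):
        used[8, size - 1 - i] = True
        used[size - 1 - i, 8] = True
    return m, used


def _format_positions(size: int) -> tuple[list, list]:
    """Module coordinates for the two format-info copies, MSB (bit 14) first."""
    copy1 = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
             (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    copy2 = [(size - 1, 8), (size - 2, 8), (size - 3, 8), (size - 4, 8),
             (size - 5, 8), (size - 6, 8), (size - 7, 8),
             (8, size - 8), (8, size - 7), (8, size - 6), (8, size - 5),
             (8, size - 4), (8, size - 3), (8, size - 2), (8, size - 1)]
    return copy1, copy2


def _data_coordinates(size: int, used: np.ndarray) -> list[tuple[int, int]]:
    """Zigzag placement order of all non-function modules."""
    coords = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for row in rows:
            for c in (col, col - 1):
                if not used[row, c]:
                    coords.append((row, c))
        upward = not upward
        col -= 2
    return coords


def _build_bitstream(payload: bytes, version: int) -> list[int]:
    total_cw, data_cw = _VERSIONS_L[version]
    bits = []

    def push(value, n):
        for i in range(n - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)             # byte mode
    push(len(payload), 8)       # character count (8 bits for versions 1-9)
    for b in payload:
        push(b, 8)
    push(0, min(4, data_cw * 8 - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    codewords = [int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)]
    pad = (0xEC, 0x11)
    i = 0
    while len(codewords) < data_cw:
        codewords.append(pad[i % 2])
        i += 1
    parity = _rs_parity(codewords, total_cw - data_cw)
    full = codewords + parity
    assert len(full) == total_cw
    out = []
    for cw in full:
        push_bits = [(cw >> i) & 1 for i in range(7, -1, -1)]
        out.extend(push_bits)
    return out


def _make_matrix(payload: bytes) -> np.ndarray:
    version = next((v for v, (_, d) in _VERSIONS_L.items() if len(payload) <= d - 2), None)
    if version is None:
        raise RangeError(
            f"payload of {len(payload)} bytes exceeds the supported QR capacity (106)")
    size = 17 + 4 * version
    m, used = _function_modules(version)
    bitstream = _build_bitstream(payload, version)
    coords = _data_coordinates(size, used)
    for idx, (r, c) in enumerate(coords):
        bit = bitstream[idx] if idx < len(bitstream) else 0
        if (r + c) % 2 == 0:  # mask 0
            bit ^= 1
        m[r, c] = bit
    fmt = _FORMAT_CODES[(_EC_L_BITS, _MASK_USED)]
    copy1, copy2 = _format_positions(size)
    for i, (r, c) in enumerate(copy1):
        m[r, c] = (fmt >> (14 - i)) & 1
    for i, (r, c) in enumerate(copy2):
        m[r, c] = (fmt >> (14 - i)) & 1
    return m


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

QUIET_ZONE = 4
SCALE = 8


def generate_qr(identifier: str, out_path) -> Path:
    """Render *identifier* as a QR PNG and return the output path."""
    if not identifier:
        raise RangeError("cannot encode an empty identifier")
    try:
        payload = identifier.encode("ascii")
    except UnicodeEncodeError as exc:
        raise RangeError(f"identifier is not ASCII: {exc}") from exc
    m = _make_matrix(payload)
    size = m.shape[0]
    canvas = np.ones((size + 2 * QUIET_ZONE, size + 2 * QUIET_ZONE), dtype=np.uint8)
    canvas[QUIET_ZONE:QUIET_ZONE + size, QUIET_ZONE:QUIET_ZONE + size] = 1 - m
    img = Image.fromarray(canvas * 255, mode="L")
    img = img.resize((canvas.shape[1] * SCALE, canvas.shape[0] * SCALE), Image.NEAREST)
    out_path = Path(out_path)
    img.save(out_path, format="PNG")
    return out_path


def _sample_matrix(path) -> np.ndarray:
    try:
        img = Image.open(path).convert("L")
    except (OSError, ValueError) as exc:
        raise QRReadError(f"cannot open image {path}: {exc}") from exc
    arr = np.asarray(img) < 128
    if not arr.any():
        raise QRReadError("image contains no dark modules (no QR symbol)")
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    top, bottom, left, right = rows[0], rows[-1], cols[0], cols[-1]
    height, width = bottom - top + 1, right - left + 1
    if abs(height - width) > max(2, width // 20):
        raise QRReadError("dark region is not square; no QR symbol found")
    # the first dark run on the top row is the 7-module finder edge
    run = 0
    for c in range(left, right + 1):
        if arr[top, c]:
            run += 1
        else:
            break
    module = run / 7.0
    if module <= 0:
        raise QRReadError("cannot estimate module size")
    n = round(width / module)
    if n < 21 or (n - 17) % 4:
        raise QRReadError(f"implausible symbol size {n} modules")
    centers_r = top + (np.arange(n) + 0.5) * (height / n)
    centers_c = left + (np.arange(n) + 0.5) * (width / n)
    grid = arr[np.clip(centers_r.astype(int), 0, arr.shape[0] - 1)][:,
               np.clip(centers_c.astype(int), 0, arr.shape[1] - 1)]
    return grid.astype(np.uint8)


def _read_format(m: np.ndarray) -> tuple[int, int]:
    size = m.shape[0]
    copy1, copy2 = _format_positions(size)
    best = None
    for positions in (copy1, copy2):
        observed = 0
        for r, c in positions:
            observed = (observed << 1) | int(m[r, c])
        for (ec, mask), code in _FORMAT_CODES.items():
            dist = bin(observed ^ code).count("1")
            if best is None or dist < best[0]:
                best = (dist, ec, mask)
    dist, ec, mask = best
    if dist > 3:
        raise QRReadError("format information unreadable")
    return ec, mask


_MASKS = {
    0: lambda r, c: (r + c) % 2 == 0,
    1: lambda r, c: r % 2 == 0,
    2: lambda r, c: c % 3 == 0,
    3: lambda r, c: (r + c) % 3 == 0,
    4: lambda r, c: (r // 2 + c // 3) % 2 == 0,
    5: lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    6: lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    7: lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
}


def read_qr(path) -> str:
    """Read back an identifier from a QR PNG written by :func:`generate_qr`."""
    m = _sample_matrix(path)
    size = m.shape[0]
    version = (size - 17) // 4
    if version not in _VERSIONS_L:
        raise QRReadError(f"unsupported QR version {version}")
    ec, mask = _read_format(m)
    if ec != _EC_L_BITS:
        raise QRReadError("only error-correction level L symbols are supported")
    _, used = _function_modules(version)
    coords = _data_coordinates(size, used)
    mask_fn = _MASKS[mask]
    bits = [int(m[r, c]) ^ int(mask_fn(r, c)) for r, c in coords]
    total_cw, data_cw = _VERSIONS_L[version]
    if len(bits) < total_cw * 8:
        raise QRReadError("symbol too small for its declared version")
    codewords = [int("".join(map(str, bits[i:i + 8])), 2)
                 for i in range(0, total_cw * 8, 8)]
    if not _rs_syndromes_ok(codewords, total_cw - data_cw):
        raise QRReadError("Reed-Solomon check failed; symbol is corrupt")
    data = codewords[:data_cw]
    stream = 0
    for cw in data:
        stream = (stream << 8) | cw
    nbits = data_cw * 8

    def take(k):
        nonlocal nbits
        nbits -= k
        return (stream >> nbits) & ((1 << k) - 1)

    if take(4) != 0b0100:
        raise QRReadError("symbol does not use byte mode")
    count = take(8)
    if count * 8 > nbits:
        raise QRReadError("byte-mode length exceeds the data capacity")
    payload = bytes(take(8) for _ in range(count))
    try:
        return payload.decode("ascii")
    except UnicodeDecodeError as exc:
        raise QRReadError(f"payload is not ASCII: {exc}") from exc
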