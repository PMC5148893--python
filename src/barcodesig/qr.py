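"""QR-code serialization of signatures and FASTA entries.

Implements QR model-2 symbols, byte mode, error-correction level M,
versions 1-40 with automatic version selection, mask chosen by the
standard penalty score. Payloads are UTF-8; ``decode(encode(p)) == p``
byte-exactly. The decoder handles clean, axis-aligned symbol images
(the kind this package writes): it locates the symbol by its dark
bounding box, verifies the three finder patterns, reads the format
information (with BCH error tolerance), unmasks, de-interleaves and
Reed-Solomon-corrects the codewords. Only EC level M symbols are
decoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from ._galois import rs_decode, rs_encode
from ._qr_tables import (
    ALIGNMENT_POSITIONS,
    EC_BLOCKS_M,
    data_codewords_m,
    symbol_size,
    total_codewords_m,
)
from .records import BarcodeError

MAX_VERSION = 40
_EC_M_FORMAT_BITS = 0b00  # level-M indicator in the format information


class QRError(BarcodeError):
    """Raised for QR capacity, structural or decoding failures."""


@dataclass(frozen=True)
class QRPayload:
    """Text payload of a QR symbol with its inferred content kind."""

    text: str
    kind: str = "signature"  # "signature" | "fasta" | "other"

    def __post_init__(self) -> None:
        if not self.text:
            raise QRError("QR payload must be non-empty")

    @staticmethod
    def infer(text: str) -> "QRPayload":
        if text.startswith("#species="):
            kind = "signature"
        elif text.startswith(">"):
            kind = "fasta"
        else:
            kind = "other"
        return QRPayload(text=text, kind=kind)


# ---------------------------------------------------------------------------
# bit-level encoding

def _format_bits(mask: int, ec_bits: int = _EC_M_FORMAT_BITS) -> int:
    """15-bit format information: 5 data bits + BCH(15,5) + fixed XOR mask."""
    data = ec_bits << 3 | mask
    rem = data
    for _ in range(10):
        rem = (rem << 1) ^ ((rem >> 9) * 0x537)
    return ((data << 10) | rem) ^ 0x5412


def _version_bits(version: int) -> int:
    """18-bit version information (versions >= 7): 6 bits + BCH(18,6)."""
    rem = version
    for _ in range(12):
        rem = (rem << 1) ^ ((rem >> 11) * 0x1F25)
    return (version << 12) | rem


def _count_bits(version: int) -> int:
    return 8 if version <= 9 else 16


def choose_version(n_bytes: int) -> int:
    """Smallest version whose level-M byte-mode capacity fits the payload."""
    for v in range(1, MAX_VERSION + 1):
        capacity_bits = 8 * data_codewords_m(v)
        needed = 4 + _count_bits(v) + 8 * n_bytes
        if needed <= capacity_bits:
            return v
    raise QRError(
        f"payload of {n_bytes} bytes exceeds QR capacity at EC level M "
        f"(max {data_codewords_m(MAX_VERSION) - 3} bytes); split the payload"
    )


def _data_bitstream(payload: bytes, version: int) -> list[int]:
    """Byte-mode segment + terminator + padding, as a list of codewords."""
    bits: list[int] = []

    def push(value: int, n: int) -> None:
        for i in range(n - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)  # byte mode
    push(len(payload), _count_bits(version))
    for byte in payload:
        push(byte, 8)
    capacity = 8 * data_codewords_m(version)
    if len(bits) > capacity:
        raise QRError("internal: bitstream exceeds capacity")
    push(0, min(4, capacity - len(bits)))  # terminator
    if len(bits) % 8:
        push(0, 8 - len(bits) % 8)
    codewords = [
        int("".join(map(str, bits[i : i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    pad = (0xEC, 0x11)
    i = 0
    while len(codewords) < data_codewords_m(version):
        codewords.append(pad[i % 2])
        i += 1
    return codewords


def _block_structure(version: int) -> list[int]:
    """Data-codeword count of each block, in order."""
    ec, g1, d1, g2, d2 = EC_BLOCKS_M[version]
    return [d1] * g1 + [d2] * g2


def _interleave(codewords: list[int], version: int) -> list[int]:
    """Split into blocks, append RS parity, interleave both sections."""
    ec = EC_BLOCKS_M[version][0]
    sizes = _block_structure(version)
    blocks: list[list[int]] = []
    ec_blocks: list[list[int]] = []
    pos = 0
    for size in sizes:
        block = codewords[pos : pos + size]
        pos += size
        blocks.append(block)
        ec_blocks.append(rs_encode(block, ec))
    out: list[int] = []
    for i in range(max(sizes)):
        for block in blocks:
            if i < len(block):
                out.append(block[i])
    for i in range(ec):
        for block in ec_blocks:
            out.append(block[i])
    return out


def _deinterleave(codewords: list[int], version: int) -> list[list[int]]:
    """Inverse of :func:`_interleave`: per-block data+parity codewords."""
    ec = EC_BLOCKS_M[version][0]
    sizes = _block_structure(version)
    blocks: list[list[int]] = [[] for _ in sizes]
    it = iter(codewords)
    for i in range(max(sizes)):
        for b, size in enumerate(sizes):
            if i < size:
                blocks[b].append(next(it))
    ec_parts: list[list[int]] = [[] for _ in sizes]
    for i in range(ec):
        for b in range(len(sizes)):
            ec_parts[b].append(next(it))
    return [blocks[b] + ec_parts[b] for b in range(len(sizes))]


# ---------------------------------------------------------------------------
# matrix construction

def function_module_map(version: int) -> np.ndarray:
    """Boolean (size, size) map of function (non-data) modules."""
    size = symbol_size(version)
    fn = np.zeros((size, size), dtype=bool)
    for r0, c0 in ((0, 0), (0, size - 7), (size - 7, 0)):
        # finder pattern plus its separator ring
        fn[max(0, r0 - 1) : r0 + 8, max(0, c0 - 1) : c0 + 8] = True
    fn[6, :] = True  # timing rows/columns
    fn[:, 6] = True
    centers = ALIGNMENT_POSITIONS[version]
    for r in centers:
        for c in centers:
            # alignment patterns never overlap the three finder corners
            if (r < 9 and c < 9) or (r < 9 and c > size - 10) or (r > size - 10 and c < 9):
                continue
            fn[r - 2 : r + 3, c - 2 : c + 3] = True
    fn[8, 0:9] = True  # format information areas
    fn[0:9, 8] = True
    fn[8, size - 8 :] = True
    fn[size - 8 :, 8] = True
    if version >= 7:  # version information areas
        fn[0:6, size - 11 : size - 8] = True
        fn[size - 11 : size - 8, 0:6] = True
    return fn


def _draw_function_patterns(matrix: np.ndarray, version: int) -> None:
    size = matrix.shape[0]
    for r0, c0 in ((0, 0), (0, size - 7), (size - 7, 0)):
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < size and 0 <= c < size):
                    continue
                dark = max(abs(dr - 3), abs(dc - 3)) != 2 and 0 <= dr <= 6 and 0 <= dc <= 6
                matrix[r, c] = 1 if dark else 0
    for i in range(8, size - 8):
        matrix[6, i] = matrix[i, 6] = 1 - i % 2
    centers = ALIGNMENT_POSITIONS[version]
    for r in centers:
        for c in centers:
            if (r < 9 and c < 9) or (r < 9 and c > size - 10) or (r > size - 10 and c < 9):
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    matrix[r + dr, c + dc] = 1 if max(abs(dr), abs(dc)) != 1 else 0
    if version >= 7:
        bits = _version_bits(version)
        for i in range(18):
            bit = (bits >> i) & 1
            a = size - 11 + i % 3
            b = i // 3
            matrix[b, a] = bit
            matrix[a, b] = bit


def _draw_format(matrix: np.ndarray, mask: int) -> None:
    size = matrix.shape[0]
    bits = _format_bits(mask)

    def bit(i: int) -> int:
        return (bits >> i) & 1

    for i in range(6):  # first copy, around the top-left finder
        matrix[i, 8] = bit(i)
    matrix[7, 8] = bit(6)
    matrix[8, 8] = bit(7)
    matrix[8, 7] = bit(8)
    for i in range(9, 15):
        matrix[8, 14 - i] = bit(i)
    for i in range(8):  # second copy, split right/bottom
        matrix[8, size - 1 - i] = bit(i)
    for i in range(8, 15):
        matrix[size - 15 + i, 8] = bit(i)
    matrix[size - 8, 8] = 1  # dark module


def _mask_matrix(mask: int, size: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    if mask == 0:
        cond = (rr + cc) % 2 == 0
    elif mask == 1:
        cond = rr % 2 == 0
    elif mask == 2:
        cond = cc % 3 == 0
    elif mask == 3:
        cond = (rr + cc) % 3 == 0
    elif mask == 4:
        cond = (rr // 2 + cc // 3) % 2 == 0
    elif mask == 5:
        cond = (rr * cc) % 2 + (rr * cc) % 3 == 0
    elif mask == 6:
        cond = ((rr * cc) % 2 + (rr * cc) % 3) % 2 == 0
    else:
        cond = ((rr + cc) % 2 + (rr * cc) % 3) % 2 == 0
    return cond


def _data_coordinates(version: int) -> list[tuple[int, int]]:
    """(row, col) of every data module in placement (zigzag) order."""
    size = symbol_size(version)
    fn = function_module_map(version)
    coords: list[tuple[int, int]] = []
    right = size - 1
    while right >= 1:
        if right == 6:
            right = 5
        upward = ((right + 1) & 2) == 0
        for vert in range(size):
            row = size - 1 - vert if upward else vert
            for col in (right, right - 1):
                if not fn[row, col]:
                    coords.append((row, col))
        right -= 2
    return coords


def _place_data(matrix: np.ndarray, version: int, codewords: list[int]) -> None:
    coords = _data_coordinates(version)
    bits_needed = 8 * len(codewords)
    for i, (row, col) in enumerate(coords):
        if i < bits_needed:
            matrix[row, col] = (codewords[i >> 3] >> (7 - (i & 7))) & 1
        else:
            matrix[row, col] = 0  # remainder bits


def _penalty(matrix: np.ndarray) -> int:
    """Standard mask-evaluation penalty (rules N1-N4)."""
    size = matrix.shape[0]
    score = 0
    for grid in (matrix, matrix.T):
        for line in grid:
            run = 1
            for i in range(1, size):
                if line[i] == line[i - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + (run - 5)
                    run = 1
            if run >= 5:
                score += 3 + (run - 5)
    blocks = (
        (matrix[:-1, :-1] == matrix[1:, :-1])
        & (matrix[:-1, :-1] == matrix[:-1, 1:])
        & (matrix[:-1, :-1] == matrix[1:, 1:])
    )
    score += 3 * int(blocks.sum())
    finder = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0])
    for grid in (matrix, matrix.T):
        for line in grid:
            s = line.astype(int)
            for i in range(size - 10):
                win = s[i : i + 11]
                if np.array_equal(win, finder) or np.array_equal(win, finder[::-1]):
                    score += 40
    dark = int(matrix.sum())
    total = size * size
    k = (abs(dark * 20 - total * 10) + total - 1) // total
    score += 10 * max(0, k - 1)
    return score


def build_matrix(payload: bytes, version: int | None = None) -> np.ndarray:
    """Full QR module matrix (1 = dark) for a byte payload at EC level M."""
    if version is None:
        version = choose_version(len(payload))
    elif not 1 <= version <= MAX_VERSION:
        raise QRError(f"version must be 1..{MAX_VERSION}, got {version}")
    elif 4 + _count_bits(version) + 8 * len(payload) > 8 * data_codewords_m(version):
        raise QRError(f"payload does not fit version {version} at EC level M")
    codewords = _interleave(_data_bitstream(payload, version), version)
    size = symbol_size(version)
    fn = function_module_map(version)
    base = np.zeros((size, size), dtype=np.uint8)
    _draw_function_patterns(base, version)
    _place_data(base, version, codewords)
    best: tuple[int, int, np.ndarray] | None = None
    for mask in range(8):
        m = base.copy()
        cond = _mask_matrix(mask, size) & ~fn
        m[cond] ^= 1
        _draw_format(m, mask)
        p = _penalty(m)
        if best is None or p < best[0]:
            best = (p, mask, m)
    assert best is not None
    return best[2]


# ---------------------------------------------------------------------------
# public API

def encode_qr(
    payload: QRPayload | str,
    path: str | Path,
    box_size: int = 8,
    border: int = 4,
    version: int | None = None,
) -> Path:
    """Encode a payload as a QR PNG (EC level M, UTF-8, auto version).

    ``box_size`` is the pixel edge of one module; ``border`` the quiet
    zone in modules (the standard minimum is 4).
    """
    if isinstance(payload, str):
        payload = QRPayload.infer(payload)
    matrix = build_matrix(payload.text.encode("utf-8"), version=version)
    size = matrix.shape[0]
    full = np.ones((size + 2 * border, size + 2 * border), dtype=np.uint8)
    full[border : border + size, border : border + size] = 1 - matrix
    img = Image.fromarray(full * 255, mode="L").resize(
        ((size + 2 * border) * box_size,) * 2, Image.NEAREST
    )
    path = Path(path)
    img.save(path, format="PNG")
    return path


def _read_module_grid(path: str | Path) -> np.ndarray:
    img = Image.open(path).convert("L")
    arr = (np.asarray(img) < 128).astype(np.uint8)  # dark = 1
    rows = np.flatnonzero(arr.any(axis=1))
    cols = np.flatnonzero(arr.any(axis=0))
    if rows.size == 0:
        raise QRError(f"{path}: no QR symbol found (blank image)")
    crop = arr[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    h, w = crop.shape
    for version in range(1, MAX_VERSION + 1):
        size = symbol_size(version)
        if w % size or h % size or w // size != h // size or w // size == 0:
            continue
        scale = w // size
        # sample module centres
        centres = crop[scale // 2 :: scale, scale // 2 :: scale][:size, :size]
        if _verify_finders(centres):
            return centres
    raise QRError(f"{path}: no decodable QR symbol found in image")


_FINDER = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1],
        [1, 0, 0, 0, 0, 0, 1],
        [1, 0, 1, 1, 1, 0, 1],
        [1, 0, 1, 1, 1, 0, 1],
        [1, 0, 1, 1, 1, 0, 1],
        [1, 0, 0, 0, 0, 0, 1],
        [1, 1, 1, 1, 1, 1, 1],
    ],
    dtype=np.uint8,
)


def _verify_finders(grid: np.ndarray) -> bool:
    size = grid.shape[0]
    return (
        np.array_equal(grid[0:7, 0:7], _FINDER)
        and np.array_equal(grid[0:7, size - 7 :], _FINDER)
        and np.array_equal(grid[size - 7 :, 0:7], _FINDER)
    )


def _read_format(grid: np.ndarray) -> tuple[int, int]:
    """Recover (ec_bits, mask) from the format information.

    Both copies are read; each is matched against all 32 valid format
    codewords and the nearest (Hamming) wins, tolerating a few damaged
    modules just as the BCH code intends.
    """
    size = grid.shape[0]
    copy1 = []
    for i in range(6):
        copy1.append(int(grid[i, 8]))
    copy1.append(int(grid[7, 8]))
    copy1.append(int(grid[8, 8]))
    copy1.append(int(grid[8, 7]))
    for i in range(9, 15):
        copy1.append(int(grid[8, 14 - i]))
    copy2 = []
    for i in range(8):
        copy2.append(int(grid[8, size - 1 - i]))
    for i in range(8, 15):
        copy2.append(int(grid[size - 15 + i, 8]))

    def value(bits: list[int]) -> int:
        return sum(b << i for i, b in enumerate(bits))

    best = None
    for observed in (value(copy1), value(copy2)):
        for ec_bits in range(4):
            for mask in range(8):
                expected = _format_bits(mask, ec_bits)
                dist = bin(observed ^ expected).count("1")
                if best is None or dist < best[0]:
                    best = (dist, ec_bits, mask)
    assert best is not None
    if best[0] > 3:  # BCH(15,5) corrects up to 3 bit errors
        raise QRError("format information unreadable")
    return best[1], best[2]


def decode_matrix(grid: np.ndarray) -> bytes:
    """Decode a sampled module grid back to the payload bytes."""
    size = grid.shape[0]
    version = (size - 17) // 4
    if symbol_size(version) != size or not 1 <= version <= MAX_VERSION:
        raise QRError(f"invalid symbol size {size}")
    ec_bits, mask = _read_format(grid)
    if ec_bits != _EC_M_FORMAT_BITS:
        raise QRError("only error-correction level M symbols are supported")
    unmasked = grid.copy().astype(np.uint8)
    cond = _mask_matrix(mask, size) & ~function_module_map(version)
    unmasked[cond] ^= 1
    coords = _data_coordinates(version)
    n_codewords = total_codewords_m(version)
    bits = [int(unmasked[r, c]) for r, c in coords[: 8 * n_codewords]]
    codewords = [
        int("".join(map(str, bits[i : i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    ec = EC_BLOCKS_M[version][0]
    data: list[int] = []
    for block in _deinterleave(codewords, version):
        try:
            data.extend(rs_decode(block, ec))
        except ValueError as exc:
            raise QRError(f"undecodable symbol: {exc}") from exc
    # parse the byte-mode bitstream
    stream = 0
    for byte in data:
        stream = (stream << 8) | byte
    total_bits = 8 * len(data)

    def take(offset: int, n: int) -> int:
        return (stream >> (total_bits - offset - n)) & ((1 << n) - 1)

    mode = take(0, 4)
    if mode != 0b0100:
        raise QRError(f"unsupported QR mode indicator {mode:04b} (byte mode only)")
    nbits = _count_bits(version)
    length = take(4, nbits)
    if 4 + nbits + 8 * length > total_bits:
        raise QRError("corrupt length field in QR bitstream")
    payload = bytes(take(4 + nbits + 8 * i, 8) for i in range(length))
    return payload


def decode_qr(path: str | Path) -> QRPayload:
    """Decode a QR PNG produced by :func:`encode_qr` back to its payload."""
    grid = _read_module_grid(path)
    text = decode_matrix(grid).decode("utf-8")
    if not text:
        raise QRError(f"{path}: symbol decoded to an empty payload")
    return QRPayload.infer(text)
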