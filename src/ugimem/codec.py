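"""Direct data <-> presence-matrix mapping.

A data plate is a binary matrix: rows are mixtures (spots), columns are
library compounds, and entry (n, m) says whether compound m is dispensed
into mixture n. In direct mapping each payload bit becomes one matrix
cell: bits fill rows left to right in ascending compound order, so bit i
of a row maps to compound i+1 (1-based). Trailing pad bits are zeros and
their count is kept so decoding can strip them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class PresenceMatrix:
    """Binary spots x compounds matrix plus the metadata needed to invert it."""

    data: np.ndarray  # (n_spots, n_compounds) uint8 in {0,1}
    mapping: str = "direct"  # "direct" | "sparse"
    n_pad_bits: int = 0
    compound_indices: list[int] | None = None  # 1-based library subset
    payload_shape: tuple[int, int] | None = None  # image rows, cols if known

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("presence matrix must be 2-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("presence matrix must be binary")

    @property
    def n_spots(self) -> int:
        return self.data.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.data.shape[1]

    def popcount(self) -> int:
        return int(self.data.sum())

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Dense 0/1 CSV plus a JSON metadata sidecar (<path>.meta.json)."""
        path = Path(path)
        np.savetxt(path, self.data, fmt="%d", delimiter=",")
        meta = {
            "mapping": self.mapping,
            "n_pad_bits": self.n_pad_bits,
            "compound_indices": self.compound_indices,
            "payload_shape": list(self.payload_shape) if self.payload_shape else None,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PresenceMatrix":
        path = Path(path)
        data = np.loadtxt(path, dtype=np.uint8, delimiter=",", ndmin=2)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        shape = meta.get("payload_shape")
        return cls(
            data=data,
            mapping=meta.get("mapping", "direct"),
            n_pad_bits=meta.get("n_pad_bits", 0),
            compound_indices=meta.get("compound_indices"),
            payload_shape=tuple(shape) if shape else None,
        )


def bits_from_image(image) -> tuple[np.ndarray, tuple[int, int]]:
    """Flatten a bilevel image to bits, row-major; white = 0, ink = 1.

    Accepts a path, a PIL image, or a 2-D array. Arrays must be binary
    already; images are converted to 1-bit and must be bilevel.
    """
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        arr = np.asarray(image.convert("L"))
        levels = np.unique(arr)
        if len(levels) > 2:
            raise ValueError(f"image is not bilevel: {len(levels)} gray levels")
        bits = (arr < 128).astype(np.uint8)  # dark pixels carry 1
    else:
        bits = np.asarray(image)
        if bits.ndim != 2:
            raise ValueError("expected a 2-D raster")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("array raster must be binary")
        bits = bits.astype(np.uint8)
    return bits.reshape(-1), bits.shape


def image_from_bits(bits: np.ndarray, shape: tuple[int, int]) -> Image.Image:
    """Inverse of :func:`bits_from_image`: 1 -> black, 0 -> white."""
    arr = np.asarray(bits, dtype=np.uint8).reshape(shape)
    return Image.fromarray(np.where(arr, 0, 255).astype(np.uint8), mode="L")


def direct_encode(bits: np.ndarray, n_compounds: int) -> PresenceMatrix:
    """Reshape a bit vector into ceil(len/M) mixtures of M compounds each."""
    bits = np.asarray(bits, dtype=np.uint8).reshape(-1)
    if bits.size == 0:
        raise ValueError("empty bit vector")
    if n_compounds < 1:
        raise ValueError("need at least one compound per mixture")
    n_rows = -(-bits.size // n_compounds)
    n_pad = n_rows * n_compounds - bits.size
    padded = np.concatenate([bits, np.zeros(n_pad, dtype=np.uint8)])
    return PresenceMatrix(
        data=padded.reshape(n_rows, n_compounds),
        mapping="direct",
        n_pad_bits=n_pad,
    )


def direct_decode(matrix: PresenceMatrix) -> np.ndarray:
    """Reshape the matrix back to the stored bit vector, stripping pad."""
    if matrix.mapping != "direct":
        raise ValueError(f"not a direct-mapped matrix: {matrix.mapping!r}")
    flat = matrix.data.reshape(-1)
    if matrix.n_pad_bits:
        flat = flat[: flat.size - matrix.n_pad_bits]
    return flat.copy()


def bits_from_bytes(data: bytes) -> np.ndarray:
    """MSB-first bit vector of a byte string."""
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bytes_from_bits(bits: np.ndarray) -> bytes:
    """Inverse of :func:`bits_from_bytes`; pads the tail byte with zeros."""
    return np.packbits(np.asarray(bits, dtype=np.uint8)).tobytes()
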