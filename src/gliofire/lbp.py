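"""Uniform local binary pattern features over a cell grid.

For each pixel the LBP operator thresholds P = 8 circular neighbors at
radius R against the center (``>=`` maps to 1) and packs the bits into
a code ``sum_n s(g_n - g_c) 2^n``.  Codes with at most two circular
0/1 transitions are "uniform"; for P = 8 exactly 58 codes are uniform,
and together with one aggregate bin for all non-uniform codes they give
a 59-bin histogram.  A patch is divided into a grid of non-overlapping
cells, each cell contributes one L1-normalized 59-bin histogram, and
the blocks for R = 1 and R = 2 are concatenated:
feature length = 2 * n_cells * 59 (1888 for the default 4x4 grid).

Neighbors at non-integer positions are sampled with bilinear
interpolation; pixels whose full neighborhood falls outside the patch
are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LBPConfig",
    "lbp_code",
    "uniform_bin",
    "code_image",
    "cell_histogram",
    "extract_lbp_features",
    "N_BINS",
    "UNIFORM_LUT",
]

N_BINS = 59  # 58 uniform patterns + 1 aggregate bin


def _transitions(code: int, p: int = 8) -> int:
    bits = [(code >> n) & 1 for n in range(p)]
    return sum(bits[n] != bits[(n + 1) % p] for n in range(p))


def _build_uniform_lut() -> np.ndarray:
    """Map code 0..255 -> bin 0..58; uniform codes in ascending-code order,
    all non-uniform codes share the final aggregate bin."""
    uniform = [c for c in range(256) if _transitions(c) <= 2]
    lut = np.full(256, N_BINS - 1, dtype=np.int64)
    for i, c in enumerate(uniform):
        lut[c] = i
    return lut


UNIFORM_LUT = _build_uniform_lut()


@dataclass(frozen=True)
class LBPConfig:
    P: int = 8
    radii: tuple[float, ...] = (1.0, 2.0)
    grid: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        if self.P != 8:
            raise ValueError("only P = 8 neighborhoods are supported")

    @property
    def n_cells(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def feature_length(self) -> int:
        return len(self.radii) * self.n_cells * N_BINS


def uniform_bin(code: int) -> int:
    """Histogram bin of an 8-bit LBP code (own bin if uniform, else 58)."""
    if not 0 <= code <= 255:
        raise ValueError("code must lie in 0..255")
    return int(UNIFORM_LUT[code])


def _offsets(p: int, r: float) -> np.ndarray:
    """(dr, dc) sampling offsets for neighbors n = 0..P-1 on the circle."""
    n = np.arange(p)
    theta = 2.0 * np.pi * n / p
    off = np.stack([r * np.sin(theta), r * np.cos(theta)], axis=1)
    off[np.abs(off) < 1e-9] = 0.0
    return off


def _bilinear_at(patch: np.ndarray, r: np.ndarray, c: np.ndarray) -> np.ndarray:
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    fr, fc = r - r0, c - c0
    r1 = np.minimum(r0 + 1, patch.shape[0] - 1)
    c1 = np.minimum(c0 + 1, patch.shape[1] - 1)
    return (
        patch[r0, c0] * (1 - fr) * (1 - fc)
        + patch[r0, c1] * (1 - fr) * fc
        + patch[r1, c0] * fr * (1 - fc)
        + patch[r1, c1] * fr * fc
    )


def lbp_code(patch: np.ndarray, center: tuple[int, int], P: int = 8, R: float = 1.0) -> int:
    """LBP code of one pixel; errors if the neighborhood leaves the patch."""
    patch = np.asarray(patch, dtype=float)
    r, c = center
    margin = int(np.ceil(R))
    if not (margin <= r < patch.shape[0] - margin and margin <= c < patch.shape[1] - margin):
        raise ValueError("center too close to the patch border for this radius")
    g_c = patch[r, c]
    code = 0
    for n, (dr, dc) in enumerate(_offsets(P, R)):
        g_n = _bilinear_at(patch, np.array([r + dr]), np.array([c + dc]))[0]
        if g_n - g_c >= -1e-12:
            code |= 1 << n
    return code


def code_image(patch: np.ndarray, P: int = 8, R: float = 1.0) -> np.ndarray:
    """LBP codes for every pixel with a full neighborhood; -1 elsewhere.

    Vectorized over the whole patch: each neighbor sample is a bilinear
    combination of shifted copies of the image.
    """
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    margin = int(np.ceil(R))
    codes = np.full((h, w), -1, dtype=np.int64)
    if h <= 2 * margin or w <= 2 * margin:
        return codes
    rr, cc = np.mgrid[margin : h - margin, margin : w - margin]
    g_c = patch[margin : h - margin, margin : w - margin]
    block = np.zeros_like(g_c, dtype=np.int64)
    for n, (dr, dc) in enumerate(_offsets(P, R)):
        g_n = _bilinear_at(patch, rr + dr, cc + dc)
        block |= (g_n - g_c >= -1e-12).astype(np.int64) << n
    codes[margin : h - margin, margin : w - margin] = block
    return codes


def cell_histogram(cell_codes: np.ndarray) -> np.ndarray:
    """L1-normalized 59-bin histogram of a cell's codes (-1 entries are
    border pixels without a full neighborhood and are skipped); all-zero
    when the cell has no valid pixel."""
    valid = cell_codes[cell_codes >= 0]
    hist = np.zeros(N_BINS, dtype=float)
    if valid.size == 0:
        return hist
    bins = UNIFORM_LUT[valid]
    hist += np.bincount(bins, minlength=N_BINS)
    return hist / hist.sum()


def extract_lbp_features(patch: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Concatenated cell histograms, R = 1 block first, cells row-major."""
    if cfg is None:
        cfg = LBPConfig()
    patch = np.asarray(patch, dtype=float)
    gr, gc = cfg.grid
    if patch.shape[0] < gr or patch.shape[1] < gc:
        raise ValueError("patch smaller than the cell grid")
    row_edges = np.linspace(0, patch.shape[0], gr + 1).astype(int)
    col_edges = np.linspace(0, patch.shape[1], gc + 1).astype(int)
    blocks: list[np.ndarray] = []
    for R in cfg.radii:
        codes = code_image(patch, cfg.P, R)
        for i in range(gr):
            for j in range(gc):
                cell = codes[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
                blocks.append(cell_histogram(cell))
    return np.concatenate(blocks)
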