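"""Grey-level co-occurrence texture features.

The luminance channel is reduced from 256 to 32 grey levels (a pure
efficiency measure: the co-occurrence matrix shrinks from 256 x 256 to
32 x 32) and a directional grey-level co-occurrence matrix (GLCM) is
accumulated: entry (i, j) counts pixel pairs where the pixel of interest
has level i and the pixel displaced by ``offset = (DX, DY)`` has level j.
By default the displacement is one pixel to the right.

Three Haralick-style statistics are computed on the probability-normalised
matrix p:

* energy    E = sum p_ij**2          (angular second moment; order),
* entropy   H = -sum p_ij log2 p_ij  (randomness, in bits),
* contrast  C = sum (i-j)**2 p_ij    (local intensity variation).

``raw=True`` computes the statistics on raw counts, and
``as_printed=True`` drops the conventional minus sign of the entropy;
both dialects exist only for comparison with historical conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .edges import LeafImage
from .errors import ParameterError, TextureError

logger = logging.getLogger(__name__)

#: number of grey levels after degradation.
N_LEVELS = 32

#: level marking pixels outside the mask.
INVALID = -1

#: default displacement: the pixel immediately to the right.
DEFAULT_OFFSET = (1, 0)


@dataclass
class GLCM:
    """A directional co-occurrence matrix with its displacement.

    ``offset = (DX, DY)`` displaces in image coordinates where x is the
    column and y the row, so ``(1, 0)`` pairs each pixel with its right
    neighbour.  The matrix is not symmetrised.
    """

    counts: np.ndarray
    offset: tuple[int, int]
    n_levels: int = N_LEVELS
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != (self.n_levels, self.n_levels):
            raise ParameterError(
                f"counts must be {self.n_levels} x {self.n_levels}"
            )

    def total(self) -> float:
        return float(self.counts.sum())

    def to_text(self, path) -> None:
        """Dump the dense matrix as whitespace-separated text (debugging)."""
        header = (f"offset=({self.offset[0]},{self.offset[1]}) "
                  f"n_levels={self.n_levels} normalized={self.normalized}")
        np.savetxt(path, self.counts, fmt="%.10g", header=header)


@dataclass
class TextureFeatures:
    """The three texture statistics of a leaf."""

    energy: float
    entropy: float
    contrast: float

    def as_array(self) -> np.ndarray:
        return np.array([self.energy, self.entropy, self.contrast])


def degrade_gray(image: LeafImage, mask: np.ndarray | None = None,
                 n_levels: int = N_LEVELS) -> np.ndarray:
    """Reduce the luminance channel to ``n_levels`` grey levels.

    Luminance is rounded to the nearest integer and binned with
    ``floor(g * n_levels / 256)``, so 0 maps to level 0 and 255 to the top
    level.  Pixels outside the mask are flagged :data:`INVALID`.
    """
    lum = np.rint(image.luminance()).astype(np.int64)
    levels = (lum * n_levels) // 256
    np.clip(levels, 0, n_levels - 1, out=levels)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        levels = np.where(mask, levels, INVALID)
    return levels


def glcm(levels: np.ndarray, offset: tuple[int, int] = DEFAULT_OFFSET,
         mask: np.ndarray | None = None, n_levels: int = N_LEVELS) -> GLCM:
    """Accumulate the directional co-occurrence matrix of a level grid.

    A pair is counted when both the pixel and its displaced partner lie
    inside the grid and the mask (invalid levels count as outside).  The
    total of the matrix therefore equals the number of valid pairs.
    """
    levels = np.asarray(levels)
    h, w = levels.shape
    dx, dy = int(offset[0]), int(offset[1])
    if dx == 0 and dy == 0:
        raise ParameterError("offset must not be (0, 0)")
    if abs(dx) >= w or abs(dy) >= h:
        raise ParameterError(f"offset {offset} exceeds grid size {(h, w)}")
    valid = levels != INVALID
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    # source window and displaced window
    rs = slice(max(0, -dy), min(h, h - dy))
    cs = slice(max(0, -dx), min(w, w - dx))
    rt = slice(max(0, dy), min(h, h + dy))
    ct = slice(max(0, dx), min(w, w + dx))
    src = levels[rs, cs]
    dst = levels[rt, ct]
    ok = valid[rs, cs] & valid[rt, ct]
    i = src[ok].astype(np.int64)
    j = dst[ok].astype(np.int64)
    if i.size == 0:
        raise TextureError("no valid pixel pairs at this offset")
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    return GLCM(counts=counts, offset=(dx, dy), n_levels=n_levels,
                normalized=False)


def normalize_glcm(g: GLCM) -> GLCM:
    """Divide the matrix by its total so entries sum to one."""
    if g.normalized:
        return g
    total = g.total()
    if total <= 0:
        raise TextureError("cannot normalise an empty GLCM")
    return GLCM(counts=g.counts / total, offset=g.offset,
                n_levels=g.n_levels, normalized=True)


def _probabilities(g: GLCM, raw: bool) -> np.ndarray:
    if raw:
        return g.counts
    if not g.normalized:
        logger.debug("normalising GLCM before computing a statistic")
        g = normalize_glcm(g)
    return g.counts


def texture_energy(g: GLCM, raw: bool = False) -> float:
    """Angular second moment sum(p**2); 1/N**2 <= E <= 1 when normalised."""
    p = _probabilities(g, raw)
    return float((p * p).sum())


def texture_entropy(g: GLCM, raw: bool = False,
                    as_printed: bool = False) -> float:
    """Entropy -sum(p log2 p) in bits, with 0 log 0 := 0.

    ``as_printed=True`` returns the sign-flipped variant ``sum(p log2 p)``.
    """
    p = _probabilities(g, raw)
    nz = p[p > 0]
    h = -float((nz * np.log2(nz)).sum())
    return -h if as_printed else h


def texture_contrast(g: GLCM, raw: bool = False) -> float:
    """Inertia sum((i - j)**2 p_ij); zero iff all mass is diagonal."""
    p = _probabilities(g, raw)
    idx = np.arange(g.n_levels)
    w = (idx[:, None] - idx[None, :]) ** 2
    return float((w * p).sum())


def texture_features(image: LeafImage, mask: np.ndarray,
                     offset: tuple[int, int] = DEFAULT_OFFSET,
                     raw: bool = False,
                     entropy_as_printed: bool = False) -> TextureFeatures:
    """Degrade, accumulate the GLCM over the leaf mask, and summarise.

    ``raw`` and ``entropy_as_printed`` select the historical dialects
    (statistics over raw counts; sign-flipped entropy).
    """
    levels = degrade_gray(image, mask)
    g = glcm(levels, offset)
    if not raw:
        g = normalize_glcm(g)
    return TextureFeatures(
        energy=texture_energy(g, raw=raw),
        entropy=texture_entropy(g, raw=raw, as_printed=entropy_as_printed),
        contrast=texture_contrast(g, raw=raw),
    )
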