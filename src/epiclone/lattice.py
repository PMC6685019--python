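"""Hexagonal lattice geometry on a torus.

The proliferative compartment of the epithelium is modelled as a 2D sheet of
progenitor cells packed hexagonally, with periodic boundaries so that no cell
sits at an edge.  Sites are addressed as ``(row, col)`` on a ``height × width``
array using the axial (rhombus) embedding of the triangular lattice: the six
neighbours of a site are obtained from the offset set

    (0, +1), (0, -1), (+1, 0), (-1, 0), (-1, +1), (+1, -1)

taken modulo the lattice shape.  Because the offset set is closed under
negation, the neighbour relation is symmetric on any torus, and every site has
exactly six distinct neighbours whenever both dimensions are at least 3.
"""

from __future__ import annotations

import numpy as np

#: Axial-coordinate offsets of the six hexagonal neighbours.
HEX_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (0, -1),
    (1, 0),
    (-1, 0),
    (-1, 1),
    (1, -1),
)


def hex_neighbors(site: tuple[int, int], width: int, height: int) -> list[tuple[int, int]]:
    """Return the six toroidal neighbours of ``site`` = (row, col).

    Parameters
    ----------
    site:
        ``(row, col)`` with ``0 <= row < height`` and ``0 <= col < width``.
    width, height:
        Lattice dimensions (columns, rows).  Both must be >= 3 for the six
        neighbours to be distinct.

    Raises
    ------
    ValueError
        If ``site`` is out of bounds or the lattice is smaller than 3 × 3.
    """
    r, c = site
    if width < 3 or height < 3:
        raise ValueError("hexagonal torus requires width and height >= 3")
    if not (0 <= r < height and 0 <= c < width):
        raise ValueError(f"site {site!r} out of bounds for {height}x{width} lattice")
    return [((r + dr) % height, (c + dc) % width) for dr, dc in HEX_OFFSETS]


def site_index(row: int, col: int, width: int) -> int:
    """Flat index of ``(row, col)`` in row-major order."""
    return row * width + col


def neighbor_indices(width: int, height: int) -> np.ndarray:
    """Dense ``(height*width, 6)`` table of flat neighbour indices."""
    idx = np.empty((height * width, 6), dtype=np.int64)
    for r in range(height):
        for c in range(width):
            for k, (dr, dc) in enumerate(HEX_OFFSETS):
                idx[r * width + c, k] = ((r + dr) % height) * width + (c + dc) % width
    return idx
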