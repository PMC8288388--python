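"""Speller character layouts and frequency maps.

The P300 speller uses the classic Farwell-Donchin 6x6 matrix (26 letters,
9 digits and an underscore standing in for space).  Rows and columns are
addressed by stimulus ids: ids 1-6 are rows, ids 7-12 are columns.

The SSVEP speller uses a 5x8 matrix of 40 characters.  Stimulation
frequencies run from 8 Hz to 15.8 Hz in 0.2 Hz steps and are assigned
column-major over the matrix, so that adjacent characters in a column
differ by 0.2 Hz (the layout used by the 40-target benchmark interfaces).
Both maps are plain data and can be replaced in configuration.
"""

from __future__ import annotations

import numpy as np

# -- P300: 6x6 row-major matrix -------------------------------------------

P300_MATRIX: tuple[str, ...] = (
    "ABCDEF",
    "GHIJKL",
    "MNOPQR",
    "STUVWX",
    "YZ1234",
    "56789_",
)

P300_CHARS: str = "".join(P300_MATRIX)


def p300_char_at(row: int, col: int) -> str:
    """Character at 1-based (row, col) of the 6x6 matrix."""
    if not (1 <= row <= 6 and 1 <= col <= 6):
        raise ValueError(f"row/col must be in 1..6, got ({row}, {col})")
    return P300_MATRIX[row - 1][col - 1]


def p300_char_position(char: str) -> tuple[int, int]:
    """1-based (row, col) of ``char`` in the 6x6 matrix."""
    idx = P300_CHARS.find(char)
    if idx < 0:
        raise ValueError(f"character {char!r} not in the 6x6 speller matrix")
    return idx // 6 + 1, idx % 6 + 1


def p300_stimulus_ids(char: str) -> tuple[int, int]:
    """(row id 1..6, column id 7..12) whose intersection spells ``char``."""
    row, col = p300_char_position(char)
    return row, 6 + col


# -- SSVEP: 5x8 matrix, column-major frequency assignment ------------------

SSVEP_MATRIX: tuple[str, ...] = (
    "ABCDEFGH",
    "IJKLMNOP",
    "QRSTUVWX",
    "YZ012345",
    "6789_,.<",
)

SSVEP_N_ROWS, SSVEP_N_COLS = 5, 8


def ssvep_frequencies(f0: float = 8.0, step: float = 0.2, k: int = 40) -> np.ndarray:
    return f0 + step * np.arange(k)


def ssvep_char_map(f0: float = 8.0, step: float = 0.2) -> dict[float, str]:
    """Bijection frequency -> character for the default 40-target layout."""
    out: dict[float, str] = {}
    for r in range(SSVEP_N_ROWS):
        for c in range(SSVEP_N_COLS):
            idx = c * SSVEP_N_ROWS + r
            out[round(f0 + step * idx, 10)] = SSVEP_MATRIX[r][c]
    return out


def ssvep_char_for(freq: float, char_map: dict[float, str] | None = None) -> str:
    cmap = ssvep_char_map() if char_map is None else char_map
    key = round(float(freq), 10)
    if key not in cmap:
        raise ValueError(f"frequency {freq} Hz is not a stimulation frequency")
    return cmap[key]
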