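"""Code-flow statistics: maximum cross-correlation of code occurrences.

Detected codes mark travelling spike waves; if the same code appears at a
neighbouring electrode within half a millisecond, the code is "flowing".
Detections of a code at an electrode are quantised into 0.5 ms frames
(5 bins), and the maximum cross-correlation

    Phi_N(C) = max_{f in N(e)} max_{|lag| <= 1} sum_t x_e(t) x_f(t + lag)

is taken over the electrode's 8 or 20 nearest neighbours and a ±1-frame
(±0.5 ms) lag.  The correlation is un-normalised (raw co-occurrence
counts); series are occurrence counts per frame, optionally clipped to
binary.

Neighbourhoods on the 8x8 electrode grid: 8N is Chebyshev distance 1; 20N
is the 5x5 block minus its centre and four corners — the unique symmetric
set of 20 electrodes — both clipped at array edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codes import N_CODES

__all__ = [
    "FRAME_BINS",
    "neighbor_electrodes",
    "occurrence_series",
    "occurrence_map",
    "max_cross_correlation",
    "code_flow_table",
]

FRAME_BINS: int = 5  # 0.5 ms at 0.1 ms bins


def neighbor_electrodes(
    electrode: tuple[int, int], mode: str = "8N", grid: tuple[int, int] = (8, 8)
) -> list[tuple[int, int]]:
    """Neighbour set of an electrode: '8N' or '20N', clipped at edges."""
    row, col = electrode
    if mode == "8N":
        offsets = [
            (dr, dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
    elif mode == "20N":
        offsets = [
            (dr, dc)
            for dr in range(-2, 3)
            for dc in range(-2, 3)
            if (dr, dc) != (0, 0) and not (abs(dr) == 2 and abs(dc) == 2)
        ]
    else:
        raise ValueError(f"mode must be '8N' or '20N', got {mode!r}")
    return [
        (row + dr, col + dc)
        for dr, dc in offsets
        if 0 <= row + dr < grid[0] and 0 <= col + dc < grid[1]
    ]


def occurrence_series(
    detections: pd.DataFrame,
    electrode: int,
    code: int,
    frame_bins: int = FRAME_BINS,
    n_frames: int | None = None,
) -> np.ndarray:
    """Counts per frame of one code's detections at one electrode.

    Frame index = start_bin // frame_bins; totals are conserved.
    """
    if frame_bins < 1:
        raise ValueError("frame_bins must be >= 1")
    sel = detections[
        (detections["electrode"] == electrode)
        & (detections["code_number"] == code)
    ]
    frames = (sel["start_bin"].to_numpy() // frame_bins).astype(np.int64)
    if n_frames is None:
        n_frames = int(frames.max()) + 1 if len(frames) else 1
    series = np.zeros(n_frames, dtype=np.int64)
    np.add.at(series, frames, 1)
    return series


def occurrence_map(
    detections: pd.DataFrame,
    horizon: int,
    grid: tuple[int, int] = (8, 8),
    frame_bins: int = FRAME_BINS,
) -> np.ndarray:
    """(grid_rows, grid_cols, n_codes, n_frames) occurrence-count array.

    ``detections['electrode']`` holds flat (row-major) electrode indices.
    """
    n_frames = -(-horizon // frame_bins)
    occ = np.zeros((grid[0], grid[1], N_CODES, n_frames), dtype=np.int64)
    if len(detections):
        e = detections["electrode"].to_numpy()
        c = detections["code_number"].to_numpy() - 1
        f = detections["start_bin"].to_numpy() // frame_bins
        np.add.at(occ, (e // grid[1], e % grid[1], c, f), 1)
    return occ


def _xcorr_max(x: np.ndarray, y: np.ndarray, max_lag: int) -> float:
    best = 0.0
    n = len(x)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            v = float(np.dot(x[: n - lag], y[lag:]))
        else:
            v = float(np.dot(x[-lag:], y[: n + lag]))
        best = max(best, v)
    return best


def max_cross_correlation(
    occ: np.ndarray,
    electrode: tuple[int, int],
    code: int,
    mode: str = "8N",
    max_lag_frames: int = 1,
    binary: bool = False,
) -> float:
    """Phi_N(C) for one electrode: max over neighbours and ±max_lag frames.

    ``occ`` is the array from :func:`occurrence_map`.  Returns NaN when the
    neighbour set is empty (degenerate grid).
    """
    grid = occ.shape[:2]
    nbrs = neighbor_electrodes(electrode, mode=mode, grid=grid)
    if not nbrs:
        return float("nan")
    x = occ[electrode[0], electrode[1], code - 1]
    if binary:
        x = (x > 0).astype(np.int64)
    best = 0.0
    for r, c in nbrs:
        y = occ[r, c, code - 1]
        if binary:
            y = (y > 0).astype(np.int64)
        best = max(best, _xcorr_max(x, y, max_lag_frames))
    return best


def code_flow_table(
    detections: pd.DataFrame,
    horizon: int,
    codes_of_interest=None,
    mode: str = "8N",
    grid: tuple[int, int] = (8, 8),
    max_lag_frames: int = 1,
    frame_bins: int = FRAME_BINS,
    binary: bool = False,
) -> pd.DataFrame:
    """Per-electrode Phi_N(C) for each requested code, plus the array mean.

    Returns a DataFrame (electrode_row, electrode_col, code_number, mode,
    phi); the mean over electrodes is available via groupby on the result.
    """
    if codes_of_interest is None:
        codes_of_interest = range(1, N_CODES + 1)
    occ = occurrence_map(detections, horizon, grid=grid, frame_bins=frame_bins)
    rows = []
    for code in codes_of_interest:
        for r in range(grid[0]):
            for c in range(grid[1]):
                phi = max_cross_correlation(
                    occ, (r, c), code, mode=mode,
                    max_lag_frames=max_lag_frames, binary=binary,
                )
                rows.append((r, c, code, mode, phi))
    return pd.DataFrame(
        rows, columns=["electrode_row", "electrode_col", "code_number", "mode", "phi"]
    )
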