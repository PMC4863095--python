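"""Canonical three-one codes and their detection in binary spike trains.

A *code* is a binary pattern that starts and ends with '1', contains exactly
three '1's, and is 3-8 bits long.  There are L - 2 such patterns per length
L, 21 in total; ordered by (length, then binary value) they form the
canonical table: code 1 = "111", code 2 = "1011", code 3 = "1101" (the core
of the reversed M-sequence "1101000"), ..., code 21 = "11000001".

Detection samples a train at a fixed *bit width* w (6-20 bins, i.e.
0.6-2.0 ms): pattern p of length L matches at start bin t iff bin t + k*w
holds a spike exactly where p[k] = '1', for every bit position k.  Zero bits
constrain only the sampled bins, not the whole gap.  Matches at different
widths or shifted starts are all counted and may overlap; no subsumption
suppression is applied (a "111" inside a longer match still counts).  The
spectrum is the 21-vector of match counts summed over electrodes, start
bins and widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CODES",
    "DEFAULT_WIDTHS",
    "N_CODES",
    "CodeSpectrum",
    "enumerate_codes",
    "code_number",
    "detect_codes",
    "compute_spectrum",
    "spectrum_from_trains",
]

DEFAULT_WIDTHS: tuple[int, ...] = tuple(range(6, 21))  # 0.6-2.0 ms at 0.1 ms bins


def enumerate_codes() -> tuple[str, ...]:
    """The canonical three-one code table, ordered by (length, binary value)."""
    out = []
    for length in range(3, 9):
        patterns = []
        for mid in range(1, length - 1):
            bits = ["0"] * length
            bits[0] = bits[-1] = bits[mid] = "1"
            patterns.append("".join(bits))
        out.extend(sorted(patterns, key=lambda p: int(p, 2)))
    return tuple(out)


CODES: tuple[str, ...] = enumerate_codes()
N_CODES: int = len(CODES)
_CODE_INDEX = {p: i + 1 for i, p in enumerate(CODES)}


def code_number(pattern: str) -> int | None:
    """1-based table index of a pattern, or None if it is not a code."""
    if not pattern or set(pattern) - {"0", "1"}:
        raise ValueError(f"pattern must be a non-empty string over {{0,1}}: {pattern!r}")
    return _CODE_INDEX.get(pattern)


@dataclass
class CodeSpectrum:
    """Per-code detection counts (index 0 holds code 1) plus run metadata."""

    counts: np.ndarray  # (21,) float; rational when trial-averaged
    window: int = 2000
    n_electrodes: int = 1
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CODES,):
            raise ValueError(f"spectrum must have {N_CODES} entries")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code_number": np.arange(1, N_CODES + 1),
                "pattern": list(CODES),
                "count": self.counts,
            }
        )


def _as_train_matrix(trains) -> np.ndarray:
    arr = trains.trains if hasattr(trains, "trains") else np.asarray(trains)
    arr = np.atleast_2d(arr).astype(bool)
    return arr


def _dilate(trains: np.ndarray, tol: int) -> np.ndarray:
    """OR each train with itself shifted by up to ±tol bins."""
    out = trains.copy()
    for s in range(1, tol + 1):
        out[:, s:] |= trains[:, :-s]
        out[:, :-s] |= trains[:, s:]
    return out


def _match_starts(
    trains: np.ndarray, pattern: str, width: int, dilated: np.ndarray | None = None
) -> np.ndarray:
    """Bool (n_trains, n_starts): pattern match at each feasible start bin.

    '1' bits are tested against ``dilated`` (the train OR-smeared by the
    per-bit tolerance) when given; '0' bits always require the exact sampled
    bin to be empty.
    """
    if dilated is None:
        dilated = trains
    T = trains.shape[1]
    span = (len(pattern) - 1) * width
    n_starts = T - span
    if n_starts <= 0:
        return np.zeros((trains.shape[0], 0), dtype=bool)
    ok = np.ones((trains.shape[0], n_starts), dtype=bool)
    for k, bit in enumerate(pattern):
        src = dilated if bit == "1" else trains
        col = src[:, k * width : k * width + n_starts]
        ok &= col if bit == "1" else ~col
    return ok


def detect_codes(
    trains,
    widths=DEFAULT_WIDTHS,
    window: int | None = None,
    tolerance: int = 0,
) -> pd.DataFrame:
    """All code matches in one train or a stack of electrode trains.

    Parameters
    ----------
    trains : 1D binary train, 2D (electrode, bin) array, or ElectrodeTrains.
    widths : iterable of bit widths in bins, each within {6, ..., 20}.
    window : restrict detection to the first ``window`` bins (codes must fit
        entirely inside); default is the whole train.
    tolerance : ±bins of slack on '1'-bit positions (0 = exact bin match;
        the bin quantisation itself already gives several-percent timing
        accuracy at these bit widths).

    Returns a DataFrame with columns (electrode, code_number, start_bin,
    width); bins 0-based.  Matches may overlap and one spike may participate
    in many matches.
    """
    widths = sorted(set(int(w) for w in widths))
    if any(w < 6 or w > 20 for w in widths):
        raise ValueError("bit widths must lie in {6, ..., 20} bins")
    arr = _as_train_matrix(trains)
    if window is not None:
        arr = arr[:, :window]
    dilated = _dilate(arr, tolerance) if tolerance else arr
    rows = []
    for w in widths:
        for ci, pattern in enumerate(CODES):
            ok = _match_starts(arr, pattern, w, dilated)
            elec, start = np.nonzero(ok)
            if len(elec):
                rows.append(
                    pd.DataFrame(
                        {
                            "electrode": elec,
                            "code_number": ci + 1,
                            "start_bin": start,
                            "width": w,
                        }
                    )
                )
    if not rows:
        return pd.DataFrame(
            columns=["electrode", "code_number", "start_bin", "width"], dtype=np.int64
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(
        ["electrode", "code_number", "width", "start_bin"], ignore_index=True
    )


def compute_spectrum(
    detections: pd.DataFrame,
    window: int = 2000,
    n_electrodes: int = 1,
    n_trials: int = 1,
) -> CodeSpectrum:
    """Aggregate detections into a 21-entry spectrum; trial-averaging divides
    counts by ``n_trials``."""
    counts = np.zeros(N_CODES)
    if len(detections):
        codes = detections["code_number"].to_numpy()
        if np.any((codes < 1) | (codes > N_CODES)):
            raise ValueError("detections reference invalid code numbers")
        np.add.at(counts, codes - 1, 1.0)
    return CodeSpectrum(
        counts=counts / n_trials,
        window=window,
        n_electrodes=n_electrodes,
        n_trials=n_trials,
    )


def spectrum_from_trains(
    trains,
    widths=DEFAULT_WIDTHS,
    window: int = 2000,
    exclude: int | None = None,
    n_trials: int = 1,
) -> CodeSpectrum:
    """Spectrum of a train stack without materialising the detection list.

    Same matcher core as :func:`detect_codes`.  ``exclude`` drops one
    electrode row (the stimulating electrode) from the aggregation.
    """
    widths = sorted(set(int(w) for w in widths))
    if any(w < 6 or w > 20 for w in widths):
        raise ValueError("bit widths must lie in {6, ..., 20} bins")
    arr = _as_train_matrix(trains)[:, :window]
    if exclude is not None:
        arr = np.delete(arr, exclude, axis=0)
    counts = np.zeros(N_CODES)
    for w in widths:
        for ci, pattern in enumerate(CODES):
            counts[ci] += _match_starts(arr, pattern, w).sum()
    return CodeSpectrum(
        counts=counts / n_trials,
        window=window,
        n_electrodes=arr.shape[0],
        n_trials=n_trials,
    )
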