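"""Pixel-wise dual-channel co-localization statistics.

Two quantities describe how well a green channel (e.g. AGO2 immunostaining)
overlaps a red channel (e.g. mitochondrial staining):

* Pearson's correlation coefficient ``rp`` over paired pixel intensities,
  in [-1, +1] with 1 meaning complete co-localization; average rp >= 0.5 is
  the conventional significance threshold;
* Van Steensel's cross-correlation function (CCF): rp as a function of a
  horizontal shift ``dx`` of one channel against the other.  Co-localizing
  patterns produce a bell-shaped curve peaking near dx = 0; mutually
  exclusive patterns produce a hollow (a dip at dx = 0).

On shifting, the correlation is computed over the cropped valid overlap
only (no wrap-around, no zero padding, which would bias rp toward 0).  No
intensity thresholding or background subtraction is applied before
correlating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColocResult",
    "pearson_coloc",
    "cross_correlation_function",
    "classify_ccf",
]


@dataclass
class ColocResult:
    """rp at zero shift, the CCF curve, its peak shift and the curve class."""

    rp: float
    shifts: np.ndarray = field(repr=False)
    ccf: np.ndarray = field(repr=False)
    dx_peak: int = 0
    max_ccf: float = float("nan")
    shape: str = "flat"


def _as_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel images differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("channel images must be 2-D")
    return a, b


def pearson_coloc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of paired pixel intensities of two channels."""
    a, b = _as_pair(a, b)
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    av, bv = a.ravel(), b.ravel()
    if np.var(av) == 0 or np.var(bv) == 0:
        raise ValueError("undefined correlation: a channel has zero variance")
    return float(np.corrcoef(av, bv)[0, 1])


def cross_correlation_function(
    a: np.ndarray, b: np.ndarray, max_dx: int = 20
) -> ColocResult:
    """rp of channel ``a`` against channel ``b`` shifted by dx pixels,
    for dx in [-max_dx, +max_dx].

    A structure present in ``b`` at x + s relative to ``a`` peaks at
    dx = +s.  Ties at the peak resolve to the smallest |dx| (then the
    smaller dx).  The result's ``shape`` field is filled by
    :func:`classify_ccf` with default settings.
    """
    a, b = _as_pair(a, b)
    w = a.shape[1]
    if not 0 <= max_dx < w - 1:
        raise ValueError(f"max_dx must be in [0, width-2], got {max_dx}")
    shifts = np.arange(-max_dx, max_dx + 1)
    ccf = np.empty(len(shifts))
    for i, dx in enumerate(shifts):
        if dx >= 0:
            aa, bb = a[:, : w - dx], b[:, dx:]
        else:
            aa, bb = a[:, -dx:], b[:, : w + dx]
        if aa.shape[1] < 2:
            raise ValueError(f"overlap at shift {dx} is narrower than 2 columns")
        ccf[i] = pearson_coloc(aa, bb)
    # peak with smallest |dx| tie-break
    best = np.flatnonzero(ccf == ccf.max())
    dx_peak = int(shifts[best[np.lexsort((shifts[best], np.abs(shifts[best])))[0]]])
    res = ColocResult(
        rp=float(ccf[max_dx]),
        shifts=shifts,
        ccf=ccf,
        dx_peak=dx_peak,
        max_ccf=float(ccf.max()),
    )
    res.shape = classify_ccf(res)
    return res


def classify_ccf(
    result: ColocResult,
    center_window: int | None = None,
    margin: float = 0.1,
    edge_fraction: float = 0.1,
) -> str:
    """Classify a CCF curve as ``bell``, ``hollow`` or ``flat``.

    ``bell``: the curve's maximum lies within ``center_window`` pixels of
    dx = 0 and exceeds the mean of the outermost ``edge_fraction`` of shifts
    by at least ``margin`` (in rp units).  ``hollow``: the minimum lies in
    the window and undercuts the edge mean by the margin.  Otherwise
    ``flat``.  The window defaults to max(1, max_dx // 5).
    """
    ccf, shifts = np.asarray(result.ccf), np.asarray(result.shifts)
    max_dx = int(shifts.max())
    if center_window is None:
        center_window = max(1, max_dx // 5)
    n_edge = max(1, int(round(edge_fraction * len(shifts) / 2)))
    edge_mean = float(np.mean(np.concatenate([ccf[:n_edge], ccf[-n_edge:]])))
    i_max, i_min = int(np.argmax(ccf)), int(np.argmin(ccf))
    if abs(int(shifts[i_max])) <= center_window and ccf[i_max] >= edge_mean + margin:
        return "bell"
    if abs(int(shifts[i_min])) <= center_window and ccf[i_min] <= edge_mean - margin:
        return "hollow"
    return "flat"
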