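"""1D spectrum preprocessing: reference alignment and equidistant bucketing.

Metabolic features enter the model as bucket intensities: each spectrum is
first shifted along its ppm axis so that a known internal-standard peak
(formic acid, 8.463 ppm by default) sits at its nominal position, then
intensities are summed over fixed-width ppm intervals ("buckets").  Bucketing
tolerates the small peak-position shifts caused by per-sample differences in
pH, salt concentration, and temperature.

Buckets are half-open intervals [c − w/2, c + w/2) with centers at
lo + w/2 + k·w; the default width of 0.01 ppm puts centers at odd multiples
of 0.005 ppm.  Regions such as the residual water signal can be excluded;
any bucket overlapping an exclusion window is dropped entirely.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "BucketTable",
    "reference_spectra",
    "bucket_spectra",
    "DEFAULT_BUCKET_WIDTH",
    "DEFAULT_EXCLUSIONS",
]

DEFAULT_BUCKET_WIDTH = 0.01
# residual water signal; fully user-configurable
DEFAULT_EXCLUSIONS = ((4.40, 5.00),)


@dataclasses.dataclass
class SpectrumSet:
    """A shared ppm grid with one intensity row per sample."""

    ppm_axis: np.ndarray
    intensities: np.ndarray
    reference_target_ppm: float = 8.463
    shifts_ppm: np.ndarray | None = None  # applied by reference_spectra
    flagged: np.ndarray | None = None  # samples left unshifted (flat window)

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        diffs = np.diff(self.ppm_axis)
        if self.ppm_axis.ndim != 1 or len(self.ppm_axis) < 2:
            raise ValueError("ppm axis must be a 1-D grid")
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.intensities.shape[1] != len(self.ppm_axis):
            raise ValueError("intensity row length must match the ppm axis")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def grid_step(self) -> float:
        return float(np.mean(np.diff(self.ppm_axis)))

    @classmethod
    def from_wide_csv(cls, path, **kwargs) -> "SpectrumSet":
        """Wide CSV: first row the ppm grid, one sample per subsequent row."""
        raw = pd.read_csv(path, header=None)
        return cls(raw.iloc[0].values.astype(float), raw.iloc[1:].values.astype(float), **kwargs)


def reference_spectra(
    s: SpectrumSet, search_window_ppm: tuple[float, float]
) -> SpectrumSet:
    """Align each spectrum so its window-maximum peak sits at the reference ppm.

    The shift is applied as a whole-grid-step translation of the intensity
    row (edge values padded), so intensities themselves are unchanged.  A
    window without a clear peak (maximum not above median + 3·sd of the
    window) leaves that spectrum unshifted and flagged, with a warning.
    """
    lo, hi = sorted(search_window_ppm)
    in_win = (s.ppm_axis >= lo) & (s.ppm_axis <= hi)
    if not np.any(in_win):
        raise ValueError("search window contains no grid points")
    win_idx = np.where(in_win)[0]
    step = s.grid_step
    out = np.empty_like(s.intensities)
    shifts = np.zeros(s.n_samples)
    flagged = np.zeros(s.n_samples, dtype=bool)
    for i in range(s.n_samples):
        row = s.intensities[i]
        win = row[win_idx]
        peak = win.max()
        baseline = np.median(win) + 3.0 * win.std()
        if not peak > baseline:
            warnings.warn(f"sample {i}: no peak above baseline in window; left unshifted")
            flagged[i] = True
            out[i] = row
            continue
        peak_ppm = s.ppm_axis[win_idx[int(np.argmax(win))]]
        delta = s.reference_target_ppm - peak_ppm
        k = int(np.round(delta / step))
        shifts[i] = k * step
        shifted = np.empty_like(row)
        if k > 0:
            shifted[k:] = row[:-k] if k else row
            shifted[:k] = row[0]
        elif k < 0:
            shifted[:k] = row[-k:]
            shifted[k:] = row[-1]
        else:
            shifted[:] = row
        out[i] = shifted
    return SpectrumSet(
        s.ppm_axis.copy(), out, s.reference_target_ppm, shifts_ppm=shifts, flagged=flagged
    )


@dataclasses.dataclass
class BucketTable:
    """Equidistantly bucketed spectra: centers, per-sample sums, shared width."""

    bucket_centers: np.ndarray
    values: np.ndarray
    width: float

    def __post_init__(self) -> None:
        self.bucket_centers = np.asarray(self.bucket_centers, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_buckets(self) -> int:
        return len(self.bucket_centers)

    def to_dataframe(self, sample_ids=None) -> pd.DataFrame:
        cols = [f"{c:g}" for c in self.bucket_centers]
        idx = sample_ids if sample_ids is not None else range(self.values.shape[0])
        return pd.DataFrame(self.values, columns=cols, index=pd.Index(idx, name="sample_id"))


def bucket_spectra(
    s: SpectrumSet,
    width_ppm: float = DEFAULT_BUCKET_WIDTH,
    range_ppm: tuple[float, float] | None = None,
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
) -> BucketTable:
    """Sum intensities over half-open buckets [c−w/2, c+w/2) of width w.

    Centers sit at lo + w/2 + k·w inside ``range_ppm`` (default: the axis
    span).  Buckets overlapping any exclusion window are dropped; an empty
    final bucket set is an error.
    """
    if not width_ppm > 0:
        raise ValueError("bucket width must be > 0")
    axis_lo, axis_hi = float(np.min(s.ppm_axis)), float(np.max(s.ppm_axis))
    if range_ppm is None:
        lo, hi = axis_lo, axis_hi
    else:
        lo, hi = sorted(float(v) for v in range_ppm)
        if lo < axis_lo - 1e-12 or hi > axis_hi + 1e-12:
            raise ValueError("range_ppm must lie within the axis span")
    n_buckets = int(np.floor((hi - lo) / width_ppm + 1e-9))
    if n_buckets < 1:
        raise ValueError("range narrower than one bucket")
    centers = lo + width_ppm / 2 + width_ppm * np.arange(n_buckets)
    keep = np.ones(n_buckets, dtype=bool)
    for elo, ehi in exclusions:
        elo, ehi = sorted((elo, ehi))
        overlap = (centers + width_ppm / 2 > elo) & (centers - width_ppm / 2 < ehi)
        keep &= ~overlap
    centers = centers[keep]
    if centers.size == 0:
        raise ValueError("no buckets left after applying exclusion regions")
    edges_lo = centers - width_ppm / 2
    # assign each grid point to a bucket (half-open on the right)
    values = np.zeros((s.n_samples, centers.size))
    for b, c in enumerate(centers):
        in_b = (s.ppm_axis >= edges_lo[b] - 1e-12) & (s.ppm_axis < edges_lo[b] + width_ppm - 1e-12)
        values[:, b] = s.intensities[:, in_b].sum(axis=1)
    return BucketTable(centers, values, width_ppm)
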