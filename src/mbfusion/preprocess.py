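"""Spectral preprocessing and block standardization.

NMR path: reference the chemical-shift axis to the TSP singlet at
0.00 ppm, then integrate the spectrum into fixed-width buckets
(0.002 ppm over 0.4–12.0 ppm, residual-water window 4.8–5.0 ppm
excluded).  MIR path: Savitzky–Golay smoothing, vector normalization to
unit Euclidean norm, then removal of the uninformative windows
4000–3500, 2400–2200 and 500–400 cm⁻¹.  Finally every block (including
the tabular MS blocks) is Z-score standardized, with the statistics
fitted on model samples only and re-applied to external samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import FeatureBlock


@dataclass
class Spectrum:
    """A 1-D spectrum on a strictly monotone axis (ppm or cm⁻¹)."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity must be 1-D and equally long")
        if self.axis.size == 0:
            raise ValueError("empty spectrum")
        d = np.diff(self.axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("axis must be strictly monotone")
        if np.isnan(self.axis).any() or np.isnan(self.intensity).any():
            raise ValueError("NaN in spectrum")

    def ascending(self) -> "Spectrum":
        if self.axis[0] <= self.axis[-1]:
            return self
        return Spectrum(self.axis[::-1].copy(), self.intensity[::-1].copy())


@dataclass
class BucketingScheme:
    """NMR bucket layout: half-open tiles [b, b+width) over ``range``.

    Buckets overlapping any exclusion window are dropped whole.
    """

    width: float = 0.002
    range: tuple[float, float] = (0.4, 12.0)
    exclusions: tuple[tuple[float, float], ...] = ((4.8, 5.0),)
    reference_shift: float = 0.0
    reference_window: float = 0.05

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bucket width must be > 0")
        lo, hi = self.range
        if hi <= lo:
            raise ValueError("invalid bucket range")
        for a, b in self.exclusions:
            if not (lo <= a < b <= hi):
                raise ValueError(f"exclusion ({a}, {b}) outside range or inverted")

    def edges(self) -> np.ndarray:
        lo, hi = self.range
        n = int(round((hi - lo) / self.width))
        return lo + self.width * np.arange(n + 1)


@dataclass
class MirPipelineConfig:
    """MIR preprocessing: SG smoothing → vector normalization → window removal."""

    sg_window: int = 11
    sg_polyorder: int = 3
    removed_regions: tuple[tuple[float, float], ...] = (
        (3500.0, 4000.0),
        (2200.0, 2400.0),
        (400.0, 500.0),
    )
    full_range: tuple[float, float] = (400.0, 4000.0)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window < 3:
            raise ValueError("sg_window must be odd and ≥ 3")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        lo, hi = self.full_range
        for a, b in self.removed_regions:
            if not (lo <= a < b <= hi):
                raise ValueError(f"removed region ({a}, {b}) outside full range")


def reference_align(spectrum: Spectrum, scheme: BucketingScheme | None = None) -> Spectrum:
    """Shift the axis so the apex of the reference peak sits at 0.00 ppm.

    The apex is the tallest point within ``reference_window`` of the
    nominal reference shift (TSP at 0.00 ppm).  Raises ``ValueError``
    if no grid point falls inside the search window.
    """
    scheme = scheme or BucketingScheme()
    sp = spectrum.ascending()
    ref, win = scheme.reference_shift, scheme.reference_window
    mask = (sp.axis >= ref - win) & (sp.axis <= ref + win)
    if not mask.any():
        raise ValueError(
            f"reference peak not found within ±{win} of {ref} (axis "
            f"covers {sp.axis[0]:.3f}–{sp.axis[-1]:.3f})"
        )
    idx = np.flatnonzero(mask)
    apex = idx[np.argmax(sp.intensity[idx])]
    offset = sp.axis[apex] - ref
    return Spectrum(sp.axis - offset, sp.intensity.copy())


def bucket_spectrum(
    spectrum: Spectrum, scheme: BucketingScheme | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a referenced spectrum into fixed-width buckets.

    Returns ``(values, centers)``: the bucket value is the *sum* of
    intensities of grid points whose shift falls in the half-open tile
    [b, b+width); buckets overlapping an exclusion window are dropped
    entirely, and ``centers`` records each retained bucket's center.
    """
    scheme = scheme or BucketingScheme()
    sp = spectrum.ascending()
    edges = scheme.edges()
    n = edges.size - 1
    # point -> bucket assignment on the half-open grid
    pos = np.searchsorted(edges, sp.axis, side="right") - 1
    inside = (pos >= 0) & (pos < n)
    sums = np.bincount(pos[inside], weights=sp.intensity[inside], minlength=n)

    tol = scheme.width * 1e-6
    keep = np.ones(n, dtype=bool)
    starts, stops = edges[:-1], edges[1:]
    for lo, hi in scheme.exclusions:
        keep &= ~((starts < hi - tol) & (stops > lo + tol))
    centers = (starts + stops) / 2.0
    return sums[keep], centers[keep]


def savitzky_golay(spectrum: Spectrum, window: int, polyorder: int) -> Spectrum:
    """Savitzky–Golay smoothing; edges use the terminal-window polynomial fit."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and ≥ 3")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if spectrum.axis.size < window:
        raise ValueError("spectrum shorter than the filter window")
    out = savgol_filter(spectrum.intensity, window, polyorder, mode="interp")
    return Spectrum(spectrum.axis.copy(), out)


def vector_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    nrm = float(np.linalg.norm(spectrum.intensity))
    if nrm == 0.0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return Spectrum(spectrum.axis.copy(), spectrum.intensity / nrm)


def remove_regions(
    spectrum: Spectrum, config: MirPipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Drop grid points inside the removed windows (closed intervals).

    Returns ``(values, retained_axis)`` in ascending axis order.
    """
    config = config or MirPipelineConfig()
    sp = spectrum.ascending()
    keep = np.ones(sp.axis.size, dtype=bool)
    for lo, hi in config.removed_regions:
        keep &= ~((sp.axis >= lo) & (sp.axis <= hi))
    if not keep.any():
        raise ValueError("all grid points removed")
    return sp.intensity[keep], sp.axis[keep]


def nmr_to_block(
    spectra: Mapping[str, Spectrum], scheme: BucketingScheme | None = None
) -> FeatureBlock:
    """Reference-align and bucket a set of ¹H spectra into one block."""
    scheme = scheme or BucketingScheme()
    rows, centers = {}, None
    for sid, sp in spectra.items():
        vals, c = bucket_spectrum(reference_align(sp, scheme), scheme)
        rows[sid] = vals
        centers = c
    cols = [f"ppm_{c:.4f}" for c in centers]
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = cols
    return FeatureBlock("NMR", data, pd.Series(centers, index=cols))


def mir_to_block(
    spectra: Mapping[str, Spectrum], config: MirPipelineConfig | None = None
) -> FeatureBlock:
    """SG-smooth, vector-normalize and window-mask MIR spectra into one block."""
    config = config or MirPipelineConfig()
    rows, axis = {}, None
    for sid, sp in spectra.items():
        sm = savitzky_golay(sp, config.sg_window, config.sg_polyorder)
        vn = vector_normalize(sm)
        vals, ax = remove_regions(vn, config)
        rows[sid] = vals
        axis = ax
    cols = [f"wn_{a:g}" for a in axis]
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = cols
    return FeatureBlock("MIR", data, pd.Series(axis, index=cols))


@dataclass
class Standardization:
    """Fitted Z-score transform (population denominator), model samples only."""

    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return (data[self.mean.index] - self.mean) / self.sd

    def inverse(self, data: pd.DataFrame) -> pd.DataFrame:
        return data * self.sd + self.mean


def zscore_block(
    block: FeatureBlock, model_ids: Sequence[str]
) -> tuple[FeatureBlock, Standardization]:
    """Standardize a block with statistics fitted on model samples only.

    Each feature becomes (x − mean)/sd where mean and sd (population,
    n denominator) come from the model rows; the same transform is
    applied to external rows.  Zero-variance features are dropped with
    a warning so no NaN enters downstream models.
    """
    model_ids = list(model_ids)
    if len(model_ids) < 2:
        raise ValueError("need at least 2 model samples to standardize")
    fit = block.data.loc[model_ids]
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    dead = sd.index[sd == 0.0]
    if len(dead) == len(sd):
        raise ValueError(f"{block.platform}: every feature has zero variance")
    if len(dead):
        warnings.warn(
            f"{block.platform}: dropping {len(dead)} zero-variance feature(s)",
            stacklevel=2,
        )
    keep = sd.index.difference(dead, sort=False)
    std = Standardization(mean[keep], sd[keep], dropped=list(dead))
    out = std.transform(block.data)
    coords = block.coords.loc[keep] if block.coords is not None else None
    return FeatureBlock(block.platform, out, coords), std
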