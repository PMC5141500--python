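"""Population distributions: 1-D histograms and 2-D density maps.

Densities are normalised counts over the non-missing observations — no
kernel smoothing, so every number in a report is a raw population
fraction.  Angular series are binned on (-180, 180] with bin edges
anchored at -180 so no bin straddles the wrap point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptySeriesError, ValidationError


@dataclass
class Histogram1D:
    bin_edges: np.ndarray  # (n_bins + 1,)
    densities: np.ndarray  # fractions summing to 1 over non-missing values
    peak_location: float  # midpoint of the modal bin (ties: lower bin)
    n_missing: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def modal_bins(self, k: int = 2) -> list[tuple[float, float]]:
        """The k highest-density bins as (midpoint, density), density order."""
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        order = np.argsort(-self.densities, kind="stable")[:k]
        return [(float(mids[i]), float(self.densities[i])) for i in order]

    def to_tsv(self, path) -> None:
        lines = ["bin_low\tbin_high\tdensity"]
        for lo, hi, d in zip(self.bin_edges[:-1], self.bin_edges[1:], self.densities):
            lines.append(f"{lo:.6f}\t{hi:.6f}\t{d:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class Density2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    mass: np.ndarray  # (nx, ny) fractions summing to 1
    modal_cell: tuple[int, int]

    @property
    def modal_center(self) -> tuple[float, float]:
        i, j = self.modal_cell
        return (
            float(0.5 * (self.x_edges[i] + self.x_edges[i + 1])),
            float(0.5 * (self.y_edges[j] + self.y_edges[j + 1])),
        )

    def to_tsv(self, path) -> None:
        lines = ["x_low\ty_low\tmass"]
        for i in range(self.mass.shape[0]):
            for j in range(self.mass.shape[1]):
                if self.mass[i, j] > 0:
                    lines.append(
                        f"{self.x_edges[i]:.6f}\t{self.y_edges[j]:.6f}\t{self.mass[i, j]:.6f}"
                    )
        Path(path).write_text("\n".join(lines) + "\n")


def _values_of(series) -> np.ndarray:
    return np.asarray(getattr(series, "values", series), dtype=float)


def _edges(lo: float, hi: float, width: float) -> np.ndarray:
    start = math.floor(lo / width) * width
    n = max(int(math.ceil((hi - start) / width)), 1)
    if start + n * width <= hi:  # value exactly on the top edge
        n += 1
    return start + width * np.arange(n + 1)


def histogram(series, bin_width: float, angular: bool = False) -> Histogram1D:
    """Normalised histogram of a distance or torsion series.

    ``angular=True`` bins on the fixed (-180, 180] support (the width
    must divide 360); otherwise uniform bins are anchored at integer
    multiples of the width spanning the data.
    """
    vals = _values_of(series)
    missing = ~np.isfinite(vals)
    vals = vals[~missing]
    if vals.size == 0:
        raise EmptySeriesError("histogram over an all-missing series")
    if angular:
        if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
            raise ValidationError("angular bin width must divide 360")
        edges = -180.0 + bin_width * np.arange(int(round(360.0 / bin_width)) + 1)
        # (-180, 180] support: treat each bin as (low, high]
        shifted = np.where(vals == 180.0, 180.0 - 1e-12, vals)
        counts, _ = np.histogram(shifted, bins=edges)
    else:
        edges = _edges(float(vals.min()), float(vals.max()), bin_width)
        counts, _ = np.histogram(vals, bins=edges)
    dens = counts / counts.sum()
    peak_i = int(np.argmax(dens))  # lowest bin on ties
    peak = float(0.5 * (edges[peak_i] + edges[peak_i + 1]))
    return Histogram1D(edges, dens, peak, int(missing.sum()))


def density2d(xs, ys, bin_width: float) -> Density2D:
    """Normalised 2-D occupancy grid of two paired series."""
    x = _values_of(xs)
    y = _values_of(ys)
    if x.shape != y.shape:
        raise ValidationError("x and y series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise EmptySeriesError("density2d over all-missing pairs")
    xe = _edges(float(x.min()), float(x.max()), bin_width)
    ye = _edges(float(y.min()), float(y.max()), bin_width)
    counts, _, _ = np.histogram2d(x, y, bins=(xe, ye))
    mass = counts / counts.sum()
    flat = int(np.argmax(mass))  # row-major: lowest (i, j) on ties
    modal = (flat // mass.shape[1], flat % mass.shape[1])
    return Density2D(xe, ye, mass, modal)
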