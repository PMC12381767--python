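"""Pairwise probe–probe distance time series (the r_id map).

Re-implements the distance-map analysis: for every unordered pair of probe
atoms, the inter-probe distance r_id is computed in every trajectory frame —
with minimum-image wrapping when a cubic periodic box is present — and
summarised as binned profiles and occupancy fractions. Occupancies use a
strict ``<`` at the cutoff: an interaction is counted only when r_id is
*below* the threshold (0.6 nm for selection, 0.4 nm as the hydrogen-bond
proximity proxy).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .charge_probes import ProbeAtom
from .structure_io import Trajectory

#: hydrogen-bond proximity proxy, nm
HBOND_CUTOFF = 0.4
#: interaction-selection cutoff, nm
INTERACTION_CUTOFF = 0.6


@dataclass
class DistanceSeries:
    """r_id time series (nm) for one unordered probe pair."""

    pair: tuple[ProbeAtom, ProbeAtom] | None
    values: np.ndarray
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("distance series must be 1-D")
        if self.values.size and (not np.all(np.isfinite(self.values))
                                 or np.any(self.values < 0)):
            raise ValueError("distances must be finite and non-negative")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class RidProfile:
    """Uniform-width histogram of an r_id series, with an overflow count."""

    bin_edges: np.ndarray
    counts: np.ndarray
    overflow_count: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow_count

    def to_tsv(self) -> str:
        lines = ["bin_lo\tbin_hi\tcount"]
        for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
            lines.append(f"{lo:.6g}\t{hi:.6g}\t{int(c)}")
        lines.append(f"{self.bin_edges[-1]:.6g}\tinf\t{self.overflow_count}")
        return "\n".join(lines) + "\n"


def minimum_image_distances(xi: np.ndarray, xj: np.ndarray,
                            box: np.ndarray | float | None) -> np.ndarray:
    """Distances between paired coordinate arrays (…, 3), minimum-image if boxed.

    ``box`` is the cubic edge length (scalar or per-frame array) or None for
    open boundaries. Each displacement component is wrapped to [-L/2, L/2).
    """
    d = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    if box is not None:
        L = np.asarray(box, dtype=float)
        if np.any(L <= 0):
            raise ValueError("box edge must be positive")
        if L.ndim == 1:            # per-frame edges
            L = L[:, None]
        d = d - L * np.round(d / L)
    return np.sqrt(np.sum(d * d, axis=-1))


def compute_distance_series(traj: Trajectory, probes: list[ProbeAtom]
                            ) -> dict[frozenset[int], DistanceSeries]:
    """All unordered probe-pair r_id series along a trajectory.

    Keys are frozensets of probe indices into ``probes``. Distances are
    Euclidean, or minimum-image when the trajectory carries a cubic box.
    Self-pairs are excluded; the map is symmetric by construction.
    """
    if len(probes) < 2:
        return {}
    coords = traj.coords()          # (n_frames, n_atoms, 3)
    n_atoms = coords.shape[1]
    for p in probes:
        if not 0 <= p.atom_index < n_atoms:
            raise IndexError(f"probe atom index {p.atom_index} ({p.label}) "
                             "not present in trajectory frames")
    boxes = traj.boxes()            # None or (n_frames,)
    pcoords = coords[:, [p.atom_index for p in probes], :]
    out: dict[frozenset[int], DistanceSeries] = {}
    for i in range(len(probes)):
        for j in range(i + 1, len(probes)):
            values = minimum_image_distances(pcoords[:, i, :], pcoords[:, j, :], boxes)
            out[frozenset((i, j))] = DistanceSeries(
                pair=(probes[i], probes[j]),
                values=values,
                sampling_interval=traj.sampling_interval,
            )
    return out


def import_series(path: str | Path, pair: tuple[ProbeAtom, ProbeAtom] | None = None,
                  time_tolerance: float = 1e-6) -> DistanceSeries:
    """Read a two-column time (ps) / distance (nm) text file (XVG-style).

    Lines beginning with ``#`` or ``@`` are ignored. Times must be uniformly
    spaced within ``time_tolerance`` ps; a single-row file defaults to a 1 ps
    interval.
    """
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    times = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    if len(times) > 1:
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise ValueError(f"{path}: times are not strictly increasing")
        if np.max(steps) - np.min(steps) > time_tolerance:
            raise ValueError(f"{path}: non-uniform time spacing "
                             f"(spread {np.max(steps) - np.min(steps):.3g} ps)")
        interval = float(np.mean(steps))
    else:
        interval = 1.0
    return DistanceSeries(pair=pair, values=values, sampling_interval=interval)


def export_series(series: DistanceSeries, path: str | Path,
                  comment: str | None = None) -> None:
    """Write a series as two-column XVG-style text (time ps, distance nm)."""
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("@    xaxis  label \"Time (ps)\"")
    lines.append("@    yaxis  label \"Distance (nm)\"")
    t = np.arange(len(series)) * series.sampling_interval
    for ti, vi in zip(t, series.values):
        lines.append(f"{ti:.6f} {vi:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def bin_distances(series: DistanceSeries, bin_width: float = 0.02,
                  max_range: float = 2.0) -> RidProfile:
    """Histogram an r_id series into uniform half-open bins [lo, hi).

    Values ≥ ``max_range`` fall in the overflow count, so the profile always
    conserves the frame count.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(round(max_range / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    in_range = series.values < edges[-1]
    idx = np.floor(series.values[in_range] / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    return RidProfile(bin_edges=edges, counts=counts,
                      overflow_count=int((~in_range).sum()))


def occupancy_fraction(series: DistanceSeries, cutoff: float) -> float:
    """Fraction of frames with r_id strictly below ``cutoff`` (nm)."""
    if len(series) == 0:
        raise ValueError("occupancy of an empty series is undefined")
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    return float(np.count_nonzero(series.values < cutoff)) / len(series)


def hbond_fraction(series: DistanceSeries) -> float:
    """Fraction of frames with r_id below the 0.4 nm hydrogen-bond proxy."""
    return occupancy_fraction(series, HBOND_CUTOFF)
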