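"""Contact-map and 1-D track I/O, normalization, windowing and assembly.

Conventions: coordinates are 0-based bin indices; genomic spans are
half-open ``[start, end)``; contact maps are dense symmetric numpy arrays
for a single chromosome at a fixed resolution (10 Kbp by default).

Supported formats: coordinate-triplet text (``bin_i  bin_j  count``), a
single-resolution ``.cool``-style HDF5 container, bedGraph, and bigWig
(read-only, via pyBigWig).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ContactMap",
    "BinnedTrack",
    "Window",
    "ChromosomeNotFoundError",
    "BalancingError",
    "read_contact_map",
    "write_triplet",
    "read_cool",
    "write_cool",
    "kr_normalize",
    "clip_normalize",
    "sample_windows",
    "assemble",
    "read_track",
    "write_bedgraph",
    "normalize_track",
]

DEFAULT_RESOLUTION = 10_000
DEFAULT_WINDOW = 256
DEFAULT_STRIDE = 30
CLIP_PERCENTILE = 99.9


class ChromosomeNotFoundError(KeyError):
    """Requested chromosome is absent from the file."""


class BalancingError(RuntimeError):
    """Matrix balancing failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class ContactMap:
    """Symmetric non-negative contact matrix for one chromosome (or window).

    ``norm_state`` tracks the normalization pipeline stage:
    ``raw`` (counts) -> ``kr`` (balanced) -> ``clipped`` (scaled to [0,1]).
    """

    matrix: np.ndarray
    chrom: str = "chr?"
    resolution: int = DEFAULT_RESOLUTION
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("contact matrix must be symmetric within 1e-8")
        if self.matrix.min() < 0:
            raise ValueError("contact matrix entries must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def total_reads(self) -> float:
        """Total count over the upper triangle, diagonal included."""
        return float(np.triu(self.matrix).sum())


@dataclass
class BinnedTrack:
    """Per-bin 1-D signal for one chromosome, aligned to the map binning."""

    values: np.ndarray
    chrom: str = "chr?"
    resolution: int = DEFAULT_RESOLUTION
    assay_name: str = "signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("track values must be a 1-D vector")
        if self.values.min() < 0:
            raise ValueError("track values must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class Window:
    """One diagonal window: a size x size submatrix plus aligned track slices."""

    chrom: str
    start_bin: int
    size: int
    submatrix: np.ndarray
    track_slices: dict[str, np.ndarray] = field(default_factory=dict)
    padded: bool = False


# ---------------------------------------------------------------------------
# Contact-map I/O
# ---------------------------------------------------------------------------

def read_contact_map(path: str | Path, chrom: str,
                     resolution: int = DEFAULT_RESOLUTION,
                     n_bins: int | None = None) -> ContactMap:
    """Read a dense intra-chromosomal contact map from ``.cool`` or triplet text.

    Triplet text has whitespace-separated columns ``bin_i bin_j count`` (0-based
    bin indices within the chromosome).  If the file lists both orientations
    of a pair with different counts, the map is symmetrized by the maximum
    and a warning is emitted.
    """
    path = Path(path)
    if path.suffix == ".cool":
        return read_cool(path, chrom)
    if n_bins is None and path.stat().st_size == 0:
        raise ValueError("empty triplet file requires an explicit n_bins")
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["bin_i", "bin_j", "count"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["bin_i", "bin_j", "count"])
    if n_bins is None:
        n_bins = int(max(df["bin_i"].max(), df["bin_j"].max())) + 1
    m = np.zeros((n_bins, n_bins))
    i = df["bin_i"].to_numpy(dtype=np.intp)
    j = df["bin_j"].to_numpy(dtype=np.intp)
    c = df["count"].to_numpy(dtype=np.float64)
    if len(i) and (i.max() >= n_bins or j.max() >= n_bins):
        raise ValueError("triplet bin index exceeds declared n_bins")
    np.maximum.at(m, (i, j), c)
    mt = m.T
    both = (m > 0) & (mt > 0) & ~np.isclose(m, mt)
    if both.any():
        warnings.warn(f"{path}: asymmetric triplet input; symmetrizing by max")
    m = np.maximum(m, mt)
    return ContactMap(matrix=m, chrom=chrom, resolution=resolution,
                      norm_state="raw")


def write_triplet(cmap: ContactMap, path: str | Path) -> None:
    """Write the upper triangle (nonzero entries) as ``bin_i bin_j count``."""
    i, j = np.nonzero(np.triu(cmap.matrix))
    df = pd.DataFrame({"bin_i": i, "bin_j": j,
                       "count": cmap.matrix[i, j]})
    df.to_csv(path, sep="\t", header=False, index=False)


def write_cool(maps: list[ContactMap] | ContactMap, path: str | Path) -> None:
    """Write contact maps to a minimal single-resolution cooler-style HDF5 file.

    Layout follows the cooler schema (``chroms``, ``bins``, ``pixels``
    tables with upper-triangle pixels); only the fields this package reads
    back are populated.
    """
    import h5py

    if isinstance(maps, ContactMap):
        maps = [maps]
    resolution = maps[0].resolution
    with h5py.File(path, "w") as f:
        f.attrs["bin-size"] = resolution
        f.attrs["format"] = "HDF5::Cooler"
        names = [m.chrom for m in maps]
        lengths = [m.n_bins * resolution for m in maps]
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(names, dtype="S32"))
        g.create_dataset("length", data=np.array(lengths, dtype=np.int64))
        chrom_ids, starts, ends = [], [], []
        offsets = {}
        offset = 0
        for ci, m in enumerate(maps):
            offsets[m.chrom] = offset
            for b in range(m.n_bins):
                chrom_ids.append(ci)
                starts.append(b * resolution)
                ends.append((b + 1) * resolution)
            offset += m.n_bins
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.array(chrom_ids, dtype=np.int32))
        g.create_dataset("start", data=np.array(starts, dtype=np.int64))
        g.create_dataset("end", data=np.array(ends, dtype=np.int64))
        b1, b2, cnt = [], [], []
        for m in maps:
            i, j = np.nonzero(np.triu(m.matrix))
            b1.append(i + offsets[m.chrom])
            b2.append(j + offsets[m.chrom])
            cnt.append(m.matrix[i, j])
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=np.concatenate(b1).astype(np.int64)
                         if b1 else np.zeros(0, dtype=np.int64))
        g.create_dataset("bin2_id", data=np.concatenate(b2).astype(np.int64)
                         if b2 else np.zeros(0, dtype=np.int64))
        g.create_dataset("count", data=np.concatenate(cnt)
                         if cnt else np.zeros(0))


def read_cool(path: str | Path, chrom: str) -> ContactMap:
    """Read one chromosome's dense matrix from a cooler-style HDF5 file."""
    import h5py

    with h5py.File(path, "r") as f:
        resolution = int(f.attrs["bin-size"])
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["chroms/name"][:]]
        if chrom not in names:
            raise ChromosomeNotFoundError(
                f"chromosome {chrom!r} not in {path} (has {names})")
        ci = names.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        bin_ids = np.nonzero(bin_chrom == ci)[0]
        lo, hi = bin_ids.min(), bin_ids.max() + 1
        n = hi - lo
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
        sel = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        m = np.zeros((n, n))
        m[b1[sel] - lo, b2[sel] - lo] = cnt[sel]
        m = np.maximum(m, m.T)
    return ContactMap(matrix=m, chrom=chrom, resolution=resolution,
                      norm_state="raw")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def kr_normalize(cmap: ContactMap, tol: float = 1e-8,
                 max_iter: int = 1000) -> ContactMap:
    """Knight-Ruiz matrix balancing: find diagonal D with D.M.D doubly stochastic.

    All-zero rows are masked out of the balancing and returned as zero; every
    non-masked row of the balanced matrix sums to 1 within ``tol``.  Uses the
    Knight-Ruiz inexact-Newton iteration with an inner conjugate-gradient
    solve.  Raises :class:`BalancingError` on non-convergence.
    """
    M = cmap.matrix
    n = M.shape[0]
    nz = M.sum(axis=1) > 0
    A = M[np.ix_(nz, nz)]
    out = np.zeros_like(M)
    if A.size:
        x, residual, converged = _knight_ruiz(A, tol=tol, max_iter=max_iter)
        if not converged:
            raise BalancingError(
                f"KR balancing did not converge in {max_iter} iterations "
                f"(residual {residual:.3e})", residual)
        out[np.ix_(nz, nz)] = A * np.outer(x, x)
    return ContactMap(matrix=(out + out.T) / 2.0, chrom=cmap.chrom,
                      resolution=cmap.resolution, norm_state="kr")


def _knight_ruiz(A: np.ndarray, tol: float, max_iter: int,
                 delta: float = 0.1, Delta: float = 3.0):
    """Inexact-Newton balancing of a symmetric non-negative matrix.

    Returns ``(x, residual, converged)`` with row sums of
    ``diag(x) A diag(x)`` equal to 1 at convergence.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_iter:
            return x, float(np.sqrt(rout)), False
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > innertol:
            k += 1
            if k > max_iter:
                break
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(np.sqrt(rout), 1e-300))
    return x, float(np.sqrt(rout)), True


def clip_normalize(cmap: ContactMap, percentile: float = CLIP_PERCENTILE,
                   band_bins: int = DEFAULT_WINDOW) -> ContactMap:
    """Clip at the per-chromosome ``percentile`` value and scale to [0,1].

    The percentile is computed over nonzero upper-triangle entries within
    ``band_bins`` of the diagonal — the region the model actually operates
    on.  An all-zero matrix is returned unchanged with a warning.
    """
    m = cmap.matrix
    n = m.shape[0]
    i, j = np.triu_indices(n)
    band = (j - i) <= band_bins
    vals = m[i[band], j[band]]
    vals = vals[vals > 0]
    if vals.size == 0:
        warnings.warn(f"{cmap.chrom}: all-zero matrix; clip normalization "
                      "skipped (divisor undefined)")
        return ContactMap(matrix=m.copy(), chrom=cmap.chrom,
                          resolution=cmap.resolution,
                          norm_state=cmap.norm_state)
    cutoff = float(np.percentile(vals, percentile))
    if cutoff <= 0:
        cutoff = float(vals.max())
    out = np.minimum(m, cutoff) / cutoff
    return ContactMap(matrix=out, chrom=cmap.chrom,
                      resolution=cmap.resolution, norm_state="clipped")


def normalize_track(track: BinnedTrack,
                    percentile: float = CLIP_PERCENTILE) -> BinnedTrack:
    """0-to-percentile normalization of a track, mirroring the map pipeline."""
    v = track.values
    pos = v[v > 0]
    if pos.size == 0:
        warnings.warn(f"{track.assay_name}/{track.chrom}: empty track")
        return BinnedTrack(values=v.copy(), chrom=track.chrom,
                           resolution=track.resolution,
                           assay_name=track.assay_name)
    cutoff = float(np.percentile(pos, percentile))
    if cutoff <= 0:
        cutoff = float(pos.max())
    return BinnedTrack(values=np.minimum(v, cutoff) / cutoff,
                       chrom=track.chrom, resolution=track.resolution,
                       assay_name=track.assay_name)


# ---------------------------------------------------------------------------
# Windowing and re-assembly
# ---------------------------------------------------------------------------

def sample_windows(cmap: ContactMap, tracks: list[BinnedTrack] | None = None,
                   size: int = DEFAULT_WINDOW,
                   stride_bins: int = DEFAULT_STRIDE) -> list[Window]:
    """Sample diagonal windows at ``{0, stride, 2*stride, ...}``.

    The final window is right-anchored at ``n - size`` so the chromosome
    tail is covered without zero padding.  A chromosome shorter than
    ``size`` yields a single zero-padded window with ``padded=True``.
    """
    tracks = tracks or []
    n = cmap.n_bins
    for t in tracks:
        if t.n_bins != n:
            raise ValueError(
                f"track {t.assay_name} has {t.n_bins} bins, map has {n}")
    if n < size:
        sub = np.zeros((size, size))
        sub[:n, :n] = cmap.matrix
        slices = {}
        for t in tracks:
            v = np.zeros(size)
            v[:n] = t.values
            slices[t.assay_name] = v
        return [Window(chrom=cmap.chrom, start_bin=0, size=size,
                       submatrix=sub, track_slices=slices, padded=True)]
    starts = list(range(0, n - size + 1, stride_bins))
    if starts[-1] != n - size:
        starts.append(n - size)
    windows = []
    for s in starts:
        sub = cmap.matrix[s:s + size, s:s + size].copy()
        slices = {t.assay_name: t.values[s:s + size].copy() for t in tracks}
        windows.append(Window(chrom=cmap.chrom, start_bin=s, size=size,
                              submatrix=sub, track_slices=slices))
    return windows


def assemble(windows_with_predictions: list[tuple[Window, np.ndarray]],
             chrom_bin_count: int, chrom: str = "chr?",
             resolution: int = DEFAULT_RESOLUTION) -> ContactMap:
    """Average overlapping window predictions into a chromosome-wide map.

    Each output entry is the arithmetic mean of all predictions covering it
    (the border-effect correction); uncovered entries are 0.  The result is
    symmetrized as ``(A + A.T) / 2``.
    """
    n = chrom_bin_count
    acc = np.zeros((n, n))
    cov = np.zeros((n, n))
    for win, pred in windows_with_predictions:
        pred = np.asarray(pred, dtype=np.float64)
        if pred.shape != (win.size, win.size):
            raise ValueError(
                f"prediction shape {pred.shape} != window size {win.size}")
        s = win.start_bin
        if win.padded:
            k = min(n - s, win.size)
            acc[s:s + k, s:s + k] += pred[:k, :k]
            cov[s:s + k, s:s + k] += 1.0
        else:
            acc[s:s + win.size, s:s + win.size] += pred
            cov[s:s + win.size, s:s + win.size] += 1.0
    out = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    out = (out + out.T) / 2.0
    out = np.maximum(out, 0.0)
    return ContactMap(matrix=out, chrom=chrom, resolution=resolution,
                      norm_state="clipped")


# ---------------------------------------------------------------------------
# 1-D track I/O
# ---------------------------------------------------------------------------

def read_track(path: str | Path, chrom: str,
               resolution: int = DEFAULT_RESOLUTION,
               n_bins: int | None = None,
               assay_name: str | None = None) -> BinnedTrack:
    """Bin a bedGraph (or bigWig) signal into per-bin coverage-weighted means.

    An interval straddling bin borders contributes to each bin in proportion
    to its overlap; uncovered bins are 0.  The returned track is *raw* —
    apply :func:`normalize_track` for the [0,1] pipeline scale.
    """
    path = Path(path)
    name = assay_name or path.stem
    if path.suffix in (".bw", ".bigwig", ".bigWig"):
        return _read_bigwig(path, chrom, resolution, n_bins, name)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    present = set(df["chrom"].unique())
    if chrom not in present:
        if n_bins is None:
            raise ChromosomeNotFoundError(
                f"chromosome {chrom!r} not in {path}")
        warnings.warn(f"{path}: no intervals for {chrom}; empty track")
        return BinnedTrack(values=np.zeros(n_bins), chrom=chrom,
                           resolution=resolution, assay_name=name)
    df = df[df["chrom"] == chrom]
    if n_bins is None:
        n_bins = int(np.ceil(df["end"].max() / resolution))
    wsum = np.zeros(n_bins)
    cover = np.zeros(n_bins)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        b0 = int(start // resolution)
        b1 = int((end - 1) // resolution)
        for b in range(max(b0, 0), min(b1, n_bins - 1) + 1):
            lo = max(start, b * resolution)
            hi = min(end, (b + 1) * resolution)
            if hi > lo:
                wsum[b] += value * (hi - lo)
                cover[b] += hi - lo
    values = np.divide(wsum, cover, out=np.zeros(n_bins), where=cover > 0)
    if not df.shape[0]:
        warnings.warn(f"{path}: empty track for {chrom}")
    return BinnedTrack(values=np.maximum(values, 0.0), chrom=chrom,
                       resolution=resolution, assay_name=name)


def _read_bigwig(path: Path, chrom: str, resolution: int,
                 n_bins: int | None, name: str) -> BinnedTrack:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        if chrom not in bw.chroms():
            raise ChromosomeNotFoundError(
                f"chromosome {chrom!r} not in {path}")
        length = bw.chroms()[chrom]
        if n_bins is None:
            n_bins = int(np.ceil(length / resolution))
        stats = bw.stats(chrom, 0, min(length, n_bins * resolution),
                         nBins=n_bins, type="mean")
        values = np.array([0.0 if s is None else float(s) for s in stats])
    finally:
        bw.close()
    return BinnedTrack(values=np.maximum(values, 0.0), chrom=chrom,
                       resolution=resolution, assay_name=name)


def write_bedgraph(track: BinnedTrack, path: str | Path) -> None:
    """Write a track as 4-column bedGraph (one interval per nonzero bin)."""
    res = track.resolution
    with open(path, "w") as f:
        for b, v in enumerate(track.values):
            if v != 0:
                f.write(f"{track.chrom}\t{b * res}\t{(b + 1) * res}\t{v:.6g}\n")
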