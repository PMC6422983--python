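"""cfDNA fragmentation maps: filter -> trim -> count -> smooth, plus
nucleosome peak calling and the peak/amplicon interception test.

The processing chain mirrors how plasma WGS fragment data are turned into
a per-base fragmentation signal: paired reads define the outer span of the
original molecule; fragments are restricted to the mononucleosome range
(80-250 bp, dinucleosome fragments excluded); each fragment is replaced by
the 40 bp window centered on its midpoint (the dyad proxy) so that all
fragments contribute equal weight at their dyad; per-base overlap counts
are then low-pass filtered with a 21 bp square-pulse kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import AmpliconDef, FragmentRecord

__all__ = [
    "CoverageTrack",
    "NucleosomeMap",
    "fragments_from_pairs",
    "filter_by_length",
    "trim_to_dyad_window",
    "position_overlap_counts",
    "square_pulse_smooth",
    "call_nucleosome_peaks",
    "interception_test",
    "build_fragmentation_track",
]


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base fragment-overlap counts over ``[origin, origin + len(values))``."""

    contig: str
    origin: int
    values: np.ndarray
    smoothed_flag: bool = False
    kernel_width: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("track values must be a non-empty 1-D array")
        if np.any(vals < 0):
            raise ValueError("track values must be non-negative")
        if self.kernel_width is not None and self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd")

    @property
    def end(self) -> int:
        return self.origin + len(self.values)

    def segment(self, start: int, end: int) -> np.ndarray:
        """Values over [start, end); raises if the track does not cover it."""
        if start < self.origin or end > self.end or end <= start:
            raise ValueError(
                f"track [{self.origin}, {self.end}) does not cover [{start}, {end})"
            )
        return self.values[start - self.origin : end - self.origin]


@dataclass(frozen=True)
class NucleosomeMap:
    """Called nucleosome peaks with positional stringency scores.

    Stringency is the smoothed dyad density at the peak divided by the mean
    density over the flanking background window, so sharply positioned
    nucleosomes standing out of a flat background score well above 1.
    """

    contig: str
    positions: np.ndarray
    stringencies: np.ndarray
    bandwidth: float
    background_window: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        stx = np.asarray(self.stringencies, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "stringencies", stx)
        if len(pos) != len(stx):
            raise ValueError("positions and stringencies must align")
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ValueError("peak positions must be strictly increasing")
        if np.any(stx < 0):
            raise ValueError("stringencies must be non-negative")

    @property
    def n_peaks(self) -> int:
        return len(self.positions)


def fragments_from_pairs(pairs, sample_id: str = "pooled"):
    """Collapse read pairs to fragment outer spans.

    Each pair is two ``(contig, start, end)`` read intervals; the fragment
    is ``[min(starts), max(ends))`` on their shared contig. Pairs on
    different contigs or with an empty outer span are dropped, not fatal.

    Returns ``(fragments, dropped)`` where ``dropped`` maps reason ->
    count (``cross_contig``, ``invalid_span``).
    """
    fragments: list[FragmentRecord] = []
    dropped = {"cross_contig": 0, "invalid_span": 0}
    for read1, read2 in pairs:
        c1, s1, e1 = read1
        c2, s2, e2 = read2
        if c1 != c2:
            dropped["cross_contig"] += 1
            continue
        start, end = min(s1, s2), max(e1, e2)
        if end <= start or min(e1 - s1, e2 - s2) <= 0:
            dropped["invalid_span"] += 1
            continue
        fragments.append(FragmentRecord(c1, start, end, sample_id))
    return fragments, dropped


def filter_by_length(
    fragments, min_len: int = 80, max_len: int = 250
) -> list[FragmentRecord]:
    """Keep fragments with ``min_len <= length <= max_len`` (inclusive).

    The 80-250 bp default retains the mononucleosome population and
    excludes dinucleosome fragments. Order is preserved.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [f for f in fragments if min_len <= f.length <= max_len]


def trim_to_dyad_window(fragments, window: int = 40) -> list[FragmentRecord]:
    """Replace each fragment by the ``window`` bp interval centered on its
    midpoint, yielding a set of equal-length dyad-centered fragments.

    The dyad proxy is ``floor((start + end) / 2)``; the output interval is
    ``[dyad - window/2, dyad + window/2)``. Fragments shorter than the
    window are a hard error (they cannot contain it).
    """
    if window < 2 or window % 2:
        raise ValueError(f"window must be even and >= 2, got {window}")
    half = window // 2
    short = [f for f in fragments if f.length < window]
    if short:
        preview = ", ".join(f"[{f.start},{f.end})" for f in short[:5])
        raise ValueError(
            f"{len(short)} fragment(s) shorter than the {window} bp window: {preview}"
        )
    return [
        FragmentRecord(f.contig, f.midpoint - half, f.midpoint + half, f.sample_id)
        for f in fragments
    ]


def position_overlap_counts(
    fragments, start: int, end: int, contig: str | None = None
) -> CoverageTrack:
    """Per-base count of overlapping fragments over the region ``[start, end)``.

    ``values[p - start]`` equals the number of fragments with
    ``f.start <= p < f.end``. Fragments on other contigs are ignored when
    ``contig`` is given (or taken from the first fragment otherwise).
    """
    if end <= start:
        raise ValueError(f"empty region [{start}, {end})")
    n = end - start
    diff = np.zeros(n + 1, dtype=float)
    frags = list(fragments)
    if contig is None and frags:
        contig = frags[0].contig
    for f in frags:
        if contig is not None and f.contig != contig:
            continue
        lo = max(f.start, start) - start
        hi = min(f.end, end) - start
        if hi > lo:
            diff[lo] += 1
            diff[hi] -= 1
    return CoverageTrack(contig or "unknown", start, np.cumsum(diff[:-1]))


def square_pulse_smooth(track: CoverageTrack, width: int = 21) -> CoverageTrack:
    """Low-pass filter with a square-pulse kernel: a centered moving mean.

    At the edges the window is truncated to the positions that exist and
    renormalized by its actual size, so constant signals stay constant all
    the way to the boundary instead of being dragged toward zero.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"kernel width must be odd and >= 1, got {width}")
    n = len(track.values)
    if width > n:
        raise ValueError(f"kernel width {width} exceeds track length {n}")
    kernel = np.ones(width)
    sums = np.convolve(track.values, kernel, mode="same")
    norms = np.convolve(np.ones(n), kernel, mode="same")
    return CoverageTrack(
        track.contig, track.origin, sums / norms, smoothed_flag=True, kernel_width=width
    )


def call_nucleosome_peaks(
    dyads,
    bandwidth: float = 30.0,
    background_window: int = 1000,
    min_stringency: float = 0.0,
    contig: str = "unknown",
) -> NucleosomeMap:
    """Call nucleosome peaks from dyad positions by Gaussian kernel density.

    Dyad counts are binned per base pair and smoothed with a Gaussian of sd
    ``bandwidth``; peaks are strict local maxima of the density. Each
    peak's stringency is its density divided by the mean density over
    flanking positions within ``background_window / 2`` on each side,
    excluding positions within ``bandwidth`` of the peak. Peaks below
    ``min_stringency`` are dropped.
    """
    dyads = np.asarray(list(dyads), dtype=np.int64)
    if dyads.size == 0:
        raise ValueError("no dyads provided")
    if bandwidth <= 0 or background_window <= 0:
        raise ValueError("bandwidth and background_window must be positive")

    pad = int(np.ceil(3 * bandwidth))
    origin = int(dyads.min()) - pad
    grid_len = int(dyads.max()) - origin + pad + 1
    hist = np.zeros(grid_len)
    np.add.at(hist, dyads - origin, 1.0)
    density = gaussian_filter1d(hist, sigma=bandwidth, mode="constant")

    interior = density[1:-1]
    is_peak = (interior > density[:-2]) & (interior > density[2:])
    peak_idx = np.flatnonzero(is_peak) + 1

    half_bg = background_window // 2
    bw = int(np.ceil(bandwidth))
    offsets = np.arange(-half_bg, half_bg + 1)
    flank_mask = np.abs(offsets) > bw
    positions, stringencies = [], []
    for idx in peak_idx:
        around = idx + offsets
        valid = flank_mask & (around >= 0) & (around < grid_len)
        background = density[around[valid]]
        bg_mean = background.mean() if background.size else 0.0
        stringency = density[idx] / bg_mean if bg_mean > 0 else np.inf
        if stringency >= min_stringency:
            positions.append(origin + idx)
            stringencies.append(stringency)
    return NucleosomeMap(
        contig,
        np.array(positions, dtype=np.int64),
        np.array(stringencies),
        bandwidth,
        background_window,
    )


def interception_test(
    nmap: NucleosomeMap,
    panel: list[AmpliconDef],
    n_perm: int = 999,
    seed: int = 0,
    region: tuple[int, int] | None = None,
) -> tuple[float, int]:
    """Permutation test of whether amplicons intercept nucleosome peaks.

    The statistic is the number of amplicons whose interval contains at
    least one peak position. The null redistributes each amplicon by an
    independent uniform circular shift within the mapped region;
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.

    Returns ``(p_value, observed_count)``.
    """
    if nmap.n_peaks == 0 or not panel:
        raise ValueError("need at least one peak and one amplicon")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if region is None:
        lo = min(int(nmap.positions.min()), min(a.outer_start for a in panel))
        hi = max(int(nmap.positions.max()) + 1, max(a.outer_end for a in panel))
    else:
        lo, hi = region
    region_len = hi - lo
    if region_len <= 0:
        raise ValueError("empty region")

    in_region = (nmap.positions >= lo) & (nmap.positions < hi)
    peaks = np.sort(nmap.positions[in_region] - lo)
    starts = np.array([a.outer_start - lo for a in panel]) % region_len
    lengths = np.array([a.length for a in panel])

    def count_intercepting(shifted_starts: np.ndarray) -> int:
        # amplicon i contains a peak iff some peak q satisfies
        # (q - start_i) mod region_len < length_i; count via sorted peaks,
        # splitting intervals that wrap around the region end.
        a = shifted_starts % region_len
        b = a + lengths
        n_main = np.searchsorted(peaks, np.minimum(b, region_len), side="left") - \
            np.searchsorted(peaks, a, side="left")
        wrap = np.maximum(b - region_len, 0)
        n_wrap = np.searchsorted(peaks, wrap, side="left")
        return int(np.count_nonzero(n_main + np.where(b > region_len, n_wrap, 0) > 0))

    observed = count_intercepting(starts)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        offsets = rng.integers(0, region_len, size=len(panel))
        if count_intercepting(starts + offsets) >= observed:
            exceed += 1
    return (1 + exceed) / (n_perm + 1), observed


def build_fragmentation_track(
    fragments,
    start: int,
    end: int,
    min_len: int = 80,
    max_len: int = 250,
    trim_window: int = 40,
    kernel_width: int = 21,
    contig: str | None = None,
) -> CoverageTrack:
    """Full chain: length filter -> dyad trim -> overlap counts -> smooth."""
    kept = filter_by_length(fragments, min_len, max_len)
    trimmed = trim_to_dyad_window(kept, trim_window)
    raw = position_overlap_counts(trimmed, start, end, contig=contig)
    return square_pulse_smooth(raw, kernel_width)
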