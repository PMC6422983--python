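"""GC-band normalization and the regression/ANOVA suite for amplicon
coverage.

Amplicon sequencing depth depends strongly and non-linearly on GC content.
Normalization rescales each amplicon's read count by the ratio of the
overall median to the median of its 5%-wide GC band,

    r~_i = r_i * m / m_GC ,

computed within each sample, after which coverage can be related to
amplicon length (ordinary and broken-stick least squares), to GC (quadratic
regression, equal-frequency discretization + one-way ANOVA), and to
inter-sample uniformity (per-amplicon coefficient of variation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AmpliconDef

__all__ = [
    "CountMatrix",
    "RegressionResult",
    "gc_normalize",
    "length_coverage_regression",
    "broken_stick_regression",
    "polynomial_gc_regression",
    "equal_frequency_discretize",
    "anova_between_groups",
    "coverage_uniformity",
]


@dataclass(frozen=True)
class CountMatrix:
    """Amplicon x sample read counts with per-amplicon GC and length."""

    counts: pd.DataFrame          # index: amplicon names, columns: sample ids
    gc_fraction: pd.Series        # per amplicon, in [0, 1]
    length: pd.Series             # per amplicon, bp incl. primers

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for name, series in (("gc_fraction", self.gc_fraction), ("length", self.length)):
            if not series.index.equals(self.counts.index):
                raise ValueError(f"{name} index does not match counts index")
        if ((self.gc_fraction < 0) | (self.gc_fraction > 1)).any():
            raise ValueError("gc_fraction must lie in [0, 1]")

    @classmethod
    def from_panel(cls, counts: pd.DataFrame, panel: list[AmpliconDef]) -> "CountMatrix":
        meta = {a.name: (a.gc_fraction, a.length) for a in panel}
        missing = [n for n in counts.index if n not in meta]
        if missing:
            raise ValueError(f"amplicons absent from panel: {missing[:5]}")
        gc = pd.Series({n: meta[n][0] for n in counts.index}, name="gc_fraction")
        ln = pd.Series({n: meta[n][1] for n in counts.index}, name="length")
        return cls(counts, gc.loc[counts.index], ln.loc[counts.index])

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    stderr: float
    pvalue: float
    r_squared: float
    n: int


def _gc_bands(gc_fraction: pd.Series, band_width: float) -> np.ndarray:
    """Fixed-width GC bands anchored at 0%: band k covers
    ``[k*w, (k+1)*w)`` percent, with 100% folded into the top band."""
    n_bands = int(np.ceil(100.0 / band_width))
    band = np.floor(gc_fraction.to_numpy() * 100.0 / band_width).astype(int)
    return np.minimum(band, n_bands - 1)


def gc_normalize(matrix: CountMatrix, band_width: float = 5.0) -> CountMatrix:
    """GC-band median normalization, per sample.

    Within each sample, every amplicon count is scaled by
    ``m / m_GC``: the sample's overall median count over the median count
    of the amplicon's GC band. A band whose median is zero cannot be
    rescaled and is reported as an error.
    """
    if band_width <= 0 or band_width > 100:
        raise ValueError(f"band_width {band_width} out of (0, 100]")
    band = _gc_bands(matrix.gc_fraction, band_width)
    normalized = matrix.counts.copy().astype(float)
    for sample in matrix.counts.columns:
        col = matrix.counts[sample].to_numpy(dtype=float)
        m = np.median(col)
        scale = np.empty_like(col)
        for b in np.unique(band):
            in_band = band == b
            m_gc = np.median(col[in_band])
            if m_gc == 0:
                lo = b * band_width
                raise ValueError(
                    f"sample {sample}: GC band [{lo:g}%, {lo + band_width:g}%) "
                    "has zero median count"
                )
            scale[in_band] = m / m_gc
        normalized[sample] = col * scale
    return CountMatrix(normalized, matrix.gc_fraction, matrix.length)


def length_coverage_regression(
    lengths, coverage, max_length: float | None = None
) -> RegressionResult:
    """OLS of (normalized) mean coverage on amplicon length.

    When ``max_length`` is given the fit is restricted to amplicons no
    longer than that, which is how the tolerated amplicon-length range is
    probed. Returns slope, its standard error and the two-sided t-test
    p-value of the slope.
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(coverage, dtype=float)
    if max_length is not None:
        keep = x <= max_length
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 amplicons for regression, have {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all amplicon lengths identical; slope undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        pvalue=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
        n=int(x.size),
    )


def broken_stick_regression(
    lengths, coverage, breakpoint: float = 170.0
) -> dict[str, RegressionResult]:
    """Independent OLS fits below and above a fixed length breakpoint.

    Segment "below" covers lengths <= breakpoint, "above" the rest. An
    empty (or < 3 point) segment is an error. The default breakpoint of
    170 bp sits just above the mononucleosome fragment mode.
    """
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(coverage, dtype=float)
    below = x <= breakpoint
    out = {}
    for name, mask in (("below", below), ("above", ~below)):
        if mask.sum() < 3:
            raise ValueError(
                f"segment {name!r} of breakpoint {breakpoint} has only "
                f"{int(mask.sum())} point(s)"
            )
        out[name] = length_coverage_regression(x[mask], y[mask])
    return out


def polynomial_gc_regression(gc, y, degree: int = 2) -> tuple[np.ndarray, float]:
    """Least-squares polynomial of coverage (or its CV) on GC content.

    Returns ``(coefficients, r_squared)`` with coefficients highest order
    first; R^2 = 1 - SSE/SST.
    """
    gc = np.asarray(gc, dtype=float)
    y = np.asarray(y, dtype=float)
    if gc.size < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for degree {degree}")
    if np.unique(gc).size <= degree:
        raise ValueError("degenerate design: too few distinct GC values")
    coeffs = np.polyfit(gc, y, degree)
    fitted = np.polyval(coeffs, gc)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return coeffs, r2


def equal_frequency_discretize(values, k: int) -> np.ndarray:
    """Split values into ``k`` equal-frequency groups (labels 0..k-1).

    Group sizes differ by at most one when values are distinct. Tied
    values are always assigned to the lower group of any tie-spanning
    boundary, deterministically; if the ties collapse a group to empty the
    split is impossible and an error is raised.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"cannot form {k} groups from {n} values")
    order = np.argsort(vals, kind="stable")
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) * k // n
    # ties span group boundaries: pull every occurrence down to the lowest
    # label seen for that value
    for v in np.unique(vals):
        mask = vals == v
        labels[mask] = labels[mask].min()
    if np.unique(labels).size < k:
        raise ValueError(f"ties prevent {k} non-empty equal-frequency groups")
    return labels


def anova_between_groups(y, labels) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of ``y`` between label groups.

    Returns ``(F, p)``. Every group must have at least two members.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    groups = [y[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [g.size for g in groups if g.size < 2]
    if small:
        raise ValueError("every group needs >= 2 members")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def coverage_uniformity(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-amplicon coefficient of inter-sample variation of read counts.

    CV_i = (n-1)-denominator sample sd / mean across samples. Amplicons
    with zero mean have undefined CV and are flagged as NaN.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if counts.shape[1] < 2:
        raise ValueError("uniformity needs >= 2 samples")
    mean = counts.mean(axis=1)
    sd = counts.std(axis=1, ddof=1)
    cv = sd / mean
    cv[mean == 0] = np.nan
    cv.name = "uniformity_cv"
    return cv
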