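"""Variant filtering/classification, paired allele-frequency statistics
between two amplicon panels, fragment-length enrichment ratios and a
Poisson screen for low-frequency hotspot mutations.

The rules encoded here govern which variant calls enter a panel
comparison: read-support filters (>= 20 total reads, >= 4 alternative
reads), then classification into confidently somatic (COSMIC hotspot, seen
in >= 10 samples) or confidently germline (population MAF >= 5%); anything
else is excluded. Allele frequencies of shared loci are compared across
panels by Wilcoxon signed-rank, Pearson correlation, and the geometric
mean ratio with a log-scale t interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "VariantObservation",
    "LengthDistribution",
    "BootstrapAF",
    "classify_variant",
    "apply_read_filters",
    "allele_frequency",
    "bootstrap_af_normalize",
    "paired_af_comparison",
    "geometric_mean_ratio",
    "enrichment_ratio",
    "poisson_hotspot_screen",
    "DEFAULT_ERROR_MULTIPLIERS",
]

COSMIC_HOTSPOT_MIN = 10     # variant seen in >= this many COSMIC samples
GERMLINE_MAF_MIN = 0.05     # population MAF at/above this => germline
MIN_TOTAL_READS = 20
MIN_ALT_READS = 4


@dataclass(frozen=True)
class VariantObservation:
    """One variant call on one panel, with the annotations the filter and
    classification rules need."""

    locus_id: str
    panel_id: str
    total_reads: int
    alt_reads: int
    cosmic_sample_count: int = 0
    population_maf: float = 0.0
    variant_class: str = "SNV"          # "SNV" | "indel"
    context_complexity: int = 1         # homopolymer run length at the site, bp

    def __post_init__(self) -> None:
        if self.total_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.total_reads:
            raise ValueError("alt_reads cannot exceed total_reads")
        if not 0.0 <= self.population_maf <= 1.0:
            raise ValueError("population_maf must lie in [0, 1]")
        if self.variant_class not in ("SNV", "indel"):
            raise ValueError(f"variant_class must be SNV or indel, got {self.variant_class!r}")


def classify_variant(v: VariantObservation) -> str:
    """'confidently_somatic' (COSMIC hotspot), 'confidently_germline'
    (common in the population) or 'unclassified' (excluded downstream)."""
    if v.cosmic_sample_count >= COSMIC_HOTSPOT_MIN:
        return "confidently_somatic"
    if v.population_maf >= GERMLINE_MAF_MIN:
        return "confidently_germline"
    return "unclassified"


def apply_read_filters(v: VariantObservation) -> tuple[bool, str | None]:
    """Read-support filter: ``(True, None)`` to keep, otherwise
    ``(False, 'low_total'|'low_alt')``."""
    if v.total_reads < MIN_TOTAL_READS:
        return False, "low_total"
    if v.alt_reads < MIN_ALT_READS:
        return False, "low_alt"
    return True, None


def allele_frequency(v: VariantObservation) -> float:
    """Variant allele frequency: alt reads over total qualified reads."""
    if v.total_reads < 1:
        raise ValueError("allele frequency undefined without reads")
    return v.alt_reads / v.total_reads


@dataclass(frozen=True)
class BootstrapAF:
    mean: float
    ci_low: float
    ci_high: float
    target_depth: int
    n_boot: int


def bootstrap_af_normalize(
    alt_reads: int,
    total_reads: int,
    target_depth: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapAF:
    """Normalize an allele frequency to a common coverage by bootstrap.

    Resamples ``target_depth`` reads with replacement from the observed
    pool of ``alt_reads`` mutant + ``total_reads - alt_reads`` wild-type
    reads (equivalently Binomial(target_depth, AF)) ``n_boot`` times;
    reports the mean resampled AF and its 2.5/97.5 percentile interval.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("alt_reads out of range")
    if target_depth < 1:
        raise ValueError("target_depth must be >= 1")
    rng = np.random.default_rng(seed)
    af = alt_reads / total_reads
    draws = rng.binomial(target_depth, af, size=n_boot) / target_depth
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return BootstrapAF(float(draws.mean()), float(lo), float(hi), target_depth, n_boot)


@dataclass(frozen=True)
class PairedComparison:
    wilcoxon_p: float
    pearson_r: float
    pearson_p: float
    n: int


def paired_af_comparison(af_pairs) -> PairedComparison:
    """Compare allele frequencies of the same loci measured by two panels.

    Two-sided Wilcoxon signed-rank on the paired differences (zero
    differences dropped; exact null for <= 25 non-zero untied pairs,
    normal approximation otherwise) plus Pearson correlation with its
    t-based p-value. All-zero differences give Wilcoxon p = 1 with a
    warning; Pearson is an error when either margin is constant.
    """
    pairs = np.asarray(af_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (af_panel1, af_panel2) pairs")
    a, b = pairs[:, 0], pairs[:, 1]
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; Wilcoxon p set to 1")
        wilcoxon_p = 1.0
    else:
        has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
        method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
        wilcoxon_p = float(
            sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method).pvalue
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for constant allele frequencies")
    r, p = sps.pearsonr(a, b)
    return PairedComparison(wilcoxon_p, float(r), float(p), pairs.shape[0])


def geometric_mean_ratio(af_pairs) -> tuple[float, float, float]:
    """Geometric mean of panel1/panel2 AF ratios with a 95% t interval on
    the log scale. All frequencies must be positive."""
    pairs = np.asarray(af_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 pairs")
    if np.any(pairs <= 0):
        raise ValueError("geometric mean ratio requires positive allele frequencies")
    logr = np.log(pairs[:, 0] / pairs[:, 1])
    n = logr.size
    mean = logr.mean()
    sd = logr.std(ddof=1)
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return float(np.exp(mean)), float(np.exp(mean - half)), float(np.exp(mean + half))


@dataclass(frozen=True)
class LengthDistribution:
    """Discrete fragment-length distribution (support in bp, probability
    mass summing to 1)."""

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        sup = np.asarray(self.support, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", sup)
        object.__setattr__(self, "mass", mass)
        if sup.shape != mass.shape or sup.ndim != 1 or sup.size == 0:
            raise ValueError("support and mass must be matching non-empty 1-D arrays")
        if np.any(sup <= 0):
            raise ValueError("fragment lengths must be positive")
        if np.any(mass < 0) or not np.isclose(mass.sum(), 1.0, atol=1e-9):
            raise ValueError("mass must be non-negative and sum to 1")

    @classmethod
    def from_lengths(cls, lengths) -> "LengthDistribution":
        values, counts = np.unique(np.asarray(lengths), return_counts=True)
        return cls(values.astype(float), counts / counts.sum())

    def sf(self, x: float) -> float:
        """P(L >= x)."""
        return float(self.mass[self.support >= x].sum())


def _tail(dist, x: float) -> float:
    """P(L >= x) for a LengthDistribution or any scipy-like frozen
    distribution exposing ``sf`` (continuous: P(L > x) == P(L >= x))."""
    if isinstance(dist, LengthDistribution):
        return dist.sf(x)
    return float(dist.sf(x))


def enrichment_ratio(dist, amplicon_len: int, deletion_len: int) -> float:
    """Expected mutant:wild-type amplification efficiency ratio.

    A deletion of ``deletion_len`` bp shortens the template an amplicon of
    ``amplicon_len`` bp needs, so more cfDNA fragments are long enough to
    serve as template for the mutant allele. The ratio of the two tail
    masses of the fragment-length distribution,

        P(L >= amplicon_len - deletion_len) / P(L >= amplicon_len),

    is the factor by which mutant alleles out-amplify wild-type ones.
    Always >= 1; exactly 1 when ``deletion_len == 0``.
    """
    if deletion_len < 0 or amplicon_len <= deletion_len:
        raise ValueError("require amplicon_len > deletion_len >= 0")
    denom = _tail(dist, amplicon_len)
    if denom == 0:
        raise ValueError(
            f"no fragments reach {amplicon_len} bp; wild-type allele cannot amplify"
        )
    if deletion_len == 0:
        return 1.0
    return _tail(dist, amplicon_len - deletion_len) / denom


# error-rate multiplier per extra homopolymer base beyond 3, capped, and a
# penalty for indels (sequencing chemistry slips in homopolymer runs)
DEFAULT_ERROR_MULTIPLIERS = {
    "homopolymer_base": 2.0,
    "homopolymer_start": 3,
    "homopolymer_cap": 16.0,
    "indel_factor": 4.0,
}


def poisson_hotspot_screen(
    total_reads: int,
    alt_reads: int,
    base_error: float,
    context_complexity: int = 1,
    variant_class: str = "SNV",
    multipliers: dict | None = None,
) -> float:
    """Poisson upper-tail p-value that ``alt_reads`` arose from sequencing
    error alone.

    The per-read error probability is ``base_error`` scaled by a
    complexity multiplier that doubles for every homopolymer base beyond
    3 (capped at 16x) and is 4x larger for indels; the expected error
    count is ``lambda = total_reads * e`` and
    ``p = P(Poisson(lambda) >= alt_reads)``.
    """
    if not 0.0 < base_error < 1.0:
        raise ValueError("base_error must lie in (0, 1)")
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if variant_class not in ("SNV", "indel"):
        raise ValueError(f"variant_class must be SNV or indel, got {variant_class!r}")
    m = dict(DEFAULT_ERROR_MULTIPLIERS)
    if multipliers:
        m.update(multipliers)
    extra = max(0, context_complexity - m["homopolymer_start"])
    mult = min(m["homopolymer_base"] ** extra, m["homopolymer_cap"])
    if variant_class == "indel":
        mult *= m["indel_factor"]
    rate = min(base_error * mult, 1.0)
    lam = total_reads * rate
    return float(sps.poisson.sf(alt_reads - 1, lam))
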