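"""Synthetic cfDNA data with known ground truth.

Plasma cfDNA is released mostly by apoptotic cells whose genome is cut by
nucleases between nucleosomes, so fragment lengths pile up at the
mononucleosome size (~167 bp) with a minor dinucleosome mode (~350 bp), and
fragment midpoints concentrate at nucleosome dyads. This module generates

* a nucleosome landscape (dyad positions with occupancy weights and
  positional spread) over a synthetic contig,
* cfDNA fragment populations coupled to that landscape,
* amplicon panels, and
* per-sample amplicon read-count matrices whose mean depth depends on GC
  content and on template availability, and whose inter-sample variability
  is driven by nucleosome-occupancy instability,

all deterministically reproducible from a seed, so every downstream stage
of the pipeline can be exercised against a known generative truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import AmpliconDef, FragmentRecord

__all__ = [
    "NucleosomeLandscape",
    "SimulationConfig",
    "generate_nucleosome_landscape",
    "sample_fragments",
    "generate_amplicon_panel",
    "simulate_amplicon_counts",
]


@dataclass(frozen=True)
class NucleosomeLandscape:
    """Dyad positions along one synthetic contig.

    ``occupancy_weight`` is the fraction of cells in which the nucleosome is
    present at this dyad (stably positioned nucleosomes have weights near 1);
    ``positional_sd`` is the cell-to-cell standard deviation of the dyad
    position in bp (sharply positioned nucleosomes have small spread).
    """

    contig_name: str
    contig_length: int
    positions: np.ndarray        # int, strictly increasing
    occupancy_weight: np.ndarray  # float in [0, 1]
    positional_sd: np.ndarray     # float, >= 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        occ = np.asarray(self.occupancy_weight, dtype=float)
        psd = np.asarray(self.positional_sd, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "occupancy_weight", occ)
        object.__setattr__(self, "positional_sd", psd)
        if not (len(pos) == len(occ) == len(psd)):
            raise ValueError("dyad arrays must have equal length")
        if len(pos) and (np.any(np.diff(pos) <= 0)):
            raise ValueError("dyad positions must be strictly increasing")
        if len(pos) and (pos[0] < 0 or pos[-1] >= self.contig_length):
            raise ValueError("dyad positions must lie within the contig")
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancy weights must lie in [0, 1]")
        if np.any(psd < 0):
            raise ValueError("positional sd must be non-negative")

    @property
    def n_dyads(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Defaults encode the canonical plasma picture: ~85% of fragments in a
    mononucleosome mode at 167 bp, the remainder in a dinucleosome mode at
    350 bp. ``tumor_mode_shift`` (bp, subtracted from the mono mode) models
    the known shortening of tumor-derived fragments and is off by default.
    ``gc_bias_coefficients`` are the (a2, a1, a0) of the quadratic
    ``a2*gc**2 + a1*gc + a0`` multiplying expected amplicon depth;
    ``occupancy_noise_sd`` scales the per-sample log-normal depth noise
    attached to nucleosome instability.
    """

    n_fragments: int = 50_000
    mono_fraction: float = 0.85
    mono_length_mode: float = 167.0
    mono_length_sd: float = 20.0
    di_length_mode: float = 350.0
    di_length_sd: float = 35.0
    dyad_protection_halfwidth: int = 73
    tumor_mode_shift: float = 0.0
    seed: int = 0
    n_samples: int = 10
    gc_bias_coefficients: tuple[float, float, float] = (-6.0, 6.0, -0.5)
    occupancy_noise_sd: float = 0.5
    gc_cv_coefficient: float = 1.0
    baseline_depth: float = 2000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mono_fraction <= 1.0:
            raise ValueError(f"mono_fraction {self.mono_fraction} not in [0, 1]")
        if self.n_fragments < 0 or self.n_samples < 1:
            raise ValueError("counts must be non-negative / positive")
        for name in ("mono_length_mode", "mono_length_sd", "di_length_mode", "di_length_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.occupancy_noise_sd < 0:
            raise ValueError("occupancy_noise_sd must be non-negative")


def generate_nucleosome_landscape(
    contig_length: int,
    mean_spacing: int = 190,
    spacing_jitter_sd: float = 20.0,
    occupancy_range: tuple[float, float] = (0.1, 0.9),
    seed: int = 0,
    positional_sd_range: tuple[float, float] = (5.0, 25.0),
    contig_name: str = "sim1",
) -> NucleosomeLandscape:
    """Lay down dyads at roughly regular spacing along a synthetic contig.

    Dyads start at ``mean_spacing // 2`` and repeat every ``mean_spacing``
    bp, each displaced by Gaussian jitter of sd ``spacing_jitter_sd``.
    Occupancy weights and positional spreads are drawn uniformly from their
    ranges. Deterministic given ``seed``.
    """
    if contig_length <= 0 or mean_spacing <= 0:
        raise ValueError("contig_length and mean_spacing must be positive")
    if mean_spacing >= contig_length:
        raise ValueError("mean_spacing must be smaller than contig_length")
    if spacing_jitter_sd < 0:
        raise ValueError("spacing_jitter_sd must be non-negative")
    lo, hi = occupancy_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"occupancy_range {occupancy_range} not within [0, 1]")

    rng = np.random.default_rng(seed)
    base = np.arange(mean_spacing // 2, contig_length, mean_spacing, dtype=float)
    if spacing_jitter_sd > 0:
        base = base + rng.normal(0.0, spacing_jitter_sd, size=base.size)
    pos = np.unique(np.clip(np.rint(base), 0, contig_length - 1).astype(np.int64))
    occ = rng.uniform(lo, hi, size=pos.size)
    psd = rng.uniform(positional_sd_range[0], positional_sd_range[1], size=pos.size)
    return NucleosomeLandscape(contig_name, contig_length, pos, occ, psd)


def sample_fragments(
    landscape: NucleosomeLandscape,
    cfg: SimulationConfig,
    sample_id: str = "pooled",
    seed: int | None = None,
) -> list[FragmentRecord]:
    """Draw cfDNA fragments coupled to the nucleosome landscape.

    Mononucleosome fragments are centered on a single dyad (chosen
    proportionally to occupancy weight, center jittered by that dyad's
    positional sd); dinucleosome fragments are centered between two
    adjacent dyads. Lengths are discretized normals truncated at 1 bp.
    Fragments extending past the contig ends are discarded.
    """
    if landscape.n_dyads == 0:
        raise ValueError("landscape has no dyads")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_fragments
    if n == 0:
        return []

    is_mono = rng.random(n) < cfg.mono_fraction
    n_mono = int(is_mono.sum())
    n_di = n - n_mono

    centers = np.empty(n, dtype=float)
    lengths = np.empty(n, dtype=float)

    weights = landscape.occupancy_weight.astype(float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    p_dyad = weights / weights.sum()

    if n_mono:
        idx = rng.choice(landscape.n_dyads, size=n_mono, p=p_dyad)
        centers[is_mono] = landscape.positions[idx] + rng.normal(
            0.0, 1.0, n_mono
        ) * landscape.positional_sd[idx]
        mode = cfg.mono_length_mode - cfg.tumor_mode_shift
        lengths[is_mono] = rng.normal(mode, cfg.mono_length_sd, n_mono)
    if n_di:
        if landscape.n_dyads >= 2:
            pair_w = weights[:-1] + weights[1:]
            pair_p = pair_w / pair_w.sum()
            idx = rng.choice(landscape.n_dyads - 1, size=n_di, p=pair_p)
            mid = (landscape.positions[idx] + landscape.positions[idx + 1]) / 2.0
            sd = (landscape.positional_sd[idx] + landscape.positional_sd[idx + 1]) / 2.0
        else:
            idx = np.zeros(n_di, dtype=int)
            mid = landscape.positions[idx].astype(float)
            sd = landscape.positional_sd[idx]
        centers[~is_mono] = mid + rng.normal(0.0, 1.0, n_di) * sd
        lengths[~is_mono] = rng.normal(cfg.di_length_mode, cfg.di_length_sd, n_di)

    lengths = np.maximum(np.rint(lengths), 1).astype(np.int64)
    starts = np.rint(centers - lengths / 2.0).astype(np.int64)
    ends = starts + lengths
    keep = (starts >= 0) & (ends <= landscape.contig_length)
    contig = landscape.contig_name
    return [
        FragmentRecord(contig, int(s), int(e), sample_id)
        for s, e in zip(starts[keep], ends[keep])
    ]


def generate_amplicon_panel(
    landscape: NucleosomeLandscape,
    n_amplicons: int,
    length_range: tuple[int, int] = (100, 200),
    gc_range: tuple[float, float] = (0.25, 0.75),
    primer_len_range: tuple[int, int] = (18, 27),
    seed: int = 0,
    fixed_length: int | None = None,
) -> list[AmpliconDef]:
    """Place amplicons uniformly along the contig.

    Lengths are uniform over ``length_range`` (or all ``fixed_length`` when
    given), GC fractions uniform over ``gc_range`` and independent of both
    length and position. Amplicons are returned sorted by start.
    """
    if n_amplicons < 1:
        raise ValueError("n_amplicons must be >= 1")
    rng = np.random.default_rng(seed)
    if fixed_length is not None:
        lengths = np.full(n_amplicons, fixed_length, dtype=np.int64)
    else:
        lengths = rng.integers(length_range[0], length_range[1] + 1, n_amplicons)
    margin = int(lengths.max())
    if landscape.contig_length <= margin:
        raise ValueError("contig too short for requested amplicon lengths")
    starts = rng.integers(0, landscape.contig_length - margin, n_amplicons)
    gcs = rng.uniform(gc_range[0], gc_range[1], n_amplicons)
    fwd = rng.integers(primer_len_range[0], primer_len_range[1] + 1, n_amplicons)
    rev = rng.integers(primer_len_range[0], primer_len_range[1] + 1, n_amplicons)
    order = np.argsort(starts, kind="stable")
    return [
        AmpliconDef(
            contig=landscape.contig_name,
            outer_start=int(starts[i]),
            outer_end=int(starts[i] + lengths[i]),
            name=f"amp_{k:04d}",
            fwd_primer_len=int(fwd[i]),
            rev_primer_len=int(rev[i]),
            gc_fraction=float(gcs[i]),
        )
        for k, i in enumerate(order)
    ]


def _length_survival(x: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """P(fragment length >= x) under the mono/di mixture."""
    mono = norm.sf(x, loc=cfg.mono_length_mode - cfg.tumor_mode_shift, scale=cfg.mono_length_sd)
    di = norm.sf(x, loc=cfg.di_length_mode, scale=cfg.di_length_sd)
    return cfg.mono_fraction * mono + (1.0 - cfg.mono_fraction) * di


def template_availability(lengths: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Spanning-template availability factor as a function of amplicon length.

    Amplification saturates while amplicons are no longer than the typical
    (modal) cfDNA fragment — template is not limiting — and declines with
    the survival of the fragment-length mixture once the amplicon outgrows
    the mononucleosome mode:

        A(len) = min(1, S(len) / S(mono_mode)),   S(x) = P(L >= x).
    """
    lengths = np.asarray(lengths, dtype=float)
    s_mode = _length_survival(
        np.array([cfg.mono_length_mode - cfg.tumor_mode_shift]), cfg
    )[0]
    return np.minimum(1.0, _length_survival(lengths, cfg) / s_mode)


def _amplicon_stability(
    panel: list[AmpliconDef], landscape: NucleosomeLandscape, halfwidth: int
) -> np.ndarray:
    """Mean occupancy weight of dyads whose protected interval overlaps each
    amplicon; the nearest dyad when none overlaps."""
    pos = landscape.positions
    occ = landscape.occupancy_weight
    out = np.empty(len(panel))
    for i, amp in enumerate(panel):
        lo = np.searchsorted(pos, amp.outer_start - halfwidth, side="left")
        hi = np.searchsorted(pos, amp.outer_end + halfwidth, side="right")
        if hi > lo:
            out[i] = occ[lo:hi].mean()
        else:
            center = (amp.outer_start + amp.outer_end) // 2
            j = np.clip(np.searchsorted(pos, center), 0, len(pos) - 1)
            j = j if abs(pos[j] - center) <= abs(pos[max(j - 1, 0)] - center) else j - 1
            out[i] = occ[j]
    return out


def simulate_amplicon_counts(
    panel: list[AmpliconDef],
    landscape: NucleosomeLandscape,
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample amplicon count matrix plus the generative ground truth.

    Expected count per amplicon is

        baseline_depth * gc_factor(gc) * availability(length),

    with the GC factor a quadratic in GC fraction (floored at 0.05) and the
    availability factor from :func:`template_availability`. Per-sample
    counts multiply the expectation by mean-one log-normal noise whose log-sd

        s_i = occupancy_noise_sd * ((1 - stability_i)
                                    + gc_cv_coefficient * |gc_i - 0.5|)

    ties inter-sample variability to nucleosome-occupancy instability
    (1 - stability of overlapping dyads) and, more weakly, to extreme GC.

    Returns ``(counts, truth)``: counts indexed by amplicon name with one
    column per sample; truth holds gc, length, gc_factor, availability,
    stability, instability, noise log-sd, expected count and the analytic
    CV ``sqrt(exp(s^2) - 1)`` per amplicon.
    """
    if not panel:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(cfg.seed)

    gc = np.array([a.gc_fraction for a in panel])
    lengths = np.array([a.length for a in panel], dtype=float)
    a2, a1, a0 = cfg.gc_bias_coefficients
    gc_factor = np.maximum(a2 * gc**2 + a1 * gc + a0, 0.05)
    avail = template_availability(lengths, cfg)
    stability = _amplicon_stability(panel, landscape, cfg.dyad_protection_halfwidth)
    s = cfg.occupancy_noise_sd * (
        (1.0 - stability) + cfg.gc_cv_coefficient * np.abs(gc - 0.5)
    )
    expected = cfg.baseline_depth * gc_factor * avail

    z = rng.normal(0.0, 1.0, size=(len(panel), cfg.n_samples))
    # exp(s*z - s^2/2) has mean exactly 1, so instability perturbs only the
    # spread of counts across samples, never their expectation.
    noise = np.exp(s[:, None] * z - 0.5 * s[:, None] ** 2)
    counts = expected[:, None] * noise

    names = [a.name for a in panel]
    samples = [f"S{j:02d}" for j in range(cfg.n_samples)]
    counts_df = pd.DataFrame(counts, index=pd.Index(names, name="amplicon"), columns=samples)
    truth = pd.DataFrame(
        {
            "gc": gc,
            "length": lengths.astype(int),
            "gc_factor": gc_factor,
            "availability": avail,
            "stability": stability,
            "instability": 1.0 - stability,
            "noise_log_sd": s,
            "expected_count": expected,
            "true_cv": np.sqrt(np.expm1(s**2)),
        },
        index=pd.Index(names, name="amplicon"),
    )
    return counts_df, truth
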