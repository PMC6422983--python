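"""Per-amplicon cfDNA fragmentation features.

Four descriptors summarize how the fragmentation signal of plasma cfDNA
maps onto an amplicon:

* **Feature A** — spanning-fragment count: how many observed cfDNA
  molecules fully contain the amplicon (both primer sites included), i.e.
  how much amplifiable template exists;
* **Feature B** — depth range: amplitude (max - min) of the smoothed
  fragmentation signal within the amplicon;
* **Feature C** — depth change: absolute difference of the signal between
  the two amplicon boundaries;
* **Feature D** — depth shape: total absolute area between the signal and
  the straight line joining its values at the amplicon boundaries.

A is computed on length-filtered full fragments (a 40 bp dyad-trimmed
fragment cannot span an amplicon); B-D are computed on the smoothed
dyad-trimmed coverage track produced by :mod:`nucleoamp.fragmap`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AmpliconDef, FragmentRecord
from .fragmap import CoverageTrack, build_fragmentation_track, filter_by_length

__all__ = [
    "spanning_fragment_count",
    "depth_range",
    "depth_change",
    "depth_shape",
    "compute_feature_table",
    "feature_robustness",
]

FEATURE_COLUMNS = ("feature_a", "feature_b", "feature_c", "feature_d")


def spanning_fragment_count(amplicon: AmpliconDef, fragments) -> int:
    """Feature A: fragments whose span contains the whole amplicon.

    A fragment qualifies when ``start <= outer_start`` and
    ``end >= outer_end`` on the amplicon's contig, i.e. both primers could
    anneal to the intact molecule.
    """
    return sum(
        1
        for f in fragments
        if f.contig == amplicon.contig
        and f.start <= amplicon.outer_start
        and f.end >= amplicon.outer_end
    )


def depth_range(track: CoverageTrack, amplicon: AmpliconDef) -> float:
    """Feature B: max - min of the signal over the amplicon interval."""
    seg = track.segment(amplicon.outer_start, amplicon.outer_end)
    return float(seg.max() - seg.min())


def depth_change(track: CoverageTrack, amplicon: AmpliconDef) -> float:
    """Feature C: absolute signal change between the amplicon boundaries,
    ``|signal[outer_end - 1] - signal[outer_start]|``."""
    seg = track.segment(amplicon.outer_start, amplicon.outer_end)
    return float(abs(seg[-1] - seg[0]))


def depth_shape(
    track: CoverageTrack, amplicon: AmpliconDef, normalize: bool = False
) -> float:
    """Feature D: area between the signal and its linear approximation.

    The line joins the signal values at ``outer_start`` and
    ``outer_end - 1``; the feature is the per-position sum of absolute
    deviations (optionally divided by the amplicon length).
    """
    if amplicon.length < 2:
        raise ValueError(f"{amplicon.name}: need >= 2 bp for a linear approximation")
    seg = track.segment(amplicon.outer_start, amplicon.outer_end)
    line = np.linspace(seg[0], seg[-1], len(seg))
    area = float(np.abs(seg - line).sum())
    return area / len(seg) if normalize else area


def compute_feature_table(
    fragments_by_sample: dict[str, list[FragmentRecord]],
    panel: list[AmpliconDef],
    min_len: int = 80,
    max_len: int = 250,
    trim_window: int = 40,
    kernel_width: int = 21,
    margin: int = 200,
) -> pd.DataFrame:
    """Features A-D + GC for every amplicon in every sample.

    Each sample's fragments go through the standard chain (length filter,
    dyad trim, overlap counts, square-pulse smoothing) over a region
    padded by ``margin`` bp around the panel; Feature A uses the
    length-filtered, untrimmed fragments. Returns a tidy frame with
    columns amplicon, sample, feature_a..feature_d, gc.
    """
    if not panel:
        raise ValueError("panel is empty")
    lo = min(a.outer_start for a in panel) - margin
    hi = max(a.outer_end for a in panel) + margin
    lo = max(lo, 0)
    rows = []
    for sample, fragments in fragments_by_sample.items():
        kept = filter_by_length(fragments, min_len, max_len)
        track = build_fragmentation_track(
            kept, lo, hi, min_len=min_len, max_len=max_len,
            trim_window=trim_window, kernel_width=kernel_width,
        )
        for amp in panel:
            rows.append(
                {
                    "amplicon": amp.name,
                    "sample": sample,
                    "feature_a": spanning_fragment_count(amp, kept),
                    "feature_b": depth_range(track, amp),
                    "feature_c": depth_change(track, amp),
                    "feature_d": depth_shape(track, amp),
                    "gc": amp.gc_fraction,
                }
            )
    return pd.DataFrame(rows)


def feature_robustness(
    table: pd.DataFrame, features=FEATURE_COLUMNS
) -> tuple[pd.Series, pd.Series]:
    """Cross-sample robustness of each feature.

    For each feature: the coefficient of variation (sample sd over mean)
    across samples is computed per amplicon, then averaged over amplicons.
    Amplicons whose mean feature value is zero carry an undefined CV; they
    are skipped and counted.

    Returns ``(mean_cv, n_skipped)`` indexed by feature name.
    """
    n_samples = table["sample"].nunique()
    if n_samples < 2:
        raise ValueError("feature robustness needs >= 2 samples")
    mean_cv, skipped = {}, {}
    for feat in features:
        wide = table.pivot(index="amplicon", columns="sample", values=feat)
        mean = wide.mean(axis=1)
        sd = wide.std(axis=1, ddof=1)
        valid = mean != 0
        skipped[feat] = int((~valid).sum())
        mean_cv[feat] = float((sd[valid] / mean[valid]).mean())
    return pd.Series(mean_cv), pd.Series(skipped)
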