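"""Shared domain records for cfDNA fragmentomics.

All genomic coordinates in this package are 0-based, half-open
(BED convention): a fragment ``[start, end)`` covers positions
``start .. end - 1`` and has length ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One sequenced cfDNA molecule, represented by its outer genomic span.

    For paired-end data the fragment is the interval from the leftmost
    aligned base of either read to the rightmost, so the record stands for
    the original plasma DNA molecule rather than a single read.
    """

    contig: str
    start: int
    end: int
    sample_id: str = "pooled"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Proxy for the nucleosome dyad: floor of the fragment center."""
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class AmpliconDef:
    """One amplicon of a PCR panel.

    ``outer_start``/``outer_end`` delimit the amplified product *including*
    both primer footprints; the insert is what remains after removing
    ``fwd_primer_len`` and ``rev_primer_len``. ``gc_fraction`` is the GC
    content of the amplified interval in [0, 1].
    """

    contig: str
    outer_start: int
    outer_end: int
    name: str
    fwd_primer_len: int = 20
    rev_primer_len: int = 20
    gc_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.outer_start < 0 or self.outer_end <= self.outer_start:
            raise ValueError(
                f"{self.name}: invalid interval [{self.outer_start}, {self.outer_end})"
            )
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise ValueError(f"{self.name}: negative primer length")
        if self.length <= self.fwd_primer_len + self.rev_primer_len:
            raise ValueError(
                f"{self.name}: amplicon of {self.length} bp leaves no insert "
                f"after {self.fwd_primer_len}+{self.rev_primer_len} bp primers"
            )
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"{self.name}: gc_fraction {self.gc_fraction} not in [0, 1]")

    @property
    def length(self) -> int:
        """Amplicon length including primers."""
        return self.outer_end - self.outer_start

    @property
    def insert_start(self) -> int:
        return self.outer_start + self.fwd_primer_len

    @property
    def insert_end(self) -> int:
        return self.outer_end - self.rev_primer_len
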