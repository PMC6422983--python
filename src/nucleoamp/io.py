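"""Plain-text readers and writers for fragments, panels, counts and tracks.

On-disk conventions follow BED: 0-based half-open intervals, tab-separated
columns, no header for interval files. All readers report the offending
line number on malformed input. Round trips are lossless for the fields the
in-memory records carry.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .core import AmpliconDef, FragmentRecord

PANEL_COLUMNS = (
    "contig",
    "outer_start",
    "outer_end",
    "name",
    "fwd_primer_len",
    "rev_primer_len",
    "gc_fraction",
)


class ParseError(ValueError):
    """Malformed line in a tabular input file."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}, line {lineno}: {message}")
        self.lineno = lineno


def write_fragments(path, fragments: Iterable[FragmentRecord], format: str = "bed") -> None:
    """Write fragments as 3-column BED + sample id, or as BEDPE.

    In BEDPE the two records are the fragment's outermost 101 bp read
    alignments (shorter when the fragment itself is shorter); the name
    column carries the sample id, so the outer span round-trips exactly.
    """
    if format not in ("bed", "bedpe"):
        raise ValueError(f"unknown fragment format {format!r}")
    with open(path, "w") as fh:
        for f in fragments:
            if format == "bed":
                fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.sample_id}\n")
            else:
                r1_end = min(f.start + 101, f.end)
                r2_start = max(f.end - 101, f.start)
                fh.write(
                    f"{f.contig}\t{f.start}\t{r1_end}\t"
                    f"{f.contig}\t{r2_start}\t{f.end}\t{f.sample_id}\t.\t+\t-\n"
                )


def read_fragments(path, format: str | None = None) -> list[FragmentRecord]:
    """Read fragments from BED(+sample) or BEDPE; format inferred from the
    ``.bedpe`` extension when not given. Empty files yield an empty list."""
    if format is None:
        format = "bedpe" if str(path).endswith(".bedpe") else "bed"
    if format not in ("bed", "bedpe"):
        raise ValueError(f"unknown fragment format {format!r}")
    out: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    if len(fields) < 3:
                        raise ValueError(f"expected >= 3 columns, got {len(fields)}")
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    sample = fields[3] if len(fields) > 3 else "pooled"
                else:
                    if len(fields) < 6:
                        raise ValueError(f"expected >= 6 columns, got {len(fields)}")
                    c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                    c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
                    if c1 != c2:
                        raise ValueError(f"read pair on different contigs {c1}/{c2}")
                    contig, start, end = c1, min(s1, s2), max(e1, e2)
                    sample = fields[6] if len(fields) > 6 else "pooled"
                out.append(FragmentRecord(contig, start, end, sample))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def read_fragments_bam(path, sample_id: str | None = None,
                       min_mapq: int = 20) -> list[FragmentRecord]:
    """Extract fragment outer spans from a coordinate-accessible BAM/SAM.

    Uses only primary, properly paired alignments; each pair is counted
    once via its leftmost read (positive template length), so paired reads
    continue to represent the original molecules.
    """
    import pysam

    sample = sample_id if sample_id is not None else os.path.basename(str(path)).split(".")[0]
    out: list[FragmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or not aln.is_proper_pair
                or aln.mapping_quality < min_mapq
                or aln.template_length <= 0
            ):
                continue
            start = aln.reference_start
            out.append(
                FragmentRecord(aln.reference_name, start, start + aln.template_length, sample)
            )
    return out


def write_panel(path, panel: Sequence[AmpliconDef]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for a in panel:
            fh.write(
                f"{a.contig}\t{a.outer_start}\t{a.outer_end}\t{a.name}\t"
                f"{a.fwd_primer_len}\t{a.rev_primer_len}\t{a.gc_fraction!r}\n"
            )


def read_panel(path) -> list[AmpliconDef]:
    out: list[AmpliconDef] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "contig":
                continue
            try:
                if len(fields) < 7:
                    raise ValueError(f"expected 7 columns, got {len(fields)}")
                out.append(
                    AmpliconDef(
                        contig=fields[0],
                        outer_start=int(fields[1]),
                        outer_end=int(fields[2]),
                        name=fields[3],
                        fwd_primer_len=int(fields[4]),
                        rev_primer_len=int(fields[5]),
                        gc_fraction=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return out


def write_counts(path, counts: pd.DataFrame) -> None:
    """Counts matrix: rows = amplicon names, columns = sample ids, TSV."""
    counts.to_csv(path, sep="\t", index_label="amplicon")


def read_counts(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in count matrix")
    return df


def write_bedgraph(path, track) -> None:
    """Write a CoverageTrack as bedGraph, merging runs of equal value."""
    values = track.values
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                fh.write(
                    f"{track.contig}\t{track.origin + run_start}\t"
                    f"{track.origin + i}\t{values[run_start]:.6g}\n"
                )
                run_start = i


def write_nucleosome_map(path, nmap) -> None:
    """NucleosomeMap as BED intervals of 1 bp with stringency in the score
    column."""
    with open(path, "w") as fh:
        for pos, stringency in zip(nmap.positions, nmap.stringencies):
            fh.write(f"{nmap.contig}\t{pos}\t{pos + 1}\tpeak\t{stringency:.6g}\n")
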