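"""Junction evidence parsing and RPM normalization.

Back-splice junctions use the convention: ``start`` = first base of the
most (genomically) upstream circRNA exon, ``end`` = one past the last
base of the most downstream exon (0-based half-open span of the circle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "BackSpliceJunction",
    "LinearJunction",
    "LibraryInfo",
    "RNA_FRACTIONS",
    "parse_star_chimeric",
    "parse_junction_bed",
    "write_junction_bed",
    "compute_rpm",
    "read_samples_yaml",
    "write_samples_yaml",
    "read_boundary_counts",
    "write_boundary_counts",
]

RNA_FRACTIONS = ("pA_plus", "pA_minus", "pA_minus_RNaseR", "ribo_minus")


@dataclass(frozen=True)
class LibraryInfo:
    library_id: str
    rna_fraction: str
    total_mapped_reads: int
    cell_line: str = ""

    def __post_init__(self) -> None:
        if self.rna_fraction not in RNA_FRACTIONS:
            raise ValueError(
                f"{self.library_id}: rna_fraction must be one of {RNA_FRACTIONS}"
            )
        if self.total_mapped_reads <= 0:
            raise ValueError(f"{self.library_id}: total_mapped_reads must be > 0")


@dataclass(frozen=True)
class BackSpliceJunction:
    chrom: str
    start: int
    end: int
    read_count: int
    strand: str = "."
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"back-splice junction {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.read_count < 1:
            raise ValueError("observed junction requires read_count >= 1")


@dataclass(frozen=True)
class LinearJunction:
    """A collinear splice junction stored as its genomic intron interval.

    ``start`` is the end of the upstream exon and ``end`` the start of the
    downstream exon in genomic order; donor/acceptor follow strand.
    """

    chrom: str
    start: int
    end: int
    read_count: int
    strand: str = "."
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"linear junction {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")

    @property
    def donor(self) -> int:
        return self.start if self.strand != "-" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand != "-" else self.start


def compute_rpm(read_count: int, library: LibraryInfo) -> float:
    """Reads per million mapped reads in the library."""
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return 1e6 * read_count / library.total_mapped_reads


def parse_star_chimeric(
    path: str | Path,
    library: LibraryInfo,
    keep_noncanonical: bool = False,
) -> list[BackSpliceJunction]:
    """Collapse a STAR-style chimeric junction file into back-splice junctions.

    Only same-chromosome, same-strand chimeras in back-splice orientation
    (downstream donor joined to upstream acceptor) are kept.  Column map:
    chrA coordA strandA chrB coordB strandB junction_type repeatL repeatR
    read_name [...] — the first segment is the donor side, the second the
    acceptor side; coordinates are the dialect's 1-based intron breakpoint
    bases.  Lines with junction_type < 0 (no canonical splice motif) are
    dropped unless ``keep_noncanonical``.
    """
    counts: dict[tuple[str, int, int, str], int] = {}
    n_lines = n_cross = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"line {line_no}: expected >= 10 columns")
            chr_d, coord_d_s, strand_d, chr_a, coord_a_s, strand_a, jtype_s = fields[:7]
            try:
                coord_d, coord_a, jtype = int(coord_d_s), int(coord_a_s), int(jtype_s)
            except ValueError as exc:
                raise ValueError(f"line {line_no}: non-integer coordinate field") from exc
            n_lines += 1
            if chr_d != chr_a or strand_d != strand_a:
                n_cross += 1
                continue
            if jtype < 0 and not keep_noncanonical:
                continue
            if strand_d == "+":
                # breakpoints: first intron base after the donor exon /
                # last intron base before the acceptor exon (1-based)
                donor_end = coord_d - 1
                acceptor_start = coord_a
            elif strand_d == "-":
                donor_start = coord_d
                acceptor_end = coord_a - 1
                donor_end, acceptor_start = acceptor_end, donor_start
            else:
                continue
            # back-splice orientation: acceptor genomically upstream of donor
            if acceptor_start >= donor_end:
                continue
            key = (chr_d, acceptor_start, donor_end, strand_d)
            counts[key] = counts.get(key, 0) + 1
    if n_lines and not counts and n_cross == n_lines:
        warnings.warn("all chimeric records were cross-chromosome or cross-strand")
    return [
        BackSpliceJunction(c, s, e, n, strand, library.library_id)
        for (c, s, e, strand), n in sorted(counts.items())
    ]


def parse_junction_bed(
    path: str | Path, kind: str, library: LibraryInfo
) -> list[BackSpliceJunction] | list[LinearJunction]:
    """Parse the BED6 junction dialect (score column = read count).

    ``kind`` is ``"backsplice"`` (start/end per the BackSpliceJunction
    convention) or ``"linear"`` (start/end = intron interval).  Duplicate
    (chrom, start, end, strand) lines are summed.
    """
    if kind not in ("backsplice", "linear"):
        raise ValueError(f"kind must be 'backsplice' or 'linear', got {kind!r}")
    counts: dict[tuple[str, int, int, str], int] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {line_no}: expected >= 6 BED columns")
            chrom, start_s, end_s, _name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {line_no}: non-integer coordinates") from exc
            try:
                score = int(score_s)
            except ValueError as exc:
                raise ValueError(f"line {line_no}: read count must be an integer") from exc
            if start >= end:
                raise ValueError(f"line {line_no}: start >= end")
            key = (chrom, start, end, strand)
            counts[key] = counts.get(key, 0) + score
    cls = BackSpliceJunction if kind == "backsplice" else LinearJunction
    out = []
    for (chrom, start, end, strand), n in sorted(counts.items()):
        if cls is BackSpliceJunction and n < 1:
            continue
        out.append(cls(chrom, start, end, n, strand, library.library_id))
    return out


def write_junction_bed(
    junctions: Iterable[BackSpliceJunction | LinearJunction], path: str | Path
) -> None:
    rows = sorted(junctions, key=lambda j: (j.chrom, j.start, j.end, j.strand))
    with open(path, "w") as fh:
        for i, j in enumerate(rows):
            fh.write(
                f"{j.chrom}\t{j.start}\t{j.end}\tJ{i + 1}\t{j.read_count}\t{j.strand}\n"
            )


def read_samples_yaml(path: str | Path) -> dict[str, LibraryInfo]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    libs = {}
    for entry in data["libraries"]:
        info = LibraryInfo(
            library_id=str(entry["library_id"]),
            rna_fraction=str(entry["rna_fraction"]),
            total_mapped_reads=int(entry["total_mapped_reads"]),
            cell_line=str(entry.get("cell_line", "")),
        )
        libs[info.library_id] = info
    return libs


def write_samples_yaml(libraries: Iterable[LibraryInfo], path: str | Path) -> None:
    data = {
        "libraries": [
            {
                "library_id": lib.library_id,
                "rna_fraction": lib.rna_fraction,
                "total_mapped_reads": lib.total_mapped_reads,
                "cell_line": lib.cell_line,
            }
            for lib in sorted(libraries, key=lambda l: l.library_id)
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_boundary_counts(
    path: str | Path,
) -> dict[tuple[str, str, int, int, str], tuple[int, int]]:
    """Exon-intron boundary read counts per retained-intron candidate.

    TSV columns: library_id chrom intron_start intron_end strand e5 e3.
    Returns {(library_id, chrom, start, end, strand): (e5, e3)}.
    """
    out = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("library_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"line {line_no}: expected 7 columns")
            lib, chrom, start_s, end_s, strand, e5_s, e3_s = fields[:7]
            out[(lib, chrom, int(start_s), int(end_s), strand)] = (int(e5_s), int(e3_s))
    return out


def write_boundary_counts(
    counts: dict[tuple[str, str, int, int, str], tuple[int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tchrom\tintron_start\tintron_end\tstrand\te5\te3\n")
        for (lib, chrom, start, end, strand), (e5, e3) in sorted(counts.items()):
            fh.write(f"{lib}\t{chrom}\t{start}\t{end}\t{strand}\t{e5}\t{e3}\n")
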