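"""Exon-resolved circRNA annotation from back-splice junctions.

Each back-splice junction is realigned ("snapped") against exon
boundaries of the loaded gene models within a small tolerance; the best
matching isoform supplies the circRNA exon blocks.  Junctions with no
boundary match fall back to ciRNA-like (single-intron) or intergenic
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_annotation import (
    GeneModel,
    GenomeSequence,
    SpliceSiteIndex,
    REFERENCE_SOURCES,
)
from .junction_io import BackSpliceJunction, LibraryInfo, compute_rpm

__all__ = [
    "CircRNARecord",
    "SnapCandidate",
    "realign_and_snap",
    "annotate",
    "write_circ_bed",
    "read_circ_bed",
]

CIRC_TYPES = ("exonic", "ciRNA-like", "intergenic")


@dataclass(frozen=True)
class CircRNARecord:
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str
    isoform_name: str
    blocks: tuple[tuple[int, int], ...]  # absolute genomic (start, end) pairs
    read_count: int
    rpm: float
    site_status: tuple[str, str]  # (start side, end side), each annotated|novel
    circ_type: str
    library_id: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        object.__setattr__(self, "site_status", tuple(self.site_status))
        if self.circ_type not in CIRC_TYPES:
            raise ValueError(f"bad circ_type {self.circ_type!r}")
        if not self.blocks:
            raise ValueError("record must have >= 1 block")
        if self.blocks[0][0] != self.start or self.blocks[-1][1] != self.end:
            raise ValueError("blocks must span exactly [start, end)")
        prev = self.start
        for s, e in self.blocks:
            if s >= e or s < prev:
                raise ValueError("blocks must be increasing and non-overlapping")
            prev = e
        for status in self.site_status:
            if status not in ("annotated", "novel"):
                raise ValueError(f"bad site status {status!r}")

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.blocks)

    @property
    def block_starts(self) -> tuple[int, ...]:
        """BED-style block starts relative to the record start."""
        return tuple(s - self.start for s, _ in self.blocks)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class SnapCandidate:
    model: GeneModel
    start: int
    end: int
    total_offset: int


def _best_boundary(hits) -> tuple[int, int] | None:
    """Pick (coordinate, |offset|) — hits are pre-sorted by |offset|, coord."""
    if not hits:
        return None
    h = hits[0]
    return h.coordinate, abs(h.offset)


def realign_and_snap(
    j: BackSpliceJunction, index: SpliceSiteIndex, tolerance: int = 2
) -> list[SnapCandidate]:
    """All isoforms whose exon boundaries match both back-splice sites.

    ``j.start`` must match an exon-start boundary and ``j.end`` an
    exon-end boundary of the same isoform, each within ``tolerance`` nt.
    Per isoform the closest boundary on each side is chosen (ties toward
    the smaller coordinate); results are sorted by total |offset|, then
    isoform name.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    strands = [j.strand] if j.strand in ("+", "-") else ["+", "-"]
    per_model: dict[GeneModel, tuple[int, int, int]] = {}
    for strand in strands:
        start_hits = index.lookup_exon_starts(j.chrom, strand, j.start, tolerance)
        end_hits = index.lookup_exon_ends(j.chrom, strand, j.end, tolerance)
        end_models = set()
        for h in end_hits:
            end_models.update(h.models)
        for model in sorted(
            {m for h in start_hits for m in h.models} & end_models,
            key=lambda m: m.isoform_name,
        ):
            s_best = _best_boundary([h for h in start_hits if model in h.models])
            e_best = _best_boundary([h for h in end_hits if model in h.models])
            assert s_best and e_best
            per_model[model] = (s_best[0], e_best[0], s_best[1] + e_best[1])
    out = [
        SnapCandidate(m, s, e, off) for m, (s, e, off) in per_model.items() if s < e
    ]
    out.sort(key=lambda c: (c.total_offset, c.model.isoform_name))
    return out


def _blocks_in_span(model: GeneModel, start: int, end: int) -> tuple[tuple[int, int], ...]:
    blocks = []
    for s, e in model.exons:
        cs, ce = max(s, start), min(e, end)
        if cs < ce:
            blocks.append((cs, ce))
    return tuple(blocks)


def _exons_in_span(model: GeneModel, start: int, end: int) -> int:
    return sum(1 for s, e in model.exons if s < end and start < e)


def _reference_boundaries(models: Sequence[GeneModel]) -> tuple[set, set]:
    """(exon-start, exon-end) boundary sets from non-assembled sources."""
    starts, ends = set(), set()
    for m in models:
        if m.source_tag == "assembled":
            continue
        for s, e in m.exons:
            starts.add((m.chrom, m.strand, s))
            ends.add((m.chrom, m.strand, e))
    return starts, ends


def annotate(
    junctions: Iterable[BackSpliceJunction],
    models: Sequence[GeneModel],
    libraries: Mapping[str, LibraryInfo],
    genome: GenomeSequence | None = None,
    tolerance: int = 2,
    index: SpliceSiteIndex | None = None,
) -> list[CircRNARecord]:
    """Annotate back-splice junctions into exon-resolved circRNA records.

    The best isoform per junction minimizes total snap offset; ties are
    broken toward the isoform with more exons inside the span, then
    lexicographically.  An exact cross-strand tie yields one record per
    strand, flagged ambiguous.
    """
    if index is None:
        index = SpliceSiteIndex(models)
    if genome is not None:
        known = set(genome.lengths)
        missing = {m.chrom for m in models if m.chrom not in known}
        missing |= {j.chrom for j in junctions if j.chrom not in known}
        if missing:
            raise ValueError(
                f"chromosomes absent from the genome: {sorted(missing)} "
                "(supply a rename map upstream if names differ)"
            )
    ref_starts, ref_ends = _reference_boundaries(models)
    records: list[CircRNARecord] = []
    for j in junctions:
        lib = libraries[j.library_id]
        rpm = compute_rpm(j.read_count, lib)
        candidates = realign_and_snap(j, index, tolerance)
        if candidates:
            best_off = candidates[0].total_offset
            tied = [c for c in candidates if c.total_offset == best_off]
            by_strand: dict[str, SnapCandidate] = {}
            for strand in ("+", "-"):
                pool = [c for c in tied if c.model.strand == strand]
                if pool:
                    pool.sort(
                        key=lambda c: (
                            -_exons_in_span(c.model, c.start, c.end),
                            c.model.isoform_name,
                        )
                    )
                    by_strand[strand] = pool[0]
            ambiguous = len(by_strand) > 1
            for strand in sorted(by_strand):
                c = by_strand[strand]
                records.append(
                    CircRNARecord(
                        chrom=j.chrom,
                        start=c.start,
                        end=c.end,
                        strand=strand,
                        gene_name=c.model.gene_name,
                        isoform_name=c.model.isoform_name,
                        blocks=_blocks_in_span(c.model, c.start, c.end),
                        read_count=j.read_count,
                        rpm=rpm,
                        site_status=(
                            "annotated" if (j.chrom, strand, c.start) in ref_starts else "novel",
                            "annotated" if (j.chrom, strand, c.end) in ref_ends else "novel",
                        ),
                        circ_type="exonic",
                        library_id=j.library_id,
                        ambiguous=ambiguous,
                    )
                )
            continue
        # no boundary match: intronic (ciRNA-like), intragenic novel, or intergenic
        hosts = [
            m
            for m in index.transcripts_overlapping(j.chrom, j.start, j.end)
            if m.tx_start <= j.start and j.end <= m.tx_end
        ]
        hosts.sort(key=lambda m: m.isoform_name)
        intronic = [
            m
            for m in hosts
            if any(s <= j.start and j.end <= e for s, e in m.introns)
        ]
        if intronic:
            m = intronic[0]
            circ_type, gene, iso, strand = "ciRNA-like", m.gene_name, m.isoform_name, m.strand
        elif hosts:
            m = hosts[0]
            circ_type, gene, iso, strand = "exonic", m.gene_name, "novel_candidate", m.strand
        else:
            circ_type, gene, iso = "intergenic", "NA", "NA"
            strand = j.strand if j.strand in ("+", "-") else "."
        records.append(
            CircRNARecord(
                chrom=j.chrom,
                start=j.start,
                end=j.end,
                strand=strand if strand in ("+", "-") else "+",
                gene_name=gene,
                isoform_name=iso,
                blocks=((j.start, j.end),),
                read_count=j.read_count,
                rpm=rpm,
                site_status=("novel", "novel"),
                circ_type=circ_type,
                library_id=j.library_id,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand, r.library_id))
    return records


_EXTRA_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tthickStart\tthickEnd\titemRgb\t"
    "blockCount\tblockSizes\tblockStarts\treadCount\tRPM\tcircType\t"
    "geneName\tisoformName\tsiteStatus\n"
)


def write_circ_bed(records: Iterable[CircRNARecord], path: str | Path) -> None:
    """BED12 + 6 extra columns (readCount, RPM, circType, geneName,
    isoformName, siteStatus); the BED name column carries the library id."""
    with open(path, "w") as fh:
        fh.write(_EXTRA_HEADER)
        for r in records:
            sizes = ",".join(str(s) for s in r.block_sizes) + ","
            starts = ",".join(str(s) for s in r.block_starts) + ","
            fh.write(
                "\t".join(
                    [
                        r.chrom, str(r.start), str(r.end),
                        r.library_id or "circ", str(min(r.read_count, 1000)),
                        r.strand, str(r.start), str(r.end), "0,0,0",
                        str(len(r.blocks)), sizes, starts,
                        str(r.read_count), repr(r.rpm), r.circ_type,
                        r.gene_name, r.isoform_name,
                        ",".join(r.site_status),
                    ]
                )
                + "\n"
            )


def read_circ_bed(path: str | Path) -> list[CircRNARecord]:
    records = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) != 18:
                raise ValueError(f"line {line_no}: expected 18 columns, got {len(fields)}")
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            library_id, strand = fields[3], fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            rel_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(rel_starts) != n_blocks:
                raise ValueError(f"line {line_no}: blockCount mismatch")
            blocks = tuple(
                (start + rs, start + rs + sz) for rs, sz in zip(rel_starts, sizes)
            )
            if blocks[0][0] != start or blocks[-1][1] != end:
                raise ValueError(f"line {line_no}: blocks do not span the record")
            try:
                rec = CircRNARecord(
                    chrom=chrom, start=start, end=end, strand=strand,
                    gene_name=fields[15], isoform_name=fields[16],
                    blocks=blocks, read_count=int(fields[12]),
                    rpm=float(fields[13]),
                    site_status=tuple(fields[17].split(",")),
                    circ_type=fields[14], library_id=library_id,
                )
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from exc
            records.append(rec)
    return records
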