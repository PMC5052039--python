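"""Genome sequences, transcript models, and splice-site indices.

All internal coordinates are 0-based half-open on the forward genomic
strand.  GTF input (1-based inclusive) is converted at the parsing
boundary; genePred/refFlat is already 0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "SpliceSiteIndex",
    "BoundaryHit",
    "reverse_complement",
    "read_genepred",
    "write_genepred",
    "read_gtf",
    "build_splice_site_index",
    "flanking_introns",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REFERENCE_SOURCES = frozenset({"refseq", "known_genes", "ensembl"})
VALID_SOURCES = frozenset({"refseq", "known_genes", "ensembl", "assembled", "synthetic"})


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """In-memory genome with uppercase access and strand-aware slicing."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(s).upper() for name, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        from pyfaidx import Fasta

        with Fasta(str(path), as_raw=True, rebuild=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self._seqs):
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chromosomes(self) -> list[str]:
        return sorted(self._seqs)

    def slice(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); minus strand returns the reverse complement."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        if not (0 <= start <= end <= n):
            raise ValueError(
                f"slice {chrom}:{start}-{end} out of bounds for length {n}"
            )
        seq = self._seqs[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq


@dataclass(frozen=True)
class GeneModel:
    """One transcript isoform with genePred exon-list semantics."""

    gene_name: str
    isoform_name: str
    chrom: str
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    source_tag: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_starts", tuple(self.exon_starts))
        object.__setattr__(self, "exon_ends", tuple(self.exon_ends))
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.isoform_name}: bad strand {self.strand!r}")
        if self.source_tag not in VALID_SOURCES:
            raise ValueError(f"{self.isoform_name}: bad source_tag {self.source_tag!r}")
        ns, ne = len(self.exon_starts), len(self.exon_ends)
        if ns != ne or ns < 1:
            raise ValueError(
                f"{self.isoform_name}: exon list lengths differ ({ns} vs {ne})"
            )
        prev_end = -1
        for k, (s, e) in enumerate(zip(self.exon_starts, self.exon_ends)):
            if s >= e:
                raise ValueError(f"{self.isoform_name}: exon {k} empty ({s} >= {e})")
            if s < prev_end:
                raise ValueError(
                    f"{self.isoform_name}: exon {k} overlaps or is out of order"
                )
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    @property
    def tx_start(self) -> int:
        return self.exon_starts[0]

    @property
    def tx_end(self) -> int:
        return self.exon_ends[-1]

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals between consecutive exons."""
        return [
            (self.exon_ends[k], self.exon_starts[k + 1])
            for k in range(self.n_exons - 1)
        ]

    def mrna_sequence(self, genome: GenomeSequence) -> str:
        """Spliced transcript sequence in transcript (sense) orientation."""
        seq = "".join(genome.slice(self.chrom, s, e) for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq


def _parse_int_list(text: str, line_no: int, col: str) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")
    except ValueError as exc:
        raise ValueError(f"line {line_no}, column {col}: not a comma list of ints") from exc


def read_genepred(path: str | Path, source_tag: str = "synthetic") -> list[GeneModel]:
    """Parse a refFlat-style genePred file (0-based half-open).

    Columns: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    exonCount exonStarts exonEnds.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(
                    f"line {line_no}: expected 11 tab-separated columns, got {len(fields)}"
                )
            (gene, name, chrom, strand, _tx_s, _tx_e, _cds_s, _cds_e,
             exon_count, starts_s, ends_s) = fields[:11]
            try:
                n = int(exon_count)
            except ValueError as exc:
                raise ValueError(f"line {line_no}, column exonCount: not an integer") from exc
            starts = _parse_int_list(starts_s, line_no, "exonStarts")
            ends = _parse_int_list(ends_s, line_no, "exonEnds")
            if len(starts) != n or len(ends) != n:
                raise ValueError(
                    f"line {line_no}: exonCount {n} does not match list lengths "
                    f"({len(starts)}, {len(ends)})"
                )
            try:
                models.append(
                    GeneModel(gene, name, chrom, strand, starts, ends, source_tag)
                )
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from exc
    return models


def write_genepred(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models in refFlat layout (CDS set to the transcript span)."""
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            fh.write(
                "\t".join(
                    [
                        m.gene_name, m.isoform_name, m.chrom, m.strand,
                        str(m.tx_start), str(m.tx_end),
                        str(m.tx_start), str(m.tx_end),
                        str(m.n_exons), starts, ends,
                    ]
                )
                + "\n"
            )


def _gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path, source_tag: str = "assembled") -> list[GeneModel]:
    """Parse exon features of a GTF into GeneModels (coordinates converted
    from 1-based inclusive to 0-based half-open)."""
    by_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"line {line_no}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            if feature != "exon":
                continue
            attrs = _gtf_attributes(attr_s)
            tx = attrs.get("transcript_id")
            if not tx:
                raise ValueError(f"line {line_no}: exon feature missing transcript_id")
            gene = attrs.get("gene_id", tx)
            start, end = int(start_s) - 1, int(end_s)
            rec = by_tx.get(tx)
            if rec is None:
                rec = {"gene": gene, "chrom": chrom, "strand": strand, "exons": []}
                by_tx[tx] = rec
                order.append(tx)
            rec["exons"].append((start, end))
    models = []
    for tx in order:
        rec = by_tx[tx]
        exons = sorted(rec["exons"])
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {tx}: overlapping exons {s1}-{e1} and {s2}-")
        models.append(
            GeneModel(
                rec["gene"], tx, rec["chrom"], rec["strand"],
                tuple(s for s, _ in exons), tuple(e for _, e in exons),
                source_tag,
            )
        )
    return models


@dataclass(frozen=True)
class BoundaryHit:
    """One splice-site boundary returned by an index lookup."""

    coordinate: int
    offset: int  # query - coordinate
    kind: str  # "exon_start" | "exon_end"
    terminal: bool
    models: tuple[GeneModel, ...]


class _BoundarySet:
    """Sorted unique coordinates with model sets and terminal flags."""

    def __init__(self) -> None:
        self._models: dict[int, set[GeneModel]] = {}
        self._internal: dict[int, bool] = {}
        self._sorted: list[int] | None = None

    def add(self, coord: int, model: GeneModel, internal: bool) -> None:
        self._models.setdefault(coord, set()).add(model)
        self._internal[coord] = self._internal.get(coord, False) or internal
        self._sorted = None

    def coordinates(self) -> list[int]:
        if self._sorted is None:
            self._sorted = sorted(self._models)
        return self._sorted

    def near(self, query: int, tolerance: int, kind: str) -> list[BoundaryHit]:
        coords = self.coordinates()
        lo = bisect.bisect_left(coords, query - tolerance)
        hi = bisect.bisect_right(coords, query + tolerance)
        hits = [
            BoundaryHit(
                coordinate=c,
                offset=query - c,
                kind=kind,
                terminal=not self._internal[c],
                models=tuple(sorted(self._models[c], key=lambda m: m.isoform_name)),
            )
            for c in coords[lo:hi]
        ]
        hits.sort(key=lambda h: (abs(h.offset), h.coordinate))
        return hits


class SpliceSiteIndex:
    """Queryable exon-boundary index over a set of GeneModels.

    Boundaries are stored genomically as exon starts and exon ends;
    donor/acceptor semantics follow strand (plus strand: exon end is the
    donor, exon start the acceptor; minus strand mirrored).
    """

    def __init__(self, models: Sequence[GeneModel]):
        if not models:
            raise ValueError("cannot index an empty model list")
        self.models = list(models)
        self._starts: dict[tuple[str, str], _BoundarySet] = {}
        self._ends: dict[tuple[str, str], _BoundarySet] = {}
        self._spans: dict[tuple[str, str], list[tuple[int, int, GeneModel]]] = {}
        for m in models:
            key = (m.chrom, m.strand)
            starts = self._starts.setdefault(key, _BoundarySet())
            ends = self._ends.setdefault(key, _BoundarySet())
            for k, (s, e) in enumerate(m.exons):
                starts.add(s, m, internal=k > 0)
                ends.add(e, m, internal=k < m.n_exons - 1)
            self._spans.setdefault(key, []).append((m.tx_start, m.tx_end, m))
        for spans in self._spans.values():
            spans.sort(key=lambda t: (t[0], t[1], t[2].isoform_name))

    def lookup_exon_starts(
        self, chrom: str, strand: str, coord: int, tolerance: int = 0
    ) -> list[BoundaryHit]:
        bset = self._starts.get((chrom, strand))
        return bset.near(coord, tolerance, "exon_start") if bset else []

    def lookup_exon_ends(
        self, chrom: str, strand: str, coord: int, tolerance: int = 0
    ) -> list[BoundaryHit]:
        bset = self._ends.get((chrom, strand))
        return bset.near(coord, tolerance, "exon_end") if bset else []

    def lookup_donors(
        self, chrom: str, strand: str, coord: int, tolerance: int = 0
    ) -> list[BoundaryHit]:
        if strand == "+":
            return self.lookup_exon_ends(chrom, strand, coord, tolerance)
        return self.lookup_exon_starts(chrom, strand, coord, tolerance)

    def lookup_acceptors(
        self, chrom: str, strand: str, coord: int, tolerance: int = 0
    ) -> list[BoundaryHit]:
        if strand == "+":
            return self.lookup_exon_starts(chrom, strand, coord, tolerance)
        return self.lookup_exon_ends(chrom, strand, coord, tolerance)

    def transcripts_overlapping(
        self, chrom: str, start: int, end: int
    ) -> Iterator[GeneModel]:
        for strand in ("+", "-"):
            for s, e, m in self._spans.get((chrom, strand), []):
                if s < end and start < e:
                    yield m

    def strands(self, chrom: str) -> list[str]:
        return [st for st in ("+", "-") if (chrom, st) in self._starts]


def build_splice_site_index(models: Sequence[GeneModel]) -> SpliceSiteIndex:
    return SpliceSiteIndex(models)


def flanking_introns(
    model: GeneModel, exon_index_range: tuple[int, int]
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Introns flanking a circularized exon range, in transcript sense.

    ``exon_index_range`` is an inclusive 0-based (first, last) pair into
    the model's genomic exon order.  Returns ``(upstream, downstream)``
    genomic intervals relative to the transcript direction: upstream is
    the intron 5' of the first circRNA exon, downstream the intron 3' of
    the last.  A side without an intron (terminal exon) is ``None``.
    """
    first, last = exon_index_range
    if not (0 <= first <= last < model.n_exons):
        raise IndexError(
            f"exon range {exon_index_range} out of bounds for {model.n_exons} exons"
        )
    left = (
        (model.exon_ends[first - 1], model.exon_starts[first]) if first > 0 else None
    )
    right = (
        (model.exon_ends[last], model.exon_starts[last + 1])
        if last < model.n_exons - 1
        else None
    )
    if model.strand == "+":
        return left, right
    return right, left
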