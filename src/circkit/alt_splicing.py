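"""Alternative splicing inside circRNA spans and circ-vs-linear contrast.

Four basic event types are detected from junction/boundary evidence that
falls entirely inside a circRNA span: cassette exons (PSI), retained
introns (PIR), and alternative 5'/3' splice sites (PSU).  Circ-fraction
metrics are contrasted with the parallel poly(A)+ library of the same
cell line to call circRNA-predominant events.

Estimator conventions (documented, config-frozen): PSI and PIR average
the two flanking informative counts in the numerator —
PSI = 100 * ((a+b)/2) / ((a+b)/2 + c) and
PIR = 100 * ((e5+e3)/2) / ((e5+e3)/2 + s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .circ_annotate import CircRNARecord
from .genome_annotation import GeneModel
from .junction_io import LibraryInfo, LinearJunction

__all__ = [
    "SpliceEventCall",
    "compute_psi",
    "compute_pir",
    "compute_psu",
    "detect_events",
    "quantify_linear",
    "call_circ_predominant",
    "high_confidence_across_lines",
    "flag_novel_regions",
]

EVENT_TYPES = ("cassette_exon", "intron_retention", "alt_5ss", "alt_3ss")
CIRC_FRACTIONS = ("pA_minus", "pA_minus_RNaseR")


@dataclass(frozen=True)
class SpliceEventCall:
    event_type: str
    chrom: str
    strand: str
    circ_start: int
    circ_end: int
    region: tuple[int, int]  # variable region (exon, intron, or site gap)
    circ_counts: tuple[int, ...]
    circ_metric: float | None
    library_id: str
    sites: tuple[int, ...] = ()  # alt-SS alternative coordinates, proximal first
    shared_site: int | None = None
    linear_counts: tuple[int, ...] | None = None
    linear_metric: float | None = None
    linear_library_id: str | None = None
    verdict: str = "unset"
    novel: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"bad event_type {self.event_type!r}")
        for metric in (self.circ_metric, self.linear_metric):
            if metric is not None and not (0.0 <= metric <= 100.0):
                raise ValueError("metrics must lie in [0, 100]")
        if not (self.circ_start <= self.region[0] < self.region[1] <= self.circ_end):
            raise ValueError("variable region must lie inside the circRNA span")

    @property
    def key(self) -> tuple:
        return (self.event_type, self.chrom, self.strand, self.region, self.sites)

    @property
    def circ_support(self) -> int:
        return sum(self.circ_counts)


def compute_psi(a: int, b: int, c: int, min_reads: int = 5) -> float | None:
    """Percent spliced-in of a cassette exon; None below ``min_reads``."""
    if min(a, b, c) < 0:
        raise ValueError("read counts must be >= 0")
    if a + b + c < min_reads:
        return None
    inc = (a + b) / 2.0
    return 100.0 * inc / (inc + c) if inc + c > 0 else None

def compute_pir(e5: int, e3: int, s: int, min_reads: int = 5) -> float | None:
    """Percent intron retention from boundary (e5, e3) vs spliced (s) reads."""
    if min(e5, e3, s) < 0:
        raise ValueError("read counts must be >= 0")
    ret = (e5 + e3) / 2.0
    if ret + s < min_reads:
        return None
    return 100.0 * ret / (ret + s) if ret + s > 0 else None

def compute_psu(read_counts: Sequence[int]) -> tuple[float, ...]:
    """Percent splice-site usage across alternative sites; sums to 100."""
    total = sum(read_counts)
    if total < 1:
        raise ValueError("PSU undefined for zero total reads")
    return tuple(100.0 * r / total for r in read_counts)


def _junction_counts(
    junctions: Iterable[LinearJunction], library_id: str | None = None
) -> dict[tuple[str, int, int], int]:
    counts: dict[tuple[str, int, int], int] = {}
    for j in junctions:
        if library_id is not None and j.library_id != library_id:
            continue
        key = (j.chrom, j.start, j.end)
        counts[key] = counts.get(key, 0) + j.read_count
    return counts


def _detect_for_record(
    r: CircRNARecord,
    counts: dict[tuple[str, int, int], int],
    boundary_counts,
    min_reads: int,
) -> list[SpliceEventCall]:
    inside = {
        (s, e): n
        for (chrom, s, e), n in counts.items()
        if chrom == r.chrom and r.start <= s and e <= r.end
    }
    events: list[SpliceEventCall] = []

    # cassette exons: inclusion junctions (x, s2), (e2, y) plus skip (x, y)
    seen_regions = set()
    for (x, y) in sorted(inside):  # candidate skip junction
        for (x2, s2) in sorted(inside):
            if x2 != x or not (x < s2 < y):
                continue
            for (e2, y2) in sorted(inside):
                if y2 != y or not (s2 < e2 < y):
                    continue
                region = (s2, e2)
                if region in seen_regions:
                    continue
                seen_regions.add(region)
                a, b, c = inside[(x, s2)], inside[(e2, y)], inside[(x, y)]
                events.append(
                    SpliceEventCall(
                        event_type="cassette_exon",
                        chrom=r.chrom, strand=r.strand,
                        circ_start=r.start, circ_end=r.end,
                        region=region,
                        circ_counts=(a, b, c),
                        circ_metric=compute_psi(a, b, c, min_reads),
                        library_id=r.library_id,
                        shared_site=None,
                    )
                )

    # intron retention over the record's annotated introns
    for (gs, ge) in zip((e for _, e in r.blocks[:-1]), (s for s, _ in r.blocks[1:])):
        key = (r.library_id, r.chrom, gs, ge, r.strand)
        e5, e3 = (boundary_counts or {}).get(key, (0, 0))
        s_reads = inside.get((gs, ge), 0)
        if e5 + e3 == 0:
            continue
        events.append(
            SpliceEventCall(
                event_type="intron_retention",
                chrom=r.chrom, strand=r.strand,
                circ_start=r.start, circ_end=r.end,
                region=(gs, ge),
                circ_counts=(e5, e3, s_reads),
                circ_metric=compute_pir(e5, e3, s_reads, min_reads),
                library_id=r.library_id,
            )
        )

    # alternative 5'/3' splice sites: junctions sharing one end
    by_donor: dict[int, dict[int, int]] = {}
    by_acceptor: dict[int, dict[int, int]] = {}
    for (s, e), n in inside.items():
        donor, acceptor = (s, e) if r.strand != "-" else (e, s)
        by_donor.setdefault(donor, {})[acceptor] = n
        by_acceptor.setdefault(acceptor, {})[donor] = n
    for event_type, groups in (("alt_3ss", by_donor), ("alt_5ss", by_acceptor)):
        for shared, alts in sorted(groups.items()):
            if len(alts) < 2:
                continue
            sites = sorted(alts, key=lambda s: (abs(s - shared), s))
            counts_t = tuple(alts[s] for s in sites)
            lo, hi = min(sites), max(sites)
            events.append(
                SpliceEventCall(
                    event_type=event_type,
                    chrom=r.chrom, strand=r.strand,
                    circ_start=r.start, circ_end=r.end,
                    region=(lo, hi),
                    circ_counts=counts_t,
                    circ_metric=(
                        compute_psu(counts_t)[0]
                        if sum(counts_t) >= min_reads
                        else None
                    ),
                    library_id=r.library_id,
                    sites=tuple(sites),
                    shared_site=shared,
                )
            )
    return events


def detect_events(
    records: Sequence[CircRNARecord],
    junctions: Sequence[LinearJunction],
    boundary_counts: Mapping | None = None,
    min_rpm: float = 0.1,
    min_reads: int = 5,
) -> list[SpliceEventCall]:
    """Detect splicing events inside highly expressed circRNAs.

    Only junction/boundary evidence with both ends inside a circRNA span
    contributes; circRNAs below ``min_rpm`` are skipped.  For alt-SS
    events the scalar circ_metric is the PSU of the proximal site.
    Duplicate events (same type and coordinates) across records are merged,
    keeping the first.
    """
    events: list[SpliceEventCall] = []
    seen = set()
    by_lib: dict[str, dict] = {}
    for r in sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.library_id)):
        if r.rpm < min_rpm:
            continue
        if r.library_id not in by_lib:
            by_lib[r.library_id] = _junction_counts(junctions, r.library_id)
        for ev in _detect_for_record(r, by_lib[r.library_id], boundary_counts, min_reads):
            k = (ev.library_id,) + ev.key
            if k in seen:
                continue
            seen.add(k)
            events.append(ev)
    return events


def _linear_counts_for(
    ev: SpliceEventCall, counts: dict[tuple[str, int, int], int], boundary_counts, lib: str
) -> tuple[int, ...]:
    def n(s: int, e: int) -> int:
        return counts.get((ev.chrom, s, e), 0)

    if ev.event_type == "cassette_exon":
        s2, e2 = ev.region
        # find flanking anchors from any junction into the region boundaries
        a = sum(v for (c, s, e), v in counts.items() if c == ev.chrom and e == s2)
        b = sum(v for (c, s, e), v in counts.items() if c == ev.chrom and s == e2)
        skip = 0
        for (c, s, e), v in counts.items():
            if c == ev.chrom and s < s2 and e > e2:
                skip += v
        return (a, b, skip)
    if ev.event_type == "intron_retention":
        gs, ge = ev.region
        e5, e3 = (boundary_counts or {}).get((lib, ev.chrom, gs, ge, ev.strand), (0, 0))
        return (e5, e3, n(gs, ge))
    # alt SS: same shared site, same alternative sites
    out = []
    for site in ev.sites:
        s, e = (
            (ev.shared_site, site) if ev.shared_site < site else (site, ev.shared_site)
        )
        out.append(n(s, e))
    return tuple(out)


def quantify_linear(
    events: Sequence[SpliceEventCall],
    linear_junctions: Sequence[LinearJunction],
    linear_library: LibraryInfo,
    boundary_counts: Mapping | None = None,
    min_reads: int = 5,
) -> list[SpliceEventCall]:
    """Fill the linear-side counts/metric of each event from a p(A)+ library."""
    counts = _junction_counts(linear_junctions, linear_library.library_id)
    out = []
    for ev in events:
        lc = _linear_counts_for(ev, counts, boundary_counts, linear_library.library_id)
        if ev.event_type == "cassette_exon":
            metric = compute_psi(*lc, min_reads=min_reads)
        elif ev.event_type == "intron_retention":
            metric = compute_pir(*lc, min_reads=min_reads)
        else:
            metric = compute_psu(lc)[0] if sum(lc) >= min_reads else None
        out.append(
            replace(
                ev,
                linear_counts=lc,
                linear_metric=metric,
                linear_library_id=linear_library.library_id,
            )
        )
    return out


def call_circ_predominant(
    event: SpliceEventCall,
    circ_library: LibraryInfo,
    linear_library: LibraryInfo,
    delta: float = 20.0,
    min_reads: int = 5,
) -> SpliceEventCall:
    """Verdict on whether an event is predominantly spliced in circRNAs.

    Requires the circ side from a p(A)- or p(A)-/RNase R library and the
    linear side from the parallel p(A)+ library of the same cell line;
    ribo- libraries carry linear transcripts too and are rejected.
    """
    if circ_library.rna_fraction not in CIRC_FRACTIONS:
        raise ValueError(
            f"library {circ_library.library_id} ({circ_library.rna_fraction}) is not "
            "suitable for the circRNA side; use pA_minus or pA_minus_RNaseR"
        )
    if linear_library.rna_fraction != "pA_plus":
        raise ValueError(
            f"library {linear_library.library_id} ({linear_library.rna_fraction}) is "
            "not a pA_plus library"
        )
    if circ_library.cell_line != linear_library.cell_line:
        raise ValueError(
            f"cell line mismatch: {circ_library.cell_line!r} vs "
            f"{linear_library.cell_line!r}"
        )
    if event.circ_metric is None or event.circ_support < min_reads:
        return replace(event, verdict="insufficient")
    if event.linear_metric is None:
        return replace(event, verdict="unassessable")
    predominant = event.circ_metric - event.linear_metric >= delta
    return replace(event, verdict="predominant" if predominant else "not_predominant")


def high_confidence_across_lines(
    calls_by_line: Mapping[str, Sequence[SpliceEventCall]],
    min_lines: int = 2,
) -> list[SpliceEventCall]:
    """Keep calls whose event is predominant in >= ``min_lines`` cell lines."""
    votes: dict[tuple, set[str]] = {}
    for line, calls in calls_by_line.items():
        for c in calls:
            if c.verdict == "predominant":
                votes.setdefault(c.key, set()).add(line)
    kept_keys = {k for k, lines in votes.items() if len(lines) >= min_lines}
    out = []
    for line in sorted(calls_by_line):
        for c in calls_by_line[line]:
            if c.key in kept_keys and c.verdict == "predominant":
                out.append(c)
    return out


def flag_novel_regions(
    calls: Sequence[SpliceEventCall], reference_models: Sequence[GeneModel]
) -> list[SpliceEventCall]:
    """Mark cassette-exon calls whose exon is absent from the reference union."""
    ref_exons = {
        (m.chrom, m.strand, s, e)
        for m in reference_models
        if m.source_tag != "assembled"
        for s, e in m.exons
    }
    out = []
    for c in calls:
        novel = (
            c.event_type == "cassette_exon"
            and (c.chrom, c.strand, c.region[0], c.region[1]) not in ref_exons
        )
        out.append(replace(c, novel=novel))
    return out
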