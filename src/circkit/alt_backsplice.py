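"""Alternative back-splicing: clustering, PCU, filters, cross-sample spread.

Alternative 5' back-splicing: two or more donor sites share one acceptor
site.  Alternative 3' back-splicing: two or more acceptor sites share
one donor.  Site usage is quantified by PCU (Percent Circularized-site
Usage) = 100 * reads at a site / total reads over the event's sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .circ_annotate import CircRNARecord

__all__ = [
    "AltBackspliceEvent",
    "PcuVariationSummary",
    "cluster_backsplice",
    "compute_pcu",
    "filter_high_confidence",
    "pcu_across_samples",
    "write_events_tsv",
    "write_summary_tsv",
]

EVENT_TYPES = ("alt5BS", "alt3BS")


@dataclass(frozen=True)
class AltBackspliceEvent:
    event_type: str  # alt5BS (shared acceptor) | alt3BS (shared donor)
    chrom: str
    strand: str
    common_site: int
    common_side: str  # "acceptor" | "donor"
    alternative_sites: tuple[int, ...]  # ordered proximal -> distal
    read_counts: tuple[int, ...]
    pcus: tuple[float, ...]
    member_rpms: tuple[float, ...]
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"bad event_type {self.event_type!r}")
        if len(self.alternative_sites) < 2:
            raise ValueError("an alternative event needs >= 2 sites")
        spans = [abs(s - self.common_site) for s in self.alternative_sites]
        if sorted(spans) != spans:
            raise ValueError("alternative sites must be ordered proximal -> distal")
        if abs(sum(self.pcus) - 100.0) > 1e-9:
            raise ValueError("PCUs must sum to 100")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.event_type, self.chrom, self.strand, self.common_site)

    @property
    def spans(self) -> tuple[int, ...]:
        return tuple(abs(s - self.common_site) for s in self.alternative_sites)


@dataclass(frozen=True)
class PcuVariationSummary:
    event_type: str
    chrom: str
    strand: str
    common_site: int
    proximal_pcus: tuple[float, ...]  # per contributing library, sorted by library id
    libraries: tuple[str, ...]
    minimum: float
    q1: float
    q3: float
    maximum: float
    n_detected: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.q1 <= self.q3 <= self.maximum):
            raise ValueError("order statistics out of order")


def compute_pcu(read_counts: Sequence[int]) -> tuple[float, ...]:
    """Per-site PCU; sites with zero reads keep PCU 0, total must be >= 1."""
    total = sum(read_counts)
    if total < 1:
        raise ValueError("PCU undefined for an event with zero total reads")
    return tuple(100.0 * r / total for r in read_counts)


def _sites(record: CircRNARecord) -> tuple[int, int]:
    """(acceptor, donor) genomic coordinates of a circRNA's back-splice sites."""
    if record.strand == "-":
        return record.end, record.start
    return record.start, record.end


def cluster_backsplice(records: Sequence[CircRNARecord]) -> list[AltBackspliceEvent]:
    """Group one library's circRNAs by shared back-splice sites.

    A shared acceptor with >= 2 distinct donors yields one alt5BS event;
    a shared donor with >= 2 distinct acceptors one alt3BS event.  A
    circRNA may belong to one event of each type.  Order-invariant.
    """
    libs = {r.library_id for r in records}
    if len(libs) > 1:
        raise ValueError(f"cluster_backsplice expects one library, got {sorted(libs)}")
    by_acceptor: dict[tuple[str, str, int], list[CircRNARecord]] = {}
    by_donor: dict[tuple[str, str, int], list[CircRNARecord]] = {}
    for r in records:
        if r.strand not in ("+", "-"):
            continue
        acceptor, donor = _sites(r)
        by_acceptor.setdefault((r.chrom, r.strand, acceptor), []).append(r)
        by_donor.setdefault((r.chrom, r.strand, donor), []).append(r)
    events: list[AltBackspliceEvent] = []
    for (event_type, common_side, groups, alt_of) in (
        ("alt5BS", "acceptor", by_acceptor, lambda r: _sites(r)[1]),
        ("alt3BS", "donor", by_donor, lambda r: _sites(r)[0]),
    ):
        for (chrom, strand, common), members in sorted(groups.items()):
            per_site: dict[int, int] = {}
            per_site_rpm: dict[int, float] = {}
            for r in members:
                site = alt_of(r)
                per_site[site] = per_site.get(site, 0) + r.read_count
                per_site_rpm[site] = per_site_rpm.get(site, 0.0) + r.rpm
            if len(per_site) < 2:
                continue
            # proximal = shortest back-splice span; ties by coordinate
            sites = sorted(per_site, key=lambda s: (abs(s - common), s))
            counts = tuple(per_site[s] for s in sites)
            events.append(
                AltBackspliceEvent(
                    event_type=event_type,
                    chrom=chrom,
                    strand=strand,
                    common_site=common,
                    common_side=common_side,
                    alternative_sites=tuple(sites),
                    read_counts=counts,
                    pcus=compute_pcu(counts),
                    member_rpms=tuple(per_site_rpm[s] for s in sites),
                    library_id=members[0].library_id,
                )
            )
    events.sort(key=lambda e: (e.chrom, e.common_site, e.event_type))
    return events


def filter_high_confidence(
    events: Iterable[AltBackspliceEvent], rpm_threshold: float = 0.1
) -> list[AltBackspliceEvent]:
    """Keep events where at least one member circRNA has RPM >= threshold
    (inclusive boundary)."""
    return [e for e in events if any(r >= rpm_threshold for r in e.member_rpms)]


def pcu_across_samples(
    events_by_library: Mapping[str, Sequence[AltBackspliceEvent]],
    min_libraries: int = 3,
) -> list[PcuVariationSummary]:
    """Cross-sample PCU spread of the proximal alternative site.

    Events are matched across libraries by (event_type, chrom, strand,
    common_site) and a non-empty intersection of alternative sites; PCU
    is renormalized over the intersection so totals stay comparable.
    Events detected in fewer than ``min_libraries`` libraries are dropped.
    Q1/Q3 use linear interpolation.
    """
    if len(events_by_library) < min_libraries:
        raise ValueError(
            f"need >= {min_libraries} libraries, got {len(events_by_library)}"
        )
    grouped: dict[tuple, dict[str, AltBackspliceEvent]] = {}
    for lib in sorted(events_by_library):
        for e in events_by_library[lib]:
            grouped.setdefault(e.key, {})[lib] = e
    summaries = []
    for key in sorted(grouped):
        per_lib = grouped[key]
        if len(per_lib) < min_libraries:
            continue
        shared = set.intersection(
            *(set(e.alternative_sites) for e in per_lib.values())
        )
        if not shared:
            continue
        common = key[3]
        proximal = min(shared, key=lambda s: (abs(s - common), s))
        libs, pcus = [], []
        for lib in sorted(per_lib):
            e = per_lib[lib]
            counts = {
                s: c for s, c in zip(e.alternative_sites, e.read_counts) if s in shared
            }
            total = sum(counts.values())
            if total < 1:
                continue
            libs.append(lib)
            pcus.append(100.0 * counts[proximal] / total)
        if len(pcus) < min_libraries:
            continue
        arr = np.asarray(pcus)
        summaries.append(
            PcuVariationSummary(
                event_type=key[0],
                chrom=key[1],
                strand=key[2],
                common_site=common,
                proximal_pcus=tuple(pcus),
                libraries=tuple(libs),
                minimum=float(arr.min()),
                q1=float(np.percentile(arr, 25)),
                q3=float(np.percentile(arr, 75)),
                maximum=float(arr.max()),
                n_detected=len(pcus),
            )
        )
    return summaries


EVENTS_TSV_COLUMNS = (
    "event_id\tevent_type\tchrom\tstrand\tcommon_site\tcommon_side\t"
    "alternative_sites\tread_counts\tpcus\tmember_rpms\tlibrary_id"
)


def write_events_tsv(
    events: Sequence[AltBackspliceEvent], path, header_extra: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(EVENTS_TSV_COLUMNS + "\n")
        for i, e in enumerate(
            sorted(events, key=lambda e: (e.chrom, e.common_site, e.event_type, e.library_id))
        ):
            fh.write(
                "\t".join(
                    [
                        f"ABS{i + 1}", e.event_type, e.chrom, e.strand,
                        str(e.common_site), e.common_side,
                        ",".join(str(s) for s in e.alternative_sites),
                        ",".join(str(c) for c in e.read_counts),
                        ",".join(f"{p:.4f}" for p in e.pcus),
                        ",".join(f"{r:.6g}" for r in e.member_rpms),
                        e.library_id,
                    ]
                )
                + "\n"
            )


def write_summary_tsv(
    summaries: Sequence[PcuVariationSummary], path, header_extra: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(
            "event_type\tchrom\tstrand\tcommon_site\tn_detected\t"
            "min\tq1\tq3\tmax\tlibraries\tproximal_pcus\n"
        )
        for s in sorted(summaries, key=lambda s: (s.chrom, s.common_site, s.event_type)):
            fh.write(
                "\t".join(
                    [
                        s.event_type, s.chrom, s.strand, str(s.common_site),
                        str(s.n_detected),
                        f"{s.minimum:.4f}", f"{s.q1:.4f}", f"{s.q3:.4f}", f"{s.maximum:.4f}",
                        ",".join(s.libraries),
                        ",".join(f"{p:.4f}" for p in s.proximal_pcus),
                    ]
                )
                + "\n"
            )
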