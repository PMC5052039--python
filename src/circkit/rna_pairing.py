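"""Orientation-opposite complementary sequence pairs across flanking introns.

A pair is a local ungapped alignment between one intron and the reverse
complement of another (seed-and-extend: exact k-mer seeds, X-drop
extension).  Competition between a pair bracketing the proximal
back-splice sites and one bracketing the distal sites is what the
alternative back-splice classification reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alt_backsplice import AltBackspliceEvent
from .circ_annotate import CircRNARecord
from .genome_annotation import GeneModel, GenomeSequence, flanking_introns, reverse_complement

__all__ = [
    "PairingParams",
    "ComplementaryPair",
    "CompetitionCall",
    "find_complementary_pairs",
    "classify_competition",
    "control_has_pair",
    "pairing_summary",
]


@dataclass(frozen=True)
class PairingParams:
    seed_k: int = 11
    min_len: int = 30
    min_identity: float = 0.8
    match: int = 1
    mismatch: int = -2
    xdrop: int = 15
    max_pairs: int = 50
    max_intron: int = 50_000


@dataclass(frozen=True)
class ComplementaryPair:
    """arm1 in intron A, arm2 in intron B (both forward-strand intervals);
    arm2's reverse complement aligns to arm1."""

    arm1: tuple[int, int]
    arm2: tuple[int, int]
    length: int
    identity: float
    score: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("empty pair")


@dataclass(frozen=True)
class CompetitionCall:
    event_key: tuple
    has_proximal_pair: bool
    has_distal_pair: bool
    proximal_pairs: tuple[ComplementaryPair, ...]
    distal_pairs: tuple[ComplementaryPair, ...]
    unsearchable: tuple[str, ...] = ()

    @property
    def verdict(self) -> str:
        if self.has_proximal_pair and self.has_distal_pair:
            return "competing"
        if self.has_proximal_pair:
            return "proximal_only"
        if self.has_distal_pair:
            return "distal_only"
        return "none"


def _extend(a: str, b: str, i: int, j: int, k: int, p: PairingParams):
    """Ungapped X-drop extension of an exact seed a[i:i+k] == b[j:j+k]."""
    score = k * p.match
    best = score
    # right
    ae, be = i + k, j + k
    best_ae = ae
    x, y, cur = ae, be, score
    while x < len(a) and y < len(b):
        cur += p.match if a[x] == b[y] else p.mismatch
        x += 1
        y += 1
        if cur > best:
            best, best_ae = cur, x
        if best - cur > p.xdrop:
            break
    ae = best_ae
    # left
    score = best
    asv, bsv = i, j
    best_as = asv
    x, y, cur = i, j, best
    while x > 0 and y > 0:
        x -= 1
        y -= 1
        cur += p.match if a[x] == b[y] else p.mismatch
        if cur > best:
            best, best_as = cur, x
        if best - cur > p.xdrop:
            break
    asv = best_as
    length = ae - asv
    bs = j - (i - asv)
    matches = sum(1 for u, v in zip(a[asv:ae], b[bs : bs + length]) if u == v)
    return asv, ae, bs, best, matches / length if length else 0.0


def find_complementary_pairs(
    intron_a: str,
    intron_b: str,
    params: PairingParams = PairingParams(),
    offset_a: int = 0,
    offset_b: int = 0,
) -> list[ComplementaryPair]:
    """Complementary (reverse-orientation) matches between two introns.

    Both inputs are forward-strand sequences; ``offset_a``/``offset_b``
    shift reported arm coordinates to genomic positions.  Overlapping
    hits are merged keeping the best score; at most ``max_pairs`` pairs
    (best first) are returned.
    """
    p = params
    a = intron_a.upper()
    b = intron_b.upper()
    if len(a) < p.seed_k or len(b) < p.seed_k:
        return []
    brc = reverse_complement(b)
    index: dict[str, list[int]] = {}
    for j in range(len(brc) - p.seed_k + 1):
        kmer = brc[j : j + p.seed_k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    covered: dict[int, int] = {}  # diagonal -> rightmost extended a-position
    raw = []
    for i in range(len(a) - p.seed_k + 1):
        kmer = a[i : i + p.seed_k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):  # noqa: B905
            d = i - j
            if covered.get(d, -1) >= i + p.seed_k:
                continue
            asv, ae, bs, score, ident = _extend(a, brc, i, j, p.seed_k, p)
            covered[d] = max(covered.get(d, -1), ae)
            length = ae - asv
            if length >= p.min_len and ident >= p.min_identity:
                raw.append((asv, ae, bs, bs + length, score, ident))
    # merge overlapping hits (both arms overlap): greedy by score
    raw.sort(key=lambda t: (-t[4], t[0], t[2]))
    kept = []
    for asv, ae, bs, be, score, ident in raw:
        clash = any(
            asv < ka_e and ka_s < ae and bs < kb_e and kb_s < be
            for ka_s, ka_e, kb_s, kb_e, _, _ in kept
        )
        if not clash:
            kept.append((asv, ae, bs, be, score, ident))
        if len(kept) >= p.max_pairs:
            break
    pairs = []
    for asv, ae, bs, be, score, ident in kept:
        # map arm2 back from reverse-complement coordinates to forward strand
        fwd_s, fwd_e = len(b) - be, len(b) - bs
        pairs.append(
            ComplementaryPair(
                arm1=(offset_a + asv, offset_a + ae),
                arm2=(offset_b + fwd_s, offset_b + fwd_e),
                length=ae - asv,
                identity=ident,
                score=score,
            )
        )
    pairs.sort(key=lambda q: (-q.score, q.arm1, q.arm2))
    return pairs


def _clip_intron(
    interval: tuple[int, int], anchored_at_end: bool, cap: int
) -> tuple[int, int]:
    """Cap an intron to ``cap`` nt measured from the back-splice side."""
    s, e = interval
    if e - s <= cap:
        return s, e
    return (e - cap, e) if anchored_at_end else (s, s + cap)


def _member_introns(
    record: CircRNARecord,
    model: GeneModel,
    cap: int,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """(upstream, downstream) flanking introns of a circRNA, transcript sense,
    clipped to ``cap`` nt from the back-splice side."""
    first = last = None
    for k, (s, e) in enumerate(model.exons):
        if s == record.start:
            first = k
        if e == record.end:
            last = k
    if first is None or last is None or first > last:
        raise ValueError(
            f"record {record.chrom}:{record.start}-{record.end} does not match "
            f"exon boundaries of {model.isoform_name}"
        )
    up, down = flanking_introns(model, (first, last))
    # the back-splice-adjacent end of an intron is the one touching the
    # circ span: interval end == record.start, or interval start == record.end
    if up is not None:
        up = _clip_intron(up, anchored_at_end=up[1] == record.start, cap=cap)
    if down is not None:
        down = _clip_intron(down, anchored_at_end=down[1] == record.start, cap=cap)
    return up, down


def classify_competition(
    event: AltBackspliceEvent,
    records: Sequence[CircRNARecord],
    models_by_isoform: Mapping[str, GeneModel],
    genome: GenomeSequence,
    params: PairingParams = PairingParams(),
) -> CompetitionCall:
    """Search proximal- and distal-bracketing complementary pairs for one
    alternative back-splice event.

    The common-site flanking intron is paired against the proximal
    member's far-side intron (proximal pair) and against the distal
    member's far-side intron (distal pair).  A member at a transcript-
    terminal exon leaves that side unsearchable rather than erroring.
    """
    by_key = {(r.chrom, r.start, r.end, r.strand): r for r in records}

    def member(site: int) -> CircRNARecord | None:
        lo, hi = min(event.common_site, site), max(event.common_site, site)
        return by_key.get((event.chrom, lo, hi, event.strand))

    proximal = member(event.alternative_sites[0])
    distal = member(event.alternative_sites[-1])

    unsearchable: list[str] = []
    results: dict[str, tuple[ComplementaryPair, ...]] = {}
    for side_name, rec in (("proximal", proximal), ("distal", distal)):
        if rec is None or rec.isoform_name not in models_by_isoform:
            unsearchable.append(side_name)
            results[side_name] = ()
            continue
        model = models_by_isoform[rec.isoform_name]
        try:
            up, down = _member_introns(rec, model, params.max_intron)
        except ValueError:
            unsearchable.append(side_name)
            results[side_name] = ()
            continue
        # for alt5BS the common site is the acceptor (transcript-upstream
        # side); the varying donor sits transcript-downstream — mirrored
        # for alt3BS
        common_intron, far_intron = (up, down) if event.event_type == "alt5BS" else (down, up)
        if common_intron is None or far_intron is None:
            unsearchable.append(side_name)
            results[side_name] = ()
            continue
        pairs = find_complementary_pairs(
            genome.slice(event.chrom, *common_intron),
            genome.slice(event.chrom, *far_intron),
            params,
            offset_a=common_intron[0],
            offset_b=far_intron[0],
        )
        results[side_name] = tuple(pairs)
    return CompetitionCall(
        event_key=event.key,
        has_proximal_pair=bool(results["proximal"]),
        has_distal_pair=bool(results["distal"]),
        proximal_pairs=results["proximal"],
        distal_pairs=results["distal"],
        unsearchable=tuple(unsearchable),
    )


def control_has_pair(
    record: CircRNARecord,
    models_by_isoform: Mapping[str, GeneModel],
    genome: GenomeSequence,
    params: PairingParams = PairingParams(),
) -> bool | None:
    """Whether a (non-alternative) circRNA's own flanking introns hold a
    qualifying pair; None when a flanking intron is unavailable."""
    model = models_by_isoform.get(record.isoform_name)
    if model is None:
        return None
    try:
        up, down = _member_introns(record, model, params.max_intron)
    except ValueError:
        return None
    if up is None or down is None:
        return None
    pairs = find_complementary_pairs(
        genome.slice(record.chrom, *up),
        genome.slice(record.chrom, *down),
        params,
        offset_a=up[0],
        offset_b=down[0],
    )
    return bool(pairs)


def pairing_summary(
    calls: Sequence[CompetitionCall],
    control_flags: Sequence[bool],
) -> dict:
    """Fractions table: competing among alternative events vs any-pair among
    a matched non-alternative control set."""
    import warnings

    n_alt = len(calls)
    n_competing = sum(1 for c in calls if c.verdict == "competing")
    out = {
        "n_alternative": n_alt,
        "n_competing": n_competing,
        "fraction_competing": (n_competing / n_alt) if n_alt else None,
        "n_control": len(control_flags),
        "n_control_paired": sum(bool(f) for f in control_flags),
        "fraction_control_paired": (
            sum(bool(f) for f in control_flags) / len(control_flags)
            if control_flags
            else None
        ),
    }
    if not control_flags:
        warnings.warn("empty control set: control fraction is undefined")
    return out


def write_bedpe(
    pairs: Sequence[tuple[str, ComplementaryPair]], path
) -> None:
    """Pairs as BEDPE (chrom per arm; both arms on one chromosome here);
    two extra columns carry alignment length and identity."""
    with open(path, "w") as fh:
        for i, (chrom, p) in enumerate(pairs):
            fh.write(
                "\t".join(
                    [
                        chrom, str(p.arm1[0]), str(p.arm1[1]),
                        chrom, str(p.arm2[0]), str(p.arm2[1]),
                        f"pair{i + 1}", str(p.score), "+", "-",
                        str(p.length), repr(p.identity),
                    ]
                )
                + "\n"
            )


def read_bedpe(path) -> list[tuple[str, ComplementaryPair]]:
    out = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"line {line_no}: expected 12 BEDPE columns")
            if f[0] != f[3]:
                raise ValueError(f"line {line_no}: arms on different chromosomes")
            out.append(
                (
                    f[0],
                    ComplementaryPair(
                        arm1=(int(f[1]), int(f[2])),
                        arm2=(int(f[4]), int(f[5])),
                        length=int(f[10]),
                        identity=float(f[11]),
                        score=int(f[7]),
                    ),
                )
            )
    return out
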