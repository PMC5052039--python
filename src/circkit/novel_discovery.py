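"""Discovery and characterization of unannotated exons in circRNA loci.

Novelty is tested against the union of the reference annotation sources
(refseq / known_genes / ensembl — anything not tagged ``assembled``); an
exon present in any one of them is not novel.  Splice-site strength is a
PWM log-odds score trained on annotated sites: 9-nt donor windows
(3 exonic + 6 intronic) and 23-nt acceptor windows (20 intronic +
3 exonic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .circ_annotate import CircRNARecord
from .genome_annotation import (
    GeneModel,
    GenomeSequence,
    reverse_complement,
)
from .junction_io import LinearJunction

__all__ = [
    "NovelExon",
    "SpliceStrengthModel",
    "DONOR_WINDOW",
    "ACCEPTOR_WINDOW",
    "discover_novel_exons",
    "train_splice_strength",
    "score_splice_site",
    "donor_window",
    "acceptor_window",
    "characterize_exons",
]

BASES = "ACGT"
DONOR_WINDOW = (3, 6)  # exonic, intronic nt
ACCEPTOR_WINDOW = (20, 3)  # intronic, exonic nt


@dataclass(frozen=True)
class NovelExon:
    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("exon start must be < end")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class SpliceStrengthModel:
    donor_pwm: np.ndarray  # shape (9, 4), probabilities
    acceptor_pwm: np.ndarray  # shape (23, 4)
    background: np.ndarray  # shape (4,)
    n_donors: int
    n_acceptors: int

    def consensus(self, kind: str) -> str:
        pwm = self.donor_pwm if kind == "donor" else self.acceptor_pwm
        return "".join(BASES[i] for i in pwm.argmax(axis=1))


def _exon_has_canonical_sites(
    genome: GenomeSequence, chrom: str, start: int, end: int, strand: str
) -> bool:
    n = genome.lengths[chrom]
    if start < 2 or end + 2 > n:
        return False
    before = genome.slice(chrom, start - 2, start)
    after = genome.slice(chrom, end, end + 2)
    if strand == "+":
        return before == "AG" and after == "GT"
    return before == "AC" and after == "CT"


def discover_novel_exons(
    circ_records: Sequence[CircRNARecord],
    linear_junctions: Sequence[LinearJunction],
    reference_models: Sequence[GeneModel],
    assembled_models: Sequence[GeneModel] = (),
    genome: GenomeSequence | None = None,
    require_canonical: bool = True,
) -> list[NovelExon]:
    """Unannotated exon candidates inside circRNA spans.

    Candidates come from (a) assembled-model exons overlapping a circRNA
    span and (b) intervals bounded by two linear-junction ends inside a
    span whose implied splice sites carry strand-appropriate GT/AG motifs.
    Candidates matching a reference exon exactly, or fully contained in
    one, are dropped.
    """
    if require_canonical and genome is None:
        raise ValueError("a genome is required for the canonical-motif check")
    ref_exact = set()
    ref_by_strand: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in reference_models:
        if m.source_tag == "assembled":
            continue
        for s, e in m.exons:
            ref_exact.add((m.chrom, m.strand, s, e))
            ref_by_strand.setdefault((m.chrom, m.strand), []).append((s, e))

    spans: list[tuple[str, str, int, int, str]] = [
        (r.chrom, r.strand, r.start, r.end, r.gene_name)
        for r in circ_records
        if r.strand in ("+", "-")
    ]

    candidates: dict[tuple[str, int, int, str], dict] = {}

    def add(chrom, s, e, strand, gene, evidence):
        rec = candidates.setdefault(
            (chrom, s, e, strand), {"gene": gene, "evidence": set()}
        )
        rec["evidence"].add(evidence)

    for m in assembled_models:
        for s, e in m.exons:
            for chrom, strand, cs, ce, gene in spans:
                if m.chrom == chrom and m.strand == strand and s < ce and cs < e:
                    add(m.chrom, s, e, m.strand, gene, f"assembled:{m.isoform_name}")

    # junction-bounded intervals: exon [x, y) implied by one junction
    # ending at x (acceptor side on +) and another starting at y
    by_chrom: dict[str, list[LinearJunction]] = {}
    for j in linear_junctions:
        by_chrom.setdefault(j.chrom, []).append(j)
    for chrom, strand, cs, ce, gene in spans:
        js = [
            j
            for j in by_chrom.get(chrom, [])
            if cs <= j.start and j.end <= ce and j.strand in (strand, ".")
        ]
        ends_at = sorted({j.end for j in js})
        starts_at = sorted({j.start for j in js})
        boundaries = sorted(set(ends_at) | set(starts_at))
        for x in ends_at:
            for y in starts_at:
                if x >= y:
                    continue
                # a single exon has no splice evidence strictly inside it
                if any(x < b < y for b in boundaries):
                    continue
                if require_canonical and not _exon_has_canonical_sites(
                    genome, chrom, x, y, strand
                ):
                    continue
                add(chrom, x, y, strand, gene, f"junctions:{chrom}:{x}-{y}")

    novel = []
    for (chrom, s, e, strand), rec in sorted(candidates.items()):
        if (chrom, strand, s, e) in ref_exact:
            continue
        contained = any(
            rs <= s and e <= re for rs, re in ref_by_strand.get((chrom, strand), [])
        )
        if contained:
            continue
        novel.append(
            NovelExon(
                chrom=chrom, start=s, end=e, strand=strand,
                gene_name=rec["gene"],
                evidence=tuple(sorted(rec["evidence"])),
            )
        )
    return novel


def donor_window(genome: GenomeSequence, chrom: str, donor: int, strand: str) -> str:
    """9-nt donor window (3 exonic + 6 intronic) in transcript orientation.

    ``donor`` is the genomic exon-end boundary on +, exon-start on -.
    """
    exonic, intronic = DONOR_WINDOW
    if strand == "+":
        return genome.slice(chrom, donor - exonic, donor + intronic)
    return reverse_complement(genome.slice(chrom, donor - intronic, donor + exonic))


def acceptor_window(genome: GenomeSequence, chrom: str, acceptor: int, strand: str) -> str:
    """23-nt acceptor window (20 intronic + 3 exonic), transcript orientation."""
    intronic, exonic = ACCEPTOR_WINDOW
    if strand == "+":
        return genome.slice(chrom, acceptor - intronic, acceptor + exonic)
    return reverse_complement(genome.slice(chrom, acceptor - exonic, acceptor + intronic))


def _pwm_from_windows(windows: Sequence[str], length: int) -> np.ndarray:
    counts = np.ones((length, 4))  # pseudocount 1 per base per position
    idx = {b: i for i, b in enumerate(BASES)}
    for w in windows:
        for pos, base in enumerate(w):
            if base in idx:
                counts[pos, idx[base]] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def train_splice_strength(
    models: Sequence[GeneModel],
    genome: GenomeSequence,
    min_sites: int = 200,
) -> SpliceStrengthModel:
    """Train donor/acceptor PWMs on the internal splice sites of ``models``."""
    donor_seen, acceptor_seen = set(), set()
    donor_windows, acceptor_windows = [], []
    for m in models:
        for k in range(m.n_exons - 1):
            if m.strand == "+":
                donor, acceptor = m.exon_ends[k], m.exon_starts[k + 1]
            else:
                donor, acceptor = m.exon_starts[k + 1], m.exon_ends[k]
            dkey = (m.chrom, m.strand, donor)
            akey = (m.chrom, m.strand, acceptor)
            try:
                if dkey not in donor_seen:
                    donor_windows.append(donor_window(genome, m.chrom, donor, m.strand))
                    donor_seen.add(dkey)
                if akey not in acceptor_seen:
                    acceptor_windows.append(
                        acceptor_window(genome, m.chrom, acceptor, m.strand)
                    )
                    acceptor_seen.add(akey)
            except ValueError:
                continue  # window runs off the contig
    if len(donor_windows) < min_sites or len(acceptor_windows) < min_sites:
        raise ValueError(
            f"need >= {min_sites} training donors and acceptors, got "
            f"{len(donor_windows)}/{len(acceptor_windows)}"
        )
    all_nt = "".join(donor_windows) + "".join(acceptor_windows)
    bg_counts = np.array([all_nt.count(b) + 1 for b in BASES], dtype=float)
    return SpliceStrengthModel(
        donor_pwm=_pwm_from_windows(donor_windows, sum(DONOR_WINDOW)),
        acceptor_pwm=_pwm_from_windows(acceptor_windows, sum(ACCEPTOR_WINDOW)),
        background=bg_counts / bg_counts.sum(),
        n_donors=len(donor_windows),
        n_acceptors=len(acceptor_windows),
    )


def score_splice_site(model: SpliceStrengthModel, window: str, kind: str) -> float:
    """Log-odds score in bits: sum over positions of log2(weight/background)."""
    pwm = model.donor_pwm if kind == "donor" else model.acceptor_pwm
    if kind not in ("donor", "acceptor"):
        raise ValueError(f"kind must be donor or acceptor, got {kind!r}")
    if len(window) != pwm.shape[0]:
        raise ValueError(
            f"{kind} window must be {pwm.shape[0]} nt, got {len(window)}"
        )
    idx = {b: i for i, b in enumerate(BASES)}
    score = 0.0
    for pos, base in enumerate(window.upper()):
        if base not in idx:  # N scores at background (contributes 0)
            continue
        score += math.log2(pwm[pos, idx[base]] / model.background[idx[base]])
    return score


def characterize_exons(
    exons: Sequence[NovelExon],
    genome: GenomeSequence,
    strength_model: SpliceStrengthModel,
    ese_motifs: Sequence[str] = (),
) -> list[dict]:
    """Per-exon GC fraction, splice-site strengths, and ESE density per kb.

    Overlapping ESE motif matches are counted.  Exons of only-N sequence
    get ``gc_fraction=None`` rather than an error.
    """
    rows = []
    motifs = [m.upper() for m in ese_motifs]
    for ex in exons:
        seq = genome.slice(ex.chrom, ex.start, ex.end, ex.strand)
        acgt = sum(seq.count(b) for b in BASES)
        gc = (seq.count("G") + seq.count("C")) / acgt if acgt else None
        donor_coord = ex.end if ex.strand == "+" else ex.start
        acceptor_coord = ex.start if ex.strand == "+" else ex.end
        try:
            dscore = score_splice_site(
                strength_model,
                donor_window(genome, ex.chrom, donor_coord, ex.strand),
                "donor",
            )
            ascore = score_splice_site(
                strength_model,
                acceptor_window(genome, ex.chrom, acceptor_coord, ex.strand),
                "acceptor",
            )
        except ValueError:
            dscore = ascore = None
        hits = 0
        for motif in motifs:
            for i in range(len(seq) - len(motif) + 1):
                if seq[i : i + len(motif)] == motif:
                    hits += 1
        rows.append(
            {
                "chrom": ex.chrom,
                "start": ex.start,
                "end": ex.end,
                "strand": ex.strand,
                "gene_name": ex.gene_name,
                "gc_fraction": gc,
                "donor_score": dscore,
                "acceptor_score": ascore,
                "ese_density_per_kb": 1000.0 * hits / len(seq),
            }
        )
    return rows


def write_novel_exons(exons: Iterable[NovelExon], path) -> None:
    with open(path, "w") as fh:
        for ex in sorted(exons, key=lambda e: e.key):
            fh.write(
                f"{ex.chrom}\t{ex.start}\t{ex.end}\t{ex.gene_name}\t0\t{ex.strand}\t"
                + ";".join(ex.evidence)
                + "\n"
            )
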