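"""Seeded synthetic-data generator with ground truth.

Produces a random genome, gene models with canonical GT/AG splice
motifs, planted circRNA loci (optionally with alternative back-splice
sites, internal cassette/retention/alt-SS designs, and intronic
complementary elements), and junction/boundary evidence files per
library, all byte-reproducible from one integer seed.

Evidence is emitted at junction-count level (the formats the pipeline
reads), not as raw reads.  Library semantics: p(A)+ libraries carry
linear junctions only; p(A)- libraries carry circRNA-derived junctions
inside circ spans plus linear junctions outside them; p(A)-/RNase R
libraries carry circRNA-derived junctions only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_annotation import (
    GeneModel,
    GenomeSequence,
    reverse_complement,
    write_genepred,
)
from .junction_io import (
    BackSpliceJunction,
    LibraryInfo,
    LinearJunction,
    write_boundary_counts,
    write_junction_bed,
    write_samples_yaml,
)

__all__ = ["LibraryDesign", "CircLocusDesign", "SimConfig", "SimOutput", "generate", "evaluate"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class LibraryDesign:
    library_id: str
    rna_fraction: str
    total_mapped_reads: int = 1_000_000
    cell_line: str = "CL1"
    backsplice_depth: int = 100  # junction reads per circ locus
    linear_depth: int = 100  # reads per linear junction / splicing design

    def info(self) -> LibraryInfo:
        return LibraryInfo(
            self.library_id, self.rna_fraction, self.total_mapped_reads, self.cell_line
        )


@dataclass(frozen=True)
class CircLocusDesign:
    """One planted circRNA locus.

    ``spans`` are inclusive (first_exon, last_exon) ordinal pairs into the
    host gene's genomic exon order; all spans share the same first exon
    (shared genomic-start back-splice boundary), so >= 2 spans make an
    alternative event (alt5BS on + genes, alt3BS on - genes).
    """

    gene_index: int
    spans: tuple[tuple[int, int], ...]
    fractions: tuple[float, ...] = (1.0,)
    cassette: dict | None = None  # {"exon": k, "p_circ": x, "p_lin": y}
    retained_intron: dict | None = None  # {"after_exon": k, "pir_circ": x, "pir_lin": y}
    altss: dict | None = None  # {"after_exon": k, "shift": nt, "usage_circ": [...], "usage_lin": [...]}
    elements: str = "none"  # none | proximal | distal | both | self

    def __post_init__(self) -> None:
        if len(self.spans) != len(self.fractions):
            raise ValueError("spans and fractions must align")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        firsts = {s[0] for s in self.spans}
        if len(firsts) != 1:
            raise ValueError("all spans must share the first exon")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (300, 800)
    intergenic: int = 500
    chrom: str = "chr1"
    n_circ_loci: int = 5
    alt_fraction: float = 0.5  # fraction of auto loci given two alternative spans
    proximal_p: float = 0.5  # true proximal usage for auto alternative loci
    jitter: int = 0
    withhold_fraction: float = 0.0  # internal exons withheld from the reference
    element_len: int = 60
    libraries: tuple[LibraryDesign, ...] = (
        LibraryDesign("LIB_PAM", "pA_minus"),
        LibraryDesign("LIB_PAP", "pA_plus"),
        LibraryDesign("LIB_RNR", "pA_minus_RNaseR"),
    )
    circ_designs: tuple[CircLocusDesign, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_fraction <= 1.0 and 0.0 <= self.proximal_p <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if not (0.0 <= self.withhold_fraction <= 1.0):
            raise ValueError("withhold_fraction must be in [0, 1]")
        if self.exon_len[0] > self.exon_len[1] or self.intron_len[0] > self.intron_len[1]:
            raise ValueError("length ranges must be (low, high) with low <= high")
        if self.intron_len[0] < self.element_len + 20:
            raise ValueError("introns too short to host complementary elements")


@dataclass
class SimOutput:
    genome: GenomeSequence
    truth_models: list[GeneModel]
    reference_models: list[GeneModel]
    libraries: dict[str, LibraryInfo]
    backsplice: dict[str, list[BackSpliceJunction]]
    linear: dict[str, list[LinearJunction]]
    boundary_counts: dict
    manifest: dict
    outdir: Path | None = None


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)].copy()


def _write_motifs(seq: np.ndarray, model: GeneModel) -> None:
    """Stamp canonical splice dinucleotides at every intron boundary."""
    for gs, ge in model.introns:
        if model.strand == "+":
            seq[gs : gs + 2] = np.frombuffer(b"GT", dtype="S1")
            seq[ge - 2 : ge] = np.frombuffer(b"AG", dtype="S1")
        else:
            seq[gs : gs + 2] = np.frombuffer(b"CT", dtype="S1")
            seq[ge - 2 : ge] = np.frombuffer(b"AC", dtype="S1")


def _plant(seq: np.ndarray, pos: int, element: str) -> None:
    seq[pos : pos + len(element)] = np.frombuffer(element.encode(), dtype="S1")


def _auto_designs(cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator):
    """Default circ loci: spans start at exon 1 so every back-splice
    boundary has a flanking intron on both sides."""
    designs = []
    usable = [i for i, g in enumerate(genes) if g.n_exons >= 4]
    chosen = list(rng.choice(usable, size=min(cfg.n_circ_loci, len(usable)), replace=False))
    for gi in sorted(chosen):
        g = genes[gi]
        is_alt = rng.random() < cfg.alt_fraction and g.n_exons >= 5
        if is_alt:
            spans = ((1, g.n_exons - 3), (1, g.n_exons - 2))
            fractions = (cfg.proximal_p, 1.0 - cfg.proximal_p)
            elements = "both"
        else:
            spans = ((1, g.n_exons - 2),)
            fractions = (1.0,)
            elements = "none"
        cassette = None
        if not is_alt and g.n_exons >= 5:
            cassette = {"exon": 2, "p_circ": 0.8, "p_lin": 0.2}
        designs.append(
            CircLocusDesign(
                gene_index=gi,
                spans=spans,
                fractions=fractions,
                cassette=cassette,
                elements=elements,
            )
        )
    return designs


def _locus_geometry(design: CircLocusDesign, gene: GeneModel) -> dict:
    """Genomic coordinates derived from a design (spans, sites, introns)."""
    spans = []
    for first, last in design.spans:
        if not (0 <= first <= last < gene.n_exons):
            raise ValueError(
                f"span {first}-{last} out of bounds for {gene.isoform_name}"
            )
        spans.append((gene.exon_starts[first], gene.exon_ends[last]))
    return {"spans": spans}


def generate(cfg: SimConfig, outdir: str | Path | None = None) -> SimOutput:
    """Generate the full synthetic fixture set (and optionally write it)."""
    rng = np.random.default_rng(cfg.seed)

    # --- gene geometry ---------------------------------------------------
    genes: list[GeneModel] = []
    pos = 0
    for gi in range(cfg.n_genes):
        pos += cfg.intergenic
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        starts, ends = [], []
        for k in range(n_ex):
            if k > 0:
                pos += int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
            starts.append(pos)
            pos += int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
            ends.append(pos)
        genes.append(
            GeneModel(
                gene_name=f"G{gi + 1}",
                isoform_name=f"G{gi + 1}.t1",
                chrom=cfg.chrom,
                strand=strand,
                exon_starts=tuple(starts),
                exon_ends=tuple(ends),
                source_tag="synthetic",
            )
        )
    chrom_len = pos + cfg.intergenic
    seq = _rand_seq(rng, chrom_len)
    for g in genes:
        _write_motifs(seq, g)

    designs = (
        list(cfg.circ_designs)
        if cfg.circ_designs is not None
        else _auto_designs(cfg, genes, rng)
    )
    for d in designs:
        _locus_geometry(d, genes[d.gene_index])  # validate early

    # --- alt-SS shifted acceptor motifs ----------------------------------
    for d in designs:
        if d.altss:
            g = genes[d.gene_index]
            k = d.altss["after_exon"]
            shift = d.altss["shift"]
            if g.strand == "+":
                alt_acc = g.exon_starts[k + 1] + shift  # into the exon
                seq[alt_acc - 2 : alt_acc] = np.frombuffer(b"AG", dtype="S1")
            else:
                alt_acc = g.exon_ends[k] - shift
                seq[alt_acc : alt_acc + 2] = np.frombuffer(b"CT", dtype="S1")

    # --- complementary elements ------------------------------------------
    planted_elements = []
    for li, d in enumerate(designs):
        if d.elements == "none":
            continue
        g = genes[d.gene_index]
        element = "".join(np.char.decode(_rand_seq(rng, cfg.element_len), "ascii"))
        first = d.spans[0][0]
        if first == 0 and g.tx_start - cfg.intergenic < 0:
            raise ValueError("no room for an upstream element")
        # common intron: genomically adjacent to the shared start boundary
        if first > 0:
            common = (g.exon_ends[first - 1], g.exon_starts[first])
        else:
            common = (max(0, g.tx_start - cfg.intergenic + 20), g.tx_start)
        mid = (common[0] + common[1] - cfg.element_len) // 2
        _plant(seq, mid, element)
        planted_elements.append([cfg.chrom, mid, mid + cfg.element_len, f"L{li}", "fwd"])

        def far_intron(last_exon: int) -> tuple[int, int] | None:
            if last_exon < g.n_exons - 1:
                return (g.exon_ends[last_exon], g.exon_starts[last_exon + 1])
            return None

        targets = []
        if d.elements in ("proximal", "both") or d.elements == "self":
            targets.append(d.spans[0][1])
        if d.elements in ("distal", "both") and len(d.spans) > 1:
            targets.append(d.spans[-1][1])
        for last_exon in targets:
            intron = far_intron(last_exon)
            if intron is None:
                continue
            mid2 = (intron[0] + intron[1] - cfg.element_len) // 2
            _plant(seq, mid2, reverse_complement(element))
            planted_elements.append(
                [cfg.chrom, mid2, mid2 + cfg.element_len, f"L{li}", "rev"]
            )

    genome = GenomeSequence({cfg.chrom: b"".join(seq).decode("ascii")})

    # --- withheld ("novel") exons ----------------------------------------
    span_bounds = set()
    for d in designs:
        g = genes[d.gene_index]
        for first, last in d.spans:
            span_bounds.add((d.gene_index, first))
            span_bounds.add((d.gene_index, last))
    cassette_exons = {
        (d.gene_index, d.cassette["exon"]) for d in designs if d.cassette
    }
    withholdable = [
        (gi, k)
        for gi, g in enumerate(genes)
        for k in range(1, g.n_exons - 1)
        if (gi, k) not in span_bounds and (gi, k) not in cassette_exons
    ]
    n_withhold = int(round(cfg.withhold_fraction * len(withholdable)))
    withheld = set()
    if n_withhold:
        picks = rng.choice(len(withholdable), size=n_withhold, replace=False)
        withheld = {withholdable[i] for i in sorted(picks)}

    reference_models = []
    for gi, g in enumerate(genes):
        keep = [k for k in range(g.n_exons) if (gi, k) not in withheld]
        reference_models.append(
            GeneModel(
                g.gene_name, g.isoform_name, g.chrom, g.strand,
                tuple(g.exon_starts[k] for k in keep),
                tuple(g.exon_ends[k] for k in keep),
                g.source_tag,
            )
        )
    withheld_exons = sorted(
        [cfg.chrom, genes[gi].exon_starts[k], genes[gi].exon_ends[k],
         genes[gi].strand, genes[gi].gene_name]
        for gi, k in withheld
    )

    # --- evidence emission ------------------------------------------------
    libraries = {ld.library_id: ld.info() for ld in cfg.libraries}
    backsplice: dict[str, list[BackSpliceJunction]] = {l: [] for l in libraries}
    linear: dict[str, list[LinearJunction]] = {l: [] for l in libraries}
    boundary_counts: dict = {}
    truth_loci = []

    circ_span_set = []
    for d in designs:
        g = genes[d.gene_index]
        for first, last in d.spans:
            circ_span_set.append((g.exon_starts[first], g.exon_ends[last]))

    def in_circ_span(s: int, e: int) -> bool:
        return any(cs <= s and e <= ce for cs, ce in circ_span_set)

    for ld in cfg.libraries:
        lib = ld.library_id
        is_circ_lib = ld.rna_fraction in ("pA_minus", "pA_minus_RNaseR")
        is_rnaser = ld.rna_fraction == "pA_minus_RNaseR"
        lin_counts: dict[tuple[int, int, str], int] = {}

        def add_linear(s: int, e: int, strand: str, n: int) -> None:
            if n > 0:
                key = (s, e, strand)
                lin_counts[key] = lin_counts.get(key, 0) + n

        # back-splice junctions (multinomial over alternative spans)
        if is_circ_lib:
            for li, d in enumerate(designs):
                g = genes[d.gene_index]
                geo = _locus_geometry(d, g)
                counts = rng.multinomial(ld.backsplice_depth, d.fractions)
                for (s, e), n in zip(geo["spans"], counts):
                    if n < 1:
                        continue
                    js, je = s, e
                    if cfg.jitter:
                        js += int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                        je += int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                    backsplice[lib].append(
                        BackSpliceJunction(cfg.chrom, js, je, int(n), g.strand, lib)
                    )

        # linear / circ-internal splice junctions per gene
        for gi, g in enumerate(genes):
            locus = next((d for d in designs if d.gene_index == gi), None)
            cassette_k = locus.cassette["exon"] if locus and locus.cassette else None
            retained_k = (
                locus.retained_intron["after_exon"]
                if locus and locus.retained_intron
                else None
            )
            altss_k = locus.altss["after_exon"] if locus and locus.altss else None
            for k in range(g.n_exons - 1):
                gs, ge = g.exon_ends[k], g.exon_starts[k + 1]
                inside = in_circ_span(gs, ge)
                if is_rnaser and not inside:
                    continue  # RNase R digests linear-only molecules
                emit_depth = ld.backsplice_depth if (is_circ_lib and inside) else ld.linear_depth
                # cassette handling: junctions around the cassette exon
                if cassette_k is not None and k in (cassette_k - 1, cassette_k):
                    if k == cassette_k - 1:  # emit the whole trio once
                        p = (
                            locus.cassette["p_circ"]
                            if (is_circ_lib and inside)
                            else locus.cassette["p_lin"]
                        )
                        n_inc, n_skip = rng.multinomial(emit_depth, [p, 1.0 - p])
                        ex_s = g.exon_starts[cassette_k]
                        ex_e = g.exon_ends[cassette_k]
                        prev_end = g.exon_ends[cassette_k - 1]
                        next_start = g.exon_starts[cassette_k + 1]
                        add_linear(prev_end, ex_s, g.strand, int(n_inc))
                        add_linear(ex_e, next_start, g.strand, int(n_inc))
                        add_linear(prev_end, next_start, g.strand, int(n_skip))
                    continue
                if retained_k is not None and k == retained_k:
                    pir = (
                        locus.retained_intron["pir_circ"]
                        if (is_circ_lib and inside)
                        else locus.retained_intron["pir_lin"]
                    )
                    n_ret, n_spl = rng.multinomial(emit_depth, [pir, 1.0 - pir])
                    add_linear(gs, ge, g.strand, int(n_spl))
                    if n_ret > 0:
                        boundary_counts[(lib, cfg.chrom, gs, ge, g.strand)] = (
                            int(n_ret),
                            int(n_ret),
                        )
                    continue
                if altss_k is not None and k == altss_k:
                    shift = locus.altss["shift"]
                    usage = (
                        locus.altss["usage_circ"]
                        if (is_circ_lib and inside)
                        else locus.altss["usage_lin"]
                    )
                    ns = rng.multinomial(emit_depth, usage)
                    if g.strand == "+":
                        sites = [ge, ge + shift]  # canonical and shifted acceptor
                        for site, n in zip(sites, ns):
                            add_linear(gs, site, g.strand, int(n))
                    else:
                        sites = [gs, gs - shift]
                        for site, n in zip(sites, ns):
                            add_linear(site, ge, g.strand, int(n))
                    continue
                add_linear(gs, ge, g.strand, emit_depth)
        linear[lib] = [
            LinearJunction(cfg.chrom, s, e, n, strand, lib)
            for (s, e, strand), n in sorted(lin_counts.items())
        ]

    # --- ground truth manifest -------------------------------------------
    for li, d in enumerate(designs):
        g = genes[d.gene_index]
        geo = _locus_geometry(d, g)
        event_type = None
        if len(d.spans) > 1:
            event_type = "alt5BS" if g.strand == "+" else "alt3BS"
        entry = {
            "locus_id": f"L{li}",
            "gene": g.gene_name,
            "chrom": cfg.chrom,
            "strand": g.strand,
            "spans": [list(sp) for sp in geo["spans"]],
            "exon_ranges": [list(sp) for sp in d.spans],
            "fractions": list(d.fractions),
            "event_type": event_type,
            "common_site": geo["spans"][0][0] if event_type else None,
            "elements": d.elements,
        }
        if d.cassette:
            k = d.cassette["exon"]
            entry["cassette"] = {
                "region": [g.exon_starts[k], g.exon_ends[k]],
                "p_circ": d.cassette["p_circ"],
                "p_lin": d.cassette["p_lin"],
            }
        if d.retained_intron:
            k = d.retained_intron["after_exon"]
            entry["retained_intron"] = {
                "region": [g.exon_ends[k], g.exon_starts[k + 1]],
                "pir_circ": d.retained_intron["pir_circ"],
                "pir_lin": d.retained_intron["pir_lin"],
            }
        if d.altss:
            entry["altss"] = dict(d.altss)
        truth_loci.append(entry)

    manifest = {
        "seed": cfg.seed,
        "chrom": cfg.chrom,
        "chrom_length": chrom_len,
        "genes": [
            {
                "gene_name": g.gene_name,
                "isoform_name": g.isoform_name,
                "strand": g.strand,
                "exon_starts": list(g.exon_starts),
                "exon_ends": list(g.exon_ends),
            }
            for g in genes
        ],
        "circ_loci": truth_loci,
        "withheld_exons": withheld_exons,
        "planted_elements": planted_elements,
        "jitter": cfg.jitter,
        "libraries": [dataclasses.asdict(ld) for ld in cfg.libraries],
    }

    out = SimOutput(
        genome=genome,
        truth_models=genes,
        reference_models=reference_models,
        libraries=libraries,
        backsplice=backsplice,
        linear=linear,
        boundary_counts=boundary_counts,
        manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(outdir / "genome.fa")
        write_genepred(reference_models, outdir / "reference.genepred")
        write_genepred(genes, outdir / "truth.genepred")
        write_samples_yaml(libraries.values(), outdir / "samples.yaml")
        for lib in sorted(libraries):
            write_junction_bed(backsplice[lib], outdir / f"{lib}.backsplice.bed")
            write_junction_bed(linear[lib], outdir / f"{lib}.linear.bed")
        write_boundary_counts(boundary_counts, outdir / "boundary_counts.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        out.outdir = outdir
    return out


def evaluate(
    manifest: Mapping,
    records: Sequence,
    events: Sequence = (),
    novel_exons: Sequence = (),
    competition_calls: Sequence = (),
) -> dict:
    """Recovery report: planted truth vs pipeline output.

    Coordinates are compared exactly; PCU against true fractions; novel
    exons as set precision/recall; competition verdicts against planted
    element placements.
    """
    truth_spans = set()
    for locus in manifest["circ_loci"]:
        for s, e in locus["spans"]:
            truth_spans.add((manifest["chrom"], s, e, locus["strand"]))
    found = {(r.chrom, r.start, r.end, r.strand) for r in records}
    tp = len(found & truth_spans)
    report = {
        "circ_precision": tp / len(found) if found else None,
        "circ_recall": tp / len(truth_spans) if truth_spans else None,
        "n_called": len(found),
        "n_truth": len(truth_spans),
    }

    pcu_errors = []
    truth_by_common = {
        (manifest["chrom"], l["strand"], l["common_site"]): l
        for l in manifest["circ_loci"]
        if l["event_type"]
    }
    for e in events:
        locus = truth_by_common.get((e.chrom, e.strand, e.common_site))
        if locus is None:
            continue
        true_prox = locus["fractions"][0]
        pcu_errors.append(abs(e.pcus[0] / 100.0 - true_prox))
    report["pcu_abs_errors"] = pcu_errors

    withheld = {
        (c, s, e, st) for c, s, e, st, _gene in manifest["withheld_exons"]
    }
    found_novel = {ex.key for ex in novel_exons}
    report["novel_true_positives"] = len(found_novel & withheld)
    report["novel_false_positives"] = len(found_novel - withheld)
    report["novel_false_negatives"] = len(withheld - found_novel)

    confusion: dict[str, dict[str, int]] = {}
    placements = {
        (manifest["chrom"], l["strand"], l["common_site"]): l["elements"]
        for l in manifest["circ_loci"]
        if l["event_type"]
    }
    for call in competition_calls:
        _etype, chrom, strand, common = call.event_key
        planted = placements.get((chrom, strand, common), "unknown")
        confusion.setdefault(planted, {})
        confusion[planted][call.verdict] = confusion[planted].get(call.verdict, 0) + 1
    report["competition_confusion"] = confusion
    return report
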