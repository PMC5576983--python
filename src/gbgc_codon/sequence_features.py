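"""Per-gene and per-gene-set codon usage and base-composition statistics.

This module turns sequences plus gene models into the quantities the rest
of the analysis consumes: codon count tables, relative synonymous codon
usage (RSCU), GC content at third codon positions (GC3), intronic GC (GCi)
and flanking-region GC (GC-flank).

RSCU of codon *y* for amino acid *x* encoded by ``n_x`` synonymous codons is

    RSCU_xy = C_xy / (A_x / n_x)

where ``C_xy`` is the observed count of codon *y* and ``A_x = sum_y C_xy``.
Under uniform synonymous usage every RSCU is 1, and for every amino acid the
RSCU values of its codons always average to 1.

Undefined quantities (an amino acid never observed, an intronless gene's
GCi, an all-N interval) are represented as ``float('nan')`` throughout.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERATE_AAS,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: contig names treated as mitochondrial and excluded from gene loading
MITOCHONDRIAL_NAMES = frozenset({"chrm", "mt", "chrmt", "m", "mito"})

Interval = tuple[int, int]


class MalformedCDSError(ValueError):
    """Raised when a coding sequence violates the CDS contract."""


@dataclass
class GeneModel:
    """A gene's canonical-transcript coordinates, 0-based half-open.

    ``tss`` and ``polya`` are genome coordinates of the transcription start
    and polyadenylation site; on the minus strand ``tss > polya``. ``start``
    and ``end`` give the strand-agnostic span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    polya: int
    cds_intervals: list[Interval]
    intron_intervals: list[Interval] = field(default_factory=list)
    flank_intervals: list[Interval] | None = None

    @property
    def start(self) -> int:
        return min(self.tss, self.polya)

    @property
    def end(self) -> int:
        return max(self.tss, self.polya)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class CodonUsageTable:
    """Counts of the 61 sense codons for a gene or a concatenated gene set."""

    counts: dict[str, int]
    n_codons_total: int
    skipped: int = 0
    source: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in table: {sorted(bad)}")
        if sum(self.counts.values()) != self.n_codons_total:
            raise ValueError("counts do not sum to n_codons_total")

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonUsageTable(
            counts=dict(merged),
            n_codons_total=self.n_codons_total + other.n_codons_total,
            skipped=self.skipped + other.skipped,
            source=None,
        )


def codon_counts(cds_sequence: str, source: str | None = None) -> CodonUsageTable:
    """Count sense codons in a coding sequence.

    The terminal stop codon, if present, is excluded. Codons containing N
    (or any non-ACGT character) are skipped and tallied in ``skipped``. An
    internal stop codon raises :class:`MalformedCDSError` naming its
    position.
    """
    seq = cds_sequence.upper()
    if len(seq) % 3 != 0:
        raise MalformedCDSError(
            f"CDS length {len(seq)} not divisible by 3" + (f" ({source})" if source else "")
        )
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: Counter[str] = Counter()
    skipped = 0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise MalformedCDSError(
                f"internal stop codon {codon} at codon {i} (nt {3 * i})"
                + (f" in {source}" if source else "")
            )
        if codon in CODON_TO_AA:
            counts[codon] += 1
        else:
            skipped += 1
    return CodonUsageTable(
        counts=dict(counts),
        n_codons_total=sum(counts.values()),
        skipped=skipped,
        source=source,
    )


def rscu(table: CodonUsageTable) -> pd.Series:
    """Relative synonymous codon usage over the 59 synonymous sense codons.

    Codons of amino acids with zero observations are NaN (undefined), never
    0/0. Met and Trp codons are excluded: with a single codon their RSCU is
    identically 1 and carries no information.
    """
    values: dict[str, float] = {}
    for aa in sorted(DEGENERATE_AAS):
        codons = AA_TO_CODONS[aa]
        a_x = sum(table.counts.get(c, 0) for c in codons)
        n_x = len(codons)
        for c in codons:
            values[c] = table.counts.get(c, 0) / (a_x / n_x) if a_x > 0 else math.nan
    return pd.Series(values, name=table.source).reindex(list(SYNONYMOUS_CODONS))


def gc3(table: CodonUsageTable, universe: str = "synonymous") -> float:
    """Fraction of counted codons whose third base is G or C.

    ``universe`` selects the codon set: ``"synonymous"`` (default, the 59
    codons of degenerate amino acids, matching the RSCU universe) or
    ``"sense"`` (all 61). NaN when no codon of the universe was counted.
    """
    if universe == "synonymous":
        codons: Sequence[str] = SYNONYMOUS_CODONS
    elif universe == "sense":
        codons = SENSE_CODONS
    else:
        raise ValueError(f"unknown codon universe: {universe!r}")
    total = sum(table.counts.get(c, 0) for c in codons)
    if total == 0:
        return math.nan
    gc = sum(table.counts.get(c, 0) for c in codons if c[2] in "GC")
    return gc / total


def partitioned_gc3(
    table: CodonUsageTable, partition
) -> tuple[float, float]:
    """GC3 restricted to mono- and multi-isoacceptor amino acids.

    ``partition`` is any object with ``mono`` and ``multi`` attributes (or a
    ``(mono, multi)`` pair) holding one-letter amino acid sets that together
    cover the 18 degenerate amino acids. Returns ``(gc3_mono, gc3_multi)``;
    an empty side yields NaN.
    """
    if hasattr(partition, "mono"):
        mono_aas, multi_aas = set(partition.mono), set(partition.multi)
    else:
        mono_aas, multi_aas = set(partition[0]), set(partition[1])
    if mono_aas | multi_aas != set(DEGENERATE_AAS) or (mono_aas & multi_aas):
        raise ValueError("partition must split exactly the 18 degenerate amino acids")

    def _subset_gc3(aas: set[str]) -> float:
        codons = [c for c in SYNONYMOUS_CODONS if CODON_TO_AA[c] in aas]
        total = sum(table.counts.get(c, 0) for c in codons)
        if total == 0:
            return math.nan
        gc = sum(table.counts.get(c, 0) for c in codons if c[2] in "GC")
        return gc / total

    return _subset_gc3(mono_aas), _subset_gc3(multi_aas)


def concat_usage(
    gene_ids: Iterable[str], tables: Mapping[str, CodonUsageTable], source: str | None = None
) -> CodonUsageTable:
    """Total codon usage of a gene set: elementwise sum of member tables.

    Equivalent to counting codons on the literal concatenation of the member
    coding sequences.
    """
    ids = list(gene_ids)
    missing = [g for g in ids if g not in tables]
    if missing:
        raise KeyError(f"unknown gene ids: {missing}")
    merged: Counter[str] = Counter()
    skipped = 0
    for g in ids:
        merged.update(tables[g].counts)
        skipped += tables[g].skipped
    return CodonUsageTable(
        counts=dict(merged),
        n_codons_total=sum(merged.values()),
        skipped=skipped,
        source=source,
    )


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N and other characters excluded.

    NaN for an empty or all-N sequence.
    """
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def gc_fraction_intervals(
    genome: Mapping[str, str], chrom: str, intervals: Iterable[Interval]
) -> float:
    """GC fraction over the union of 0-based half-open intervals."""
    seq = genome[chrom]
    merged = _merge_intervals(intervals)
    for s, e in merged:
        if s < 0 or e > len(seq):
            raise ValueError(f"interval ({s}, {e}) outside {chrom} (length {len(seq)})")
    return gc_fraction("".join(seq[s:e] for s, e in merged))


def _merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# gene model loading
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def cds_sequence(model: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenated CDS of a gene in reading orientation.

    Minus-strand genes are reverse-complemented so the returned string reads
    5'→3' in codons.
    """
    seq = genome[model.chrom]
    parts = [seq[s:e] for s, e in sorted(model.cds_intervals)]
    cds = "".join(parts)
    if model.strand == "-":
        cds = reverse_complement(cds)
    return cds


def load_gene_models(
    annotation, genome: Mapping[str, str] | None = None, *, filetype: str | None = None
) -> list[GeneModel]:
    """Load one canonical-transcript model per gene from GFF3 or BED12.

    Canonical transcript = longest total CDS, ties broken by lexicographic
    transcript id. Mitochondrial contigs are dropped. Genes whose CDS length
    is not divisible by 3 are excluded with a logged reason.
    """
    path = str(annotation)
    if filetype is None:
        low = path.lower()
        if low.endswith((".gff", ".gff3")):
            filetype = "gff3"
        elif low.endswith(".bed"):
            filetype = "bed12"
        else:
            raise ValueError(f"cannot infer annotation format from {path!r}")
    if filetype == "gff3":
        models = _load_gff3(path)
    elif filetype == "bed12":
        models = _load_bed12(path)
    else:
        raise ValueError(f"unknown annotation format {filetype!r}")

    kept: list[GeneModel] = []
    for m in models:
        if m.chrom.lower() in MITOCHONDRIAL_NAMES:
            logger.info("excluding mitochondrial gene %s on %s", m.gene_id, m.chrom)
            continue
        if m.cds_length % 3 != 0:
            logger.warning(
                "excluding gene %s: CDS length %d not divisible by 3",
                m.gene_id,
                m.cds_length,
            )
            continue
        if genome is not None and m.chrom not in genome:
            raise ValueError(f"gene {m.gene_id} references missing chromosome {m.chrom}")
        kept.append(m)
    return kept


def _load_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str, GeneModel] | None = None
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            cds = sorted(
                (f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")
            )
            if not cds:
                continue
            exons = sorted(
                (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
            )
            if not exons:
                exons = cds
            introns = [
                (exons[i][1], exons[i + 1][0])
                for i in range(len(exons) - 1)
                if exons[i + 1][0] > exons[i][1]
            ]
            start, end = tx.start - 1, tx.end
            strand = tx.strand if tx.strand in "+-" else "+"
            model = GeneModel(
                gene_id=gene.id,
                chrom=tx.seqid,
                strand=strand,
                tss=start if strand == "+" else end,
                polya=end if strand == "+" else start,
                cds_intervals=cds,
                intron_intervals=introns,
            )
            cds_len = model.cds_length
            key = (-cds_len, tx.id)
            if best is None or key < (-best[0], best[1]):
                best = (cds_len, tx.id, model)
        if best is not None:
            models.append(best[2])
    return models


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "item_rgb", "block_count",
    "block_sizes", "block_starts",
]


def _load_bed12(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    models: list[GeneModel] = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        exons = [
            (row.start + off, row.start + off + size)
            for off, size in zip(offsets, sizes)
        ]
        ts, te = int(row.thick_start), int(row.thick_end)
        cds = [(max(s, ts), min(e, te)) for s, e in exons if min(e, te) > max(s, ts)]
        introns = [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]
        strand = row.strand if row.strand in "+-" else "+"
        models.append(
            GeneModel(
                gene_id=str(row.name),
                chrom=str(row.chrom),
                strand=strand,
                tss=int(row.start) if strand == "+" else int(row.end),
                polya=int(row.end) if strand == "+" else int(row.start),
                cds_intervals=cds,
                intron_intervals=introns,
            )
        )
    return models


def flank_intervals(
    model: GeneModel,
    width: int,
    chrom_length: int,
    neighbor_spans: Sequence[Interval] = (),
) -> list[Interval]:
    """Up- and downstream flanks of a gene, trimmed to the chromosome and to
    annotated neighbouring gene spans (so GC-flank measures non-genic DNA).
    """
    up = (max(0, model.start - width), model.start)
    down = (model.end, min(chrom_length, model.end + width))
    out: list[Interval] = []
    for s, e in (up, down):
        for ns, ne in neighbor_spans:
            if ns >= e or ne <= s:
                continue
            # trim the side of the flank that the neighbour covers
            if ns <= s < ne:
                s = min(ne, e)
            if ns < e <= ne:
                e = max(ns, s)
        if e > s:
            out.append((s, e))
    return out


def gene_features(
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    *,
    cds_seqs: Mapping[str, str] | None = None,
    flank_width: int = 10_000,
    gc3_universe: str = "synonymous",
) -> pd.DataFrame:
    """Per-gene feature table: GC3, GCi, GC-flank, codon count.

    GCi is NaN for intronless genes; GC-flank uses ``flank_width`` bp on each
    side, trimmed to chromosome bounds and neighbouring gene spans.
    """
    spans_by_chrom: dict[str, list[Interval]] = {}
    for m in models:
        spans_by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    rows = []
    for m in models:
        cds = cds_seqs[m.gene_id] if cds_seqs is not None else cds_sequence(m, genome)
        table = codon_counts(cds, source=m.gene_id)
        neighbors = [
            sp for sp in spans_by_chrom[m.chrom] if sp != (m.start, m.end)
        ]
        flanks = flank_intervals(m, flank_width, len(genome[m.chrom]), neighbors)
        rows.append(
            {
                "gene_id": m.gene_id,
                "gc3": gc3(table, universe=gc3_universe),
                "gci": (
                    gc_fraction_intervals(genome, m.chrom, m.intron_intervals)
                    if m.intron_intervals
                    else math.nan
                ),
                "gc_flank": (
                    gc_fraction_intervals(genome, m.chrom, flanks) if flanks else math.nan
                ),
                "n_codons": table.n_codons_total,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
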