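"""Synthetic genomes with a GC-biased gene conversion (gBGC) causal chain.

The generator emits everything the analysis pipeline consumes — genome and
CDS FASTA, gene models, genetic maps, DSB hotspots, an expression matrix
with replicate structure, overlapping GO-like gene sets and a ground-truth
table — under two switchable generative regimes:

``gbgc``
    Synonymous codon choice is governed purely by a per-gene equilibrium GC
    shared by third codon positions, introns and flanks. Equilibrium GC
    follows the local long-term intragenic crossover rate (after
    expression-dependent suppression) through a logistic link, so the whole
    causal chain of the analysis — meiotic expression → intragenic
    recombination suppression → gBGC → GC3 — is physically present.

``trna_coadapted``
    The counterfactual world: codons of multi-isoacceptor amino acids
    follow per-program preferred-codon tables shared by co-expressed gene
    sets (tRNA-pool co-adaptation), while mono-isoacceptor codons remain
    GC-driven. The isoacceptor selection test must separate the regimes.

Everything is deterministic given ``(config, seed)``; independent random
streams per stage keep e.g. the expression matrix identical whether or not
sequences are generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._genetic_code import (
    AA_TO_CODONS,
    DEGENERATE_AAS,
    SYNONYMOUS_CODONS,
    reverse_complement,
)
from .gene_sets import GeneSetCollection
from .recombination import MB, GeneticMap
from .sequence_features import GeneModel

# fixed internals of the stated world (see docs/methods.md)
GRID_STEP = 10_000  # bp; resolution of the recombination landscape
LOG_RATE_SD = 0.7  # marginal sd of log crossover rate (few-fold variation)
INTERGENIC_GC = 0.40  # background GC of non-flank intergenic DNA
FLANK_REGION = 10_000  # bp of flank written at the flank equilibrium GC
HOTSPOTS_PER_CM = 10.0
HOTSPOT_WIDTH = 1_500  # bp
PREFERRED_CODON_PROB = 0.75  # usage of the preferred codon in trna regime
N_PROGRAMS = 30  # co-expression programs in the trna regime
STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the stated synthetic world.

    Defaults give four 20-Mb chromosomes carrying 2,000 non-overlapping
    genes of 5–15 kb, a 1-Mb-correlated crossover landscape averaging
    1.2 cM/Mb, strong (0.75) expression-rank-linear intragenic suppression
    and 600 overlapping gene sets of 40–400 genes tilted by meiotic
    expression.
    """

    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    isochore_scale: int = 1_000_000
    n_genes: int = 2_000
    gene_length_range: tuple[int, int] = (5_000, 15_000)
    base_rate: float = 1.2  # genome-mean crossover rate, cM/Mb
    gbgc_slope: float = 1.2  # d logit(eq. GC) / d ln(rate/base_rate)
    suppression_strength: float = 0.75
    expression_lognormal_params: tuple[float, float] = (1.7, 1.6)  # ln-FPKM mu, sigma
    replicate_sigma: float = 0.3  # ln-scale replicate noise around group means
    n_gene_sets: int = 600
    set_size_range: tuple[int, int] = (40, 400)
    expression_bias_of_sets: float = 1.0
    regime: Literal["gbgc", "trna_coadapted"] = "gbgc"
    noise_sd_gc: float = 0.02  # gaussian noise on equilibrium GC (fraction scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.isochore_scale,
               self.n_genes, self.n_gene_sets) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not (0.0 <= self.suppression_strength <= 1.0):
            raise ValueError("suppression_strength must lie in [0, 1]")
        if self.gbgc_slope < 0:
            raise ValueError("gbgc_slope must be >= 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.regime not in ("gbgc", "trna_coadapted"):
            raise ValueError(f"unknown regime {self.regime!r}")


@dataclass
class SyntheticDataset:
    """In-memory bundle of one simulated world plus its ground truth."""

    config: SyntheticConfig
    models: list[GeneModel]
    base_map: GeneticMap  # landscape before intragenic suppression
    genetic_map: GeneticMap  # landscape after suppression (the emitted map)
    hotspots: pd.DataFrame
    expression: pd.DataFrame
    sample_metadata: pd.DataFrame
    sets: GeneSetCollection
    set_names: dict[str, str]
    truth: pd.DataFrame  # indexed by gene_id
    genome: dict[str, str] | None = None
    cds: dict[str, str] | None = None

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.genome is not None:
            with open(out / "genome.fa", "w") as fh:
                for chrom, seq in self.genome.items():
                    fh.write(f">{chrom}\n")
                    for i in range(0, len(seq), 80):
                        fh.write(seq[i : i + 80] + "\n")
        if self.cds is not None:
            with open(out / "cds.fa", "w") as fh:
                for gid in sorted(self.cds):
                    fh.write(f">{gid}\n{self.cds[gid]}\n")
        write_gff3(self.models, out / "genes.gff3")
        write_bed12(self.models, out / "genes.bed")
        self.genetic_map.write_tsv(out / "genetic_map.tsv")
        self.base_map.write_tsv(out / "genetic_map_base.tsv")
        self.hotspots.to_csv(out / "hotspots.bed", sep="\t", header=False, index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.sample_metadata.to_csv(out / "sample_metadata.tsv", sep="\t", index=False)
        self.sets.write_gmt(out / "gene_sets.gmt", descriptions=self.set_names)
        self.truth.to_csv(out / "truth.tsv", sep="\t")


# ---------------------------------------------------------------------------
# stage 1: recombination landscape
# ---------------------------------------------------------------------------

def generate_recombination_landscape(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[GeneticMap, dict[str, np.ndarray]]:
    """Smooth positive crossover-rate field per chromosome.

    Log-rate is Gaussian-smoothed white noise (circular smoothing with
    kernel sigma = isochore_scale / 2, so autocorrelation decays to 1/e at
    roughly one isochore scale), rescaled to marginal sd ``LOG_RATE_SD``
    via the exact kernel norm, exponentiated, and finally rescaled so the
    genome-wide mean rate equals ``base_rate`` exactly.

    Returns the map and the per-chromosome grid rate fields (used by later
    stages).
    """
    n_cells = config.chrom_length // GRID_STEP
    if n_cells < 2:
        raise ValueError("chrom_length must cover at least 2 grid cells")
    sigma = max(config.isochore_scale / (2.0 * GRID_STEP), 1e-9)
    delta = np.zeros(n_cells)
    delta[n_cells // 2] = 1.0
    kernel_norm = float(np.sqrt(np.sum(gaussian_filter1d(delta, sigma, mode="wrap") ** 2)))
    fields: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        white = rng.standard_normal(n_cells)
        z = gaussian_filter1d(white, sigma, mode="wrap") / kernel_norm * LOG_RATE_SD
        fields[f"chr{c + 1}"] = config.base_rate * np.exp(z)
    mean_rate = float(np.mean(np.concatenate(list(fields.values()))))
    for chrom in fields:
        fields[chrom] *= config.base_rate / mean_rate
    segments = {
        chrom: (np.arange(n_cells + 1, dtype=float) * GRID_STEP, rates)
        for chrom, rates in fields.items()
    }
    return GeneticMap.from_rates(segments), fields


# ---------------------------------------------------------------------------
# stage 2: gene placement and expression-dependent suppression
# ---------------------------------------------------------------------------

def place_genes_and_suppress(
    config: SyntheticConfig,
    fields: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[list[GeneModel], GeneticMap, pd.DataFrame]:
    """Place non-overlapping genes, draw meiotic expression, and suppress
    intragenic crossover rate by f(e) = 1 − strength · rank(e)/n.

    Flanking DNA keeps the base landscape untouched; only [TSS, polyA) is
    multiplied by the gene's factor. Returns the models, the modified map
    and the truth table.
    """
    chroms = list(fields)
    lo, hi = config.gene_length_range
    n = config.n_genes
    lengths = rng.integers(lo, hi + 1, size=n)
    per_chrom = np.array_split(np.arange(n), len(chroms))
    min_gap = 2 * FLANK_REGION + 1_000

    models: list[GeneModel] = []
    gene_meta: list[dict] = []
    for chrom, idx in zip(chroms, per_chrom):
        k = len(idx)
        occupied = int(lengths[idx].sum()) + (k + 1) * min_gap
        if occupied > config.chrom_length:
            raise ValueError(
                f"genome too small: {chrom} needs {occupied} bp for {k} "
                f"non-overlapping genes but has {config.chrom_length}"
            )
        slack = config.chrom_length - occupied
        extra = np.floor(rng.dirichlet(np.ones(k + 1)) * slack).astype(int)
        pos = min_gap + extra[0]
        for j, gi in enumerate(idx):
            gene_len = int(lengths[gi])
            start, end = pos, pos + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                _gene_structure(f"G{gi:05d}", chrom, strand, start, end, rng)
            )
            gene_meta.append({"gene_id": f"G{gi:05d}", "chrom": chrom,
                              "start": start, "end": end, "strand": strand})
            pos = end + min_gap + extra[j + 1]

    mu, sigma = config.expression_lognormal_params
    expr = rng.lognormal(mu, sigma, size=len(models))
    order = np.argsort(np.argsort(expr, kind="stable"))  # 0-based ascending ranks
    factor = 1.0 - config.suppression_strength * (order + 1) / len(models)

    # base intragenic rate: length-weighted mean of the grid field over the gene
    base_rates = np.array(
        [
            _mean_grid_rate(fields[m["chrom"]], m["start"], m["end"])
            for m in gene_meta
        ]
    )
    suppressed_map = _apply_suppression(fields, gene_meta, factor)
    truth = pd.DataFrame(
        {
            "gene_id": [m["gene_id"] for m in gene_meta],
            "chrom": [m["chrom"] for m in gene_meta],
            "start": [m["start"] for m in gene_meta],
            "end": [m["end"] for m in gene_meta],
            "strand": [m["strand"] for m in gene_meta],
            "true_base_rate": base_rates,
            "suppression_factor": factor,
            "true_intragenic_rate": base_rates * factor,
            "meiotic_expression": expr,
            "regime": config.regime,
        }
    ).set_index("gene_id")
    return models, suppressed_map, truth


def _mean_grid_rate(field: np.ndarray, start: int, end: int) -> float:
    edges = np.arange(field.size + 1) * GRID_STEP
    overlap = np.clip(np.minimum(end, edges[1:]) - np.maximum(start, edges[:-1]), 0, None)
    return float(np.sum(field * overlap) / (end - start))


def _apply_suppression(
    fields: dict[str, np.ndarray], gene_meta: list[dict], factor: np.ndarray
) -> GeneticMap:
    segments = {}
    genes_by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in fields}
    for m, f in zip(gene_meta, factor):
        genes_by_chrom[m["chrom"]].append((m["start"], m["end"], float(f)))
    for chrom, field in fields.items():
        grid_edges = np.arange(field.size + 1, dtype=float) * GRID_STEP
        cuts = sorted(
            set(grid_edges.tolist())
            | {float(s) for s, _, _ in genes_by_chrom[chrom]}
            | {float(e) for _, e, _ in genes_by_chrom[chrom]}
        )
        bp = np.array(cuts)
        mids = (bp[:-1] + bp[1:]) / 2.0
        cell = np.clip((mids // GRID_STEP).astype(int), 0, field.size - 1)
        rates = field[cell].astype(float)
        for s, e, f in genes_by_chrom[chrom]:
            rates[(mids >= s) & (mids < e)] *= f
        segments[chrom] = (bp, rates)
    return GeneticMap.from_rates(segments)


def _gene_structure(
    gene_id: str, chrom: str, strand: str, start: int, end: int,
    rng: np.random.Generator,
) -> GeneModel:
    """Exon/intron structure: the CDS (including stop) is split into exons,
    introns fill the remaining transcription unit."""
    gene_len = end - start
    max_codons = (gene_len - 1_000) // 3
    n_codons = int(rng.integers(300, min(651, max_codons + 1)))
    cds_nt = 3 * n_codons + 3  # + stop codon
    n_exons = int(rng.integers(2, 7))
    intron_total = gene_len - cds_nt
    n_introns = n_exons - 1
    while n_introns > 0 and intron_total < 80 * n_introns:
        n_exons -= 1
        n_introns = n_exons - 1
    exon_sizes = _partition(cds_nt, n_exons, 30, rng)
    intron_sizes = _partition(intron_total, n_introns, 80, rng) if n_introns else []
    cds_intervals = []
    introns = []
    pos = start
    for i, ex in enumerate(exon_sizes):
        cds_intervals.append((pos, pos + ex))
        pos += ex
        if i < len(intron_sizes):
            introns.append((pos, pos + intron_sizes[i]))
            pos += intron_sizes[i]
    assert pos == end
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=start if strand == "+" else end,
        polya=end if strand == "+" else start,
        cds_intervals=cds_intervals,
        intron_intervals=introns,
    )


def _partition(total: int, parts: int, minimum: int, rng: np.random.Generator) -> list[int]:
    if parts == 1:
        return [total]
    slack = total - parts * minimum
    if slack < 0:
        raise ValueError("cannot partition")
    w = np.floor(rng.dirichlet(np.ones(parts)) * slack).astype(int)
    w[0] += slack - int(w.sum())
    return [minimum + int(x) for x in w]


# ---------------------------------------------------------------------------
# stage 3: expression matrix and gene sets
# ---------------------------------------------------------------------------

SAMPLE_GROUPS = [
    # (group, sex, cell_type, n_replicates, kind)
    ("female_meiotic", "F", "PGC_17w", 2, "meiotic"),
    ("male_meiotic", "M", "pachytene_spermatocyte", 3, "meiotic"),
    ("male_postmeiotic", "M", "round_spermatid", 3, "postmeiotic"),
    ("somatic_liver", "NA", "somatic", 2, "somatic"),
    ("somatic_brain", "NA", "somatic", 2, "somatic"),
    ("somatic_muscle", "NA", "somatic", 2, "somatic"),
]


def synthesize_expression_and_sets(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSetCollection, dict[str, str], pd.DataFrame]:
    """Replicated FPKM matrix plus overlapping, expression-tilted gene sets.

    Meiotic group means track the true meiotic expression (with mild
    per-sex divergence); somatic groups are fresh lognormal draws,
    uncorrelated with the meiotic truth. Set membership probability is
    exponentially tilted by the gene's meiotic expression rank with
    strength ``expression_bias_of_sets``; a fraction of sets carries
    proliferation- or differentiation-flavoured names tilted up or down,
    mirroring how proliferation-associated sets are enriched in genes
    highly expressed at meiosis.
    """
    genes = truth.index.to_list()
    n = len(genes)
    e = truth["meiotic_expression"].to_numpy()
    mu, sigma = config.expression_lognormal_params
    sr = config.replicate_sigma

    group_means: dict[str, np.ndarray] = {}
    for group, _sex, _ct, _reps, kind in SAMPLE_GROUPS:
        if kind in ("meiotic", "postmeiotic"):
            divergence = rng.lognormal(-0.25**2 / 2, 0.25, size=n)
            group_means[group] = e * divergence
        else:
            group_means[group] = rng.lognormal(mu, sigma, size=n)

    cols, meta_rows = {}, []
    for group, sex, ct, reps, kind in SAMPLE_GROUPS:
        for r in range(1, reps + 1):
            name = f"{group}_rep{r}"
            noise = (
                rng.lognormal(-sr**2 / 2, sr, size=n) if sr > 0 else np.ones(n)
            )
            cols[name] = group_means[group] * noise
            meta_rows.append(
                {"sample": name, "group": group, "sex": sex,
                 "cell_type": ct, "replicate": r, "kind": kind}
            )
    expression = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    metadata = pd.DataFrame(meta_rows)

    # gene sets: exponential tilt on the standardized expression rank
    rank = pd.Series(e, index=genes).rank(method="first").to_numpy()
    z = 2.0 * (rank / (n + 1) - 0.5)  # in (-1, 1)
    lo, hi = config.set_size_range
    if hi > n:
        raise ValueError("set_size_range exceeds number of genes")
    flavors = rng.choice(
        ["proliferation", "differentiation", "none"], size=config.n_gene_sets,
        p=[0.10, 0.20, 0.70],
    )
    programs = rng.integers(0, N_PROGRAMS, size=n)  # trna-regime co-expression
    set_programs = rng.integers(0, N_PROGRAMS, size=config.n_gene_sets)
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    prolif_names = ["mitotic cell cycle", "translation", "nucleosome assembly"]
    diff_names = ["development", "cell adhesion", "differentiation"]
    gene_arr = np.array(genes)
    for i in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        b = config.expression_bias_of_sets
        if flavors[i] == "proliferation":
            tilt = b * rng.uniform(0.5, 1.0)
            names_pool = prolif_names
        elif flavors[i] == "differentiation":
            tilt = -b * rng.uniform(0.5, 1.0)
            names_pool = diff_names
        else:
            tilt = b * rng.uniform(-1.0, 1.0)
            names_pool = None
        logw = 2.0 * tilt * z
        if config.regime == "trna_coadapted":
            logw = logw + 3.0 * (programs == set_programs[i])
        w = np.exp(logw - logw.max())
        members = rng.choice(gene_arr, size=size, replace=False, p=w / w.sum())
        set_id = f"SET:{i:04d}"
        sets[set_id] = frozenset(members.tolist())
        if names_pool is not None:
            names[set_id] = f"{names_pool[i % len(names_pool)]} process {i:04d}"
        else:
            names[set_id] = f"generic biological process {i:04d}"

    program_table = pd.DataFrame(
        {"gene_id": genes, "program": programs}
    ).set_index("gene_id")
    return expression, metadata, GeneSetCollection(sets), names, program_table


# ---------------------------------------------------------------------------
# stage 4: sequences
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """n bases with the given GC fraction, as uint8 ASCII."""
    is_gc = rng.random(n) < gc
    second = rng.integers(0, 2, size=n)  # A/T or C/G within class
    idx = np.where(is_gc, 1 + second, 3 * second)  # C/G else A/T
    return _BASES[idx]


def equilibrium_gc(config: SyntheticConfig, intragenic_rate: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """logistic(gbgc_slope · ln(rate / base_rate)) + N(0, noise_sd_gc),
    truncated into (0, 1). Slope 0 gives 0.5 exactly (plus noise)."""
    x = config.gbgc_slope * np.log(np.maximum(intragenic_rate, 1e-12) / config.base_rate)
    p = 1.0 / (1.0 + np.exp(-x))
    if config.noise_sd_gc > 0:
        p = p + rng.normal(0.0, config.noise_sd_gc, size=p.shape)
    return np.clip(p, 0.01, 0.99)


def _codon_weights_gc(aa: str, p: float) -> np.ndarray:
    w = np.array(
        [p / 2.0 if c[2] in "GC" else (1.0 - p) / 2.0 for c in AA_TO_CODONS[aa]]
    )
    return w / w.sum()


def _sample_cds(
    aa_choices: np.ndarray,
    p_gc: float,
    rng: np.random.Generator,
    preferred: dict[str, str] | None,
) -> str:
    """Codon string (without start/stop handling) for an amino acid array."""
    codons = np.empty(aa_choices.size, dtype="<U3")
    for aa in np.unique(aa_choices):
        pos = np.where(aa_choices == aa)[0]
        fam = AA_TO_CODONS[aa]
        if preferred is not None and aa in preferred:
            w = np.full(len(fam), (1.0 - PREFERRED_CODON_PROB) / len(fam))
            w[fam.index(preferred[aa])] += PREFERRED_CODON_PROB
        else:
            w = _codon_weights_gc(aa, p_gc)
        codons[pos] = rng.choice(np.array(fam), size=pos.size, p=w)
    return "".join(codons.tolist())


# amino-acid sampling weights: degenerate aas uniform, Met/Trp rare
_AA_POOL = sorted(DEGENERATE_AAS) + ["M", "W"]
_AA_WEIGHTS = np.array([1.0] * len(DEGENERATE_AAS) + [0.3, 0.3])
_AA_WEIGHTS /= _AA_WEIGHTS.sum()


def synthesize_sequences(
    config: SyntheticConfig,
    models: list[GeneModel],
    truth: pd.DataFrame,
    rng: np.random.Generator,
    *,
    program_table: pd.DataFrame | None = None,
    mode: Literal["full", "cds_only"] = "full",
) -> tuple[dict[str, str] | None, dict[str, str], pd.Series]:
    """Genome and CDS sequences realizing each gene's equilibrium GC.

    Third codon positions, introns and ``FLANK_REGION``-bp flanks share the
    gene's equilibrium GC; remaining intergenic DNA sits at the background
    GC. In the ``trna_coadapted`` regime, multi-isoacceptor codons of a
    gene follow its co-expression program's preferred-codon table instead
    of the GC rule; mono-isoacceptor codons stay GC-driven in both regimes.

    Returns ``(genome, cds, equilibrium_gc_by_gene)``; genome is None in
    ``cds_only`` mode.
    """
    eq_gc = equilibrium_gc(
        config, truth["true_intragenic_rate"].to_numpy(), rng
    )
    eq_by_gene = pd.Series(eq_gc, index=truth.index, name="equilibrium_gc")
    flank_gc = equilibrium_gc(
        replace(config, noise_sd_gc=0.0), truth["true_base_rate"].to_numpy(),
        rng,
    )
    flank_by_gene = pd.Series(flank_gc, index=truth.index)

    preferred_tables: list[dict[str, str]] | None = None
    gene_program: pd.Series | None = None
    if config.regime == "trna_coadapted":
        if program_table is None:
            raise ValueError("trna_coadapted regime needs the program table")
        from .isoacceptor import HUMAN_MULTI_AAS

        preferred_tables = []
        for _ in range(N_PROGRAMS):
            preferred_tables.append(
                {
                    aa: AA_TO_CODONS[aa][int(rng.integers(0, len(AA_TO_CODONS[aa])))]
                    for aa in sorted(HUMAN_MULTI_AAS)
                }
            )
        gene_program = program_table["program"]

    chrom_arrays: dict[str, np.ndarray] | None = None
    if mode == "full":
        chrom_arrays = {}
        chroms = sorted({m.chrom for m in models}, key=lambda c: int(c[3:]))
        for chrom in chroms:
            chrom_arrays[chrom] = _random_bases(config.chrom_length, INTERGENIC_GC, rng)

    cds_seqs: dict[str, str] = {}
    for m in models:
        p = float(eq_by_gene[m.gene_id])
        n_codons = m.cds_length // 3 - 2  # minus start and stop
        aa_choices = np.array(_AA_POOL)[
            rng.choice(len(_AA_POOL), size=n_codons, p=_AA_WEIGHTS)
        ]
        preferred = None
        if preferred_tables is not None:
            preferred = preferred_tables[int(gene_program[m.gene_id])]
        body = _sample_cds(aa_choices, p, rng, preferred)
        stop = STOPS[int(rng.integers(0, 3))]
        cds = "ATG" + body + stop
        cds_seqs[m.gene_id] = cds
        if chrom_arrays is not None:
            arr = chrom_arrays[m.chrom]
            # flanks at the gene's (unsuppressed) flank equilibrium GC
            fgc = float(flank_by_gene[m.gene_id])
            ls = max(0, m.start - FLANK_REGION)
            arr[ls : m.start] = _random_bases(m.start - ls, fgc, rng)
            re_ = min(arr.size, m.end + FLANK_REGION)
            arr[m.end : re_] = _random_bases(re_ - m.end, fgc, rng)
            for s, e in m.intron_intervals:
                arr[s:e] = _random_bases(e - s, p, rng)
            genomic_cds = cds if m.strand == "+" else reverse_complement(cds)
            off = 0
            for s, e in m.cds_intervals:
                arr[s:e] = np.frombuffer(
                    genomic_cds[off : off + (e - s)].encode(), dtype=np.uint8
                )
                off += e - s

    genome = None
    if chrom_arrays is not None:
        genome = {c: a.tobytes().decode("ascii") for c, a in chrom_arrays.items()}
    return genome, cds_seqs, eq_by_gene


# ---------------------------------------------------------------------------
# stage 5: DSB hotspots
# ---------------------------------------------------------------------------

def generate_hotspots(
    genetic_map: GeneticMap, rng: np.random.Generator
) -> pd.DataFrame:
    """Hotspot intervals sampled proportionally to local genetic distance,
    so suppressed (highly expressed) genes carry fewer hotspots."""
    rows = []
    for chrom in genetic_map.chromosomes:
        pos, cm = genetic_map.markers(chrom)
        total = cm[-1] - cm[0]
        n_hot = int(round(total * HOTSPOTS_PER_CM))
        u = rng.uniform(cm[0], cm[-1], size=n_hot)
        centers = np.interp(u, cm, pos)
        for c in np.sort(centers):
            s = max(0, int(c) - HOTSPOT_WIDTH // 2)
            rows.append({"chrom": chrom, "start": s, "end": s + HOTSPOT_WIDTH})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def simulate(
    config: SyntheticConfig,
    sequences: Literal["full", "cds_only", "none"] = "full",
) -> SyntheticDataset:
    """Run all generator stages deterministically from ``config.seed``.

    Stage-specific random streams are spawned from one seed sequence, so
    e.g. the expression matrix does not depend on whether sequences are
    generated.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_land, rng_genes, rng_expr, rng_seq, rng_hot = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    base_map, fields = generate_recombination_landscape(config, rng_land)
    models, genetic_map, truth = place_genes_and_suppress(config, fields, rng_genes)
    expression, metadata, sets, set_names, program_table = (
        synthesize_expression_and_sets(config, truth, rng_expr)
    )
    genome = cds = None
    if sequences != "none":
        genome, cds, eq = synthesize_sequences(
            config, models, truth, rng_seq,
            program_table=program_table,
            mode="full" if sequences == "full" else "cds_only",
        )
        truth = truth.assign(equilibrium_gc=eq)
    hotspots = generate_hotspots(genetic_map, rng_hot)
    return SyntheticDataset(
        config=config,
        models=models,
        base_map=base_map,
        genetic_map=genetic_map,
        hotspots=hotspots,
        expression=expression,
        sample_metadata=metadata,
        sets=sets,
        set_names=set_names,
        truth=truth,
        genome=genome,
        cds=cds,
    )


# ---------------------------------------------------------------------------
# annotation writers
# ---------------------------------------------------------------------------

def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.start + 1, m.end  # GFF3 is 1-based inclusive
            fh.write(
                f"{m.chrom}\tsynthetic\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            tx = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chrom}\tsynthetic\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={tx};Parent={m.gene_id}\n"
            )
            cds_sorted = sorted(m.cds_intervals)
            if m.strand == "-":
                ordered = list(reversed(cds_sorted))
            else:
                ordered = cds_sorted
            phase, rows = 0, []
            for cs, ce in ordered:
                rows.append((cs, ce, phase))
                phase = (3 - ((ce - cs) - phase) % 3) % 3
            for i, (cs, ce) in enumerate(cds_sorted):
                fh.write(
                    f"{m.chrom}\tsynthetic\texon\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t"
                    f"ID={tx}.exon{i + 1};Parent={tx}\n"
                )
            for cs, ce, ph in sorted(rows):
                fh.write(
                    f"{m.chrom}\tsynthetic\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t{ph}\t"
                    f"ID={tx}.cds;Parent={tx}\n"
                )


def write_bed12(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            exons = sorted(m.cds_intervals)
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            starts = ",".join(str(s - m.start) for s, _ in exons) + ","
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, m.start, m.end, m.gene_id, 0, m.strand,
                        exons[0][0], exons[-1][1], "0,0,0", len(exons),
                        sizes, starts,
                    )
                )
                + "\n"
            )
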