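"""Genetic-map arithmetic and recombination-landscape summaries.

A genetic map is a piecewise-linear cumulative genetic position (cM) along
each chromosome. The crossover rate of any physical interval follows by
differencing: rate = ΔcM / Δ(Mb). On top of interval rates this module
provides DSB-hotspot densities, quantile-bin contrasts of gene-level rates
against a stratifier such as meiotic expression, and strand-aware metagene
profiles of crossover rate anchored at the TSS or the polyadenylation site.

Positions outside a chromosome's map span clamp to the terminal cumulative
values (real maps do not reach chromosome ends); ``covered_fraction``
records how much of an interval the map actually spans so callers can filter
poorly covered genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_features import GeneModel

MB = 1e6


@dataclass
class IntervalRate:
    """Crossover rate of one interval, with map-coverage bookkeeping."""

    interval_id: str
    rate: float  # cM/Mb
    covered_fraction: float


class GeneticMap:
    """Piecewise-linear cumulative cM along one or more chromosomes.

    Internally a dict of ``(positions, cum_cM)`` marker arrays per
    chromosome; positions strictly increasing, cumulative cM non-decreasing.
    """

    def __init__(self, markers: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._markers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in markers.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if pos.ndim != 1 or pos.shape != cm.shape or pos.size < 2:
                raise ValueError(f"{chrom}: need >= 2 markers of equal shape")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if np.any(np.diff(cm) < -1e-12):
                raise ValueError(f"{chrom}: cumulative cM must be non-decreasing")
            self._markers[chrom] = (pos, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._markers)

    def markers(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        self._check(chrom)
        return self._markers[chrom]

    def span(self, chrom: str) -> tuple[float, float]:
        pos, _ = self.markers(chrom)
        return float(pos[0]), float(pos[-1])

    def total_cm(self) -> float:
        return float(sum(cm[-1] - cm[0] for _, cm in self._markers.values()))

    def total_mb(self) -> float:
        return float(sum(pos[-1] - pos[0] for pos, _ in self._markers.values())) / MB

    def _check(self, chrom: str) -> None:
        if chrom not in self._markers:
            raise KeyError(f"chromosome {chrom!r} not in map")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_rates(
        cls, segments: Mapping[str, tuple[np.ndarray, np.ndarray]]
    ) -> "GeneticMap":
        """Build from per-chromosome ``(breakpoints, segment_rates)``.

        ``breakpoints`` has n+1 positions; ``segment_rates`` gives the
        constant cM/Mb rate inside each of the n segments.
        """
        markers = {}
        for chrom, (bp, rates) in segments.items():
            bp = np.asarray(bp, dtype=float)
            rates = np.asarray(rates, dtype=float)
            if rates.size != bp.size - 1:
                raise ValueError(f"{chrom}: need len(breakpoints) == len(rates)+1")
            if np.any(rates < 0):
                raise ValueError(f"{chrom}: negative rates")
            cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(bp) / MB)])
            markers[chrom] = (bp, cm)
        return cls(markers)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        """Read a map TSV; the dialect is auto-detected from the header.

        Accepted columns: ``chrom pos cum_cM`` (cumulative) or
        ``chrom pos rate_cM_per_Mb`` (the rate applies from each position to
        the next; the last row's rate is ignored). Files carrying both use
        the cumulative column.
        """
        df = pd.read_csv(path, sep="\t")
        if "chrom" not in df.columns or "pos" not in df.columns:
            raise ValueError("map TSV must have 'chrom' and 'pos' columns")
        markers = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            pos = grp["pos"].to_numpy(dtype=float)
            if "cum_cM" in df.columns:
                cm = grp["cum_cM"].to_numpy(dtype=float)
            elif "rate_cM_per_Mb" in df.columns:
                rates = grp["rate_cM_per_Mb"].to_numpy(dtype=float)[:-1]
                cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(pos) / MB)])
            else:
                raise ValueError("map TSV needs a 'cum_cM' or 'rate_cM_per_Mb' column")
            markers[str(chrom)] = (pos, cm)
        return cls(markers)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (pos, cm) in self._markers.items():
            rate = np.diff(cm) / (np.diff(pos) / MB)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "rate_cM_per_Mb": np.concatenate([rate, [np.nan]]),
                        "cum_cM": cm,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    # -- queries -----------------------------------------------------------

    def interpolate_cm(self, chrom: str, position) -> np.ndarray | float:
        """Cumulative cM at ``position`` by piecewise-linear interpolation.

        Positions outside the marker span clamp to the terminal values.
        """
        pos, cm = self.markers(chrom)
        out = np.interp(np.asarray(position, dtype=float), pos, cm)
        return float(out) if np.isscalar(position) else out

    def covered(self, chrom: str, position) -> np.ndarray | bool:
        lo, hi = self.span(chrom)
        p = np.asarray(position, dtype=float)
        out = (p >= lo) & (p <= hi)
        return bool(out) if np.isscalar(position) else out

    def interval_rate(
        self, chrom: str, start: float, end: float, interval_id: str = ""
    ) -> IntervalRate:
        """Mean crossover rate (cM/Mb) of ``[start, end)``.

        rate = (cM(end) − cM(start)) / length-in-Mb, which equals the
        length-weighted mean of the per-segment rates the interval covers.
        """
        if end <= start:
            raise ValueError(f"zero- or negative-length interval ({start}, {end})")
        cm = self.interpolate_cm(chrom, np.array([start, end], dtype=float))
        rate = float(cm[1] - cm[0]) / ((end - start) / MB)
        lo, hi = self.span(chrom)
        overlap = max(0.0, min(end, hi) - max(start, lo))
        return IntervalRate(interval_id, rate, overlap / (end - start))


def interval_rates(
    genetic_map: GeneticMap, models: Sequence[GeneModel], unit: str = "transcript"
) -> pd.DataFrame:
    """Intragenic crossover rate per gene over the transcription unit
    (TSS→polyA; ``unit="cds"`` restricts to the CDS span)."""
    rows = []
    for m in models:
        if unit == "transcript":
            s, e = m.start, m.end
        elif unit == "cds":
            s, e = m.cds_intervals[0][0], m.cds_intervals[-1][1]
        else:
            raise ValueError(f"unknown unit {unit!r}")
        ir = genetic_map.interval_rate(m.chrom, s, e, interval_id=m.gene_id)
        rows.append(
            {
                "gene_id": m.gene_id,
                "rate_cM_per_Mb": ir.rate,
                "covered_fraction": ir.covered_fraction,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# DSB hotspots
# ---------------------------------------------------------------------------

def read_hotspots_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return df


def hotspot_density(
    hotspots: pd.DataFrame, chrom: str, start: float, end: float
) -> float:
    """DSB hotspots per kb: count of hotspot midpoints inside ``[start, end)``.

    Membership by midpoint avoids double counting a hotspot straddling a
    window edge.
    """
    if end <= start:
        raise ValueError("zero-length interval")
    sub = hotspots[hotspots["chrom"] == chrom]
    mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) / 2.0
    n = int(np.count_nonzero((mid >= start) & (mid < end)))
    return n / ((end - start) / 1e3)


# ---------------------------------------------------------------------------
# quantile-bin contrasts
# ---------------------------------------------------------------------------

def quantile_assign(stratifier: pd.Series, k: int) -> pd.Series:
    """Equal-count quantile bins (0 = lowest) with a stable gene-id
    tie-break, so ties in the stratifier never make bin sizes unequal."""
    if k < 2:
        raise ValueError("k must be >= 2")
    s = stratifier.dropna()
    if len(s) < 2 * k:
        raise ValueError(f"need at least {2 * k} genes for k={k} bins, got {len(s)}")
    # deterministic: sort by (value, gene id) so ties never reorder across runs
    idx = sorted(s.index, key=lambda g: (s[g], str(g)))
    bins = pd.Series(
        (np.arange(len(idx)) * k) // len(idx), index=idx, name="bin"
    )
    return bins.reindex(stratifier.index)


@dataclass
class DecileContrast:
    fold_change: float  # mean(bottom bin) / mean(top bin)
    per_bin: pd.DataFrame  # bin, mean, ci_low, ci_high, n


def decile_contrast(
    values: pd.Series, stratifier: pd.Series, k: int = 10
) -> DecileContrast:
    """Fold change of ``values`` between the bottom and top quantile bins of
    ``stratifier`` (bottom mean / top mean), with per-bin means and 95% CI.

    Genes missing either quantity are dropped. Invariant to monotone
    transforms of the stratifier (binning is rank-based).
    """
    df = pd.DataFrame({"v": values, "s": stratifier}).dropna()
    bins = quantile_assign(df["s"], k)
    df["bin"] = bins
    rows = []
    for b, grp in df.groupby("bin"):
        m = grp["v"].mean()
        sem = grp["v"].std(ddof=1) / np.sqrt(len(grp)) if len(grp) > 1 else np.nan
        rows.append(
            {"bin": int(b), "mean": m, "ci_low": m - 1.96 * sem,
             "ci_high": m + 1.96 * sem, "n": len(grp)}
        )
    per_bin = pd.DataFrame(rows).set_index("bin").sort_index()
    fold = per_bin.loc[0, "mean"] / per_bin.loc[k - 1, "mean"]
    return DecileContrast(fold_change=float(fold), per_bin=per_bin)


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Across-gene mean crossover rate in fixed windows around an anchor.

    Offsets are in transcriptional orientation: positive offsets at the TSS
    anchor point into the gene body, also for minus-strand genes.
    """

    anchor: str
    frame: pd.DataFrame  # offset_bp, mean_rate, ci_low, ci_high, n


def metagene_profile(
    genetic_map: GeneticMap,
    models: Sequence[GeneModel],
    anchor: str = "tss",
    window: int = 1000,
    span: int = 5000,
    min_covered: float = 1.0,
) -> MetageneProfile:
    """Strand-aware metagene profile of crossover rate around TSS or polyA.

    ``span`` bp on each side of the anchor are tiled with non-overlapping
    ``window``-bp windows. Windows falling off the chromosome's map span by
    more than ``1 − min_covered`` are dropped for that gene and ``n``
    adjusted. 95% CI is mean ± 1.96·SEM.
    """
    if anchor not in ("tss", "polya"):
        raise ValueError("anchor must be 'tss' or 'polya'")
    if span % window != 0:
        raise ValueError("span must be a multiple of window")
    nwin = span // window
    offsets = np.arange(-nwin, nwin) * window  # window starts, oriented
    acc: dict[int, list[float]] = {int(o): [] for o in offsets}
    for m in models:
        a = m.tss if anchor == "tss" else m.polya
        sign = 1 if m.strand == "+" else -1
        for o in offsets:
            # oriented window [o, o+window) maps to genome coords
            g1 = a + sign * o
            g2 = a + sign * (o + window)
            s, e = (g1, g2) if g1 < g2 else (g2, g1)
            lo, hi = genetic_map.span(m.chrom)
            if s < 0 or min(e, hi) - max(s, lo) < min_covered * window:
                continue
            ir = genetic_map.interval_rate(m.chrom, s, e)
            acc[int(o)].append(ir.rate)
    rows = []
    for o in offsets:
        vals = np.asarray(acc[int(o)], dtype=float)
        if vals.size == 0:
            continue
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append(
            {"offset_bp": int(o), "mean_rate": mean, "ci_low": mean - 1.96 * sem,
             "ci_high": mean + 1.96 * sem, "n": int(vals.size)}
        )
    return MetageneProfile(anchor=anchor, frame=pd.DataFrame(rows))


def stratified_metagene_profiles(
    genetic_map: GeneticMap,
    models: Sequence[GeneModel],
    expression: pd.Series,
    n_strata: int = 3,
    **kwargs,
) -> dict[int, MetageneProfile]:
    """Metagene profiles per expression stratum (equal-count bins, 0=lowest)."""
    by_id = {m.gene_id: m for m in models}
    expr = expression.reindex([m.gene_id for m in models]).dropna()
    bins = quantile_assign(expr, n_strata)
    out = {}
    for b in range(n_strata):
        ids = bins.index[bins == b]
        out[b] = metagene_profile(genetic_map, [by_id[g] for g in ids], **kwargs)
    return out
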