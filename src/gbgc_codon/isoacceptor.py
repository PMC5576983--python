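"""Translational-selection test based on tRNA isoacceptor repertoires.

If synonymous codon usage (SCU) were shaped by co-adaptation with the tRNA
pool, only amino acids decoded by several tRNA isoacceptors could show
usage variation across gene sets: for an amino acid decoded by a single
isoacceptor the available anticodon pool cannot differ between cell types,
so its codon usage has nothing to co-adapt with. The test therefore splits
the 18 degenerate amino acids into mono- and multi-isoacceptor groups,
computes GC3 separately on the two codon subsets for every gene set, and
regresses one on the other: a strong mono~multi correlation across sets
means a single process drives both and rules tRNA abundance out as the
driver.

In the human tRNA gene census (506 tRNA genes, 48 isoacceptors) the
mono-isoacceptor amino acids are Phe, Asp, His and Cys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._genetic_code import AA_TO_CODONS, DEGENERATE_AAS, SINGLE_CODON_AAS
from .sequence_features import CodonUsageTable, partitioned_gc3

#: the partition reported for the human tRNA gene repertoire
HUMAN_MONO_AAS = frozenset({"F", "D", "H", "C"})
HUMAN_MULTI_AAS = frozenset(DEGENERATE_AAS) - HUMAN_MONO_AAS


@dataclass(frozen=True)
class IsoacceptorPartition:
    """Degenerate amino acids split by isoacceptor count; Met/Trp excluded."""

    mono: frozenset[str]
    multi: frozenset[str]
    excluded: frozenset[str] = frozenset(SINGLE_CODON_AAS)

    def __post_init__(self) -> None:
        if self.mono | self.multi != frozenset(DEGENERATE_AAS) or (self.mono & self.multi):
            raise ValueError("mono/multi must partition the 18 degenerate amino acids")


HUMAN_PARTITION = IsoacceptorPartition(mono=HUMAN_MONO_AAS, multi=frozenset(HUMAN_MULTI_AAS))


class TRNARepertoire:
    """Anticodon-level tRNA gene counts (gtRNAdb-style table).

    Wobble rules are deliberately not modelled: an anticodon's amino acid is
    taken from the table, and all that matters downstream is the number of
    distinct anticodons (with at least one gene) per amino acid.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"anticodon", "aa", "gene_count"}
        if not required.issubset(table.columns):
            raise ValueError(f"repertoire table needs columns {sorted(required)}")
        if table["anticodon"].duplicated().any():
            dup = table.loc[table["anticodon"].duplicated(), "anticodon"].tolist()
            raise ValueError(f"duplicate anticodons: {dup}")
        bad = ~table["anticodon"].str.fullmatch("[ACGT]{3}")
        if bad.any():
            raise ValueError(
                f"malformed anticodons: {table.loc[bad, 'anticodon'].tolist()}"
            )
        if (table["gene_count"] < 0).any():
            raise ValueError("negative gene counts")
        self.table = table.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path) -> "TRNARepertoire":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def human_synthetic(cls) -> "TRNARepertoire":
        """Bundled stand-in for the human tRNA gene census.

        Synthetic: assembled to reproduce the published summary of the human
        repertoire (48 isoacceptors; Phe/Asp/His/Cys mono-isoacceptor), not
        downloaded from gtRNAdb.
        """
        with resources.files("gbgc_codon.data").joinpath(
            "human_trna_repertoire_synthetic.tsv"
        ).open() as fh:
            return cls.read_tsv(fh)

    def isoacceptor_counts(self) -> dict[str, int]:
        """Distinct anticodons with gene_count > 0, per amino acid."""
        present = self.table[self.table["gene_count"] > 0]
        return present.groupby("aa")["anticodon"].nunique().to_dict()


def build_partition(repertoire: TRNARepertoire) -> IsoacceptorPartition:
    """Partition degenerate amino acids into mono-/multi-isoacceptor sets.

    Raises if a degenerate amino acid has no isoacceptor at all (the
    repertoire could not translate the CDS universe).
    """
    counts = repertoire.isoacceptor_counts()
    missing = sorted(aa for aa in DEGENERATE_AAS if counts.get(aa, 0) == 0)
    if missing:
        raise ValueError(f"repertoire has no isoacceptor for: {missing}")
    mono = frozenset(aa for aa in DEGENERATE_AAS if counts[aa] == 1)
    multi = frozenset(aa for aa in DEGENERATE_AAS if counts[aa] >= 2)
    return IsoacceptorPartition(mono=mono, multi=multi)


@dataclass
class SelectionTestResult:
    per_set: pd.DataFrame  # index: set name; gc3_mono, gc3_multi
    r_squared: float  # NaN when a side has zero variance
    slope: float
    p_value: float
    n_sets_used: int
    n_sets_dropped: int


def selection_test(
    gene_set_tables: Mapping[str, CodonUsageTable],
    partition: IsoacceptorPartition = HUMAN_PARTITION,
) -> SelectionTestResult:
    """Correlate mono- vs multi-isoacceptor GC3 across gene sets.

    For every gene set's (concatenated) codon table, GC3 is computed
    separately over mono- and multi-isoacceptor codons; gc3_mono is then
    regressed on gc3_multi by OLS. A high R² says the same process moves
    both groups, which tRNA co-adaptation cannot do for the mono group.
    Sets with an undefined side are dropped. Zero variance on either axis
    yields NaN R² (degenerate, not zero).
    """
    rows = []
    dropped = 0
    for name, table in gene_set_tables.items():
        mono, multi = partitioned_gc3(table, partition)
        if math.isnan(mono) or math.isnan(multi):
            dropped += 1
            continue
        rows.append({"set": name, "gc3_mono": mono, "gc3_multi": multi})
    per_set = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["gc3_mono", "gc3_multi"]
    )
    if len(per_set) < 3:
        raise ValueError(f"need >= 3 usable gene sets, got {len(per_set)}")
    x = per_set["gc3_multi"].to_numpy()
    y = per_set["gc3_mono"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SelectionTestResult(per_set, math.nan, math.nan, math.nan,
                                   len(per_set), dropped)
    fit = stats.linregress(x, y)
    return SelectionTestResult(
        per_set=per_set,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        p_value=float(fit.pvalue),
        n_sets_used=len(per_set),
        n_sets_dropped=dropped,
    )
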