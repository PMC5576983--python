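"""Expression-matrix normalization: replicate averaging, sex-averaged
meiotic expression, log transformation and equal-count quantile binning.

Expression values are FPKM (non-negative). A matrix is a genes × samples
DataFrame accompanied by a sample-metadata table with one row per column
(``sample``, ``group``, and optionally ``sex``, ``cell_type``,
``replicate``). Sex-averaged meiotic expression is the arithmetic mean of
the female and male meiotic group means; genes missing either side carry
NaN and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recombination import quantile_assign


def validate_matrix(matrix: pd.DataFrame) -> None:
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")


def average_replicates(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicate columns, one output column per group."""
    validate_matrix(matrix)
    meta = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    unmapped = [c for c in matrix.columns if c not in meta.index]
    if unmapped:
        raise ValueError(f"samples without metadata group: {unmapped}")
    groups = meta.loc[list(matrix.columns), "group"]
    return matrix.T.groupby(groups.values).mean().T


@dataclass
class MeioticExpression:
    """Per-gene female, male and sex-averaged meiotic expression."""

    frame: pd.DataFrame  # columns: female, male, sex_averaged; NaN = undefined

    @property
    def sex_averaged(self) -> pd.Series:
        return self.frame["sex_averaged"]


def meiotic_sex_average(
    group_matrix: pd.DataFrame,
    female_group: str,
    male_groups: str | list[str],
) -> MeioticExpression:
    """Sex-averaged meiotic expression: mean(female, mean(male groups)).

    ``male_groups`` defaults to the meiotic stage only (spermatocytes); pass
    several groups to pool e.g. spermatocytes and spermatids. Genes with an
    undefined side get NaN in ``sex_averaged`` (excluded downstream).
    Symmetric in the two sexes.
    """
    if isinstance(male_groups, str):
        male_groups = [male_groups]
    missing = [g for g in [female_group, *male_groups] if g not in group_matrix.columns]
    if missing:
        raise KeyError(f"sample groups not in matrix: {missing}")
    female = group_matrix[female_group]
    male = group_matrix[male_groups].mean(axis=1)
    frame = pd.DataFrame(
        {"female": female, "male": male, "sex_averaged": (female + male) / 2.0}
    )
    return MeioticExpression(frame)


@dataclass
class QuantileBins:
    labels: pd.Series  # per-gene bin label
    cut_points: list[float]  # realized boundaries between consecutive bins


def quantile_bins(
    values: pd.Series, k: int, labels: list[str] | None = None
) -> QuantileBins:
    """Equal-count bins by rank with a stable gene-id tie-break.

    Bin sizes differ by at most one; realized cut points (the value at each
    bin boundary) are recorded so runs are auditable — the analogue of
    reporting the FPKM cuts that tercile binning produced.
    """
    vals = values.dropna()
    if k > len(vals):
        raise ValueError(f"more bins ({k}) than genes ({len(vals)})")
    bins = quantile_assign(vals, k)
    cut_points = []
    for b in range(1, k):
        cut_points.append(float(vals[bins == b].min()))
    out = bins.reindex(values.index)
    if labels is not None:
        if len(labels) != k:
            raise ValueError("need exactly k labels")
        out = out.map(lambda b: labels[int(b)] if pd.notna(b) else b)
    return QuantileBins(labels=out.rename("bin"), cut_points=cut_points)


def log_transform(values, pseudocount: float = 1.0):
    """log10(value + pseudocount); strictly monotone, 0 maps to 0 at the
    default pseudocount of 1. Negative input is an error."""
    arr = np.asarray(values, dtype=float)
    if arr.size and np.nanmin(arr) < 0:
        raise ValueError("negative expression values")
    out = np.log10(arr + pseudocount)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes × samples FPKM TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_matrix(df)
    return df
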