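"""Statistical layer: PCA of gene-set RSCU, pairwise correlations,
sequential (Type-I) variance partitioning of GC3, per-sample GC3~expression
ranking, and group location tests.

The centrepiece is the sequential ANOVA: predictors of GC3 (intronic GC,
flanking GC, log intragenic crossover rate, log meiotic expression, and the
functional category factor) enter an OLS model in a stated order, and each
step is charged with its increment in explained sum of squares. F statistics
test each increment against the full model's residual mean square by
default. The decomposition is exact: sequential SS plus residual SS equals
the total SS, and the final cumulative R² equals the full joint fit's R².

The two model-shaped operations are exposed sklearn-style (``fit`` plus
trailing-underscore fitted attributes) so they compose with sklearn
tooling; thin functional wrappers are provided for pipeline use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

import statsmodels.api as sm
import statsmodels.formula.api as smf


def smf_ols_from_matrices(y, exog: pd.DataFrame):
    return sm.OLS(y, exog).fit()


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------

@dataclass
class PairwiseR2:
    r_squared: float
    r: float  # signed correlation; the paper's R² values hide the sign
    p_value: float
    n_used: int
    n_dropped: int


def pairwise_r2(x, y) -> PairwiseR2:
    """Squared Pearson correlation with undefined pairs dropped.

    Zero variance on either side yields NaN (degenerate marker).
    """
    df = pd.DataFrame({"x": np.asarray(x, dtype=float).ravel(),
                       "y": np.asarray(y, dtype=float).ravel()})
    clean = df.dropna()
    n_dropped = len(df) - len(clean)
    if len(clean) < 3:
        raise ValueError(f"need >= 3 defined pairs, got {len(clean)}")
    if clean["x"].nunique() == 1 or clean["y"].nunique() == 1:
        return PairwiseR2(math.nan, math.nan, math.nan, len(clean), n_dropped)
    r, p = sps.pearsonr(clean["x"], clean["y"])
    return PairwiseR2(float(r) ** 2, float(r), float(p), len(clean), n_dropped)


# ---------------------------------------------------------------------------
# PCA of RSCU matrices
# ---------------------------------------------------------------------------

class RSCUPCA:
    """Principal component analysis of a gene-set × codon RSCU matrix.

    RSCU is already degeneracy-normalized, so the default is centred,
    unscaled PCA (``scale=True`` standardizes columns). Undefined entries
    (amino acid absent from a set) are imputed by the column mean and the
    count logged in ``n_imputed_``. The sign of PC1 is fixed so that its
    coordinates correlate positively with set GC3 when ``gc3`` is passed to
    :meth:`fit`.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components, "scale": self.scale}

    def set_params(self, **params) -> "RSCUPCA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, rscu_matrix: pd.DataFrame, gc3: pd.Series | None = None) -> "RSCUPCA":
        X = rscu_matrix.astype(float)
        if len(X) < 3:
            raise ValueError("need >= 3 gene sets")
        if len(X.drop_duplicates()) < 2:
            raise ValueError("rank-deficient input: fewer than 2 distinct rows")
        self.n_imputed_ = int(X.isna().to_numpy().sum())
        X = X.fillna(X.mean())
        X = X.fillna(0.0)  # columns undefined everywhere
        self._mean = X.mean()
        self._std = X.std(ddof=0).replace(0.0, 1.0)
        Z = (X - self._mean) / self._std if self.scale else X - self._mean
        pca = PCA(n_components=min(self.n_components, len(X) - 1, X.shape[1]))
        scores = pca.fit_transform(Z.to_numpy())
        if gc3 is not None:
            aligned = pd.Series(gc3).reindex(X.index).to_numpy(dtype=float)
            ok = ~np.isnan(aligned)
            if ok.sum() >= 3 and np.corrcoef(scores[ok, 0], aligned[ok])[0, 1] < 0:
                scores[:, 0] *= -1
                pca.components_[0] *= -1
        axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
        self.coordinates_ = pd.DataFrame(scores, index=X.index, columns=axes)
        self.loadings_ = pd.DataFrame(pca.components_.T, index=X.columns, columns=axes)
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, rscu_matrix: pd.DataFrame) -> pd.DataFrame:
        X = rscu_matrix.astype(float).fillna(self._mean).fillna(0.0)
        Z = (X - self._mean) / self._std if self.scale else X - self._mean
        scores = Z.to_numpy() @ self.loadings_.to_numpy()
        return pd.DataFrame(scores, index=X.index, columns=self.loadings_.columns)

    def fit_transform(self, rscu_matrix: pd.DataFrame, gc3: pd.Series | None = None):
        return self.fit(rscu_matrix, gc3=gc3).coordinates_


def rscu_pca(rscu_matrix: pd.DataFrame, gc3: pd.Series | None = None, **params) -> RSCUPCA:
    return RSCUPCA(**params).fit(rscu_matrix, gc3=gc3)


# ---------------------------------------------------------------------------
# sequential (Type-I) ANOVA
# ---------------------------------------------------------------------------

class SequentialANOVA:
    """Ordered variance partition of a response over nested OLS fits.

    Predictors enter in the given order; a categorical factor (unordered,
    reference level ``"other"`` when present) may close the sequence. Per
    step the partition records the predictor's pairwise R² with the
    response, the cumulative model R², and the sequential F statistic.

    Parameters
    ----------
    f_denominator:
        ``"full"`` (default) tests each increment against the full model's
        residual mean square (classic Type-I ANOVA table); ``"sequential"``
        uses the current nested model's residual mean square instead.
    interactions:
        When true, all pairwise interaction terms are appended after the
        main effects.
    """

    def __init__(self, f_denominator: str = "full", interactions: bool = False):
        if f_denominator not in ("full", "sequential"):
            raise ValueError("f_denominator must be 'full' or 'sequential'")
        self.f_denominator = f_denominator
        self.interactions = interactions

    def get_params(self, deep: bool = True) -> dict:
        return {"f_denominator": self.f_denominator, "interactions": self.interactions}

    def set_params(self, **params) -> "SequentialANOVA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(
        self,
        data: pd.DataFrame,
        response: str,
        predictors: list[str],
        category: str | None = None,
    ) -> "SequentialANOVA":
        cols = [response, *predictors] + ([category] if category else [])
        df = data[cols].dropna().copy()
        self.n_dropped_ = len(data) - len(df)
        self.n_used_ = len(df)
        if len(df) <= len(predictors) + 2:
            raise ValueError("not enough complete cases")

        # design-matrix blocks, one per term, entered strictly in order
        # (formula interfaces reorder categorical terms, which would change
        # the sequential decomposition)
        blocks: list[tuple[str, pd.DataFrame]] = [
            (p, df[[p]].astype(float)) for p in predictors
        ]
        if category:
            levels = sorted(df[category].astype(str).unique())
            ref = "other" if "other" in levels else levels[0]
            dummies = pd.get_dummies(df[category].astype(str), prefix=category)
            dummies = dummies.drop(columns=f"{category}_{ref}").astype(float)
            blocks.append((category, dummies))
        if self.interactions:
            mains = list(blocks)
            for i in range(len(mains)):
                for j in range(i + 1, len(mains)):
                    na, a = mains[i]
                    nb, b = mains[j]
                    inter = pd.DataFrame(
                        {
                            f"{ca}:{cb}": a[ca] * b[cb]
                            for ca in a.columns
                            for cb in b.columns
                        },
                        index=df.index,
                    )
                    blocks.append((f"{na}:{nb}", inter))

        y = df[response].to_numpy(dtype=float)
        n = y.size
        ss_total = float(np.sum((y - y.mean()) ** 2))
        X = np.ones((n, 1))
        rss = [ss_total]  # intercept-only model
        dfs = [1]
        for name, block in blocks:
            X = np.hstack([X, block.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(f"singular design after adding predictor {name!r}")
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            rss.append(float(resid @ resid))
            dfs.append(X.shape[1])
        ss_resid_full = rss[-1]
        df_resid_full = n - dfs[-1]
        if df_resid_full <= 0:
            raise ValueError("model saturates the data")

        rows = []
        for i, (name, block) in enumerate(blocks):
            # RSS is non-increasing in exact arithmetic; clip float jitter
            seq_ss = max(rss[i] - rss[i + 1], 0.0)
            d = dfs[i + 1] - dfs[i]
            if self.f_denominator == "full":
                denom, df_den = ss_resid_full / df_resid_full, df_resid_full
            else:
                denom, df_den = rss[i + 1] / (n - dfs[i + 1]), n - dfs[i + 1]
            f_stat = (seq_ss / d) / denom
            rows.append(
                {
                    "predictor": name,
                    "pairwise_r2": self._pairwise(df, response, name, predictors, category),
                    "model_r2": 1.0 - rss[i + 1] / ss_total,
                    "F": f_stat,
                    "p_value": float(sps.f.sf(f_stat, d, df_den)),
                    "df": float(d),
                    "seq_ss": float(seq_ss),
                }
            )
        self.partition_ = pd.DataFrame(rows)
        self.r_squared_ = 1.0 - ss_resid_full / ss_total
        self.residual_df_ = float(df_resid_full)
        self.ss_total_ = ss_total
        self.ss_residual_ = ss_resid_full
        # keep a statsmodels fit of the full model for inspection/prediction
        exog = pd.concat([b for _, b in blocks], axis=1)
        exog.insert(0, "Intercept", 1.0)
        self.model_ = smf_ols_from_matrices(y, exog)
        self.params_ = self.model_.params
        return self

    @staticmethod
    def _pairwise(df, response, term, predictors, category) -> float:
        if term in predictors:
            return pairwise_r2(df[response], df[term]).r_squared
        if category and term == category:
            # eta²: R² of the one-way fit on the factor alone
            fit = smf.ols(f"{response} ~ C({category})", data=df).fit()
            return float(fit.rsquared)
        return math.nan  # interaction terms carry no single pairwise R²


def sequential_anova(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    category: str | None = None,
    **params,
) -> SequentialANOVA:
    return SequentialANOVA(**params).fit(data, response, predictors, category)


# ---------------------------------------------------------------------------
# per-sample GC3 ~ expression ranking
# ---------------------------------------------------------------------------

def sample_correlation_ranking(
    gc3_by_gene: pd.Series,
    expression_matrix: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-sample squared correlation of GC3 with log10(FPKM+pseudocount),
    sorted ascending by r², with the (negative) sign retained in ``r``."""
    rows = []
    for sample in expression_matrix.columns:
        expr = np.log10(expression_matrix[sample].astype(float) + pseudocount)
        aligned = pd.DataFrame({"gc3": gc3_by_gene, "e": expr}).dropna()
        res = pairwise_r2(aligned["gc3"], aligned["e"])
        rows.append(
            {"sample": sample, "r_squared": res.r_squared, "r": res.r,
             "p_value": res.p_value, "n": res.n_used}
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["r_squared", "sample"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestReport:
    omnibus_statistic: float  # Kruskal-Wallis H
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, t, t_p, wilcoxon_u, wilcoxon_p


def group_tests(values: pd.Series, labels: pd.Series) -> GroupTestReport:
    """Rank-based omnibus (Kruskal–Wallis) plus pairwise Wilcoxon rank-sum
    (Mann–Whitney) and Welch t tests between groups."""
    df = pd.DataFrame({"v": values, "g": labels}).dropna()
    groups = {g: grp["v"].to_numpy() for g, grp in df.groupby("g")}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"groups with < 2 observations: {small}")
    h, p = sps.kruskal(*groups.values())
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, tp = sps.ttest_ind(groups[a], groups[b], equal_var=False)
            u, up = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append(
                {"group_a": a, "group_b": b, "t": float(t), "t_p": float(tp),
                 "wilcoxon_u": float(u), "wilcoxon_p": float(up)}
            )
    return GroupTestReport(float(h), float(p), pd.DataFrame(rows))
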