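"""Alpha diversity, balanced two-way ANOVA, fertility index, and
permutation-calibrated random-forest driver analysis.

Shannon entropy uses the natural log, so Pielou evenness J = H / ln(S)
equals 1 for a perfectly even community. The two-way ANOVA is restricted
to balanced designs (equal replicates per layer x time cell), where
Type I and Type III sums of squares coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .io import CountTable, SampleMetadata, SoilVariables, ValidationError, NUTRIENT_VARS


@dataclass
class DiversityRecord:
    sample_id: str
    richness: int       # S: ASVs with reads > 0
    shannon: float      # H, natural log
    evenness: float     # J = H / ln(S); NaN when S <= 1
    evenness_defined: bool


@dataclass
class AnovaTerm:
    term: str
    df: int
    ss: float
    ms: float
    f: float
    p: float


@dataclass
class AnovaResult:
    terms: list[AnovaTerm]
    residual_df: int
    residual_ss: float
    residual_ms: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t.term, "df": t.df, "SS": t.ss, "MS": t.ms,
                 "F": t.f, "P": t.p} for t in self.terms]
        rows.append({"term": "Residual", "df": self.residual_df,
                     "SS": self.residual_ss, "MS": self.residual_ms,
                     "F": np.nan, "P": np.nan})
        return pd.DataFrame(rows).set_index("term")


@dataclass
class RFImportance:
    predictor: str
    importance: float   # % increase in MSE when the predictor is permuted
    p_value: float      # response-permutation significance


def alpha_diversity(table: CountTable) -> list[DiversityRecord]:
    """Observed richness S, Shannon H (nats) and Pielou evenness J per sample."""
    out = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = row.sum()
        s = int((row > 0).sum())
        if total == 0:
            out.append(DiversityRecord(sid, 0, 0.0, float("nan"), False))
            continue
        p = row[row > 0] / total
        h = float(-(p * np.log(p)).sum())
        if s > 1:
            out.append(DiversityRecord(sid, s, h, h / math.log(s), True))
        else:
            out.append(DiversityRecord(sid, s, h, float("nan"), False))
    return out


def diversity_frame(records: list[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {"richness": [r.richness for r in records],
         "shannon": [r.shannon for r in records],
         "evenness": [r.evenness for r in records]},
        index=pd.Index([r.sample_id for r in records], name="sample_id"))


def two_way_anova(values: pd.Series, metadata: SampleMetadata,
                  factors: tuple[str, str] = ("layer", "time")) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Sequential sums of squares (equal to Type III under balance); F per
    term = MS_term / MS_residual.
    """
    fa, fb = factors
    md = metadata.table.reindex(values.index)
    df = pd.DataFrame({"y": values.to_numpy(dtype=float),
                       "A": md[fa].astype(str).to_numpy(),
                       "B": md[fb].astype(str).to_numpy()})
    cell_sizes = df.groupby(["A", "B"], sort=True).size()
    n_a, n_b = df["A"].nunique(), df["B"].nunique()
    if len(cell_sizes) != n_a * n_b or cell_sizes.nunique() != 1:
        raise ValidationError(
            "unbalanced design: two_way_anova requires equal replicates per "
            "cell; use a permutation-based alternative for unbalanced data")
    if cell_sizes.iloc[0] < 2:
        raise ValidationError("need >= 2 replicates per cell")

    fit = ols("y ~ C(A) * C(B)", data=df).fit()
    total_ss = float(((df["y"] - df["y"].mean()) ** 2).sum())
    if fit.ssr <= 1e-12 * max(total_ss, 1.0):
        raise ValidationError("zero residual variance: ANOVA F undefined")
    tbl = sm.stats.anova_lm(fit, typ=1)

    name_map = {"C(A)": fa, "C(B)": fb, "C(A):C(B)": f"{fa}:{fb}"}
    terms = []
    for key, name in name_map.items():
        row = tbl.loc[key]
        terms.append(AnovaTerm(name, int(row["df"]), float(row["sum_sq"]),
                               float(row["sum_sq"] / row["df"]),
                               float(row["F"]), float(row["PR(>F)"])))
    res = tbl.loc["Residual"]
    return AnovaResult(terms, int(res["df"]), float(res["sum_sq"]),
                       float(res["sum_sq"] / res["df"]))


def tukey_posthoc(values: pd.Series, metadata: SampleMetadata,
                  factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one factor (alpha = 0.05)."""
    md = metadata.table.reindex(values.index)
    labels = md[factor].astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has fewer than 2 levels")
    groups = [values.to_numpy(dtype=float)[(labels == lv).to_numpy()] for lv in levels]
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            mean_diff = float(groups[i].mean() - groups[j].mean())
            p = float(res.pvalue[i, j])
            rows.append({"level_a": levels[i], "level_b": levels[j],
                         "mean_diff": mean_diff, "p_adj": p,
                         "significant": p < 0.05})
    return pd.DataFrame(rows)


def fertility_index(soil: SoilVariables) -> pd.Series:
    """Soil fertility index: sum of z-scores of TC, TN, DOC, DON, NH4, NO3.

    z-scores are computed across all samples (sample sd); the index is
    centred at 0 by construction and unit-free, so affine rescaling of any
    input variable leaves it unchanged.
    """
    df = soil.table
    missing = [v for v in NUTRIENT_VARS if v not in df.columns]
    if missing:
        raise ValidationError(f"soil table missing nutrient variables: {missing}")
    z = pd.DataFrame(index=df.index)
    for v in NUTRIENT_VARS:
        sd = df[v].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"nutrient variable {v!r} has zero variance")
        z[v] = (df[v] - df[v].mean()) / sd
    idx = z.sum(axis=1)
    idx.name = "fertility_index"
    return idx


def _fit_importance(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                    rng: np.random.Generator, n_repeats: int = 5) -> np.ndarray:
    """Percent increase in MSE per predictor when that predictor is permuted."""
    rf = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                               random_state=int(rng.integers(2**31)))
    rf.fit(X, y)
    base_mse = float(np.mean((rf.predict(X) - y) ** 2))
    denom = base_mse if base_mse > 0 else float(np.var(y)) or 1.0
    n, p = X.shape
    # One batched predict over every (predictor, repeat) permutation.
    blocks = []
    for j in range(p):
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(n), j]
            blocks.append(Xp)
    preds = rf.predict(np.vstack(blocks)).reshape(p, n_repeats, n)
    mse = ((preds - y) ** 2).mean(axis=2).mean(axis=1)
    return 100.0 * (mse - base_mse) / denom


def rf_importance(predictors: pd.DataFrame, response: pd.Series,
                  n_trees: int = 500, n_response_permutations: int = 99,
                  seed: int = 0) -> list[RFImportance]:
    """Random-forest driver analysis with response-permutation significance.

    A regression forest (mtry = ceil(p/3)) is fit to the observed response;
    each predictor's importance is its percent increase in MSE under
    permutation. Significance refits the forest on permuted responses:
    P = (1 + #{null importance >= observed}) / (1 + n_response_permutations).
    """
    input_order = list(predictors.columns)
    predictors = predictors[sorted(predictors.columns)]  # canonical order: results invariant to column permutation
    X = predictors.to_numpy(dtype=float)
    y = response.reindex(predictors.index).to_numpy(dtype=float)
    if X.shape[0] < 10:
        raise ValidationError("rf_importance requires >= 10 samples")
    if X.shape[1] < 2:
        raise ValidationError("rf_importance requires >= 2 predictors")
    if np.allclose(y, y[0]):
        raise ValidationError("constant response: forest cannot be calibrated")
    rng = np.random.default_rng(seed)
    mtry = max(1, math.ceil(X.shape[1] / 3))

    obs = _fit_importance(X, y, n_trees, mtry, rng)
    exceed = np.zeros(X.shape[1])
    for _ in range(n_response_permutations):
        y_perm = rng.permutation(y)
        null = _fit_importance(X, y_perm, n_trees, mtry, rng)
        exceed += null >= obs
    pvals = (1.0 + exceed) / (1.0 + n_response_permutations)
    by_col = {col: RFImportance(col, float(obs[j]), float(pvals[j]))
              for j, col in enumerate(predictors.columns)}
    return [by_col[col] for col in input_order]
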