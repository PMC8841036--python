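"""Beta-diversity: Bray-Curtis distances, PCoA, PERMANOVA and the Mantel
test, implemented from first principles on the distance matrix.

PERMANOVA follows the distance-based linear-model partition: with the
Gower-centred matrix G = -1/2 J D^2 J, the sum of squares explained by a
design X with hat matrix H is tr(HGH); sequential (Type I) term sums of
squares are differences of cumulative-model traces, the pseudo-F compares
term and residual mean squares, and the P-value comes from free
permutation of sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, SampleMetadata, ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal not zero")
        self.values = (v + v.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray        # samples x positive axes
    eigenvalues: np.ndarray        # all, sorted descending (negatives included)
    proportion_explained: np.ndarray  # per positive axis


@dataclass
class PermanovaTerm:
    term: str
    df: int
    ss: float
    pseudo_f: float
    r2: float
    p: float


@dataclass
class PermanovaResult:
    terms: list[PermanovaTerm]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int

    @property
    def residual_r2(self) -> float:
        return self.residual_ss / self.total_ss

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t.term, "df": t.df, "SS": t.ss, "pseudo_F": t.pseudo_f,
                 "r2": t.r2, "P": t.p} for t in self.terms]
        rows.append({"term": "Residual", "df": self.residual_df,
                     "SS": self.residual_ss, "pseudo_F": np.nan,
                     "r2": self.residual_r2, "P": np.nan})
        return pd.DataFrame(rows).set_index("term")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: 1 - 2 sum(min) / (sum_x + sum_y)."""
    X = table.counts.astype(float)
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(f"all-zero sample: {table.sample_ids[int(zero[0])]!r}")
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(X[i], X[i + 1:]).sum(axis=1)
        d[i, i + 1:] = 1.0 - 2.0 * shared / (totals[i] + totals[i + 1:])
    d = d + d.T
    return DistanceMatrix(list(table.sample_ids), d)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * j @ d2 @ j


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Principal coordinates: eigendecomposition of the Gower matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; negative eigenvalues are reported uncorrected so the
    non-Euclidean share of the dissimilarity is visible.
    """
    g = _gower_center(d.values ** 2)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return PcoaResult(list(d.sample_ids), coords, eigvals, prop)


def _parse_formula(formula: str) -> list[str]:
    terms = [t.strip() for t in formula.split("+") if t.strip()]
    if not terms:
        raise ValidationError("empty PERMANOVA formula")
    return terms


def _term_columns(term: str, md: pd.DataFrame) -> np.ndarray:
    """Full dummy coding (one column per level/level-combination)."""
    parts = [p.strip() for p in term.split(":")]
    for p in parts:
        if p not in md.columns:
            raise ValidationError(f"unknown factor {p!r} in formula")
    labels = md[parts[0]].astype(str)
    for p in parts[1:]:
        labels = labels + "\x1f" + md[p].astype(str)
    levels = pd.unique(labels)
    return (labels.to_numpy()[:, None] == levels[None, :]).astype(float)


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-9 * max(diag.max(), 1.0)).sum())
    q = q[:, :rank] if rank else q[:, :0]
    return q @ q.T, rank


def permanova(d: DistanceMatrix, metadata: SampleMetadata,
              formula: str = "layer + time + layer:time",
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """Sequential PERMANOVA with free permutation of sample labels."""
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    md = metadata.table.reindex(d.sample_ids)
    terms = _parse_formula(formula)
    n = d.n
    g = _gower_center(d.values ** 2)
    total_ss = float(np.trace(g))

    ones = np.ones((n, 1))
    designs, hats, ranks = [ones], [], []
    X = ones
    h_prev, r_prev = _hat(X)
    term_info = []
    for term in terms:
        cols = _term_columns(term, md)
        X = np.hstack([X, cols])
        h, r = _hat(X)
        df = r - r_prev
        term_info.append((term, h, h_prev, df))
        h_prev, r_prev = h, r
    h_full = h_prev
    resid_df = n - r_prev
    if resid_df <= 0:
        raise ValidationError("zero residual degrees of freedom "
                              "(a term is confounded with previous terms)")
    resid_proj = np.eye(n) - h_full

    def stats_for(gm: np.ndarray):
        resid_ss = float(np.sum(resid_proj * gm.T))  # tr(P G)
        fs, sss = [], []
        for term, h, h_before, df in term_info:
            ss = float(np.sum(h * gm.T) - np.sum(h_before * gm.T))
            sss.append(ss)
            if df > 0:
                fs.append((ss / df) / (resid_ss / resid_df))
            else:
                fs.append(np.nan)
        return np.array(sss), np.array(fs), resid_ss

    obs_ss, obs_f, resid_ss = stats_for(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    # tie tolerance: permutations equivalent to the identity must count as >=
    thresh = obs_f - 1e-9 * np.maximum(np.abs(obs_f), 1.0)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        _, f_p, _ = stats_for(gp)
        exceed += np.where(np.isnan(obs_f), 0, f_p >= thresh)
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    out_terms = []
    for k, (term, _, _, df) in enumerate(term_info):
        out_terms.append(PermanovaTerm(
            term, df, obs_ss[k], float(obs_f[k]),
            obs_ss[k] / total_ss if total_ss > 0 else 0.0,
            float(pvals[k]) if df > 0 else float("nan")))
    return PermanovaResult(out_terms, resid_df, resid_ss, total_ss, n_permutations)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix,
           n_permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices (one-sided, greater).

    r is the Pearson correlation of the strictly-upper-triangle entries;
    the null permutes rows and columns of the second matrix simultaneously.
    """
    if d1.sample_ids != d2.sample_ids:
        if set(d1.sample_ids) != set(d2.sample_ids):
            raise ValidationError("Mantel requires identical sample sets")
        d2 = d2.subset(d1.sample_ids)
    x = d1.condensed()
    y = d2.condensed()
    if np.allclose(x, x.mean()) or np.allclose(y, y.mean()):
        raise ValidationError("constant distance matrix: Mantel r undefined")

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / np.sqrt((a @ a) * (b @ b)))

    r_obs = corr(x, y)
    n = d1.n
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][iu]
        if corr(x, yp) >= r_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return r_obs, p
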