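"""Alpha/beta diversity, ordination and group-comparison statistics.

Shannon entropy is computed in nats on relative abundances so that Pielou
evenness is the identity ``J = H / ln(richness)``. Beta diversity is
Bray-Curtis on relative abundances. PERMANOVA and the Mantel test are backed
by scikit-bio; non-metric MDS is backed by scikit-learn's SMACOF with
monotone regression, reporting Kruskal stress-1. Duncan's multiple range
test is implemented here (no installed package provides it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .tables import OTUTable
from .taxa import relative_abundance

__all__ = [
    "DiversityProfile",
    "DistanceMatrix",
    "PermTestResult",
    "alpha_diversity",
    "pielou",
    "bray_curtis",
    "nmds",
    "permanova",
    "mantel",
    "kruskal_wallis",
    "anova_duncan",
    "correlation_screen",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class DiversityProfile:
    """Per-sample alpha diversity: richness, Shannon (nats), Pielou evenness."""

    richness: pd.Series
    shannon: pd.Series
    pielou: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"richness": self.richness, "shannon": self.shannon, "pielou": self.pielou}
        )


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_skbio(self) -> _SkbioDM:
        return _SkbioDM(self.values, ids=self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class PermTestResult:
    """Outcome of a (permutation) test: statistic, effect size, p, n_perm."""

    statistic: float
    p_value: float
    effect: float | None = None
    n_permutations: int | None = None
    statistic_name: str = "statistic"

    def as_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": float(self.statistic),
            "effect": None if self.effect is None else float(self.effect),
            "p_value": float(self.p_value),
            "n_permutations": self.n_permutations,
        }


# ---------------------------------------------------------------------------
# Alpha / beta diversity
# ---------------------------------------------------------------------------

def pielou(shannon: float, richness: float) -> float:
    """Pielou evenness ``J = H / ln(S)``; defined as 0 when S <= 1."""
    if richness <= 1:
        return 0.0
    return float(shannon) / float(np.log(richness))


def alpha_diversity(table: OTUTable, allow_empty: bool = False) -> DiversityProfile:
    """Richness, Shannon (nats, with 0*ln 0 := 0) and Pielou per sample.

    Zero-sum samples are an error unless ``allow_empty``, in which case they
    get richness 0, Shannon 0 and Pielou 0 (useful for sub-community tables
    where a sample may simply contain no member of the sub-community).
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if allow_empty:
        rel = np.divide(
            counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0
        )
    else:
        rel = relative_abundance(table).to_numpy()
    richness = (table.counts.to_numpy() > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -terms.sum(axis=1)
    ev = np.array([pielou(h, s) for h, s in zip(shannon, richness)])
    idx = table.counts.index
    return DiversityProfile(
        richness=pd.Series(richness, index=idx, name="richness"),
        shannon=pd.Series(shannon, index=idx, name="shannon"),
        pielou=pd.Series(ev, index=idx, name="pielou"),
    )


def bray_curtis(table: OTUTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    rel = relative_abundance(table).to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(values=d, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def _kruskal_stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities.

    Fitted disparities come from isotonic regression of the configuration
    distances on the rank order of the observed dissimilarities.
    """
    d_hat = squareform(
        np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)),
        checks=False,
    )
    obs = squareform(d_obs, checks=False)
    order = np.argsort(obs, kind="stable")
    iso = IsotonicRegression()
    disp = np.empty_like(d_hat)
    disp[order] = iso.fit_transform(np.arange(len(obs)), d_hat[order])
    denom = (d_hat**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_hat - disp) ** 2).sum() / denom))


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = 0,
):
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    SMACOF majorization with monotone (isotonic) regression on dissimilarity
    ranks, restarted ``n_starts`` times from seeded random configurations;
    the best configuration and its stress-1 (in [0, 1]) are returned.
    """
    if dm.n < k + 1:
        raise ValueError("need at least k+1 samples for a k-dimensional NMDS")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        coords = model.fit_transform(dm.values)
        stress = _kruskal_stress1(dm.values, coords)
        if best is None or stress < best[1]:
            best = (coords, stress)
    coords, stress = best
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return frame, stress


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = 0
) -> PermTestResult:
    """One-factor PERMANOVA (pseudo-F, R^2, permutation p).

    Squared-distance partitioning per Anderson; p-value is
    ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``. Backed by scikit-bio.
    """
    groups = pd.Series(groups, index=dm.ids) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(dm.ids)
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(f"group(s) with fewer than two samples: {small}")
    res = _skbio_permanova(
        dm.to_skbio(), list(groups), permutations=n_perm, seed=seed
    )
    f_obs = float(res["test statistic"])
    a = len(counts)
    n = dm.n
    # R^2 from the pseudo-F identity: F = (SSB/(a-1)) / (SSW/(n-a))
    if np.isinf(f_obs):
        r2 = 1.0  # zero within-group distance
    else:
        r2 = (f_obs * (a - 1)) / (f_obs * (a - 1) + (n - a))
    return PermTestResult(
        statistic=f_obs,
        p_value=float(res["p-value"]),
        effect=r2,
        n_permutations=n_perm,
        statistic_name="pseudo-F",
    )


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """Mantel correlation between two distance matrices (skbio-backed)."""
    if d1.ids != d2.ids:
        if set(d1.ids) != set(d2.ids):
            raise ValueError("distance matrices cover different samples")
        order = [d2.ids.index(i) for i in d1.ids]
        d2 = DistanceMatrix(d2.values[np.ix_(order, order)], d1.ids)
    r, p, n = _skbio_mantel(
        d1.to_skbio(), d2.to_skbio(), method=method, permutations=n_perm, seed=seed
    )
    return PermTestResult(
        statistic=float(r), p_value=float(p), n_permutations=n_perm,
        statistic_name=f"mantel-r ({method})",
    )


def kruskal_wallis(values, groups) -> PermTestResult:
    """Kruskal-Wallis H with tie correction; p from chi^2 with k-1 df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    if np.allclose(values, values[0]):
        return PermTestResult(statistic=0.0, p_value=1.0, statistic_name="H")
    h, p = sps.kruskal(*samples)
    return PermTestResult(statistic=float(h), p_value=float(p), statistic_name="H")


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def anova_duncan(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA followed by Duncan's multiple range test.

    Critical ranges use studentized-range quantiles at Duncan's protection
    levels ``1 - (1 - alpha)^(p-1)`` for a span of ``p`` ordered means, with
    the harmonic mean group size for unbalanced designs. Returns a frame of
    group means (descending) with a connected-letter display.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {g: values[groups == g] for g in names}
    if any(len(v) < 2 for v in data.values()):
        raise ValueError("each group needs at least two replicates")

    k = len(names)
    n_total = len(values)
    df_error = n_total - k
    grand = values.mean()
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    mse = ss_within / df_error
    n_h = k / sum(1.0 / len(v) for v in data.values())

    means = pd.Series({g: data[g].mean() for g in names}).sort_values(ascending=False)
    ordered = list(means.index)

    def significant(i: int, j: int) -> bool:
        """Duncan test for the range spanning ordered means i..j (i<j)."""
        span = j - i + 1
        if mse == 0:
            return means.iloc[i] != means.iloc[j]
        protection = 1 - (1 - alpha) ** (span - 1)
        q_crit = sps.studentized_range.ppf(1 - protection, span, df_error)
        critical_range = q_crit * np.sqrt(mse / n_h)
        return (means.iloc[i] - means.iloc[j]) > critical_range

    # Stepwise: a range is declared non-significant if its own test fails or
    # it is contained in a larger non-significant range.
    nonsig: set[tuple[int, int]] = set()
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            contained = any(a <= i and j <= b for a, b in nonsig)
            if contained or not significant(i, j):
                nonsig.add((i, j))

    # Letters from maximal non-significant ranges (plus singletons).
    ranges = [(i, i) for i in range(k)]
    ranges += list(nonsig)
    maximal = [
        (a, b)
        for a, b in ranges
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in ranges)
    ]
    maximal.sort()
    letters = {g: "" for g in ordered}
    for idx, (a, b) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for pos in range(a, b + 1):
            letters[ordered[pos]] += letter

    return pd.DataFrame(
        {
            "mean": means,
            "n": [len(data[g]) for g in ordered],
            "letters": [letters[g] for g in ordered],
        }
    )


# ---------------------------------------------------------------------------
# Correlation screens
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Exact permutation p for Spearman's rho at small n (full enumeration)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    r_all = (ry_c @ rx_c) / np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    return float((np.abs(r_all) >= abs(r_obs) - 1e-12).mean())


def correlation_screen(
    x_table: pd.DataFrame, y_table: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise correlations between two variable sets on matched samples.

    Returns a long-format frame (x, y, r, p). Pearson p-values use the t
    approximation; Spearman p-values are exact (full enumeration) for n <= 8
    and use the t approximation otherwise. Constant columns yield missing
    entries with a warning.
    """
    import warnings

    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    common = x_table.index.intersection(y_table.index)
    if len(common) < 3:
        raise ValueError("fewer than three matched samples")
    x_table = x_table.loc[common]
    y_table = y_table.loc[common]
    rows = []
    n = len(common)
    for xc in x_table.columns:
        for yc in y_table.columns:
            x = x_table[xc].to_numpy(dtype=float)
            y = y_table[yc].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"constant column in pair ({xc}, {yc}); r undefined")
                rows.append((xc, yc, np.nan, np.nan))
                continue
            if method == "pearson":
                r, p = sps.pearsonr(x, y)
            else:
                r = sps.spearmanr(x, y).statistic
                if n <= 8:
                    p = _spearman_exact_p(x, y, r)
                else:
                    p = sps.spearmanr(x, y).pvalue
            rows.append((xc, yc, float(r), float(p)))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p"])
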