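"""OTU-table diversity analyses.

Covers the community side of the pipeline: count normalization, alpha
diversity (observed, rarefied/extrapolated richness, Hill number of order 1,
Pielou evenness, Berger-Parker dominance, Fisher's alpha), Baselga
partitioning of Sorensen dissimilarity into turnover (Simpson) and
nestedness components, Bray-Curtis distances, nonmetric multidimensional
scaling, PERMANOVA with permutations restricted to strata (sites), and a
multivariate dispersion test.

Rarefaction follows the sample-size-based rarefaction/extrapolation
framework: interpolation is the exact hypergeometric expectation, and
extrapolation beyond the observed depth uses the Chao1 estimate of
undetected richness driven by singleton and doubleton counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from sklearn.manifold import MDS
from skbio import DistanceMatrix
from skbio.stats.distance import permdisp

from .assay import ValidationError


@dataclass
class OTUTable:
    """Taxa x samples count table with per-sample metadata.

    ``counts``: DataFrame indexed by OTU id, columns are sample ids.
    ``metadata``: DataFrame indexed by sample id with at least ``site`` and
    ``location`` columns; a ``marker`` column distinguishes 16S-like from
    ITS-like tables.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValidationError("sample ids must be unique")
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValidationError(f"metadata missing for samples: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def normalize_table(t: OTUTable, mode: str = "relative") -> OTUTable:
    """Relative abundances (columns sum to 1) or presence/absence binaries."""
    if mode == "relative":
        totals = t.counts.sum(axis=0)
        zero = totals.index[totals == 0].tolist()
        if zero:
            raise ValidationError(f"zero-total sample(s): {zero}")
        counts = t.counts / totals
    elif mode == "presence_absence":
        counts = (t.counts > 0).astype(float)
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return OTUTable(counts=counts, metadata=t.metadata)


def rarefied_richness(counts, m: int) -> float:
    """Expected richness at sample size m (interpolated or extrapolated).

    For m <= n (n = total reads) the exact expectation
    S_obs - sum_k C(n - x_k, m) / C(n, m). For m > n the Chao1-style
    extrapolation S_obs + f0_hat * (1 - (1 - f1/(n*f0_hat + f1))**(m - n))
    with f0_hat = ((n-1)/n) * f1^2 / (2*f2) (f2 = 0 falls back to
    f1*(f1-1)/2).
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("sample has no reads")
    if m < 1:
        raise ValidationError("m must be >= 1")
    n = x.sum()
    s_obs = float(x.size)
    if m <= n:
        # log-domain hypergeometric terms; C(n-x, m) = 0 when n-x < m
        keep = (n - x) >= m
        if not np.any(keep):
            return s_obs
        xk = x[keep]
        log_term = (
            gammaln(n - xk + 1)
            - gammaln(n - xk - m + 1)
            - (gammaln(n + 1) - gammaln(n - m + 1))
        )
        return s_obs - float(np.exp(log_term).sum())
    f1 = float(np.sum(x == 1))
    f2 = float(np.sum(x == 2))
    if f1 == 0:
        return s_obs
    n_f = float(n)
    if f2 > 0:
        f0 = (n_f - 1.0) / n_f * f1 * f1 / (2.0 * f2)
    else:
        f0 = (n_f - 1.0) / n_f * f1 * (f1 - 1.0) / 2.0
    if f0 == 0:
        return s_obs
    return s_obs + f0 * (1.0 - (1.0 - f1 / (n_f * f0 + f1)) ** (m - n_f))


def chao1(counts) -> float:
    """Asymptotic Chao1 richness estimate with the (n-1)/n correction."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    n = x.sum()
    f1 = float(np.sum(x == 1))
    f2 = float(np.sum(x == 2))
    if f2 > 0:
        return float(x.size) + (n - 1.0) / n * f1 * f1 / (2.0 * f2)
    return float(x.size) + (n - 1.0) / n * f1 * (f1 - 1.0) / 2.0


def corrected_singletons(counts) -> np.ndarray:
    """Cap the singleton count at a Good-Turing estimate of true singletons.

    Amplicon pipelines inflate singletons with sequencing errors. Equating
    the Good-Turing ratios 2*f2/f1 and 3*f3/f2 yields the estimate
    f1_hat = 2*f2^2 / (3*f3); when the observed f1 exceeds it, excess
    singletons are removed (taxa with count 1 are dropped, rarest first in
    index order). Falls back to the raw counts when f3 = 0.
    """
    x = np.asarray(counts, dtype=float).copy()
    f1_idx = np.flatnonzero(x == 1)
    f2 = float(np.sum(x == 2))
    f3 = float(np.sum(x == 3))
    if f3 == 0 or f2 == 0:
        warnings.warn(
            "cannot estimate true singletons (f2 or f3 is zero); using raw counts",
            stacklevel=2,
        )
        return x
    f1_hat = 2.0 * f2 * f2 / (3.0 * f3)
    excess = int(len(f1_idx) - round(f1_hat))
    if excess > 0:
        x[f1_idx[:excess]] = 0.0
    return x


def fisher_alpha(s: int, n: int, tol: float = 1e-10) -> float:
    """Fisher's alpha: the root of S = alpha * ln(1 + n/alpha)."""
    if s < 1 or n < 1:
        raise ValidationError("need S >= 1 and n >= 1")
    if s >= n:
        raise ValidationError("Fisher's alpha undefined for S >= n")

    def f(a: float) -> float:
        return a * np.log1p(n / a) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValidationError("Fisher's alpha root bracket failed")
    return float(brentq(f, lo, hi, xtol=tol))


@dataclass
class DiversityProfile:
    observed_richness: int
    rarefied_richness: float
    target_depth: int
    shannon: float
    hill_1: float
    pielou_j: float | None
    berger_parker: float
    fishers_alpha: float | None


def alpha_profile(counts, target_depth: int = 25_000) -> DiversityProfile:
    """Alpha-diversity summary of one sample's counts.

    Hill-1 = exp(Shannon entropy), the effective number of equally abundant
    taxa; Pielou J' = H / ln S (undefined for a single taxon); Berger-Parker
    is the maximum relative abundance; Fisher's alpha solves
    S = alpha*ln(1 + n/alpha). Richness is rarefied/extrapolated to
    ``target_depth`` reads.
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("sample has no reads")
    n = x.sum()
    p = x / n
    h = float(-(p * np.log(p)).sum())
    s = int(x.size)
    return DiversityProfile(
        observed_richness=s,
        rarefied_richness=rarefied_richness(x, target_depth),
        target_depth=target_depth,
        shannon=h,
        hill_1=float(np.exp(h)),
        pielou_j=(h / np.log(s)) if s > 1 else None,
        berger_parker=float(p.max()),
        fishers_alpha=fisher_alpha(s, int(n)) if s < n else None,
    )


@dataclass
class BetaPartition:
    beta_sor: float
    beta_sim: float
    beta_nes: float
    scope: str = "pairwise"


def beta_pairwise(a, b) -> BetaPartition:
    """Partition pairwise Sorensen dissimilarity into turnover + nestedness.

    With shared taxa s and uniques u_a, u_b:
    beta_sor = (u_a + u_b) / (2s + u_a + u_b);
    beta_sim = min(u_a, u_b) / (s + min(u_a, u_b))  (turnover);
    beta_nes = beta_sor - beta_sim                  (nestedness).
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValidationError("both taxon sets must be non-empty")
    s = len(sa & sb)
    ua = len(sa - sb)
    ub = len(sb - sa)
    sor = (ua + ub) / (2 * s + ua + ub)
    mn = min(ua, ub)
    sim = mn / (s + mn) if (s + mn) > 0 else 0.0
    return BetaPartition(beta_sor=sor, beta_sim=sim, beta_nes=sor - sim)


def beta_multisite(presence: pd.DataFrame) -> BetaPartition:
    """Multi-site Baselga partition over >= 3 samples.

    ``presence``: samples x taxa binary frame (or anything truthy).
    Uses the multi-site Sorensen family: with S_i per-sample richness,
    S_T pooled richness, and pairwise uniques b_ij (taxa in i not j),
    beta_SIM = sum(min) / (sum(S_i) - S_T + sum(min)) and
    beta_SOR = (sum(min) + sum(max)) / (2*(sum(S_i) - S_T) + sum(min) + sum(max)).
    """
    pa = (presence.to_numpy() > 0).astype(int)
    n = pa.shape[0]
    if n < 3:
        raise ValidationError("multi-site partition needs >= 3 samples; use beta_pairwise")
    if np.any(pa.sum(axis=1) == 0):
        raise ValidationError("every sample must contain at least one taxon")
    shared = pa @ pa.T
    s_i = pa.sum(axis=1)
    sum_min = 0.0
    sum_max = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            b_ij = s_i[i] - shared[i, j]
            b_ji = s_i[j] - shared[i, j]
            sum_min += min(b_ij, b_ji)
            sum_max += max(b_ij, b_ji)
    s_t = int((pa.sum(axis=0) > 0).sum())
    core = float(s_i.sum() - s_t)
    denom_sim = core + sum_min
    sim = sum_min / denom_sim if denom_sim > 0 else 0.0
    denom_sor = 2.0 * core + sum_min + sum_max
    sor = (sum_min + sum_max) / denom_sor if denom_sor > 0 else 0.0
    return BetaPartition(beta_sor=sor, beta_sim=sim, beta_nes=sor - sim, scope="multisite")


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance matrix over samples (columns of a normalized table)."""
    data = table.to_numpy(dtype=float).T  # samples x taxa
    if data.shape[0] < 2:
        raise ValidationError("need >= 2 samples")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(data, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


@dataclass
class NMDSResult:
    scores: pd.DataFrame
    stress: float
    k_axes: int


def ordinate_nmds(dist: pd.DataFrame, k_axes: int = 2, seed: int = 0, n_init: int = 8) -> NMDSResult:
    """Nonmetric MDS on a precomputed distance matrix.

    Delegates to a standard stress-minimizing implementation with multiple
    seeded random starts; returns centered site scores and the normalized
    (Kruskal-style) stress.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n <= k_axes:
        raise ValidationError("need more samples than ordination axes")
    if np.allclose(d, 0.0):
        raise ValidationError("degenerate all-zero distance matrix")
    mds = MDS(
        n_components=k_axes,
        metric="precomputed",
        metric_mds=False,
        n_init=n_init,
        init="random",
        max_iter=500,
        random_state=seed,
        normalized_stress=True,
    )
    scores = mds.fit_transform(d)
    scores = scores - scores.mean(axis=0)
    cols = [f"NMDS{i + 1}" for i in range(k_axes)]
    return NMDSResult(
        scores=pd.DataFrame(scores, index=dist.index, columns=cols),
        stress=float(mds.stress_),
        k_axes=k_axes,
    )


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    strata: str = ""
    detail: str = ""


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> float:
    """One-way PERMANOVA pseudo-F from squared distances and integer labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = labels == g
        n_g = int(mask.sum())
        if n_g > 0:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova_strata(
    dist: pd.DataFrame,
    groups,
    strata,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """PERMANOVA whose null permutations shuffle labels only within strata.

    The pseudo-F compares among-group to within-group sums of squared
    distances. Restricting label permutations to strata (sites) respects
    the paired upstream/downstream structure: a label never crosses a
    stratum. p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    groups = np.asarray(groups)
    strata_arr = np.asarray(strata)
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != groups.size or groups.size != strata_arr.size:
        raise ValidationError("distance, groups, and strata sizes must agree")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValidationError("grouping is constant")
    labels = np.searchsorted(uniq, groups)
    d2 = d ** 2
    f_obs = _pseudo_f(d2, labels, uniq.size)

    rng = np.random.default_rng(seed)
    strata_idx = [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)]
    count = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        for idx in strata_idx:
            perm_labels[idx] = labels[idx][rng.permutation(idx.size)]
        if _pseudo_f(d2, perm_labels, uniq.size) >= f_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return PermutationTestResult(
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        strata=f"{len(strata_idx)} strata",
    )


def dispersion_test(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Multivariate homogeneity of group dispersions.

    Distances to group spatial medians in principal-coordinate space, with a
    permutation F test. Groups of size 1 carry no dispersion information and
    are excluded with a warning.
    """
    groups = pd.Series(np.asarray(groups), index=dist.index)
    sizes = groups.value_counts()
    singletons = sizes.index[sizes < 2].tolist()
    keep = ~groups.isin(singletons)
    if singletons:
        warnings.warn(f"excluding size-1 group(s): {singletons}", stacklevel=2)
    g = groups[keep]
    if g.nunique() < 2:
        raise ValidationError("need >= 2 groups of size >= 2")
    sub = dist.loc[keep, keep]
    dm = DistanceMatrix(sub.to_numpy(), ids=list(sub.index))
    res = permdisp(dm, g.to_numpy(), permutations=n_perm, seed=seed,
                   dimensions=min(10, dm.shape[0]))
    return PermutationTestResult(
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        n_permutations=n_perm,
        detail="distance to spatial median in PCoA space",
    )
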