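"""Alpha and beta diversity with nonparametric group inference.

Alpha diversity is the Shannon index in nats, H = -sum(p_i ln p_i), and
Pielou's evenness J = H / ln(S) with S the observed richness. Group contrasts
use the two-sided Mann-Whitney U test (exact null when both groups have
n <= 20 and there are no ties, tie-corrected normal approximation otherwise).

Beta diversity is Bray-Curtis on relative abundances, d = sum|x-y| / sum(x+y),
with single-factor PERMANOVA: pseudo-F and R^2 from the squared-distance
partition, and a permutation p-value p = (1 + #{F_perm >= F_obs}) / (1 + P)
over seeded label permutations. For small cohorts an exhaustive mode
enumerates every label permutation instead of sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .tables import CompartmentTable, RelAbundTable

_SUM_TOL = 1e-9


def _check_composition(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    return p


def shannon(fractions) -> float:
    """Shannon index H in nats; NaN for an all-zero vector."""
    p = _check_composition(fractions)
    total = p.sum()
    if total == 0:
        return math.nan
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"proportions must sum to 1 within {_SUM_TOL}, got {total}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def evenness(fractions) -> float:
    """Pielou's J = H / ln(S); NaN (flagged missing) when richness S <= 1."""
    p = _check_composition(fractions)
    s = int((p > 0).sum())
    if s <= 1:
        return math.nan
    return shannon(p) / math.log(s)


def richness(fractions) -> int:
    return int((np.asarray(fractions) > 0).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity; NaN when both vectors are all-zero."""
    x = _check_composition(x)
    y = _check_composition(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    denom = (x + y).sum()
    if denom == 0:
        return math.nan
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(rel: RelAbundTable) -> pd.DataFrame:
    """Square symmetric Bray-Curtis matrix over nonzero-library samples."""
    frac = rel.drop_zero_samples()
    if len(frac) < 2:
        raise ValueError("need at least 2 nonzero-library samples")
    dm = squareform(pdist(frac.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(dm, index=frac.index, columns=frac.index)


def mann_whitney(x, y) -> float:
    """Two-sided Mann-Whitney p; exact when both n <= 20 with no ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # degenerate: no evidence either way
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


# -- PERMANOVA ------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    f: float
    r2: float
    p: float
    n_permutations: int
    seed: int | None
    method: str  # "sampled" or "exact"
    degenerate: bool = False


def _as_matrix(d) -> np.ndarray:
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(dm)).max(initial=0.0) > 1e-12:
        raise ValueError("distance matrix must have a zero diagonal")
    return dm


def _ss_stats(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def permanova(d, labels, n_perm: int | str = 999, seed: int | None = None) -> PermanovaResult:
    """Single-factor PERMANOVA on a distance matrix.

    ``n_perm="exact"`` enumerates all n! label permutations (n <= 8) and
    reports p = #{F_perm >= F_obs} / n! (the identity permutation included);
    an integer ``n_perm`` samples that many seeded permutations and uses the
    (1 + x) / (1 + P) estimator so p can never be exactly zero.
    """
    dm = _as_matrix(d)
    labels = np.asarray(labels)
    if len(labels) != len(dm):
        raise ValueError("labels and distance matrix size mismatch")
    groups, codes = np.unique(labels, return_counts=False), None
    codes = np.searchsorted(groups, labels)
    k = len(groups)
    n = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = groups[counts.argmin()]
        raise ValueError(f"group {small!r} has fewer than 2 samples")

    d2 = dm ** 2
    ss_total, ss_within = _ss_stats(d2, codes, k)
    if ss_total <= 1e-300:
        return PermanovaResult(math.nan, math.nan, math.nan, 0, seed,
                               "degenerate", degenerate=True)

    def f_of(sw: float) -> float:
        return ((ss_total - sw) / (k - 1)) / (sw / (n - k))

    f_obs = f_of(ss_within)
    r2 = 1.0 - ss_within / ss_total
    tol = 1e-12 * max(1.0, abs(f_obs))

    if n_perm == "exact":
        if n > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            _, sw = _ss_stats(d2, codes[list(perm)], k)
            total += 1
            if f_of(sw) >= f_obs - tol:
                hits += 1
        return PermanovaResult(f_obs, r2, hits / total, total, seed, "exact")

    if seed is None:
        raise ValueError("a seed is required for sampled permutations")
    rng = substream(seed, "permanova")
    hits = 0
    for _ in range(int(n_perm)):
        perm_codes = rng.permutation(codes)
        _, sw = _ss_stats(d2, perm_codes, k)
        if f_of(sw) >= f_obs - tol:
            hits += 1
    p = (1 + hits) / (1 + int(n_perm))
    return PermanovaResult(f_obs, r2, p, int(n_perm), seed, "sampled")


def pairwise_permanova(d, labels, n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on each group pair's sub-matrix, BH-adjusted across pairs.

    Per-pair failures (e.g. a degenerate sub-matrix) become flagged NaN
    records rather than aborting the whole comparison.
    """
    dm = _as_matrix(d)
    labels = np.asarray(labels)
    idx_by_group = {g: np.flatnonzero(labels == g) for g in np.unique(labels)}
    records = []
    for g1, g2 in itertools.combinations(sorted(idx_by_group), 2):
        idx = np.concatenate([idx_by_group[g1], idx_by_group[g2]])
        sub = dm[np.ix_(idx, idx)]
        try:
            res = permanova(sub, labels[idx], n_perm=n_perm, seed=seed)
            records.append(dict(group1=g1, group2=g2, f=res.f, r2=res.r2, p=res.p,
                                n_permutations=res.n_permutations,
                                flagged=res.degenerate))
        except ValueError as exc:
            records.append(dict(group1=g1, group2=g2, f=math.nan, r2=math.nan,
                                p=math.nan, n_permutations=0, flagged=True,
                                note=str(exc)))
    out = pd.DataFrame(records)
    ok = out["p"].notna()
    out["q"] = math.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def alpha_group_tests(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests on per-sample alpha values."""
    values = values.dropna()
    groups = groups.loc[values.index]
    records = []
    for g1, g2 in itertools.combinations(sorted(groups.unique()), 2):
        x = values[groups == g1].to_numpy()
        y = values[groups == g2].to_numpy()
        p = mann_whitney(x, y) if min(len(x), len(y)) >= 2 else math.nan
        records.append(dict(group1=g1, group2=g2, n1=len(x), n2=len(y), p=p))
    return pd.DataFrame(records)


# -- report-level helpers (one call per figure panel) ----------------------

@dataclass(frozen=True)
class AlphaResult:
    per_sample: pd.DataFrame   # sample_id, compartment, group, shannon, evenness, richness
    tests: pd.DataFrame        # compartment, metric, group1, group2, n1, n2, p


@dataclass(frozen=True)
class BetaResult:
    compartment: str
    distances: pd.DataFrame
    global_test: PermanovaResult
    pairwise: pd.DataFrame


def alpha_diversity_report(table: CompartmentTable) -> AlphaResult:
    """Per-sample Shannon/evenness/richness plus per-compartment group tests."""
    rel = table.to_relative()
    frac = rel.fractions
    zero = set(rel.zero_samples)
    rows = []
    for sid in frac.index:
        p = frac.loc[sid].to_numpy()
        if sid in zero:
            h = j = math.nan
            s = 0
        else:
            h, j, s = shannon(p), evenness(p), richness(p)
        rows.append(dict(sample_id=sid, compartment=table.meta.loc[sid, "compartment"],
                         group=table.meta.loc[sid, "group"],
                         shannon=h, evenness=j, richness=s))
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    tests = []
    for comp, sub in per_sample.groupby("compartment", sort=False):
        for metric in ("shannon", "evenness"):
            t = alpha_group_tests(sub[metric], sub["group"])
            t.insert(0, "metric", metric)
            t.insert(0, "compartment", comp)
            tests.append(t)
    tests_df = (pd.concat(tests, ignore_index=True)
                if tests else pd.DataFrame(columns=["compartment", "metric"]))
    return AlphaResult(per_sample=per_sample, tests=tests_df)


def beta_diversity_report(table: CompartmentTable, compartment: str,
                          n_perm: int = 999, seed: int = 0) -> BetaResult:
    """Bray-Curtis + global and pairwise PERMANOVA within one compartment."""
    sub = table.subset(compartment=compartment)
    rel = sub.to_relative()
    dm = bray_curtis_matrix(rel)
    labels = sub.meta.loc[dm.index, "group"].to_numpy()
    global_test = permanova(dm, labels, n_perm=n_perm, seed=seed)
    pw = pairwise_permanova(dm, labels, n_perm=n_perm, seed=seed)
    return BetaResult(compartment=compartment, distances=dm,
                      global_test=global_test, pairwise=pw)
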