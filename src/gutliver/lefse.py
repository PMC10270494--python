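"""LDA-effect-size differential abundance screen (LefSe-style).

The screen is a documented variant of the classic two-stage LefSe procedure,
run per sample type (feces/blood/liver) and per pairwise disease-group
contrast on family- and genus-aggregated tables:

1. *Rank gate* — a two-sided rank-sum (Mann-Whitney) test per taxon at
   ``alpha = 0.05``; taxa that do not pass never get an effect size.
2. *LDA effect* — abundances are scaled to per-million units; over ``n_boot``
   bootstrap rounds, a 2/3 class-stratified subsample is drawn and a two-class
   Fisher discriminant is fit with a ridge-regularized pooled covariance. The
   per-taxon raw score of one round is
   ``(|w_f * (projected class-mean difference)| + |class-mean difference of
   taxon f|) / 2`` with ``w`` the unit-norm discriminant direction, and the
   reported effect is ``e = sign(mean_A - mean_B) * log10(max(1, mean raw
   score over rounds))`` — a signed log10 LDA score in per-million units.

A taxon is *reported* when its absolute effect reaches the threshold (3.5 by
default) in at least one sample type for the contrast; the report then carries
all sample types' effects for that taxon. Positive effects mean enrichment in
the first-named group of the pair.

Every constant of the variant (scaling, gate alpha, bootstraps, subsample
fraction, ridge) is recorded in the result so a run is self-describing.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .diversity import mann_whitney
from .tables import CompartmentTable, EmptySelectionError

logger = logging.getLogger("gutliver")

PPM = 1e6
DEFAULT_PAIRS = (("NAFLD", "HCC"), ("NAFLD", "cirrhosis"), ("cirrhosis", "HCC"))
DEFAULT_THRESHOLD = 3.5


@dataclass(frozen=True)
class LefseParams:
    alpha: float = 0.05
    n_boot: int = 30
    subsample: float = 2.0 / 3.0
    ridge: float = 1e-6
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0
    sign_convention: str = "positive = enriched in the first-named group of the pair"


@dataclass(frozen=True)
class EffectSizeTable:
    """Long-format screen results plus the constants that produced them."""

    records: pd.DataFrame   # taxon, rank, pair, sample_type, p_gate, effect, passed
    reported: pd.DataFrame  # subset of records for reported taxa (max |e| >= threshold)
    params: LefseParams = field(default_factory=LefseParams)


def to_per_million(fractions: pd.DataFrame) -> pd.DataFrame:
    """Scale proportion rows to per-million units (each row sums to 1e6)."""
    return fractions * PPM


def rank_gate(values_a: np.ndarray, values_b: np.ndarray, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided rank-sum p and whether the taxon passes the gate (p < alpha)."""
    pooled = np.concatenate([values_a, values_b])
    if np.all(pooled == pooled[0]):
        return 1.0, False  # constant taxon: gated out, flagged by p = 1
    p = mann_whitney(values_a, values_b)
    return p, bool(p < alpha)


def lda_effect(x: pd.DataFrame, labels: np.ndarray, class_a: str, class_b: str,
               n_boot: int = 30, subsample: float = 2.0 / 3.0,
               ridge: float = 1e-6, seed: int = 0) -> pd.Series:
    """Signed log10 LDA effect per taxon on a per-million matrix.

    ``x`` is samples x taxa in per-million units; ``labels`` assigns each row
    to ``class_a`` or ``class_b``. Positive values mean enrichment in
    ``class_a``. Taxa whose covariance stays singular after three tenfold
    ridge escalations come back as NaN (flagged).
    """
    labels = np.asarray(labels)
    # canonicalize the pair so the bootstrap stream is identical under a label
    # swap (exact antisymmetry) and under sample reordering (sort by id)
    flip = class_a > class_b
    first, second = (class_b, class_a) if flip else (class_a, class_b)
    order = np.argsort(x.index.astype(str).to_numpy(), kind="stable")
    x = x.iloc[order]
    labels = labels[order]
    idx_a = np.flatnonzero(labels == first)
    idx_b = np.flatnonzero(labels == second)
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("both classes need >= 3 samples for the LDA step")
    mat = x.to_numpy(dtype=float)
    n_taxa = mat.shape[1]
    rng = substream(seed, f"lda:{first}|{second}")
    raw = np.zeros(n_taxa)
    failed = False
    for _ in range(n_boot):
        sub_a = rng.choice(idx_a, size=max(3, math.ceil(subsample * len(idx_a))), replace=False)
        sub_b = rng.choice(idx_b, size=max(3, math.ceil(subsample * len(idx_b))), replace=False)
        xa, xb = mat[sub_a], mat[sub_b]
        mu_a, mu_b = xa.mean(axis=0), xb.mean(axis=0)
        diff = mu_a - mu_b
        scatter = ((xa - mu_a).T @ (xa - mu_a) + (xb - mu_b).T @ (xb - mu_b))
        pooled_cov = scatter / max(len(sub_a) + len(sub_b) - 2, 1)
        lam = ridge
        w = None
        for _attempt in range(4):
            try:
                c = np.linalg.cholesky(pooled_cov + lam * np.eye(n_taxa))
                w = np.linalg.solve(c.T, np.linalg.solve(c, diff))
                break
            except np.linalg.LinAlgError:
                lam *= 10.0
        if w is None:
            failed = True
            break
        norm = np.linalg.norm(w)
        w_unit = w / norm if norm > 0 else w
        proj_diff = float(w_unit @ diff)
        raw += (np.abs(w_unit * proj_diff) + np.abs(diff)) / 2.0
    if failed:
        return pd.Series(np.nan, index=x.columns)
    raw /= n_boot
    overall_sign = np.sign(mat[idx_a].mean(axis=0) - mat[idx_b].mean(axis=0))
    effect = overall_sign * np.log10(np.maximum(1.0, raw))
    if flip:
        effect = -effect
    return pd.Series(effect, index=x.columns)


def _screen_one(table: CompartmentTable, pair: tuple[str, str],
                params: LefseParams) -> pd.DataFrame:
    """Gate + effect for one sample-type table and one group pair."""
    a, b = pair
    sub_mask = table.meta["group"].isin(pair)
    counts = table.counts.loc[sub_mask]
    meta = table.meta.loc[sub_mask]
    live = counts.sum(axis=1) > 0
    counts, meta = counts.loc[live], meta.loc[live]
    frac = counts.div(counts.sum(axis=1), axis=0)
    ppm = to_per_million(frac)
    labels = meta["group"].to_numpy()
    gate = {}
    for taxon in ppm.columns:
        va = ppm.loc[labels == a, taxon].to_numpy()
        vb = ppm.loc[labels == b, taxon].to_numpy()
        gate[taxon] = rank_gate(va, vb, params.alpha)
    passing = [t for t, (_, ok) in gate.items() if ok]
    effects = pd.Series(np.nan, index=ppm.columns)
    if passing and (labels == a).sum() >= 3 and (labels == b).sum() >= 3:
        effects[passing] = lda_effect(
            ppm[passing], labels, a, b, n_boot=params.n_boot,
            subsample=params.subsample, ridge=params.ridge, seed=params.seed)
    return pd.DataFrame({
        "taxon": ppm.columns,
        "p_gate": [gate[t][0] for t in ppm.columns],
        "effect": effects.to_numpy(),
    })


def lefse_screen(table: CompartmentTable,
                 pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
                 threshold: float = DEFAULT_THRESHOLD,
                 ranks: tuple[str, ...] = ("family", "genus"),
                 sample_types: tuple[str, ...] = ("feces", "blood", "liver"),
                 alpha: float = 0.05, n_boot: int = 30,
                 subsample: float = 2.0 / 3.0, ridge: float = 1e-6,
                 seed: int = 0) -> EffectSizeTable:
    """Run the screen over ranks, sample types and pairwise group contrasts.

    A taxon/pair combination is reported when ``|effect| >= threshold`` in at
    least one sample type; the reported frame then includes that taxon's
    effect in every sample type (NaN where the gate removed it). Missing
    sample types are skipped with a warning rather than aborting.
    """
    params = LefseParams(alpha=alpha, n_boot=n_boot, subsample=subsample,
                         ridge=ridge, threshold=threshold, seed=seed)
    frames = []
    for rank in ranks:
        agg = table.aggregate_rank(rank) if rank != table.rank else table
        for st in sample_types:
            try:
                sub = agg.subset(compartment=st)
            except EmptySelectionError:
                logger.warning("sample type %r absent; screening the others", st)
                continue
            present = set(sub.meta["group"])
            for pair in pairs:
                if not set(pair) <= present:
                    continue
                one = _screen_one(sub, pair, params)
                one.insert(1, "rank", rank)
                one.insert(2, "pair", f"{pair[0]}_vs_{pair[1]}")
                one.insert(3, "sample_type", st)
                frames.append(one)
    if not frames:
        records = pd.DataFrame(columns=["taxon", "rank", "pair", "sample_type",
                                        "p_gate", "effect", "passed"])
        return EffectSizeTable(records=records, reported=records, params=params)
    records = pd.concat(frames, ignore_index=True)
    records["passed"] = records["effect"].abs() >= threshold
    max_abs = (records.assign(a=records["effect"].abs())
               .groupby(["taxon", "rank", "pair"])["a"].max())
    keys = pd.MultiIndex.from_frame(records[["taxon", "rank", "pair"]])
    reported = records.loc[max_abs.reindex(keys).to_numpy() >= threshold].copy()
    return EffectSizeTable(records=records, reported=reported, params=params)
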