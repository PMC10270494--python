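"""Negative-binomial modelling of liver gene counts.

Two uses of the same per-gene NB GLM (log link, per-gene dispersion, Wald
inference):

* disease-group differential expression (a two-level group indicator as the
  covariate, log2 fold-changes = beta1 / ln 2), and
* the gene x genus association grid, where the covariate is a genus's relative
  abundance in the matching liver 16S profile and the grid is restricted to
  genera with a nonzero read count in at least ``min_nonzero`` samples.

Dispersion is estimated per gene by profile maximum likelihood (method-of-
moments start, alpha bounded in [1e-8, 1e4]); coefficients come from IRLS at
the profiled alpha. There is no information sharing across genes; results are
method-variant with respect to shrinkage-based differential-expression
packages. Wald z = beta1 / SE(beta1) with a two-sided normal reference;
multiplicity is controlled by Benjamini-Hochberg, jointly over the whole
gene x genus grid by default.

Library depth enters as an offset of log median-of-ratios size factors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .tables import CompartmentTable

logger = logging.getLogger("gutliver")

ALPHA_MIN, ALPHA_MAX = 1e-8, 1e4


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples), geometric mean 1.

    Ratios are taken to the per-gene geometric mean over genes that are
    positive in every sample; if no such gene exists the factors fall back to
    relative library sizes, with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logref = np.log(mat[all_pos]).mean(axis=1)
        ratios = np.log(mat[all_pos]) - logref[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        logger.warning("no gene with all-positive counts; "
                       "falling back to library-size ratios")
        lib = mat.sum(axis=0)
        if (lib == 0).any():
            raise ValueError("sample with zero total gene counts")
        log_sf = np.log(lib)
    log_sf = log_sf - log_sf.mean()   # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


@dataclass(frozen=True)
class NBFit:
    beta0: float
    beta1: float
    se0: float
    se1: float
    alpha: float
    z: float
    p: float
    converged: bool
    message: str = ""


def _nb_fail(message: str) -> NBFit:
    return NBFit(*(math.nan,) * 7, converged=False, message=message)


def nb_glm(y, x, offset=None, maxiter: int = 100) -> NBFit:
    """Fit ``y ~ NB(exp(b0 + b1 x + offset), alpha)`` with profiled dispersion."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.shape != y.shape:
        raise ValueError("y and x must be equal-length vectors")
    if len(y) < 5:
        raise ValueError("need at least 5 observations")
    if not np.all(np.isfinite(x)) or np.var(x) == 0:
        raise ValueError("covariate must be finite with nonzero variance")
    if y.sum() == 0:
        return _nb_fail("all counts zero")
    exog = sm.add_constant(x)
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pois = sm.GLM(y, exog, family=sm.families.Poisson(), offset=offset
                          ).fit(maxiter=maxiter)
        except Exception as exc:  # noqa: BLE001 - flagged, not raised
            return _nb_fail(f"poisson start failed: {exc}")
        mu = pois.fittedvalues
        # method-of-moments dispersion start
        mom = float(((y - mu) ** 2 - mu).sum() / max((mu ** 2).sum(), 1e-300))
        a0 = float(np.clip(mom, ALPHA_MIN, ALPHA_MAX))

        cache: dict[float, float] = {}

        def negll(log_a: float) -> float:
            log_a = float(log_a)
            if log_a in cache:
                return cache[log_a]
            fam = sm.families.NegativeBinomial(alpha=float(np.exp(log_a)))
            try:
                res = sm.GLM(y, exog, family=fam, offset=offset).fit(
                    maxiter=maxiter, start_params=pois.params)
                val = -res.llf
            except Exception:  # noqa: BLE001
                val = np.inf
            cache[log_a] = val
            return val

        lo, hi = math.log(ALPHA_MIN), math.log(ALPHA_MAX)
        opt = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-2})
        log_a = float(opt.x) if np.isfinite(opt.fun) else math.log(a0)
        # accept the bound if it beats the interior optimum (Poisson-like data)
        for cand in (lo, math.log(a0)):
            if negll(cand) < negll(log_a):
                log_a = cand
        alpha = float(np.exp(log_a))
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            res = sm.GLM(y, exog, family=fam, offset=offset).fit(
                maxiter=maxiter, start_params=pois.params)
        except Exception as exc:  # noqa: BLE001
            return _nb_fail(f"NB fit failed: {exc}")

    if not res.converged or not np.all(np.isfinite(res.bse)) or (res.bse <= 0).any():
        return _nb_fail("IRLS did not converge")
    b0, b1 = res.params
    se0, se1 = res.bse
    z = b1 / se1
    p = 2.0 * norm.sf(abs(z))
    return NBFit(beta0=float(b0), beta1=float(b1), se0=float(se0), se1=float(se1),
                 alpha=alpha, z=float(z), p=float(p), converged=True)


def differential_expression(counts: pd.DataFrame, groups: pd.Series,
                            contrast: tuple[str, str],
                            sf: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test between two disease groups.

    ``contrast = (reference, alternative)``; positive log2 fold-changes mean
    higher expression in the alternative group. Genes that are all-zero in
    both groups are excluded (flagged), and non-converged fits are kept out of
    the BH family.
    """
    ref, alt = contrast
    groups = groups.reindex(counts.columns)
    mask = groups.isin(contrast).to_numpy()
    if (groups == ref).sum() < 2 or (groups == alt).sum() < 2:
        raise ValueError("both contrast groups need n >= 2")
    sub = counts.loc[:, mask]
    ind = (groups[mask] == alt).to_numpy(dtype=float)
    sf_sub = size_factors(sub) if sf is None else sf.reindex(sub.columns)
    offset = np.log(sf_sub.to_numpy())
    rows = []
    for gene, y in sub.iterrows():
        yv = y.to_numpy(dtype=float)
        if yv.sum() == 0:
            rows.append(dict(gene=gene, log2fc=math.nan, z=math.nan, p=math.nan,
                             alpha=math.nan, converged=False, excluded=True))
            continue
        fit = nb_glm(yv, ind, offset=offset)
        rows.append(dict(gene=gene, log2fc=fit.beta1 / math.log(2.0), z=fit.z,
                         p=fit.p, alpha=fit.alpha, converged=fit.converged,
                         excluded=False))
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["converged"] & out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["de"] = out["q"] < 0.05
    return out


@dataclass(frozen=True)
class AssociationGrid:
    """Gene x genus Wald associations with joint FDR and pruning."""

    records: pd.DataFrame   # gene, genus, beta1, z, p, q, direction, significant
    pruned: pd.DataFrame    # records restricted to genes/genera with >= 1 hit
    genera_tested: tuple[str, ...]
    min_nonzero: int
    q_threshold: float
    joint_fdr: bool
    de_annotation: pd.DataFrame | None = field(default=None, compare=False)


def gene_genus_grid(gene_counts: pd.DataFrame, liver_table: CompartmentTable,
                    genes=None, min_nonzero: int = 5, q_threshold: float = 0.05,
                    de_table: pd.DataFrame | None = None,
                    joint_fdr: bool = True,
                    standardize: bool = False) -> AssociationGrid:
    """Associate liver gene expression with liver-resident genus abundance.

    For every (gene, genus) pair an NB GLM regresses the gene's counts on the
    genus's relative abundance in the same patient's liver 16S profile, with
    median-of-ratios offsets. Genera must have a nonzero read count in at
    least ``min_nonzero`` shared samples (evaluated on counts, not fractions).
    BH runs jointly over all tested pairs unless ``joint_fdr=False`` (then per
    gene). The pruned view keeps only genes and genera carrying at least one
    significant association; ``de_table`` (from
    :func:`differential_expression`) annotates genes with their DE direction.
    """
    liver = liver_table.subset(compartment="liver")
    shared = gene_counts.columns.intersection(liver.sample_ids)
    if len(shared) < 5:
        raise ValueError(f"need >= 5 shared samples, found {len(shared)}")
    counts16 = liver.counts.loc[shared]
    nonzero = (counts16 > 0).sum(axis=0)
    genera = tuple(nonzero.index[nonzero >= min_nonzero])
    cols = ["gene", "genus", "beta1", "se1", "z", "p", "converged"]
    if not genera:
        empty = pd.DataFrame(columns=cols + ["q", "direction", "significant"])
        return AssociationGrid(records=empty, pruned=empty, genera_tested=(),
                               min_nonzero=min_nonzero, q_threshold=q_threshold,
                               joint_fdr=joint_fdr)
    rel = counts16.div(counts16.sum(axis=1), axis=0)
    gmat = gene_counts.loc[:, shared]
    gene_list = list(gmat.index if genes is None else [g for g in genes if g in gmat.index])
    sf = size_factors(gmat)
    offset = np.log(sf.to_numpy())
    rows = []
    for gene in gene_list:
        y = gmat.loc[gene].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        for genus in genera:
            x = rel[genus].to_numpy(dtype=float)
            if np.var(x) == 0:
                continue
            if standardize:
                x = (x - x.mean()) / x.std()
            fit = nb_glm(y, x, offset=offset)
            rows.append(dict(gene=gene, genus=genus, beta1=fit.beta1, se1=fit.se1,
                             z=fit.z, p=fit.p, converged=fit.converged))
    records = pd.DataFrame(rows, columns=cols)
    records["q"] = np.nan
    ok = records["converged"] & records["p"].notna()
    if ok.any():
        if joint_fdr:
            records.loc[ok, "q"] = multipletests(records.loc[ok, "p"],
                                                 method="fdr_bh")[1]
        else:
            for _gene, sub in records.loc[ok].groupby("gene"):
                records.loc[sub.index, "q"] = multipletests(sub["p"],
                                                            method="fdr_bh")[1]
    records["direction"] = np.sign(records["z"]).fillna(0).astype(int)
    records["significant"] = records["q"] < q_threshold
    hit_genes = set(records.loc[records["significant"], "gene"])
    hit_genera = set(records.loc[records["significant"], "genus"])
    pruned = records[records["gene"].isin(hit_genes)
                     & records["genus"].isin(hit_genera)].copy()
    annot = None
    if de_table is not None:
        sig = de_table[de_table["de"].fillna(False)] if "de" in de_table else de_table.iloc[:0]
        annot = pd.DataFrame({
            "gene": sig.index,
            "de_direction": np.where(sig["log2fc"] > 0, "up", "down"),
        }).set_index("gene")
        for frame in (records, pruned):
            frame["de_direction"] = frame["gene"].map(annot["de_direction"])
    return AssociationGrid(records=records, pruned=pruned, genera_tested=genera,
                           min_nonzero=min_nonzero, q_threshold=q_threshold,
                           joint_fdr=joint_fdr, de_annotation=annot)
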