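"""Fecal-translocation scoring: how much of a blood/liver community is fecal.

For each disease group, a *fecal core signature* is the set of classified
genera whose relative abundance reaches ``tau_abund`` (default 0.1%) in at
least a fraction ``tau_prev`` (default 5%) of that group's fecal samples, both
comparisons inclusive. The per-sample translocation proportion T of a blood or
liver sample is then the summed relative abundance, in that sample, of its own
group's signature genera — a number in [0, 1] that estimates the fecal mixture
weight of the tissue community. Group contrasts against a reference group
(NAFLD by default) use two-sided Mann-Whitney tests, BH-adjusted within each
compartment.

Genus mass that is unassigned at genus rank (the ``unclassified:`` labels)
never enters a signature but stays in the relative-abundance denominator, so T
is conservative with respect to unclassified reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diversity import mann_whitney
from .tables import CompartmentTable, EmptySelectionError, classified_taxa

DEFAULT_TAU_ABUND = 0.001   # >= 0.1% relative abundance
DEFAULT_TAU_PREV = 0.05     # in >= 5% of the group's fecal samples


@dataclass(frozen=True)
class FecalSignature:
    """The core fecal genera of one disease group."""

    group: str
    genera: frozenset[str]
    tau_abund: float
    tau_prev: float
    n_fecal_samples: int


@dataclass(frozen=True)
class TranslocationReport:
    samples: pd.DataFrame     # sample_id, compartment, group, proportion
    contrasts: pd.DataFrame   # compartment, group, reference, n, n_ref, p, q
    signatures: dict[str, FecalSignature]
    reference_group: str
    pooled: bool


def fecal_signature(table: CompartmentTable, group: str | None,
                    tau_abund: float = DEFAULT_TAU_ABUND,
                    tau_prev: float = DEFAULT_TAU_PREV) -> FecalSignature:
    """Build the fecal core signature of ``group`` (or pooled, if None).

    A genus enters the signature iff the fraction of the group's
    nonzero-library fecal samples in which its relative abundance is
    ``>= tau_abund`` is itself ``>= tau_prev``. Both boundaries inclusive:
    with 20 fecal samples and ``tau_prev = 0.05``, one qualifying sample
    suffices.
    """
    if not 0.0 < tau_abund < 1.0 or not 0.0 <= tau_prev < 1.0:
        raise ValueError("thresholds must lie in (0, 1)")
    try:
        feces = table.subset(compartment="feces", group=group) if group is not None \
            else table.subset(compartment="feces")
    except EmptySelectionError:
        raise ValueError(f"no fecal samples for group {group!r}") from None
    rel = feces.to_relative()
    frac = rel.drop_zero_samples()
    if len(frac) == 0:
        raise ValueError(f"no fecal samples with reads for group {group!r}")
    candidates = classified_taxa(frac.columns)
    prevalence = (frac[candidates] >= tau_abund).mean(axis=0)
    genera = frozenset(prevalence.index[prevalence >= tau_prev])
    return FecalSignature(group=group if group is not None else "pooled",
                          genera=genera, tau_abund=tau_abund, tau_prev=tau_prev,
                          n_fecal_samples=len(frac))


def translocation_proportion(sample_fractions: pd.Series, sig: FecalSignature) -> float:
    """T = summed relative abundance of the signature genera in one sample."""
    if sample_fractions.sum() == 0:
        return math.nan  # zero-library sample, flagged
    genera = [g for g in sig.genera if g in sample_fractions.index]
    if len(genera) < len(sig.genera):
        missing = sorted(set(sig.genera) - set(genera))
        raise ValueError(f"signature genera absent from sample axis: {missing[:5]}")
    return float(sample_fractions[genera].sum())


def translocation_report(table: CompartmentTable,
                         compartments: tuple[str, ...] = ("blood", "liver"),
                         reference_group: str = "NAFLD",
                         tau_abund: float = DEFAULT_TAU_ABUND,
                         tau_prev: float = DEFAULT_TAU_PREV,
                         pooled_signature: bool = False) -> TranslocationReport:
    """Score every blood/liver sample and contrast groups against a reference.

    Each sample is scored against the signature of its own disease group
    (or a single pooled-across-groups signature when ``pooled_signature``).
    Per compartment, every non-reference group is compared to the reference
    with a two-sided Mann-Whitney test; p-values are BH-adjusted within the
    compartment. With only the reference group present the report carries T
    values and no contrasts.
    """
    groups = [g for g in table.meta["group"].unique()]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")
    if pooled_signature:
        pooled = fecal_signature(table, None, tau_abund, tau_prev)
        signatures = {g: pooled for g in groups}
    else:
        signatures = {g: fecal_signature(table, g, tau_abund, tau_prev) for g in groups}

    rel = table.to_relative()
    rows = []
    for comp in compartments:
        sub = table.subset(compartment=comp)
        for sid in sub.sample_ids:
            grp = sub.meta.loc[sid, "group"]
            t = translocation_proportion(rel.fractions.loc[sid], signatures[grp])
            rows.append(dict(sample_id=sid, compartment=comp, group=grp, proportion=t))
    samples = pd.DataFrame(rows).set_index("sample_id")

    contrasts = []
    for comp in compartments:
        here = samples[samples["compartment"] == comp].dropna(subset=["proportion"])
        ref = here.loc[here["group"] == reference_group, "proportion"].to_numpy()
        recs = []
        for grp in [g for g in groups if g != reference_group]:
            vals = here.loc[here["group"] == grp, "proportion"].to_numpy()
            p = mann_whitney(vals, ref) if min(len(vals), len(ref)) >= 2 else math.nan
            recs.append(dict(compartment=comp, group=grp, reference=reference_group,
                             n=len(vals), n_ref=len(ref), p=p))
        if recs:
            df = pd.DataFrame(recs)
            ok = df["p"].notna()
            df["q"] = np.nan
            if ok.any():
                df.loc[ok, "q"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
            contrasts.append(df)
    contrasts_df = (pd.concat(contrasts, ignore_index=True) if contrasts
                    else pd.DataFrame(columns=["compartment", "group", "reference",
                                               "n", "n_ref", "p", "q"]))
    return TranslocationReport(samples=samples, contrasts=contrasts_df,
                               signatures=signatures, reference_group=reference_group,
                               pooled=pooled_signature)
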