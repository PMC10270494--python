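"""Core data model: genus-level count tables across body compartments.

The pipeline's universal input is a :class:`CompartmentTable` — a samples x taxa
matrix of nonnegative integer 16S read counts, with per-sample metadata (subject,
compartment, disease group) and an optional rank-labelled taxonomic lineage per
taxon. Relative abundances live in :class:`RelAbundTable`, which keeps the same
axes and flags zero-library samples instead of silently dropping them.

Compartments and disease groups are closed vocabularies: ``feces``, ``blood``,
``liver`` and ``NAFLD``, ``cirrhosis``, ``HCC``. Unknown labels are rejected at
construction time so that typos surface before any statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("gutliver")

COMPARTMENTS = ("feces", "blood", "liver")
GROUPS = ("NAFLD", "cirrhosis", "HCC")
#: Taxonomic ranks in order, coarsest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
#: Taxa with no assignment at a rank are kept under this reserved label prefix;
#: they count toward library size but are excluded from fecal core signatures.
UNCLASSIFIED_PREFIX = "unclassified:"

META_COLUMNS = ("subject_id", "compartment", "group")


class SchemaError(ValueError):
    """Input violates the table schema (types, enums, alignment, uniqueness)."""


class EmptySelectionError(LookupError):
    """A subset operation matched zero samples."""


def _check_meta(meta: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing required column(s): {missing}")
    if not meta.index.is_unique:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate sample_id(s): {dup}")
    bad = set(meta["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise SchemaError(
            f"unknown compartment label(s) {sorted(bad)}; expected one of {COMPARTMENTS}"
        )
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise SchemaError(f"unknown group label(s) {sorted(bad)}; expected one of {GROUPS}")


@dataclass(frozen=True)
class CompartmentTable:
    """Counts (samples x taxa) with aligned sample metadata and taxon lineages.

    Parameters
    ----------
    counts
        Nonnegative integer counts, index = sample ids, columns = taxon ids.
        Fractional values are rejected, not rounded.
    meta
        One row per sample (same index as ``counts``) with columns
        ``subject_id``, ``compartment``, ``group``.
    lineage
        Optional taxon -> rank-label table (index = taxon ids, columns a prefix
        of :data:`RANKS`). Required only for :meth:`aggregate_rank`.
    rank
        The rank of the taxa axis, ``"genus"`` by default.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    lineage: pd.DataFrame | None = None
    rank: str = "genus"

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise SchemaError("table needs at least 1 sample and 1 taxon")
        if not c.columns.is_unique:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate taxon id(s): {dup}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.issubdtype(vals.dtype, np.number):
                raise SchemaError("counts must be numeric")
            if np.isnan(vals).any() or not np.array_equal(vals, np.floor(vals)):
                raise SchemaError("counts must be integers; fractional values are rejected")
            object.__setattr__(self, "counts", c.astype(np.int64))
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise SchemaError("counts must be nonnegative")
        _check_meta(self.meta)
        if not c.index.equals(self.meta.index):
            if set(c.index) == set(self.meta.index) and c.index.is_unique:
                object.__setattr__(self, "meta", self.meta.loc[c.index])
            else:
                orphans = set(c.index) ^ set(self.meta.index)
                raise SchemaError(f"counts/metadata sample ids do not align: {sorted(orphans)[:5]}")
        if self.lineage is not None:
            absent = c.columns.difference(self.lineage.index)
            if len(absent):
                raise SchemaError(f"taxa missing from lineage table: {absent.tolist()[:5]}")
        if self.rank not in RANKS:
            raise SchemaError(f"unknown rank {self.rank!r}")
        zero = self.zero_library_samples
        if zero:
            logger.warning(
                "%d sample(s) with zero library size retained but excluded from statistics: %s",
                len(zero), zero[:5],
            )

    # -- basic properties -------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxa(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def zero_library_samples(self) -> list[str]:
        ls = self.library_sizes
        return ls.index[ls == 0].tolist()

    # -- operations --------------------------------------------------------

    def to_relative(self) -> "RelAbundTable":
        """Normalize each sample to proportions; zero-library rows are flagged.

        Rows with zero library size become all-zero fraction rows and are listed
        in :attr:`RelAbundTable.zero_samples`, to be excluded from downstream
        statistics rather than silently dropped.
        """
        ls = self.library_sizes.to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.counts.to_numpy(dtype=float) / ls[:, None]
        frac[ls == 0, :] = 0.0
        fractions = pd.DataFrame(frac, index=self.counts.index, columns=self.counts.columns)
        return RelAbundTable(fractions=fractions, meta=self.meta,
                             zero_samples=tuple(self.zero_library_samples))

    def aggregate_rank(self, rank: str) -> "CompartmentTable":
        """Sum counts of taxa sharing the same label at ``rank``.

        Library sizes are conserved per sample. Aggregating to the table's own
        rank returns an identical table. A taxon whose lineage lacks a label at
        ``rank`` triggers an error naming the taxon.
        """
        if rank == self.rank:
            return self
        if rank not in RANKS:
            raise SchemaError(f"unknown rank {rank!r}")
        if RANKS.index(rank) > RANKS.index(self.rank):
            raise SchemaError(f"cannot disaggregate {self.rank}-level table to {rank}")
        if self.lineage is None or rank not in self.lineage.columns:
            raise SchemaError(f"no lineage information for rank {rank!r}")
        labels = self.lineage.loc[self.taxa, rank]
        bad = labels.index[labels.isna() | (labels == "")]
        if len(bad):
            raise SchemaError(f"taxon {bad[0]!r} has no label at rank {rank!r}")
        agg = self.counts.T.groupby(labels, sort=False).sum().T
        keep = list(RANKS[: RANKS.index(rank) + 1])
        lin = (self.lineage.loc[self.taxa, keep]
               .groupby(labels, sort=False).first()
               .loc[agg.columns])
        return CompartmentTable(counts=agg, meta=self.meta, lineage=lin, rank=rank)

    def subset(self, compartment: str | None = None, group: str | None = None) -> "CompartmentTable":
        """Select samples matching all given filters; taxa axis unchanged."""
        if compartment is None and group is None:
            raise ValueError("give at least one of compartment=, group=")
        if compartment is not None and compartment not in COMPARTMENTS:
            raise SchemaError(f"unknown compartment {compartment!r}")
        if group is not None and group not in GROUPS:
            raise SchemaError(f"unknown group {group!r}")
        mask = pd.Series(True, index=self.meta.index)
        if compartment is not None:
            mask &= self.meta["compartment"] == compartment
        if group is not None:
            mask &= self.meta["group"] == group
        if not mask.any():
            raise EmptySelectionError(
                f"no samples match compartment={compartment!r}, group={group!r}"
            )
        return replace(self, counts=self.counts.loc[mask], meta=self.meta.loc[mask])


@dataclass(frozen=True)
class RelAbundTable:
    """Proportions on the same axes as the source :class:`CompartmentTable`."""

    fractions: pd.DataFrame
    meta: pd.DataFrame
    zero_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy()
        if (vals < 0).any() or (vals > 1 + 1e-9).any():
            raise SchemaError("fractions must lie in [0, 1]")
        sums = vals.sum(axis=1)
        live = ~self.fractions.index.isin(self.zero_samples)
        if np.abs(sums[live] - 1.0).max(initial=0.0) > 1e-9:
            raise SchemaError("each nonzero-library row must sum to 1 within 1e-9")

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index

    @property
    def taxa(self) -> pd.Index:
        return self.fractions.columns

    def drop_zero_samples(self) -> pd.DataFrame:
        """Fractions restricted to samples with nonzero library size."""
        live = ~self.fractions.index.isin(self.zero_samples)
        return self.fractions.loc[live]


def classified_taxa(taxa) -> list[str]:
    """Taxa that carry a real assignment (not the reserved unclassified label)."""
    return [t for t in taxa if not str(t).startswith(UNCLASSIFIED_PREFIX)]
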