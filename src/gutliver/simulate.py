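"""Synthetic three-compartment cohorts with known translocation ground truth.

The generator emulates the structure of a gut-blood-liver 16S study of chronic
liver disease:

* Each disease group (NAFLD, cirrhosis, HCC) has a group-level fecal community
  profile drawn from a log-normal abundance model. Cirrhosis/HCC groups get a
  ``diversity_effect`` < 1 which sharpens the profile (lower evenness, lower
  Shannon index), plus explicit multiplicative depletions of named genera.
* Each subject's fecal composition is a Dirichlet draw around their group
  profile (concentration ``theta``), and fecal counts are a multinomial at the
  fecal sequencing depth — i.e. Dirichlet-multinomial counts, overdispersed
  relative to plain multinomial sampling.
* Blood and liver communities are a mixture ``(1 - pi) * background +
  pi * fecal`` where ``pi`` is the group- and compartment-specific
  translocation fraction and ``fecal`` is that subject's own realized fecal
  composition. The tissue background lives on a disjoint set of background
  taxa except for a small configurable ``shared_tail`` of mass placed on the
  fecal genera, so that baseline overlap between tissue and gut profiles is
  controlled rather than zero.
* Paired liver transcriptomes are negative-binomial gene counts whose log mean
  is linear in the liver relative abundance of planted genera, with per-gene
  dispersions and log-normal library size factors.

Every draw comes from a named substream of one seed (:func:`gutliver._rng.substream`),
so the same configuration is bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .tables import GROUPS, CompartmentTable

TARGET_COMPARTMENTS = ("blood", "liver")


def _default_subjects() -> dict[str, int]:
    # cohort sizes of the study population the generator emulates
    return {"NAFLD": 21, "cirrhosis": 27, "HCC": 111}


def _default_pi() -> dict[str, dict[str, float]]:
    return {
        "NAFLD": {"blood": 0.03, "liver": 0.03},
        "cirrhosis": {"blood": 0.12, "liver": 0.12},
        "HCC": {"blood": 0.22, "liver": 0.22},
    }


def _default_diversity() -> dict[str, float]:
    return {"NAFLD": 1.0, "cirrhosis": 0.75, "HCC": 0.70}


def _default_depletions() -> list[tuple[str, str, float]]:
    # short-chain-fatty-acid-producer-like depletion in advanced disease
    return [
        ("genus_000", "cirrhosis", 1.0), ("genus_000", "HCC", 1.5),
        ("genus_001", "cirrhosis", 1.0), ("genus_001", "HCC", 1.5),
    ]


@dataclass
class SimConfig:
    """All knobs of the cohort and transcriptome generators.

    ``pi_by_group`` maps disease group -> {blood, liver} -> translocation
    fraction in [0, 1]. ``theta`` is the Dirichlet concentration scale
    (larger = less compositional overdispersion). ``diversity_effect`` < 1
    sharpens a group's fecal profile, lowering its alpha diversity.
    ``depleted_taxa`` holds (genus, group, log2 fold reduction) triples.
    """

    n_subjects_per_group: dict[str, int] = field(default_factory=_default_subjects)
    n_genera: int = 60
    n_background_taxa: int = 40
    depth_feces: int = 30_000
    depth_blood: int = 10_000
    depth_liver: int = 10_000
    pi_by_group: dict[str, dict[str, float]] = field(default_factory=_default_pi)
    diversity_effect: dict[str, float] = field(default_factory=_default_diversity)
    depleted_taxa: list[tuple[str, str, float]] = field(default_factory=_default_depletions)
    theta: float = 50.0
    shared_tail: float = 0.02
    pi_concentration: float = 150.0
    log_abund_sigma: float = 1.5
    # transcriptome block
    n_genes: int = 400
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    n_planted_pairs: int = 8
    planted_beta1: float = 5.0
    planted_pairs: list[tuple[str, str, float]] | None = None
    dispersion_mean: float = 0.1
    size_factor_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for group, n in self.n_subjects_per_group.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if n < 1:
                raise ValueError(f"need at least 1 subject in group {group!r}")
        for group in self.n_subjects_per_group:
            if group not in self.pi_by_group:
                raise ValueError(f"pi_by_group missing group {group!r}")
            for comp in TARGET_COMPARTMENTS:
                if comp not in self.pi_by_group[group]:
                    raise ValueError(f"pi_by_group[{group!r}] missing {comp!r}")
                pi = self.pi_by_group[group][comp]
                if not 0.0 <= pi <= 1.0:
                    raise ValueError(f"pi must be in [0, 1], got {pi}")
        if min(self.depth_feces, self.depth_blood, self.depth_liver) < 1:
            raise ValueError("sequencing depths must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0.0 <= self.shared_tail < 1.0:
            raise ValueError("shared_tail must be in [0, 1)")
        genera = set(self.genus_names())
        depleted = {t for t, _, _ in self.depleted_taxa}
        if len(depleted) > self.n_genera:
            raise ValueError("more depleted taxa than genera")
        unknown = depleted - genera
        if unknown:
            raise ValueError(f"depleted taxa not among the simulated genera: {sorted(unknown)}")

    def genus_names(self) -> list[str]:
        return [f"genus_{i:03d}" for i in range(self.n_genera)]

    def background_names(self) -> list[str]:
        return [f"tissue_taxon_{i:03d}" for i in range(self.n_background_taxa)]

    # -- round-trippable file form ----------------------------------------

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = dataclasses.asdict(self)
        d["depleted_taxa"] = [list(t) for t in self.depleted_taxa]
        if self.planted_pairs is not None:
            d["planted_pairs"] = [list(t) for t in self.planted_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "depleted_taxa" in d:
            d["depleted_taxa"] = [(t, g, float(x)) for t, g, x in d["depleted_taxa"]]
        if d.get("planted_pairs") is not None:
            d["planted_pairs"] = [(a, b, float(x)) for a, b, x in d["planted_pairs"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort, one record per sample/gene."""

    fecal_weights: pd.DataFrame        # sample_id -> pi_nominal, pi_realized
    fecal_compositions: pd.DataFrame   # subject_id x genus realized fecal profile
    group_effects: pd.DataFrame        # genus, group, log2_reduction
    gene_params: pd.DataFrame | None = None   # gene -> beta0, beta_cirrhosis, beta_HCC, alpha
    planted_pairs: pd.DataFrame | None = None  # gene, genus, beta1
    size_factors: pd.Series | None = None

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.fecal_weights.to_csv(os.path.join(outdir, "truth_fecal_weights.tsv"), sep="\t")
        self.fecal_compositions.to_csv(
            os.path.join(outdir, "truth_fecal_compositions.tsv"), sep="\t")
        self.group_effects.to_csv(
            os.path.join(outdir, "truth_group_effects.tsv"), sep="\t", index=False)
        if self.gene_params is not None:
            self.gene_params.to_csv(os.path.join(outdir, "truth_gene_params.tsv"), sep="\t")
        if self.planted_pairs is not None:
            self.planted_pairs.to_csv(
                os.path.join(outdir, "truth_planted_pairs.tsv"), sep="\t", index=False)
        if self.size_factors is not None:
            self.size_factors.rename("size_factor").to_csv(
                os.path.join(outdir, "truth_size_factors.tsv"), sep="\t")


def _lineage_frame(config: SimConfig) -> pd.DataFrame:
    rows = {}
    for i, g in enumerate(config.genus_names()):
        fam = f"family_{i // 2:02d}"
        rows[g] = dict(domain="Bacteria", phylum="phylum_gut", class_="class_gut",
                       order="order_gut", family=fam, genus=g)
    for i, t in enumerate(config.background_names()):
        fam = f"tissue_family_{i // 2:02d}"
        rows[t] = dict(domain="Bacteria", phylum="phylum_env", class_="class_env",
                       order="order_env", family=fam, genus=t)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.rename(columns={"class_": "class"})
    df.index.name = "taxon_id"
    return df[["domain", "phylum", "class", "order", "family", "genus"]]


def _group_profiles(config: SimConfig) -> pd.DataFrame:
    """Group-level mean fecal compositions over the genera axis."""
    rng = substream(config.seed, "fecal_base")
    log_abund = rng.normal(0.0, config.log_abund_sigma, size=config.n_genera)
    genera = config.genus_names()
    profiles = {}
    for group in config.n_subjects_per_group:
        eff = config.diversity_effect.get(group, 1.0)
        p = np.exp(log_abund / eff)
        for taxon, dep_group, log2fold in config.depleted_taxa:
            if dep_group == group:
                p[genera.index(taxon)] *= 2.0 ** (-log2fold)
        profiles[group] = p / p.sum()
    return pd.DataFrame(profiles, index=genera).T


def _dirichlet_multinomial(rng: np.random.Generator, mean: np.ndarray,
                           theta: float, depth: int) -> tuple[np.ndarray, np.ndarray]:
    """One Dirichlet-multinomial draw; returns (composition, counts)."""
    alpha = np.clip(theta * mean, 1e-12, None)
    comp = rng.dirichlet(alpha)
    return comp, rng.multinomial(depth, comp)


def simulate_cohort(config: SimConfig) -> tuple[CompartmentTable, SimTruth]:
    """Draw a full three-compartment cohort; deterministic given ``config.seed``."""
    genera = config.genus_names()
    background = config.background_names()
    taxa = genera + background
    profiles = _group_profiles(config)

    rng_bg = substream(config.seed, "background_base")
    bg_log = rng_bg.normal(0.0, config.log_abund_sigma, size=config.n_background_taxa)
    bg_profile = np.exp(bg_log)
    bg_profile /= bg_profile.sum()
    shared_profile = np.full(config.n_genera, 1.0 / max(config.n_genera, 1))

    rng = substream(config.seed, "cohort")
    depth = {"feces": config.depth_feces, "blood": config.depth_blood,
             "liver": config.depth_liver}
    rows, meta_rows, weights, fecal_comps = [], [], [], {}
    for group in config.n_subjects_per_group:
        for i in range(config.n_subjects_per_group[group]):
            subject = f"{group}_{i:03d}"
            fec_comp, fec_counts = _dirichlet_multinomial(
                rng, profiles.loc[group].to_numpy(), config.theta, depth["feces"])
            fecal_comps[subject] = fec_comp
            sid = f"{subject}_feces"
            rows.append(pd.Series(
                np.concatenate([fec_counts, np.zeros(config.n_background_taxa, dtype=int)]),
                index=taxa, name=sid))
            meta_rows.append(dict(sample_id=sid, subject_id=subject,
                                  compartment="feces", group=group))
            for comp_name in TARGET_COMPARTMENTS:
                pi = config.pi_by_group[group][comp_name]
                if 0.0 < pi < 1.0 and np.isfinite(config.pi_concentration):
                    c = config.pi_concentration
                    pi_r = rng.beta(pi * c, (1.0 - pi) * c)
                else:
                    pi_r = pi
                bg_full = np.concatenate([
                    config.shared_tail * shared_profile,
                    (1.0 - config.shared_tail) * bg_profile])
                fec_full = np.concatenate([fec_comp, np.zeros(config.n_background_taxa)])
                mix = (1.0 - pi_r) * bg_full + pi_r * fec_full
                _, counts = _dirichlet_multinomial(rng, mix, config.theta, depth[comp_name])
                sid = f"{subject}_{comp_name}"
                rows.append(pd.Series(counts, index=taxa, name=sid))
                meta_rows.append(dict(sample_id=sid, subject_id=subject,
                                      compartment=comp_name, group=group))
                weights.append(dict(sample_id=sid, compartment=comp_name, group=group,
                                    pi_nominal=pi, pi_realized=pi_r))

    counts = pd.DataFrame(rows).astype(np.int64)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = CompartmentTable(counts=counts, meta=meta,
                             lineage=_lineage_frame(config), rank="genus")
    truth = SimTruth(
        fecal_weights=pd.DataFrame(weights).set_index("sample_id"),
        fecal_compositions=pd.DataFrame.from_dict(
            fecal_comps, orient="index", columns=genera),
        group_effects=pd.DataFrame(config.depleted_taxa,
                                   columns=["genus", "group", "log2_reduction"]),
    )
    return table, truth


def simulate_transcriptome(
    config: SimConfig, truth: SimTruth, liver_table: CompartmentTable
) -> tuple[pd.DataFrame, SimTruth]:
    """Paired liver gene counts: NB with log mean linear in genus abundance.

    ``y[g, i] ~ NB(mean = s_i * exp(beta0_g + beta_group_g[group_i] +
    beta1_g * x[i, genus_g]), dispersion alpha_g)`` where ``x`` is the liver
    relative abundance. Only the planted (gene, genus) pairs have nonzero
    ``beta1``; only the planted DE genes have nonzero group effects.
    """
    liver = liver_table.subset(compartment="liver")
    rel = liver.to_relative().fractions
    genes = [f"gene_{i:04d}" for i in range(config.n_genes)]

    if config.planted_pairs is not None:
        pairs = list(config.planted_pairs)
    else:
        ranked = rel.mean(axis=0).sort_values(ascending=False)
        core = [g for g in ranked.index if g.startswith("genus_")]
        k = min(config.n_planted_pairs, len(core), config.n_genes)
        pairs = [(genes[i], core[i], config.planted_beta1) for i in range(k)]
    for _, genus, _ in pairs:
        if genus not in rel.columns:
            raise ValueError(f"planted genus {genus!r} absent from liver table")

    rng = substream(config.seed, "transcriptome")
    beta0 = rng.uniform(np.log(20.0), np.log(500.0), size=config.n_genes)
    alpha = rng.lognormal(np.log(config.dispersion_mean), 0.5, size=config.n_genes)
    beta_cirr = np.zeros(config.n_genes)
    beta_hcc = np.zeros(config.n_genes)
    n_de = min(config.n_de_genes, config.n_genes)
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    beta_hcc[de_idx] = signs * config.de_log2fc * np.log(2.0)
    both = rng.random(n_de) < 0.5   # half of the DE genes shift in cirrhosis too
    beta_cirr[de_idx[both]] = beta_hcc[de_idx[both]]

    beta1 = np.zeros(config.n_genes)
    pair_genus = {}
    for gene, genus, b1 in pairs:
        gi = genes.index(gene)
        beta1[gi] = b1
        pair_genus[gi] = genus

    samples = rel.index
    sf = rng.lognormal(0.0, config.size_factor_sigma, size=len(samples))
    group = liver.meta["group"]
    group_term = np.where(group == "HCC", 1.0, 0.0)[None, :] * beta_hcc[:, None] + \
        np.where(group == "cirrhosis", 1.0, 0.0)[None, :] * beta_cirr[:, None]
    x = np.zeros((config.n_genes, len(samples)))
    for gi, genus in pair_genus.items():
        x[gi, :] = rel[genus].to_numpy()
    mu = sf[None, :] * np.exp(beta0[:, None] + group_term + beta1[:, None] * x)
    # gamma-Poisson mixture == NB with Var = mu + alpha * mu^2
    lam = rng.gamma(shape=1.0 / alpha[:, None], scale=alpha[:, None] * mu)
    y = rng.poisson(lam).astype(np.int64)
    gene_counts = pd.DataFrame(y, index=genes, columns=samples)

    new_truth = dataclasses.replace(
        truth,
        gene_params=pd.DataFrame(
            dict(beta0=beta0, beta_cirrhosis=beta_cirr, beta_HCC=beta_hcc, alpha=alpha),
            index=pd.Index(genes, name="gene")),
        planted_pairs=pd.DataFrame(pairs, columns=["gene", "genus", "beta1"]),
        size_factors=pd.Series(sf, index=samples, name="size_factor"),
    )
    return gene_counts, new_truth
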