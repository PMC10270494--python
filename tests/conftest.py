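import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gutliver as gl

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_table(counts: dict[str, list[int]], meta_rows: list[tuple[str, str, str, str]],
               lineage: pd.DataFrame | None = None, rank: str = "genus") -> gl.CompartmentTable:
    """Build a CompartmentTable from column dicts and (sid, subj, comp, group) rows."""
    meta = pd.DataFrame(
        [dict(sample_id=s, subject_id=su, compartment=c, group=g)
         for s, su, c, g in meta_rows]).set_index("sample_id")
    df = pd.DataFrame(counts, index=meta.index)
    return gl.CompartmentTable(counts=df, meta=meta, lineage=lineage, rank=rank)


def trivial_lineage(taxa, families=None) -> pd.DataFrame:
    fam = families if families is not None else [f"fam_{i // 2}" for i in range(len(taxa))]
    return pd.DataFrame(
        {"domain": "Bacteria", "phylum": "P", "class": "C", "order": "O",
         "family": fam, "genus": list(taxa)},
        index=pd.Index(taxa, name="taxon_id"))


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 8/8/8-subject cohort with a clear translocation gradient."""
    cfg = gl.SimConfig(
        n_subjects_per_group={"NAFLD": 8, "cirrhosis": 8, "HCC": 8},
        n_genera=40, n_background_taxa=25,
        depth_feces=8000, depth_blood=5000, depth_liver=5000,
        n_genes=50, seed=11)
    table, truth = gl.simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_cohort_with_genes(small_cohort):
    cfg, table, truth = small_cohort
    genes, truth = gl.simulate_transcriptome(cfg, truth, table)
    return cfg, table, truth, genes


@pytest.fixture
def mixed_table():
    """Hand-built 3-genus table covering all compartments and groups."""
    taxa = ["gA", "gB", "gC"]
    rng = np.random.default_rng(7)
    rows, meta = [], []
    for g in gl.GROUPS:
        for i in range(3):
            for comp in gl.COMPARTMENTS:
                sid = f"{g}{i}_{comp}"
                rows.append(rng.integers(1, 50, size=3))
                meta.append((sid, f"{g}{i}", comp, g))
    counts = {t: [int(r[j]) for r in rows] for j, t in enumerate(taxa)}
    return make_table(counts, meta, lineage=trivial_lineage(taxa))
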