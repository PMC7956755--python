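"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import apquant as aq


def make_peptide_table(data: dict[tuple[str, str], list[float]], samples: list[str]) -> pd.DataFrame:
    """Build a peptide table from {(peptide_id, protein_id): intensities}."""
    idx = pd.MultiIndex.from_tuples(list(data), names=["peptide_id", "protein_group_id"])
    return pd.DataFrame(list(data.values()), index=idx, columns=samples, dtype=float)


def make_annotation(samples: list[str], groups: list[str], tissue: str = "cortex") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "tissue": tissue,
            "replicate_kind": "biological",
        }
    )


@pytest.fixture(scope="session")
def all_null_dataset():
    """2000-protein all-null dataset at the study's group sizes and CVs."""
    cfg = aq.SimConfig(
        n_proteins=2000,
        n_tissues=1,
        frac_null=1.0,
        frac_sustained=0.0,
        frac_ma_induced=0.0,
        frac_ma_unique=0.0,
        seed=42,
    )
    table, ann, truth = aq.simulate_dataset(cfg)
    return cfg, table, ann, truth


@pytest.fixture(scope="session")
def all_null_analysis(all_null_dataset):
    """Rollup + three contrasts + 20 EN splits of the all-null dataset."""
    cfg, table, ann, _ = all_null_dataset
    protein = aq.rollup_tissue(table.dropna(how="all"))
    t = protein.intensities
    comps = {g: aq.compare_groups(t, ann, g, "SH") for g in ("TM", "TS", "TSm")}
    nulls = aq.experimental_null(t, ann, control="SH", n_splits=20, seed=43)
    return protein, comps, nulls


@pytest.fixture(scope="session")
def planted_dataset():
    """2000-protein dataset with 2-fold effects planted on 10% per pattern."""
    cfg = aq.SimConfig(n_proteins=2000, n_tissues=1, effect_log2fc=1.0, seed=7)
    table, ann, truth = aq.simulate_dataset(cfg)
    return cfg, table, ann, truth


@pytest.fixture(scope="session")
def planted_analysis(planted_dataset):
    cfg, table, ann, truth = planted_dataset
    result = aq.analyze_tissue(
        "cortex", table, ann, fc_cutoff=1.4, n_splits=20, seed=8
    )
    return result, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise dataset: 2-fold planted effects, ~30 proteins per pattern."""
    cfg = aq.SimConfig(
        n_proteins=100,
        n_tissues=1,
        frac_null=0.10,
        frac_sustained=0.30,
        frac_ma_induced=0.30,
        frac_ma_unique=0.30,
        effect_log2fc=1.0,
        bio_cv=0.0,
        tech_cv=0.0,
        peptide_cv=0.0,
        outlier_peptide_rate=0.0,
        missing_rate=0.0,
        peptide_missing_rate=0.0,
        loading_sd_log2=0.0,
        peptides_per_protein=(2, 4, 6),
        seed=5,
    )
    table, ann, truth = aq.simulate_dataset(cfg)
    return cfg, table, ann, truth


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_dataset):
    """No loading variation in the zero-noise config, so the loading
    correction (which would only add composition noise) is switched off."""
    cfg, table, ann, truth = noiseless_dataset
    result = aq.analyze_tissue(
        "cortex", table, ann, fc_cutoff=1.4, n_splits=5, seed=6, do_normalize=False
    )
    return result, truth
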