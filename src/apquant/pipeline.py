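"""End-to-end orchestration: simulate -> rollup -> differential -> classify -> report.

:func:`run_pipeline` executes the full analysis for every tissue of one
dataset (simulated or loaded) and returns a nested results object; the CLI's
``run-all`` subcommand and the acceptance script are thin layers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import classify_aps, fold_of_significance, validate_classification
from .differential import (
    DEFAULT_ALPHA,
    DEFAULT_FC_THRESHOLDS,
    APSet,
    call_aps,
    compare_groups,
    experimental_null,
    fadr_grid,
    select_cutoff,
)
from .quant import ProteinQuantResult, aggregate_to_protein, cv_summary, normalize, remove_outlier_peptides
from .simulate import SimConfig, simulate_dataset

TREATMENT_GROUPS = ("TM", "TS", "TSm")


@dataclass
class TissueResult:
    tissue: str
    protein: ProteinQuantResult
    comparisons: pd.DataFrame  # all three contrasts stacked
    nulls: list[pd.DataFrame]
    grids: dict[str, pd.DataFrame]
    cutoff: dict
    fc_cutoff: float
    alpha: float
    ap_sets: dict[str, APSet]
    ap_union: set[str]
    z: object | None = None
    classes: pd.DataFrame | None = None
    validation: dict | None = None
    cv: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    config: SimConfig | None
    annotation: pd.DataFrame
    truth: pd.DataFrame | None
    tissues: dict[str, TissueResult] = field(default_factory=dict)


def rollup_tissue(
    peptides: pd.DataFrame,
    min_corr: float = 0.5,
    min_peptides_for_test: int = 4,
    do_normalize: bool = True,
) -> ProteinQuantResult:
    """Normalize, filter outlier peptides, and aggregate one tissue's table.

    ``do_normalize=False`` skips loading correction — appropriate for data
    known to carry no per-sample loading variation, where median centering
    would only inject composition-driven estimation noise.
    """
    norm = peptides
    if do_normalize:
        norm, _ = normalize(peptides)
    filtered, report = remove_outlier_peptides(
        norm, min_corr=min_corr, min_peptides_for_test=min_peptides_for_test
    )
    return aggregate_to_protein(filtered, removal_report=report)


def analyze_tissue(
    tissue: str,
    peptides: pd.DataFrame,
    ann: pd.DataFrame,
    fc_cutoff: float | str = "auto",
    alpha: float = DEFAULT_ALPHA,
    fc_thresholds: tuple[float, ...] = DEFAULT_FC_THRESHOLDS,
    n_splits: int = 20,
    seed: int = 0,
    classify_method: str = "cluster",
    tau: float = 0.5,
    k_max: int = 8,
    do_normalize: bool = True,
) -> TissueResult:
    """Full single-tissue analysis from a peptide table and its annotation."""
    tiss_ann = ann[ann["tissue"] == tissue]
    cols = [c for c in tiss_ann["sample_id"] if c in peptides.columns]
    sub = peptides[cols].dropna(how="all")
    protein = rollup_tissue(sub, do_normalize=do_normalize)
    table = protein.intensities

    comparisons = []
    for g in TREATMENT_GROUPS:
        comparisons.append(compare_groups(table, tiss_ann, g, "SH"))
    comp = pd.concat(comparisons, ignore_index=True)

    nulls = experimental_null(table, tiss_ann, control="SH", n_splits=n_splits, seed=seed)
    grids = {
        g: fadr_grid(
            comp[comp["contrast"] == f"{g}/SH"], nulls, fc_thresholds=fc_thresholds, alpha=alpha
        )
        for g in TREATMENT_GROUPS
    }
    stacked = pd.concat(grids.values(), ignore_index=True)
    cutoff = select_cutoff(stacked)
    chosen = float(cutoff["selected_fc_threshold"]) if fc_cutoff == "auto" else float(fc_cutoff)

    ap_sets = {
        g: call_aps(comp[comp["contrast"] == f"{g}/SH"], fc_cutoff=chosen, alpha=alpha)
        for g in TREATMENT_GROUPS
    }
    ap_union: set[str] = set()
    for s in ap_sets.values():
        ap_union |= s.protein_ids

    result = TissueResult(
        tissue=tissue,
        protein=protein,
        comparisons=comp,
        nulls=nulls,
        grids=grids,
        cutoff=cutoff,
        fc_cutoff=chosen,
        alpha=alpha,
        ap_sets=ap_sets,
        ap_union=ap_union,
        cv=cv_summary(table, tiss_ann),
    )

    # classification needs all three contrasts testable for each AP
    testable_all = (
        comp[comp["testable"]].groupby("protein_group_id")["contrast"].nunique() == 3
    )
    classifiable = sorted(ap_union & set(testable_all[testable_all].index))
    if len(classifiable) >= 3:
        z = fold_of_significance(comp, protein_ids=classifiable)
        classes = classify_aps(z, method=classify_method, tau=tau, k_max=k_max, seed=seed)
        result.z = z
        result.classes = classes
        result.validation = validate_classification(classes, comp)
    return result


def run_pipeline(
    config: SimConfig,
    fc_cutoff: float | str = "auto",
    alpha: float = DEFAULT_ALPHA,
    n_splits: int = 20,
    classify_method: str = "cluster",
    tau: float = 0.5,
    k_max: int = 8,
) -> PipelineResult:
    """Simulate one dataset and analyze every tissue."""
    peptides, ann, truth = simulate_dataset(config)
    result = PipelineResult(config=config, annotation=ann, truth=truth)
    for tissue in ann["tissue"].unique():
        result.tissues[tissue] = analyze_tissue(
            tissue,
            peptides,
            ann,
            fc_cutoff=fc_cutoff,
            alpha=alpha,
            n_splits=n_splits,
            seed=int(config.seed) + 1,
            classify_method=classify_method,
            tau=tau,
            k_max=k_max,
        )
    return result
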