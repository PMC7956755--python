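"""Peptide-to-protein rollup: normalization, outlier-peptide removal, aggregation.

The rollup turns a peptide x sample ion-current table into a protein x sample
table in three stages, each exposed both as a scikit-learn transformer and as
a plain function:

1. :class:`MedianNormalizer` — dataset-wide sample-loading correction that
   equalizes per-sample median log2 intensity;
2. :class:`OutlierPeptideFilter` — removes peptides whose across-sample
   profile disagrees with their protein's consensus profile;
3. :class:`ProteinAggregator` — sums retained peptide ion currents per
   protein, requiring >= 2 peptides per protein.

Missing cells (NaN) are never imputed; aggregation yields a missing protein
cell only when all of the protein's peptides are missing in that sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative factors.

    The robust median-of-medians target makes the geometric mean of the
    factors approximately (not exactly) 1; the realized log2 deviation is
    kept in ``log2_geomean`` for auditing.
    """

    factors: pd.Series
    reference: str
    log2_geomean: float = 0.0

    def __post_init__(self) -> None:
        self.log2_geomean = float(np.log2(self.factors.astype(float)).mean())


@dataclass
class ProteinQuantResult:
    """Aggregated protein table plus per-protein peptide bookkeeping."""

    intensities: pd.DataFrame
    #: per retained protein: n_peptides_used, n_peptides_removed
    peptide_counts: pd.DataFrame
    #: proteins dropped for having < 2 peptide rows
    dropped: pd.DataFrame


def _check_peptide_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("empty peptide table")
    if table.index.nlevels != 2:
        raise ValueError(
            "peptide table must be indexed by (peptide_id, protein_group_id)"
        )


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Equalize per-sample median log2 intensity across the dataset.

    Medians are computed over peptides present in every sample (complete
    rows); if there are none, each sample's median over its own present
    values is used instead. Every sample is scaled so its median log2
    intensity meets the grand center, defined as the *median* of the
    per-sample medians: a robust target, so rescaling any one sample (a
    loading change) leaves the normalized table untouched as long as that
    sample is not itself the pivotal median.

    Attributes
    ----------
    factors_ : NormalizationFactors
        Fitted per-sample multiplicative factors.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MedianNormalizer":
        _check_peptide_table(X)
        if X.shape[1] < 2:
            raise ValueError("normalization requires >= 2 samples")
        empty = X.columns[X.notna().sum(axis=0) == 0]
        if len(empty):
            raise ValueError(f"sample(s) with no present intensities: {list(empty)}")
        log2x = np.log2(X.astype(float))
        complete = log2x.dropna(axis=0, how="any")
        if len(complete):
            medians = complete.median(axis=0)
            reference = "median-log2-complete-rows"
        else:
            medians = log2x.median(axis=0, skipna=True)
            reference = "median-log2-present-values"
        shift = medians.median() - medians  # robust grand center (median of medians)
        self.factors_ = NormalizationFactors(
            factors=np.exp2(shift.astype(float)), reference=reference
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "factors_"):
            raise ValueError("MedianNormalizer is not fitted")
        return X * self.factors_.factors

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationFactors]:
    """Functional wrapper around :class:`MedianNormalizer`."""
    est = MedianNormalizer().fit(table)
    return est.transform(table), est.factors_


def _loo_profile_correlations(log2x: np.ndarray) -> np.ndarray:
    """Leave-one-out Pearson correlation of each peptide with the per-sample
    median profile of the protein's other peptides (pairwise-complete)."""
    k = log2x.shape[0]
    corrs = np.ones(k)
    for i in range(k):
        others = np.delete(log2x, i, axis=0)
        all_nan = np.isnan(others).all(axis=0)
        ref = np.full(others.shape[1], np.nan)
        if (~all_nan).any():
            with np.errstate(all="ignore"):
                ref[~all_nan] = np.nanmedian(others[:, ~all_nan], axis=0)
        xi = log2x[i]
        ok = ~np.isnan(xi) & ~np.isnan(ref)
        if ok.sum() < 3:
            continue  # too few pairs to judge: keep
        a, b = xi[ok], ref[ok]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue  # flat profile: keep
        corrs[i] = float(np.corrcoef(a, b)[0, 1])
    return corrs


class OutlierPeptideFilter(TransformerMixin, BaseEstimator):
    """Drop peptides whose profile disagrees with their protein's consensus.

    For proteins with at least ``min_peptides_for_test`` peptides, each
    peptide's log2 profile is correlated (Pearson, pairwise-complete) against
    the leave-one-out per-sample median profile of its siblings; peptides
    below ``min_corr`` are removed, but a protein is never reduced below two
    peptides (the highest-correlation peptides are retained instead).
    Proteins with fewer peptides pass through untouched.

    Parameters
    ----------
    min_corr : float, default 0.5
        Correlation threshold below which a peptide is an outlier.
    min_peptides_for_test : int, default 4
        Minimum peptides a protein needs before the test is applied.

    Attributes
    ----------
    report_ : pd.DataFrame
        One row per tested peptide: protein_group_id, peptide_id,
        correlation, removed.
    """

    def __init__(self, min_corr: float = 0.5, min_peptides_for_test: int = 4):
        self.min_corr = min_corr
        self.min_peptides_for_test = min_peptides_for_test

    def fit(self, X: pd.DataFrame, y=None) -> "OutlierPeptideFilter":
        _check_peptide_table(X)
        rows = []
        removed_index = []
        log2all = np.log2(X.astype(float).to_numpy())
        for pid, idx in X.groupby(level="protein_group_id").indices.items():
            if len(idx) < self.min_peptides_for_test:
                continue
            corrs = _loo_profile_correlations(log2all[idx])
            flagged = corrs < self.min_corr
            if (~flagged).sum() < 2:
                # keep the 2 best-correlated peptides regardless
                keep_best = np.argsort(corrs)[::-1][:2]
                flagged = np.ones(len(idx), dtype=bool)
                flagged[keep_best] = False
            for j, (i_row, c, f) in enumerate(zip(idx, corrs, flagged)):
                rows.append(
                    {
                        "protein_group_id": pid,
                        "peptide_id": X.index[i_row][0],
                        "correlation": c,
                        "removed": bool(f),
                    }
                )
                if f:
                    removed_index.append(i_row)
        self.report_ = pd.DataFrame(
            rows, columns=["protein_group_id", "peptide_id", "correlation", "removed"]
        )
        self._removed_positions = np.array(sorted(removed_index), dtype=int)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "report_"):
            raise ValueError("OutlierPeptideFilter is not fitted")
        removed = set(
            zip(self.report_.loc[self.report_["removed"], "peptide_id"],
                self.report_.loc[self.report_["removed"], "protein_group_id"])
        )
        keep = [i for i, key in enumerate(X.index) if (key[0], key[1]) not in removed]
        return X.iloc[keep]

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def remove_outlier_peptides(
    table: pd.DataFrame, min_corr: float = 0.5, min_peptides_for_test: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper around :class:`OutlierPeptideFilter`.

    Returns the filtered table and the per-peptide removal report.
    """
    est = OutlierPeptideFilter(min_corr=min_corr, min_peptides_for_test=min_peptides_for_test)
    filtered = est.fit_transform(table)
    return filtered, est.report_


class ProteinAggregator(TransformerMixin, BaseEstimator):
    """Sum retained peptide ion currents into protein-level intensities.

    A protein cell is the sum of its peptides' present intensities and is
    missing only when every peptide is missing in that sample. Proteins with
    fewer than two peptide rows overall are dropped and reported.
    """

    def __init__(self, removal_report: pd.DataFrame | None = None):
        self.removal_report = removal_report

    def fit(self, X: pd.DataFrame, y=None) -> "ProteinAggregator":
        _check_peptide_table(X)
        return self

    def transform(self, X: pd.DataFrame) -> ProteinQuantResult:
        _check_peptide_table(X)
        counts = X.groupby(level="protein_group_id").size()
        keep = counts[counts >= 2].index
        dropped = counts[counts < 2].rename("n_peptides").reset_index()
        sub = X[X.index.get_level_values("protein_group_id").isin(keep)]
        if sub.empty:
            raise ValueError("no protein has >= 2 peptides; nothing to aggregate")
        agg = sub.groupby(level="protein_group_id").sum(min_count=1)
        agg.index.name = "protein_group_id"
        removed = pd.Series(0, index=agg.index, dtype=int)
        if self.removal_report is not None and len(self.removal_report):
            rr = (
                self.removal_report[self.removal_report["removed"]]
                .groupby("protein_group_id")
                .size()
            )
            removed = removed.add(rr.reindex(agg.index, fill_value=0), fill_value=0).astype(int)
        meta = pd.DataFrame(
            {"n_peptides_used": counts.loc[agg.index], "n_peptides_removed": removed}
        )
        return ProteinQuantResult(intensities=agg, peptide_counts=meta, dropped=dropped)

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> ProteinQuantResult:
        return self.fit(X).transform(X)


def aggregate_to_protein(
    table: pd.DataFrame, removal_report: pd.DataFrame | None = None
) -> ProteinQuantResult:
    """Functional wrapper around :class:`ProteinAggregator`."""
    return ProteinAggregator(removal_report=removal_report).fit_transform(table)


def cv_summary(protein_table: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-(tissue, group, replicate kind) median protein-level CV.

    CV per protein is sd/mean (sd with n-1 denominator) over present
    intensities, requiring >= 2 present values. Groups with < 2 samples are
    skipped.
    """
    rows = []
    for (tissue, group, kind), sub in ann.groupby(["tissue", "group", "replicate_kind"]):
        cols = [c for c in sub["sample_id"] if c in protein_table.columns]
        if len(cols) < 2:
            continue
        vals = protein_table[cols]
        n_present = vals.notna().sum(axis=1)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        cv = (sd / mean)[n_present >= 2].dropna()
        if cv.empty:
            continue
        rows.append(
            {
                "tissue": tissue,
                "group": group,
                "replicate_kind": kind,
                "n_samples": len(cols),
                "n_proteins": int(cv.size),
                "median_cv": float(cv.median()),
                "mean_cv": float(cv.mean()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tissue", "group", "replicate_kind", "n_samples",
            "n_proteins", "median_cv", "mean_cv",
        ],
    )
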