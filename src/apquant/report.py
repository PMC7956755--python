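"""Dataset- and result-level summaries: ratio PCA, pairwise R2, AP overlap,
volcano exports.

These summaries operate on protein-level tables and AP sets and mirror the
global quality-control views of a two-tissue differential proteomics study:
a PCA of per-(tissue, contrast) log2-ratio vectors, squared Pearson
correlations between those vectors, overlap statistics between AP sets, and
plot-ready volcano tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from sklearn.decomposition import PCA  # noqa: E402

from .differential import APSet  # noqa: E402


@dataclass
class RatioMatrix:
    """Complete-case log2 ratios vs SH; columns are (tissue, contrast)."""

    values: pd.DataFrame
    #: proteins quantified (>= 1 present value) in every tissue
    shared_protein_count: int


def build_ratio_matrix(
    tables: dict[str, pd.DataFrame], ann: pd.DataFrame, per_sample: bool = False
) -> RatioMatrix:
    """Log2 ratios of group means vs SH, per tissue, complete cases only.

    ``tables`` maps tissue name to a protein x sample intensity table. With
    ``per_sample`` each non-SH sample contributes its own ratio column
    (sample / SH group mean) instead of a per-group mean ratio.
    """
    if not tables:
        raise ValueError("no protein tables given")
    shared: pd.Index | None = None
    for df in tables.values():
        quantified = df.index[df.notna().any(axis=1)]
        shared = quantified if shared is None else shared.intersection(quantified)
    if shared is None or len(shared) == 0:
        raise ValueError("no proteins shared across tissues")
    cols = {}
    for tissue, df in tables.items():
        tiss_ann = ann[(ann["tissue"] == tissue) & (ann["replicate_kind"] == "biological")]
        sh_cols = tiss_ann.loc[tiss_ann["group"] == "SH", "sample_id"]
        sh_cols = [c for c in sh_cols if c in df.columns]
        if not sh_cols:
            raise ValueError(f"tissue {tissue!r} has no SH samples")
        sh_mean = df.loc[shared, sh_cols].mean(axis=1)
        for group in ("TM", "TS", "TSm"):
            gcols = [
                c
                for c in tiss_ann.loc[tiss_ann["group"] == group, "sample_id"]
                if c in df.columns
            ]
            if not gcols:
                continue
            if per_sample:
                for c in gcols:
                    cols[(tissue, f"{group}/SH", c)] = np.log2(df.loc[shared, c] / sh_mean)
            else:
                cols[(tissue, f"{group}/SH")] = np.log2(
                    df.loc[shared, gcols].mean(axis=1) / sh_mean
                )
    mat = pd.DataFrame(cols).dropna(axis=0, how="any")
    return RatioMatrix(values=mat, shared_protein_count=int(len(shared)))


def pca_of_ratios(m: RatioMatrix | pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with the (tissue, contrast) ratio vectors as observations.

    Returns (scores, explained-variance fractions); the fractions sum to 1
    over all computed components.
    """
    df = m.values if isinstance(m, RatioMatrix) else m
    if df.shape[1] < 2:
        raise ValueError("PCA needs >= 2 ratio columns")
    X = df.to_numpy(dtype=float).T  # observations = columns of the ratio matrix
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant ratio matrix; PCA undefined")
    pca = PCA(n_components=None)
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    score_df = pd.DataFrame(
        scores,
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return score_df, evr


def pairwise_r2(m: RatioMatrix | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Squared (and signed) pairwise Pearson correlations of ratio columns.

    Computed over pairwise-complete cases; zero-variance columns yield NaN
    for their pairs. Returns (r_squared, r).
    """
    df = m.values if isinstance(m, RatioMatrix) else m
    if df.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    r = df.corr(method="pearson", min_periods=2)
    r2 = r ** 2
    for c in df.columns:
        col = df[c].dropna()
        if col.nunique() <= 1:
            r.loc[c, :] = np.nan
            r.loc[:, c] = np.nan
            r2.loc[c, :] = np.nan
            r2.loc[:, c] = np.nan
    np.fill_diagonal(r2.values, 1.0)
    np.fill_diagonal(r.values, 1.0)
    return r2, r


@dataclass
class OverlapReport:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    intersection: int
    union: int
    jaccard: float
    #: intersection / size of the smaller set (0 when either set is empty)
    overlap_coefficient: float
    #: members of the intersection altered in the same direction in both sets
    directional_agreement: int


def ap_overlap(a: APSet, b: APSet) -> OverlapReport:
    """Intersection/union/Jaccard and directional agreement of two AP sets."""
    sa, sb = a.protein_ids, b.protein_ids
    inter = sa & sb
    union = sa | sb
    jaccard = len(inter) / len(union) if union else 0.0
    overlap_coef = len(inter) / min(len(sa), len(sb)) if sa and sb else 0.0
    da, db = a.directions(), b.directions()
    same_dir = sum(1 for p in inter if da.get(p) == db.get(p))
    return OverlapReport(
        label_a=a.contrast,
        label_b=b.contrast,
        n_a=len(sa),
        n_b=len(sb),
        intersection=len(inter),
        union=len(union),
        jaccard=jaccard,
        overlap_coefficient=overlap_coef,
        directional_agreement=same_dir,
    )


def volcano_export(
    comparisons: pd.DataFrame,
    fc_cutoff: float = 1.4,
    alpha: float = 0.05,
    tsv_path: str | None = None,
    fig_path: str | None = None,
) -> pd.DataFrame:
    """Plot-ready volcano table: log2FC, -log10 p, AP flag per protein.

    The AP flag reproduces :func:`apquant.differential.call_aps` membership
    exactly. Optionally writes a TSV and a scatter figure.
    """
    if comparisons is None or len(comparisons) == 0:
        raise ValueError("empty comparison table")
    from .differential import call_aps

    aps = call_aps(comparisons, fc_cutoff=fc_cutoff, alpha=alpha)
    flagged = aps.protein_ids
    out = pd.DataFrame(
        {
            "protein_group_id": comparisons["protein_group_id"].to_numpy(),
            "contrast": comparisons["contrast"].to_numpy(),
            "log2fc": comparisons["log2fc"].to_numpy(),
            "neg_log10_p": -np.log10(
                np.clip(comparisons["p_value"].to_numpy(dtype=float), 1e-300, None)
            ),
            "is_ap": comparisons["protein_group_id"].isin(flagged).to_numpy(),
        }
    )
    if tsv_path:
        out.to_csv(tsv_path, sep="\t", index=False, na_rep="")
    if fig_path:
        fig, ax = plt.subplots(figsize=(5, 4))
        bg = out[~out["is_ap"]]
        fg = out[out["is_ap"]]
        ax.scatter(bg["log2fc"], bg["neg_log10_p"], s=4, c="grey", alpha=0.5, label="not AP")
        ax.scatter(fg["log2fc"], fg["neg_log10_p"], s=6, c="crimson", label="AP")
        ax.axhline(-np.log10(alpha), ls="--", lw=0.6, c="k")
        for v in (np.log2(fc_cutoff), -np.log2(fc_cutoff)):
            ax.axvline(v, ls="--", lw=0.6, c="k")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        ax.set_title(out["contrast"].iloc[0])
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(fig_path, dpi=150)
        plt.close(fig)
    return out
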