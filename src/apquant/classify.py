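"""Fold-of-significance z-scores and AP expression-pattern classification.

Each altered protein gets, per contrast (TM/SH, TS/SH, TSm/SH), a *fold of
significance*: a volcano-style score sign(log2FC) x (-log10 p) that carries
the direction of the change and the strength of its evidence. Row
standardization (mean 0, sd 1 across the three contrasts) puts proteins of
very different effect sizes on a common footing for clustering.

Categories are defined by how the drug-treated severe-injury group (TSm)
relates to the other two contrasts in z-space, with d_TM = |z_TSm - z_TM|
and d_TS = |z_TSm - z_TS|:

- ``sustained``  — TSm tracks TS (d_TS small): injury effect persists under drug;
- ``ma_induced`` — TSm tracks TM (d_TM small): drug restores a mild-injury-like profile;
- ``ma_unique``  — TSm resembles neither: drug-specific change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

CONTRAST_ORDER = ("TM/SH", "TS/SH", "TSm/SH")
CATEGORIES = ("sustained", "ma_induced", "ma_unique")

P_FLOOR = 1e-15


@dataclass
class ZScores:
    """Fold-of-significance matrix: raw signed scores and row-standardized z."""

    z: pd.DataFrame
    raw: pd.DataFrame
    zero_spread: pd.Series  # rows whose three raw scores coincide


def fold_of_significance(
    comparisons: pd.DataFrame,
    protein_ids: list[str] | None = None,
    standardize: bool = True,
    score: str = "signed_logp",
    p_floor: float = P_FLOOR,
) -> ZScores:
    """Per-protein, per-contrast fold-of-significance scores.

    ``comparisons`` stacks the three contrasts of one tissue (long format,
    as produced by :func:`apquant.differential.compare_groups`). The raw
    score is sign(log2FC) x (-log10 p) (``score="signed_logp"``) or
    log2FC x (-log10 p) (``score="product"``); p is floored at ``p_floor``.
    With ``standardize`` the three scores of each row are centered and
    scaled to sd 1 (n-1 denominator); rows with no spread are flagged and
    set to 0.
    """
    if score not in ("signed_logp", "product"):
        raise ValueError(f"unknown score construction: {score!r}")
    sub = comparisons
    if protein_ids is not None:
        sub = sub[sub["protein_group_id"].isin(set(protein_ids))]
    pivot_p = sub.pivot(index="protein_group_id", columns="contrast", values="p_value")
    pivot_l = sub.pivot(index="protein_group_id", columns="contrast", values="log2fc")
    missing_cols = [c for c in CONTRAST_ORDER if c not in pivot_p.columns]
    if missing_cols:
        raise ValueError(f"missing contrast(s): {missing_cols}")
    pivot_p = pivot_p[list(CONTRAST_ORDER)]
    pivot_l = pivot_l[list(CONTRAST_ORDER)]
    incomplete = pivot_p.isna().any(axis=1) | pivot_l.isna().any(axis=1)
    if incomplete.any():
        bad = list(pivot_p.index[incomplete])
        raise ValueError(
            f"{len(bad)} protein(s) lack a testable value in some contrast: {bad[:10]}"
        )
    logp = -np.log10(pivot_p.clip(lower=p_floor))
    if score == "signed_logp":
        raw = np.sign(pivot_l) * logp
    else:
        raw = pivot_l * logp
    if standardize:
        mu = raw.mean(axis=1)
        sd = raw.std(axis=1, ddof=1)
        zero_spread = sd < 1e-12
        z = raw.sub(mu, axis=0).div(sd.where(~zero_spread, 1.0), axis=0)
        z[zero_spread] = 0.0
    else:
        z = raw.copy()
        zero_spread = raw.std(axis=1, ddof=1) < 1e-12
    return ZScores(z=z, raw=raw, zero_spread=zero_spread)


def _rule_assign(
    z: pd.DataFrame, tau: float, tau_prime: float
) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    d_tm = (z["TSm/SH"] - z["TM/SH"]).abs()
    d_ts = (z["TSm/SH"] - z["TS/SH"]).abs()
    cat = pd.Series(index=z.index, dtype=object)
    ambiguous = pd.Series(False, index=z.index)
    ma_induced = d_tm < d_ts - tau
    sustained = d_ts < d_tm - tau
    unique = ~ma_induced & ~sustained & (np.minimum(d_tm, d_ts) >= tau_prime)
    cat[ma_induced] = "ma_induced"
    cat[sustained] = "sustained"
    cat[unique] = "ma_unique"
    rest = cat.isna()
    cat[rest & (d_tm <= d_ts)] = "ma_induced"
    cat[rest & (d_tm > d_ts)] = "sustained"
    ambiguous[rest] = True
    dist = pd.DataFrame({"d_tm": d_tm, "d_ts": d_ts})
    return cat, ambiguous, dist


class PatternClassifier(BaseEstimator):
    """Assign sustained / ma_induced / ma_unique categories to AP z-rows.

    Parameters
    ----------
    method : {"cluster", "rule"}, default "cluster"
        ``"cluster"`` runs agglomerative hierarchical clustering (Ward
        linkage, Euclidean distance) on the z rows and cuts the tree at the
        smallest k <= ``k_max`` for which every cluster is label-pure under
        the distance rule applied to its members; each cluster is labeled by
        its centroid. ``"rule"`` assigns each protein directly.
    tau : float, default 0.5
        Margin (z units) by which one distance must undercut the other
        before TSm is declared to track that contrast.
    tau_prime : float or None, default None
        Minimum distance to both contrasts for ``ma_unique``; defaults to
        ``tau``.
    k_max : int, default 8
        Largest tree cut examined.
    random_state : int, default 0
        Unused by the deterministic Ward linkage; kept for API symmetry.

    Attributes
    ----------
    categories_ : pd.Series of category per protein.
    cluster_ids_ : pd.Series of cluster id (``"cluster"`` method) or -1.
    distances_ : pd.DataFrame with d_tm, d_ts per protein.
    ambiguous_ : pd.Series of bool; rule fell through to nearest-neighbor.
    n_clusters_ : int.
    """

    def __init__(
        self,
        method: str = "cluster",
        tau: float = 0.5,
        tau_prime: float | None = None,
        k_max: int = 8,
        random_state: int = 0,
    ):
        self.method = method
        self.tau = tau
        self.tau_prime = tau_prime
        self.k_max = k_max
        self.random_state = random_state

    def _effective_tau_prime(self) -> float:
        return self.tau if self.tau_prime is None else self.tau_prime

    def fit(self, X: pd.DataFrame, y=None) -> "PatternClassifier":
        if self.method not in ("cluster", "rule"):
            raise ValueError(f"unknown method: {self.method!r}")
        if len(X) < 3:
            raise ValueError(f"need >= 3 APs to classify, got {len(X)}")
        z = X[list(CONTRAST_ORDER)]
        rule_cat, ambiguous, dist = _rule_assign(z, self.tau, self._effective_tau_prime())
        if self.method == "rule":
            self.categories_ = rule_cat
            self.cluster_ids_ = pd.Series(-1, index=z.index)
            self.n_clusters_ = 0
        else:
            link = hierarchy.linkage(z.to_numpy(), method="ward")
            chosen = None
            for kk in range(2, min(self.k_max, len(z)) + 1):
                labels = hierarchy.fcluster(link, t=kk, criterion="maxclust")
                if all(
                    rule_cat[labels == c].nunique() == 1 for c in np.unique(labels)
                ):
                    chosen = labels
                    break
            if chosen is None:
                chosen = hierarchy.fcluster(
                    link, t=min(self.k_max, len(z)), criterion="maxclust"
                )
            cluster_ids = pd.Series(chosen, index=z.index)
            centroid_cat = {}
            for c in np.unique(chosen):
                centroid = z[cluster_ids == c].mean(axis=0).to_frame().T
                centroid.index = [c]
                ccat, _, _ = _rule_assign(centroid, self.tau, self._effective_tau_prime())
                centroid_cat[c] = ccat.iloc[0]
            self.categories_ = cluster_ids.map(centroid_cat)
            self.cluster_ids_ = cluster_ids
            self.n_clusters_ = int(len(np.unique(chosen)))
        self.distances_ = dist
        self.ambiguous_ = ambiguous
        return self

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Rule-based assignment of (possibly new) z rows."""
        cat, _, _ = _rule_assign(
            X[list(CONTRAST_ORDER)], self.tau, self._effective_tau_prime()
        )
        return cat

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).categories_


def classify_aps(
    z: ZScores | pd.DataFrame,
    method: str = "cluster",
    tau: float = 0.5,
    tau_prime: float | None = None,
    k_max: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Classify AP z-rows; returns one row per protein.

    Columns: protein_group_id, category, cluster_id, d_tm, d_ts, ambiguous.
    """
    zdf = z.z if isinstance(z, ZScores) else z
    est = PatternClassifier(
        method=method, tau=tau, tau_prime=tau_prime, k_max=k_max, random_state=seed
    ).fit(zdf)
    return pd.DataFrame(
        {
            "protein_group_id": zdf.index,
            "category": est.categories_.to_numpy(),
            "cluster_id": est.cluster_ids_.to_numpy(),
            "d_tm": est.distances_["d_tm"].to_numpy(),
            "d_ts": est.distances_["d_ts"].to_numpy(),
            "ambiguous": est.ambiguous_.to_numpy(),
        }
    )


def validate_classification(
    classes: pd.DataFrame, comparisons: pd.DataFrame, eps: float = 0.1
) -> dict:
    """Check categories against the TSm/TM-vs-TSm/TS fold-change geometry.

    For each protein the (x, y) scatter coordinates are
    x = log2(FC_TSm / FC_TM) and y = log2(FC_TSm / FC_TS) (the SH
    denominators cancel). Sustained proteins should be displaced mostly
    along x (drug did not move them off the severe-injury profile, so they
    differ from TM); ma_induced mostly along y; ma_unique has no required
    dominance. Categories whose two mean displacements are both below
    ``eps`` are reported as not applicable.
    """
    if classes is None or len(classes) == 0:
        raise ValueError("no classified APs")
    fc = comparisons.pivot(index="protein_group_id", columns="contrast", values="fc")
    for c in CONTRAST_ORDER:
        if c not in fc.columns:
            raise ValueError(f"comparisons lack contrast {c!r}")
    x = np.log2(fc["TSm/SH"] / fc["TM/SH"])
    y = np.log2(fc["TSm/SH"] / fc["TS/SH"])
    coords = pd.DataFrame({"x_log2_tsm_tm": x, "y_log2_tsm_ts": y})
    merged = classes.merge(
        coords, left_on="protein_group_id", right_index=True, how="left"
    )
    expected_axis = {"sustained": "x", "ma_induced": "y", "ma_unique": None}
    per_category = {}
    for cat in CATEGORIES:
        sub = merged[merged["category"] == cat].dropna(
            subset=["x_log2_tsm_tm", "y_log2_tsm_ts"]
        )
        if len(sub) == 0:
            per_category[cat] = {"n": 0, "note": "no members; skipped"}
            continue
        mean_x = float(sub["x_log2_tsm_tm"].abs().mean())
        mean_y = float(sub["y_log2_tsm_ts"].abs().mean())
        entry = {"n": int(len(sub)), "mean_abs_log2_tsm_tm": mean_x,
                 "mean_abs_log2_tsm_ts": mean_y}
        axis = expected_axis[cat]
        if axis is None:
            entry["expected_ordering"] = "none"
            entry["passed"] = True
        elif max(mean_x, mean_y) < eps:
            entry["expected_ordering"] = "not_applicable"
            entry["passed"] = None
        else:
            entry["expected_ordering"] = (
                "tsm_tm_dominant" if axis == "x" else "tsm_ts_dominant"
            )
            entry["passed"] = bool(mean_x > mean_y) if axis == "x" else bool(mean_y > mean_x)
        per_category[cat] = entry
    return {"per_category": per_category, "scatter": merged}
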