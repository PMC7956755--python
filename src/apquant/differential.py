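"""Case-vs-control comparisons, experimental-null FADR calibration, AP calling.

The altered-protein (AP) discovery strategy: instead of multiple-testing
correction, fold-change and p-value cutoffs are calibrated empirically
against an *experimental null* (EN) — repeated balanced splits of the
control group compared against each other, which capture the dataset's real
biological + technical variance under the null. The false altered-protein
discovery rate (FADR) at a given cutoff pair is the mean number of APs found
in the EN comparisons divided by the number found in the real case-control
comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FC_THRESHOLDS = (1.2, 1.3, 1.4, 1.5, 2.0)
DEFAULT_ALPHA = 0.05

COMPARISON_COLUMNS = [
    "protein_group_id", "contrast", "fc", "log2fc", "p_value",
    "n_case", "n_control", "testable", "degenerate",
]


def _group_columns(ann: pd.DataFrame, group: str, biological_only: bool = True) -> list[str]:
    sub = ann[ann["group"] == group]
    if biological_only and "replicate_kind" in ann.columns:
        sub = sub[sub["replicate_kind"] == "biological"]
    return sub["sample_id"].tolist()


def compare_groups(
    table: pd.DataFrame,
    ann: pd.DataFrame,
    case: str,
    control: str,
    contrast: str | None = None,
) -> pd.DataFrame:
    """Per-protein fold change and Student's t-test p-value, case vs control.

    Fold change is the ratio of arithmetic means of present linear
    intensities; the two-sided equal-variance t-test runs on log2
    intensities. Proteins with fewer than 3 present values in either group
    are reported with ``testable=False`` rather than dropped. Groups whose
    present values are all identical (zero pooled variance) get p = 1 when
    the means agree and p = 0 otherwise, with ``degenerate=True``.
    """
    for g in (case, control):
        if g not in set(ann["group"]):
            raise ValueError(f"unknown group label: {g!r}")
    case_cols = _group_columns(ann, case)
    ctrl_cols = _group_columns(ann, control)
    case_cols = [c for c in case_cols if c in table.columns]
    ctrl_cols = [c for c in ctrl_cols if c in table.columns]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >= 2 samples per group in the table; got {len(case_cols)} {case!r} "
            f"and {len(ctrl_cols)} {control!r}"
        )

    a = table[case_cols].to_numpy(dtype=float)
    b = table[ctrl_cols].to_numpy(dtype=float)
    n_case = (~np.isnan(a)).sum(axis=1)
    n_control = (~np.isnan(b)).sum(axis=1)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
        mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
        fc = mean_a / mean_b
        log2fc = np.log2(fc)
        la, lb = np.log2(a), np.log2(b)
        # vectorized nan-aware equal-variance two-sample t-test on log2 values
        mean_la_ = np.nanmean(la, axis=1)
        mean_lb_ = np.nanmean(lb, axis=1)
        ss_a = np.nansum((la - mean_la_[:, None]) ** 2, axis=1)
        ss_b = np.nansum((lb - mean_lb_[:, None]) ** 2, axis=1)
        df = n_case + n_control - 2
        pooled = np.where(df > 0, (ss_a + ss_b) / np.maximum(df, 1), np.nan)
        se = np.sqrt(pooled * (1.0 / np.maximum(n_case, 1) + 1.0 / np.maximum(n_control, 1)))
        tstat = (mean_la_ - mean_lb_) / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
        p = np.where((df > 0) & np.isfinite(tstat), p, np.nan)
        var_a = np.nanvar(la, axis=1, ddof=0)
        var_b = np.nanvar(lb, axis=1, ddof=0)

    degenerate = (var_a == 0) & (var_b == 0) & (n_case >= 2) & (n_control >= 2)
    p = np.where(degenerate & np.isclose(mean_la_, mean_lb_), 1.0, p)
    p = np.where(degenerate & ~np.isclose(mean_la_, mean_lb_), 0.0, p)

    testable = (n_case >= 3) & (n_control >= 3)
    p = np.where(testable, p, np.nan)

    return pd.DataFrame(
        {
            "protein_group_id": table.index.to_numpy(),
            "contrast": contrast or f"{case}/{control}",
            "fc": fc,
            "log2fc": log2fc,
            "p_value": p,
            "n_case": n_case,
            "n_control": n_control,
            "testable": testable,
            "degenerate": degenerate,
        },
        columns=COMPARISON_COLUMNS,
    )


def _balanced_partitions(samples: list[str]) -> int:
    """Number of distinct unordered balanced partitions of the sample list."""
    n = len(samples)
    h = n // 2
    total = math.comb(n, h)
    if n % 2 == 0:
        total //= 2
    return total


def experimental_null(
    table: pd.DataFrame,
    ann: pd.DataFrame,
    control: str = "SH",
    n_splits: int = 20,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Null comparisons from balanced random splits of the control group.

    Each split partitions the control samples into halves of size
    floor(n/2) and ceil(n/2) and compares them with :func:`compare_groups`.
    Distinct partitions are drawn without repetition when the partition
    space allows; with the same seed and inputs the splits are identical.
    """
    samples = [c for c in _group_columns(ann, control) if c in table.columns]
    n = len(samples)
    if n < 4:
        raise ValueError(f"control group {control!r} has {n} samples; need >= 4")
    h = n // 2
    rng = np.random.default_rng(int(seed))
    total = _balanced_partitions(samples)

    chosen: list[tuple[str, ...]] = []
    if total <= n_splits:
        for combo in combinations(sorted(samples), h):
            if n % 2 == 0 and sorted(samples)[0] not in combo:
                continue  # canonical half contains the first sample
            chosen.append(combo)
    else:
        seen = set()
        while len(chosen) < n_splits:
            perm = rng.permutation(samples)
            half = frozenset(perm[:h])
            if n % 2 == 0 and samples[0] not in half:
                half = frozenset(perm[h:])
            if half in seen:
                continue
            seen.add(half)
            chosen.append(tuple(sorted(half)))

    nulls = []
    for i, half_a in enumerate(chosen):
        half_b = [s for s in samples if s not in set(half_a)]
        pseudo = pd.DataFrame(
            {
                "sample_id": list(half_a) + list(half_b),
                "group": ["ENa"] * len(half_a) + ["ENb"] * len(half_b),
                "tissue": "-",
                "replicate_kind": "biological",
            }
        )
        comp = compare_groups(table, pseudo, "ENa", "ENb", contrast=f"EN{i + 1}")
        nulls.append(comp)
    return nulls


def _count_aps(comp: pd.DataFrame, fc_threshold: float, alpha: float) -> int:
    sub = comp[comp["testable"]]
    passing = (
        ((sub["fc"] >= fc_threshold) | (sub["fc"] <= 1.0 / fc_threshold))
        & (sub["p_value"] < alpha)
    )
    return int(passing.sum())


def fadr_grid(
    case: pd.DataFrame,
    nulls: list[pd.DataFrame],
    fc_thresholds: tuple[float, ...] = DEFAULT_FC_THRESHOLDS,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """AP counts and FADR over a fold-change threshold grid.

    FADR at a threshold is the mean EN AP count divided by the case AP
    count; 0/0 is defined as 0, and a positive null count over a zero case
    count is reported as +inf.
    """
    if case is None or len(case) == 0:
        raise ValueError("empty case comparison list")
    if any(t <= 1.0 for t in fc_thresholds):
        raise ValueError("fc thresholds must all be > 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    contrast = case["contrast"].iloc[0]
    rows = []
    for t in sorted(fc_thresholds):
        n_case_aps = _count_aps(case, t, alpha)
        null_counts = [_count_aps(nc, t, alpha) for nc in nulls]
        n_null = float(np.mean(null_counts)) if null_counts else 0.0
        if n_case_aps > 0:
            fadr = n_null / n_case_aps
        else:
            fadr = 0.0 if n_null == 0 else float("inf")
        rows.append(
            {
                "fc_threshold": t,
                "contrast": contrast,
                "n_case_aps": n_case_aps,
                "n_null_aps": n_null,
                "fadr": fadr,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)


def select_cutoff(
    grid: pd.DataFrame,
    fadr_tolerance: float = 0.05,
    min_retention: float = 0.5,
) -> dict:
    """Pick the smallest fold-change threshold controlling FADR.

    The grid may stack several contrasts; a threshold qualifies when its
    worst (largest, possibly infinite) FADR over contrasts is within
    ``fadr_tolerance``. The smallest qualifying threshold is chosen; a
    larger qualifying threshold replaces it only when it both retains at
    least ``min_retention`` of the AP count and lowers the worst FADR by
    more than the AP-count fraction it gives up. If no threshold qualifies,
    the largest threshold is returned with a warning flag.
    """
    if grid is None or len(grid) == 0:
        raise ValueError("empty FADR grid")
    agg = grid.groupby("fc_threshold").agg(
        worst_fadr=("fadr", "max"), total_aps=("n_case_aps", "sum")
    )
    agg = agg.sort_index()
    qualifying = agg.index[agg["worst_fadr"] <= fadr_tolerance].tolist()
    warning = len(qualifying) == 0
    if warning:
        selected = float(agg.index.max())
    else:
        selected = float(qualifying[0])
        base = agg.loc[selected]
        for t in qualifying[1:]:
            row = agg.loc[t]
            retention = row["total_aps"] / base["total_aps"] if base["total_aps"] > 0 else 1.0
            fadr_gain = base["worst_fadr"] - row["worst_fadr"]
            if retention >= min_retention and fadr_gain > (1.0 - retention):
                selected = float(t)
                base = row
    return {
        "selected_fc_threshold": selected,
        "fadr_tolerance": fadr_tolerance,
        "min_retention": min_retention,
        "no_threshold_met_tolerance": warning,
        "grid": grid.copy(),
        "per_threshold": agg.reset_index(),
    }


@dataclass
class APSet:
    """Altered proteins for one contrast at fixed fold-change/p cutoffs."""

    contrast: str
    fc_cutoff: float
    alpha: float
    members: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["protein_group_id", "direction", "fc", "p_value"]
        )
    )

    @property
    def protein_ids(self) -> set[str]:
        return set(self.members["protein_group_id"])

    def directions(self) -> dict[str, str]:
        return dict(zip(self.members["protein_group_id"], self.members["direction"]))


def call_aps(
    comparisons: pd.DataFrame, fc_cutoff: float = 1.4, alpha: float = DEFAULT_ALPHA
) -> APSet:
    """Call altered proteins: |FC| beyond the cutoff and p below alpha."""
    if fc_cutoff <= 1.0:
        raise ValueError("fc_cutoff must be > 1")
    contrast = comparisons["contrast"].iloc[0] if len(comparisons) else "NA"
    if len(comparisons) == 0:
        return APSet(contrast=contrast, fc_cutoff=fc_cutoff, alpha=alpha)
    sub = comparisons[comparisons["testable"]]
    passing = sub[
        ((sub["fc"] >= fc_cutoff) | (sub["fc"] <= 1.0 / fc_cutoff))
        & (sub["p_value"] < alpha)
    ]
    members = pd.DataFrame(
        {
            "protein_group_id": passing["protein_group_id"].to_numpy(),
            "direction": np.where(passing["fc"] >= fc_cutoff, "up", "down"),
            "fc": passing["fc"].to_numpy(),
            "p_value": passing["p_value"].to_numpy(),
        }
    )
    return APSet(contrast=contrast, fc_cutoff=fc_cutoff, alpha=alpha, members=members)
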