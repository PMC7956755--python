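"""Synthetic peptide-level proteomics data with planted expression patterns.

The generator emulates a 4-group (sham SH, mild injury TM, severe injury TS,
severe injury + drug TSm) by 2-tissue (cortex, hippocampus) label-free MS1
quantification study. Proteins carry one of four planted patterns relative to
the sham group:

``null``
    no true change in any group;
``sustained``
    TS and TSm share a common nonzero log2 effect, TM is unchanged — the
    alteration tracks severe injury regardless of drug treatment;
``ma_induced``
    TM and TSm share a common nonzero effect, TS is unchanged — under drug
    treatment the protein behaves like mild rather than severe injury;
``ma_unique``
    only TSm carries the effect — the change is drug-specific.

The intensity model is multiplicative (normal on the log2 scale): a protein's
per-sample log2 abundance is baseline + group effect + biological noise +
technical noise, and each of its peptides observes that abundance through a
fixed per-peptide ionization factor, a per-sample loading factor, and a small
per-cell measurement noise. A configurable fraction of peptides is corrupted
with large independent per-cell noise so the downstream outlier-peptide filter
has realistic work to do. Missingness is MCAR and mostly block-structured: a
(protein, sample) pair drops all of its peptide cells together at the
configured protein-level rate (ion-current extraction fails per run, not per
peptide), and an additional small independent peptide-cell rate exercises
available-case paths downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

GROUPS = ("SH", "TM", "TS", "TSm")
TISSUES = ("cortex", "hippocampus")
_TISSUE_PREFIX = {"cortex": "ctx", "hippocampus": "hip"}
PATTERNS = ("null", "sustained", "ma_induced", "ma_unique")
CONTRASTS = ("TM/SH", "TS/SH", "TSm/SH")

#: contrasts in which each planted pattern carries its nonzero effect
AFFECTED_CONTRASTS = {
    "sustained": ("TS/SH", "TSm/SH"),
    "ma_induced": ("TM/SH", "TSm/SH"),
    "ma_unique": ("TSm/SH",),
}


def cv_to_sd_log2(cv: float) -> float:
    """Standard deviation on the log2 scale of a lognormal with the given CV."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


def sd_log2_to_cv(sd: float) -> float:
    return math.sqrt(math.expm1((sd * math.log(2.0)) ** 2))


@dataclass
class SimConfig:
    """Study-design and noise parameters for :func:`simulate_dataset`.

    Defaults reproduce the emulated study's conditions: 39 samples per tissue
    (10 SH, 11 TM, 9 TS, 9 TSm), two tissues, ~6500 protein groups spanning
    ~6 orders of magnitude, biological intra-group CV 16.7%, technical CV
    5.0%, protein-level missingness 0.5%, and 2-fold planted effects on 10%
    of proteins per non-null pattern.
    """

    n_proteins: int = 6500
    #: (min, mode, max) of the triangular integer distribution of peptides per protein
    peptides_per_protein: tuple[int, int, int] = (1, 4, 10)
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"SH": 10, "TM": 11, "TS": 9, "TSm": 9}
    )
    n_tissues: int = 2
    frac_null: float = 0.70
    frac_sustained: float = 0.10
    frac_ma_induced: float = 0.10
    frac_ma_unique: float = 0.10
    #: planted |log2 fold change| of non-null proteins (1.0 -> 2-fold)
    effect_log2fc: float = 1.0
    #: target intra-group biological CV at the protein level
    bio_cv: float = 0.167
    #: target technical-replicate CV at the protein level
    tech_cv: float = 0.05
    #: target post-aggregation protein-level missingness (block MCAR rate)
    missing_rate: float = 0.005
    #: additional independent per-peptide-cell missing rate
    peptide_missing_rate: float = 0.002
    #: fraction of peptides corrupted with large independent per-cell noise
    outlier_peptide_rate: float = 0.02
    #: per-cell peptide measurement CV (independent across cells)
    peptide_cv: float = 0.05
    #: per-sample loading-factor sd on the log2 scale
    loading_sd_log2: float = 0.25
    #: span of protein baseline abundances, in orders of magnitude (log10)
    dynamic_range_log10: float = 6.0
    #: fraction of proteins present in both tissues (when n_tissues == 2)
    tissue_overlap: float = 1.0
    #: if >= 2, inject this many technical re-measurements of the first SH sample
    n_technical_replicates: int = 0
    #: "mcar" or "intensity" (logistic in log intensity) missingness
    missing_mode: str = "mcar"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if int(self.n_proteins) < 1:
            raise ValueError("n_proteins: must be >= 1")
        pmin, pmode, pmax = self.peptides_per_protein
        if not (1 <= pmin <= pmode <= pmax):
            raise ValueError(
                "peptides_per_protein: require 1 <= min <= mode <= max, "
                f"got {self.peptides_per_protein}"
            )
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(
                f"group_sizes: keys must be exactly {set(GROUPS)}, got {set(self.group_sizes)}"
            )
        for g, n in self.group_sizes.items():
            if int(n) < 1:
                raise ValueError(f"group_sizes[{g}]: must be >= 1")
        if not 1 <= int(self.n_tissues) <= len(TISSUES):
            raise ValueError(f"n_tissues: must be in [1, {len(TISSUES)}]")
        fracs = {
            "frac_null": self.frac_null,
            "frac_sustained": self.frac_sustained,
            "frac_ma_induced": self.frac_ma_induced,
            "frac_ma_unique": self.frac_ma_unique,
        }
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {f}")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ValueError(f"frac_* must sum to 1 within 1e-9, got {sum(fracs.values())}")
        for name in ("bio_cv", "tech_cv", "missing_rate", "peptide_missing_rate",
                     "outlier_peptide_rate", "peptide_cv", "tissue_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc: must be >= 0")
        if self.missing_mode not in ("mcar", "intensity"):
            raise ValueError(f"missing_mode: must be 'mcar' or 'intensity', got {self.missing_mode}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_sizes"] = dict(self.group_sizes)
        d["peptides_per_protein"] = list(self.peptides_per_protein)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "peptides_per_protein" in d:
            d["peptides_per_protein"] = tuple(d["peptides_per_protein"])
        return cls(**d)


def _triangular_counts(rng: np.random.Generator, shape: tuple[int, int, int], n: int) -> np.ndarray:
    pmin, pmode, pmax = shape
    if pmin == pmax:
        return np.full(n, pmin, dtype=int)
    draws = rng.triangular(pmin - 0.499, pmode, pmax + 0.499, size=n)
    return np.clip(np.rint(draws).astype(int), pmin, pmax)


def _truth_effects(pattern: np.ndarray, sign: np.ndarray, effect: float) -> pd.DataFrame:
    eff = sign * effect
    tm = np.where(np.isin(pattern, ["ma_induced"]), eff, 0.0)
    ts = np.where(np.isin(pattern, ["sustained"]), eff, 0.0)
    tsm = np.where(pattern != "null", eff, 0.0)
    return pd.DataFrame({"effect_tm": tm, "effect_ts": ts, "effect_tsm": tsm})


def simulate_dataset(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (peptide table, sample annotation, truth table) for one study.

    The peptide table is indexed by (peptide_id, protein_group_id) with one
    float column per sample; missing cells are NaN. Deterministic for a fixed
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    n = int(config.n_proteins)
    protein_ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # planted patterns by exact quota; remainders go to null
    n_sus = round(config.frac_sustained * n)
    n_ind = round(config.frac_ma_induced * n)
    n_unq = round(config.frac_ma_unique * n)
    if n_sus + n_ind + n_unq > n:
        raise ValueError("pattern quotas exceed n_proteins")
    pattern = np.full(n, "null", dtype=object)
    order = rng.permutation(n)
    pattern[order[:n_sus]] = "sustained"
    pattern[order[n_sus:n_sus + n_ind]] = "ma_induced"
    pattern[order[n_sus + n_ind:n_sus + n_ind + n_unq]] = "ma_unique"
    sign = rng.choice([-1.0, 1.0], size=n)
    effects = _truth_effects(pattern, sign, config.effect_log2fc)

    # ~dynamic_range_log10 orders of magnitude of baseline abundance
    lo = math.log2(1e4)
    hi = lo + config.dynamic_range_log10 * math.log2(10.0)
    baseline = rng.uniform(lo, hi, size=n)

    k = _triangular_counts(rng, tuple(config.peptides_per_protein), n)
    protein_idx = np.repeat(np.arange(n), k)
    n_pep = protein_idx.size
    pep_within = np.concatenate([np.arange(ki) for ki in k])
    peptide_ids = np.array(
        [f"{protein_ids[p]}_pep{j + 1}" for p, j in zip(protein_idx, pep_within)]
    )
    ion_log2 = rng.normal(-2.0, 1.0, size=n_pep)
    outlier_rows = rng.random(n_pep) < config.outlier_peptide_rate

    # tissue membership
    tissues = TISSUES[: int(config.n_tissues)]
    in_tissue = {t: np.ones(n, dtype=bool) for t in tissues}
    if len(tissues) == 2 and config.tissue_overlap < 1.0:
        shuffled = rng.permutation(n)
        n_shared = round(config.tissue_overlap * n)
        exclusive = shuffled[n_shared:]
        in_tissue[tissues[0]][exclusive[0::2]] = False
        in_tissue[tissues[1]][exclusive[1::2]] = False

    sd_b = cv_to_sd_log2(config.bio_cv)
    sd_t = cv_to_sd_log2(config.tech_cv)
    sd_p = cv_to_sd_log2(config.peptide_cv)

    group_effect = {
        "SH": np.zeros(n),
        "TM": effects["effect_tm"].to_numpy(),
        "TS": effects["effect_ts"].to_numpy(),
        "TSm": effects["effect_tsm"].to_numpy(),
    }

    sample_frames: list[pd.DataFrame] = []
    ann_rows: list[dict] = []
    for tissue in tissues:
        prefix = _TISSUE_PREFIX[tissue]
        sample_ids: list[str] = []
        sample_groups: list[str] = []
        for g in GROUPS:
            for i in range(int(config.group_sizes[g])):
                sid = f"{prefix}_{g}{i + 1:02d}"
                sample_ids.append(sid)
                sample_groups.append(g)
                ann_rows.append(
                    {"sample_id": sid, "group": g, "tissue": tissue,
                     "replicate_kind": "biological"}
                )
        n_samp = len(sample_ids)
        bio = rng.normal(0.0, sd_b, size=(n, n_samp)) if sd_b > 0 else np.zeros((n, n_samp))
        tech = rng.normal(0.0, sd_t, size=(n, n_samp)) if sd_t > 0 else np.zeros((n, n_samp))
        geff = np.column_stack([group_effect[g] for g in sample_groups])
        protein_log2 = baseline[:, None] + geff + bio + tech

        def _peptide_block(prot_log2_cols: np.ndarray, ncols: int) -> np.ndarray:
            loading = rng.normal(0.0, config.loading_sd_log2, size=ncols)
            lp = prot_log2_cols[protein_idx] + ion_log2[:, None] + loading[None, :]
            if sd_p > 0:
                lp = lp + rng.normal(0.0, sd_p, size=(n_pep, ncols))
            n_out = int(outlier_rows.sum())
            if n_out:
                lp[outlier_rows] += rng.normal(0.0, 2.0, size=(n_out, ncols))
            return lp

        def _missing_blocks(prot_log2_cols: np.ndarray, ncols: int) -> np.ndarray:
            """(protein, sample) block-missing mask at the configured rate."""
            if config.missing_rate <= 0:
                return np.zeros((n, ncols), dtype=bool)
            if config.missing_mode == "mcar":
                return rng.random((n, ncols)) < config.missing_rate
            # intensity-dependent: logistic in log2 abundance, scaled to the
            # same marginal rate
            z = (prot_log2_cols - prot_log2_cols.mean()) / max(prot_log2_cols.std(), 1e-12)
            prob = 1.0 / (1.0 + np.exp(z))
            prob *= config.missing_rate / max(prob.mean(), 1e-12)
            return rng.random((n, ncols)) < np.clip(prob, 0, 1)

        lp = _peptide_block(protein_log2, n_samp)
        intens = np.exp2(lp)
        block = _missing_blocks(protein_log2, n_samp)
        intens[block[protein_idx, :]] = np.nan
        if config.peptide_missing_rate > 0:
            mask = rng.random((n_pep, n_samp)) < config.peptide_missing_rate
            intens[mask] = np.nan
        absent = ~in_tissue[tissue][protein_idx]
        intens[absent, :] = np.nan
        block = pd.DataFrame(intens, columns=sample_ids)

        if config.n_technical_replicates >= 2:
            # re-measurements of the first SH sample: same biology, fresh
            # technical noise / loading / peptide noise / missingness
            base_col = baseline + bio[:, 0]
            rep_ids = []
            rep_int = []
            for r in range(int(config.n_technical_replicates)):
                tech_r = rng.normal(0.0, sd_t, size=n) if sd_t > 0 else np.zeros(n)
                prot_r = base_col + tech_r
                lp_r = _peptide_block(prot_r[:, None], 1)[:, 0]
                col = np.exp2(lp_r)
                col[_missing_blocks(prot_r[:, None], 1)[protein_idx, 0]] = np.nan
                if config.peptide_missing_rate > 0:
                    col[rng.random(n_pep) < config.peptide_missing_rate] = np.nan
                col[absent] = np.nan
                rid = f"{prefix}_SHtech{r + 1:02d}"
                rep_ids.append(rid)
                rep_int.append(col)
                ann_rows.append(
                    {"sample_id": rid, "group": "SH", "tissue": tissue,
                     "replicate_kind": "technical"}
                )
            block = pd.concat(
                [block, pd.DataFrame(np.column_stack(rep_int), columns=rep_ids)], axis=1
            )
        sample_frames.append(block)

    table = pd.concat(sample_frames, axis=1)
    table.index = pd.MultiIndex.from_arrays(
        [peptide_ids, protein_ids[protein_idx]], names=["peptide_id", "protein_group_id"]
    )
    annotation = pd.DataFrame(ann_rows, columns=["sample_id", "group", "tissue", "replicate_kind"])

    truth = pd.DataFrame({"protein_id": protein_ids, "pattern": pattern})
    truth = pd.concat([truth, effects], axis=1)
    for t in tissues:
        truth[f"in_{t}"] = in_tissue[t]
    return table, annotation, truth


def calibration_report(
    table: pd.DataFrame,
    ann: pd.DataFrame,
    config: SimConfig,
    truth: pd.DataFrame | None = None,
) -> dict:
    """Compare realized dataset statistics against the configured targets.

    Runs the standard rollup (normalization, outlier filtering, aggregation)
    per tissue and reports realized protein-level biological CV, technical CV
    (if technical replicates are present), post-aggregation missingness, and
    mean |log2FC| per planted pattern in its affected contrasts.
    """
    from .quant import normalize, remove_outlier_peptides, aggregate_to_protein, cv_summary

    if table.empty:
        raise ValueError("empty peptide table")
    report: dict = {"targets": {
        "bio_cv": config.bio_cv,
        "tech_cv": config.tech_cv,
        "missing_rate": config.missing_rate,
        "effect_log2fc": config.effect_log2fc,
    }}
    bio_cvs: list[float] = []
    tech_cvs: list[float] = []
    n_missing = 0
    n_cells = 0
    fc_by_pattern: dict[str, list[float]] = {p: [] for p in AFFECTED_CONTRASTS}
    for tissue, tiss_ann in ann.groupby("tissue"):
        cols = tiss_ann["sample_id"].tolist()
        sub = table[cols].dropna(how="all")
        norm, _ = normalize(sub)
        filtered, _ = remove_outlier_peptides(norm)
        prot = aggregate_to_protein(filtered)
        cv = cv_summary(prot.intensities, tiss_ann)
        bio_cvs.extend(cv.loc[cv["replicate_kind"] == "biological", "median_cv"])
        tech_cvs.extend(cv.loc[cv["replicate_kind"] == "technical", "median_cv"])
        vals = prot.intensities
        n_missing += int(vals.isna().sum().sum())
        n_cells += int(vals.size)
        if truth is not None:
            ti = truth.set_index("protein_id")
            bio_ann = tiss_ann[tiss_ann["replicate_kind"] == "biological"]
            means = {
                g: vals[bio_ann.loc[bio_ann["group"] == g, "sample_id"]].mean(axis=1)
                for g in GROUPS
            }
            for pat, contrasts in AFFECTED_CONTRASTS.items():
                ids = ti.index[ti["pattern"] == pat].intersection(vals.index)
                if len(ids) == 0:
                    continue
                for c in contrasts:
                    case = c.split("/")[0]
                    ratio = means[case].loc[ids] / means["SH"].loc[ids]
                    fc_by_pattern[pat].extend(np.abs(np.log2(ratio.dropna())))
    report["realized_bio_cv"] = float(np.median(bio_cvs)) if bio_cvs else float("nan")
    report["realized_tech_cv"] = float(np.median(tech_cvs)) if tech_cvs else float("nan")
    report["realized_missing_rate"] = n_missing / n_cells if n_cells else float("nan")
    if truth is not None:
        report["realized_abs_log2fc_by_pattern"] = {
            p: (float(np.mean(v)) if v else float("nan")) for p, v in fc_by_pattern.items()
        }
    report["within_tolerance"] = {
        "bio_cv": (
            abs(report["realized_bio_cv"] - config.bio_cv) <= 0.2 * config.bio_cv
            if config.bio_cv > 0 else report["realized_bio_cv"] == 0.0
        ),
        "missing_rate": report["realized_missing_rate"] <= max(2 * config.missing_rate, 1e-9),
    }
    return report
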