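"""Bait-vs-control differential enrichment for LFQ proximity-labeling data.

The pipeline mirrors the Perseus-style workflow standard in interactome
proteomics: log2 transform, group-completeness filtering, left-censored
Gaussian imputation (down-shifted, narrowed normal), per-protein Welch's
t-test, standardization of the log2 fold changes into z-scores over the
tested population, joint hit calling (p < alpha, z > cutoff, positive
difference), and a replicate-CV quality-control summary over the hit set.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix_io import IntensityMatrix, GroupDesign

__all__ = [
    "PipelineParams",
    "QCSummary",
    "DegenerateVarianceWarning",
    "log2_transform",
    "filter_by_completeness",
    "impute_left_censored",
    "welch_t",
    "fold_change_zscores",
    "protein_cv_pct",
    "call_hits",
    "run_enrichment_pipeline",
]


class DegenerateVarianceWarning(UserWarning):
    """Both groups have zero variance but different means: p collapses to 0."""


@dataclass
class PipelineParams:
    """Every threshold of the enrichment analysis, in one place.

    min_valid_fraction
        A protein is kept when at least this fraction of one group's
        replicates quantified it (1.0 for small cell-culture designs,
        0.75 for the larger in vivo design).
    impute_width, impute_downshift
        Missing log2 intensities are drawn from
        Normal(mu - downshift*sigma, (width*sigma)^2) where mu/sigma are the
        observed mean/SD of the imputation scope (per sample column by
        default), placing imputed values in the low-abundance tail.
    alpha, z_cutoff
        Strict cutoffs: hit requires p < alpha and z > z_cutoff.
    cv_qc_limit_pct
        Dataset-level QC: the average percent CV over the hit set must stay
        below this bound.
    require_positive_diff
        Restrict hits to proteins enriched in the bait group.
    seed
        Root seed for the imputation draws.
    """

    min_valid_fraction: float = 1.0
    impute_width: float = 0.5
    impute_downshift: float = 1.6
    alpha: float = 0.05
    z_cutoff: float = 1.0
    cv_qc_limit_pct: float = 30.0
    require_positive_diff: bool = True
    seed: int = 0
    impute_scope: str = "column"  # "column" | "matrix"
    z_population: str = "all_filtered"  # "all_filtered" | "significant_only"
    cv_scope: str = "bait"  # "bait" | "pooled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ValueError("min_valid_fraction must be in [0, 1]")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be positive")
        if self.impute_downshift <= 0:
            raise ValueError("impute_downshift must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.impute_scope not in {"column", "matrix"}:
            raise ValueError("impute_scope must be 'column' or 'matrix'")
        if self.z_population not in {"all_filtered", "significant_only"}:
            raise ValueError("z_population must be 'all_filtered' or 'significant_only'")
        if self.cv_scope not in {"bait", "pooled"}:
            raise ValueError("cv_scope must be 'bait' or 'pooled'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCSummary:
    """Replicate-reproducibility QC over the called hit set."""

    average_cv_pct: float
    median_cv_pct: float
    n_hits: int
    n_tested: int
    cv_qc_limit_pct: float

    @property
    def pass_cv_qc(self) -> bool:
        return bool(self.average_cv_pct < self.cv_qc_limit_pct)


# ---------------------------------------------------------------------------
# stages


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace every present raw intensity by its base-2 log; keep the mask."""
    if matrix.log2_scale:
        raise ValueError("matrix is already on the log2 scale")
    vals = matrix.intensities.to_numpy()
    present = ~np.isnan(vals)
    if (vals[present] <= 0).any():
        raise ValueError("cannot log2-transform non-positive intensities")
    out = matrix.intensities.copy()
    out[:] = np.where(present, np.log2(np.where(present, vals, 1.0)), np.nan)
    return IntensityMatrix(out, matrix.genes.copy(), log2_scale=True)


def filter_by_completeness(
    matrix: IntensityMatrix, design: GroupDesign, min_valid_fraction: float
) -> IntensityMatrix:
    """Keep proteins quantified in >= the given fraction of one group.

    OR semantics: full coverage in either the bait or the control group is
    enough (a protein seen only with the bait is exactly the interesting
    case, so requiring both groups would discard it).
    """
    design.validate_against(matrix)
    bait = design.bait_samples
    ctrl = design.control_samples
    valid = matrix.intensities.notna()
    frac_bait = valid[bait].sum(axis=1) / len(bait)
    frac_ctrl = valid[ctrl].sum(axis=1) / len(ctrl)
    keep = (frac_bait >= min_valid_fraction) | (frac_ctrl >= min_valid_fraction)
    if not keep.any():
        warnings.warn("completeness filter removed every protein", UserWarning, stacklevel=2)
    return matrix.subset(matrix.intensities.index[keep])


def _column_rng(seed: int, column: str) -> np.random.Generator:
    # child stream keyed by the column *name* so that reordering columns
    # cannot silently reshuffle the imputation draws
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(column.encode("utf-8"))])
    )


def impute_left_censored(
    matrix: IntensityMatrix,
    width: float,
    downshift: float,
    seed: int,
    scope: str = "column",
) -> IntensityMatrix:
    """Fill missing log2 values from a down-shifted, narrowed normal.

    For scope "column" each sample column c contributes its own observed
    mean mu_c and sample SD sigma_c; missing cells in c are independent draws
    from Normal(mu_c - downshift*sigma_c, (width*sigma_c)^2).  Scope "matrix"
    pools mu/sigma over all observed cells.  Identical seed => identical
    output.
    """
    if not matrix.log2_scale:
        raise ValueError("imputation operates on log2-scale matrices")
    if scope not in {"column", "matrix"}:
        raise ValueError("scope must be 'column' or 'matrix'")
    out = matrix.intensities.copy()
    if scope == "matrix":
        obs_all = out.to_numpy()
        obs_all = obs_all[~np.isnan(obs_all)]
        if obs_all.size < 2:
            raise ValueError("matrix has fewer than 2 observed values")
        mu_all, sd_all = float(obs_all.mean()), float(obs_all.std(ddof=1))
    for col in out.columns:
        column = out[col].to_numpy()
        miss = np.isnan(column)
        obs = column[~miss]
        if obs.size < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        if scope == "column":
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        else:
            mu, sd = mu_all, sd_all
        if miss.any():
            rng = _column_rng(seed, str(col))
            column[miss] = rng.normal(mu - downshift * sd, width * sd, size=int(miss.sum()))
            out[col] = column
    return IntensityMatrix(out, matrix.genes.copy(), log2_scale=True)


def welch_t(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """Welch's two-sample t-test on log2 values.

    Returns (t, Welch-Satterthwaite df, two-sided p, mean(x) - mean(y)).
    Zero variance in both groups is handled deterministically: equal means
    give (t=0, p=1); unequal means give p=0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = x.size, y.size
    diff = float(x.mean() - y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if vx == 0.0 and vy == 0.0:
        if diff == 0.0:
            return 0.0, float(nx + ny - 2), 1.0, 0.0
        warnings.warn(
            "zero variance in both groups with unequal means",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        return float(np.sign(diff)) * np.inf, float(nx + ny - 2), 0.0, diff
    se2 = vx / nx + vy / ny
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p, diff


def _welch_rows(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test over matrix rows (complete data, no NaN)."""
    nx, ny = X.shape[1], Y.shape[1]
    diff = X.mean(axis=1) - Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1)
    vy = Y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    both_const = (vx == 0) & (vy == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(both_const, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    df = np.where(both_const, float(nx + ny - 2), df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(both_const, np.where(diff == 0, 1.0, 0.0), p)
    return t, df, p, diff


def fold_change_zscores(diffs: Sequence[float]) -> np.ndarray:
    """Standardize log2 fold changes against the population mean and SD.

    z_i = (d_i - mean(d)) / sampleSD(d); by construction mean(z) = 0 and
    sampleSD(z) = 1.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 3:
        raise ValueError("z-scoring needs at least 3 fold changes")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("fold changes are constant; z-scores undefined")
    return (d - d.mean()) / sd


def protein_cv_pct(raw_values: Sequence[float]) -> float:
    """Percent coefficient of variation of observed raw-scale intensities.

    Returns NaN (excluded from QC averages) with fewer than 2 observations.
    """
    v = np.asarray(raw_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean intensity")
    return float(100.0 * v.std(ddof=1) / mean)


def call_hits(table: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    """Set passed_p / passed_z / hit flags with strict inequalities."""
    out = table.copy()
    out["passed_p"] = out["p_welch"] < params.alpha
    out["passed_z"] = out["z"] > params.z_cutoff
    hit = out["passed_p"] & out["passed_z"]
    if params.require_positive_diff:
        hit &= out["diff_log2"] > 0
    out["hit"] = hit
    return out


def run_enrichment_pipeline(
    matrix: IntensityMatrix, design: GroupDesign, params: PipelineParams
) -> tuple[pd.DataFrame, QCSummary]:
    """Run the full enrichment analysis on a raw-scale intensity matrix.

    Stages, in order: log2 transform -> completeness filter -> seeded
    left-censored imputation -> Welch test per protein -> fold-change
    z-scores over the tested population -> hit flags -> CV QC summary
    computed from *observed* raw bait-group intensities of the hit set.
    """
    if matrix.log2_scale:
        raise ValueError("pipeline expects a raw-scale matrix")
    design.validate_against(matrix)

    logm = log2_transform(matrix)
    filtered = filter_by_completeness(logm, design, params.min_valid_fraction)
    imputed = impute_left_censored(
        filtered, params.impute_width, params.impute_downshift, params.seed, params.impute_scope
    )

    bait = design.bait_samples
    ctrl = design.control_samples
    X = imputed.intensities[bait].to_numpy()
    Y = imputed.intensities[ctrl].to_numpy()
    t, df, p, diff = _welch_rows(X, Y)

    index = imputed.intensities.index
    table = pd.DataFrame(
        {
            "protein_id": index,
            "gene": imputed.genes.values,
            "n_valid_bait": filtered.intensities[bait].notna().sum(axis=1).to_numpy(),
            "n_valid_ctrl": filtered.intensities[ctrl].notna().sum(axis=1).to_numpy(),
            "diff_log2": diff,
            "ratio": np.power(2.0, diff),
            "t_stat": t,
            "df_welch": df,
            "p_welch": p,
            "passed_filter": True,
        }
    ).reset_index(drop=True)

    if params.z_population == "all_filtered":
        table["z"] = fold_change_zscores(table["diff_log2"].to_numpy())
    else:
        z = np.full(len(table), np.nan)
        sig = (table["p_welch"] < params.alpha).to_numpy()
        if sig.sum() >= 3:
            z[sig] = fold_change_zscores(table.loc[sig, "diff_log2"].to_numpy())
        table["z"] = z

    # CV on raw-scale observed (never imputed) intensities
    raw = matrix.subset(index).intensities
    cv_cols = bait if params.cv_scope == "bait" else bait + ctrl
    raw_sub = raw[cv_cols].to_numpy()
    table["cv_bait_pct"] = [protein_cv_pct(row) for row in raw_sub]

    table = call_hits(table, params)

    hit_cv = table.loc[table["hit"], "cv_bait_pct"].dropna()
    qc = QCSummary(
        average_cv_pct=float(hit_cv.mean()) if len(hit_cv) else float("nan"),
        median_cv_pct=float(hit_cv.median()) if len(hit_cv) else float("nan"),
        n_hits=int(table["hit"].sum()),
        n_tested=int(len(table)),
        cv_qc_limit_pct=params.cv_qc_limit_pct,
    )
    return table, qc
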