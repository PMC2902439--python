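"""Probeset signal tables -> ANOVA-filtered, replicate-averaged log2 matrices.

The reduction follows the usual two-channel microarray bookkeeping: keep
probesets detected (call P or M) on every array of at least one condition,
average probesets of a gene on the *linear* signal scale, log2-transform,
filter genes by a one-way ANOVA across conditions on the replicate-level
log values, and average replicates per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataContractError

LOG_FLOOR = 2.0**-10  # linear-signal floor applied before log2


@dataclass
class GeneExpressionMatrix:
    """Replicate-averaged log2 expression, genes x conditions, per system."""

    values: pd.DataFrame  # genes x conditions, mean log2
    pvalues: pd.Series  # per-gene one-way ANOVA p-value
    flags: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


def _check_design(signal: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = [a for a in signal.columns if a not in set(design["array_id"])]
    if missing:
        raise DataContractError(f"arrays absent from design table: {missing[:5]}")
    if design["array_id"].duplicated().any():
        raise DataContractError("duplicated array_id in design table")


def condition_order(design: pd.DataFrame) -> list[str]:
    """Conditions in design-file order of first appearance (stable output order)."""
    return list(dict.fromkeys(design["condition_id"]))


def detection_filter(
    signal: pd.DataFrame, calls: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep probesets detected (P/M) on all arrays of >= 1 condition."""
    if signal.shape != calls.shape or not signal.columns.equals(calls.columns):
        raise DataContractError("signal and call grids have mismatched dimensions")
    _check_design(signal, design)
    if signal.empty:
        return signal, calls
    detected = calls.isin(["P", "M"])
    keep = np.zeros(len(signal), dtype=bool)
    arrays_of = design.groupby("condition_id", sort=False)["array_id"]
    for _, arrays in arrays_of:
        cols = [a for a in arrays if a in signal.columns]
        if cols:
            keep |= detected[cols].all(axis=1).to_numpy()
    return signal.loc[keep], calls.loc[keep]


def average_to_genes(
    signal: pd.DataFrame, probeset_map: pd.DataFrame, strict: bool = True
) -> pd.DataFrame:
    """Arithmetic mean of a gene's probeset signals (linear scale) per array.

    Unmapped probesets are dropped; a probeset mapping to more than one gene
    raises in strict mode and is dropped (with a warning) otherwise.
    """
    counts = probeset_map.groupby("probeset_id")["gene_id"].nunique()
    ambiguous = counts[counts > 1].index
    if len(ambiguous):
        if strict:
            raise DataContractError(
                f"probesets mapping to multiple genes: {list(ambiguous[:5])}"
            )
        warnings.warn(f"dropping {len(ambiguous)} ambiguous probesets", stacklevel=2)
    mapping = probeset_map[~probeset_map["probeset_id"].isin(ambiguous)]
    mapping = mapping.drop_duplicates("probeset_id").set_index("probeset_id")["gene_id"]
    gene_of = signal.index.map(mapping)
    kept = signal.loc[gene_of.notna()]
    return kept.groupby(gene_of[gene_of.notna()], sort=True).mean()


def log2_signal(gene_signal: pd.DataFrame, floor: float = LOG_FLOOR) -> tuple[pd.DataFrame, int]:
    """log2 with a small positive floor; returns (matrix, n floored cells)."""
    arr = gene_signal.to_numpy(dtype=float)
    n_floored = int((arr < floor).sum())
    return pd.DataFrame(
        np.log2(np.maximum(arr, floor)), index=gene_signal.index, columns=gene_signal.columns
    ), n_floored


def _oneway_anova(values: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Vectorised one-way fixed-effects ANOVA p-values (rows = genes).

    ``groups`` holds the column indices of each condition.  Degenerate rows:
    all-equal values -> p = 1; zero within-group variance with unequal
    means -> p = 0 (flagged by the caller).
    """
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in groups:
        sub = values[:, g]
        m = sub.mean(axis=1, keepdims=True)
        ssb += len(g) * (m[:, 0] - grand[:, 0]) ** 2
        ssw += ((sub - m) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    tiny = 1e-12 * np.maximum(ssb + ssw, 1.0)
    p = np.where(ssw <= tiny, np.where(ssb <= tiny, 1.0, 0.0), p)
    return p


def anova_filter(
    log_matrix: pd.DataFrame, design: pd.DataFrame, alpha: float = 0.05
) -> GeneExpressionMatrix:
    """One-way ANOVA across conditions; keep genes with p < alpha.

    Returns replicate means per condition for the retained genes, with the
    p-values stored alongside.
    """
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must lie in (0, 1], got {alpha}")
    _check_design(log_matrix, design)
    conds = condition_order(design)
    col_pos = {a: i for i, a in enumerate(log_matrix.columns)}
    groups = []
    for c in conds:
        arrays = design.loc[design["condition_id"] == c, "array_id"]
        idx = np.array([col_pos[a] for a in arrays if a in col_pos])
        if len(idx) < 2:
            raise DataContractError(f"condition {c!r} has fewer than 2 arrays")
        groups.append(idx)
    if len(groups) < 2:
        raise DataContractError("ANOVA needs at least 2 conditions")

    arr = log_matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = log_matrix.index[~np.isfinite(arr).all(axis=1)]
        raise DataContractError(f"non-finite log2 values for genes: {list(bad[:5])}")
    p = _oneway_anova(arr, groups)
    degenerate = [g for g, pv, row in zip(log_matrix.index, p, arr) if pv == 0.0]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} genes with zero within-condition variance and "
            "unequal means; p reported as 0",
            stacklevel=2,
        )
    keep = p < alpha
    means = np.column_stack([arr[:, g].mean(axis=1) for g in groups])
    values = pd.DataFrame(means, index=log_matrix.index, columns=conds).loc[keep]
    pv = pd.Series(p, index=log_matrix.index, name="anova_p").loc[keep]
    return GeneExpressionMatrix(values=values, pvalues=pv, flags={"zero_variance_p0": degenerate})


def preprocess(
    signal: pd.DataFrame,
    calls: pd.DataFrame,
    design: pd.DataFrame,
    probeset_map: pd.DataFrame,
    alpha: float = 0.05,
    strict: bool = True,
) -> GeneExpressionMatrix:
    """Full reduction: detection filter -> gene averaging -> log2 -> ANOVA."""
    sig, _ = detection_filter(signal, calls, design)
    gene_signal = average_to_genes(sig, probeset_map, strict=strict)
    log_mat, n_floored = log2_signal(gene_signal)
    gem = anova_filter(log_mat, design, alpha=alpha)
    gem.flags["n_floored"] = n_floored
    return gem
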