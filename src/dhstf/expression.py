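"""Expression normalisation and differential-gene selection.

Expression values are log2-scale intensities (features x samples). Replicates
within a condition are quantile-normalised to a common empirical
distribution; the treatment matrix is then scaling-normalised (a single
additive log2 shift of its trimmed mean) onto the control matrix. A gene is
differentially expressed when a Welch two-sample t-test gives p below the
threshold and the linear fold change 2**|g| exceeds the fold-change cutoff,
where g = mean(treatment) - mean(control) is the per-gene log2 ratio that
feeds the downstream linear model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, EmptyInputError

logger = logging.getLogger(__name__)

TREATMENT = "treatment"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Log2 expression values with a sample -> condition map."""

    values: pd.DataFrame  # features x samples
    conditions: Mapping[str, str]  # sample id -> "treatment" | "control"

    def __post_init__(self) -> None:
        unknown = [s for s in self.values.columns if s not in self.conditions]
        if unknown:
            raise ValueError(f"samples without a condition label: {unknown}")
        bad = {c for c in self.conditions.values()} - {TREATMENT, CONTROL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ValueError("expression values must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def subset(self, condition: str) -> "ExpressionMatrix":
        cols = self.samples(condition)
        return ExpressionMatrix(self.values[cols], dict(self.conditions))

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")


@dataclass(frozen=True)
class DifferentialGene:
    gene_id: str
    g: float  # log2 ratio, mean(treatment) - mean(control)
    p_value: float
    fold_change: float  # signed linear fold change, sign(g) * 2**|g|

    @property
    def direction(self) -> str:
        return "up" if self.g > 0 else "down"


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    each value is replaced by the reference value at its rank. Tied values
    within a column receive the mean of the reference quantiles they span,
    so the operation is deterministic and idempotent.
    """
    df = em.values
    if df.shape[1] < 2:
        logger.warning("quantile normalisation needs >= 2 samples; matrix unchanged")
        return replace(em, values=df.copy())
    arr = df.to_numpy(float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        assigned = np.empty(arr.shape[0])
        assigned[order] = reference
        # average the assigned quantile values over groups of tied inputs
        out[:, j] = (
            pd.Series(assigned).groupby(pd.Series(arr[:, j])).transform("mean")
        )
    return replace(em, values=pd.DataFrame(out, index=df.index, columns=df.columns))


def scaling_normalize(
    target: ExpressionMatrix, reference: ExpressionMatrix, trim: float = 0.02
) -> ExpressionMatrix:
    """Shift the target by one additive log2 constant to match trimmed means.

    Only the location of the target distribution changes; within-sample
    differences are preserved exactly.
    """
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    if target.values.empty or reference.values.empty:
        raise EmptyInputError("scaling normalisation needs nonempty matrices")
    t_mean = stats.trim_mean(target.values.to_numpy(float).ravel(), trim)
    r_mean = stats.trim_mean(reference.values.to_numpy(float).ravel(), trim)
    shift = r_mean - t_mean
    return replace(target, values=target.values + shift)


def select_differential(
    em: ExpressionMatrix,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    min_expression: float | None = None,
    fdr: bool = False,
) -> list[DifferentialGene]:
    """Welch t-test + fold-change filter for differentially expressed genes.

    Keeps features with p < ``p_threshold`` and linear |fold change| strictly
    greater than ``fc_threshold`` (on log2 data, |g| > log2(fc_threshold)).
    ``min_expression`` drops features whose maximum log2 value across all
    samples falls below the floor, standing in for platform detection calls.
    ``fdr`` switches the p-value filter to Benjamini-Hochberg adjusted
    values; raw p-values are the default.
    """
    t_cols = em.samples(TREATMENT)
    c_cols = em.samples(CONTROL)
    if not t_cols or not c_cols:
        raise EmptyInputError("both treatment and control samples are required")
    if max(len(t_cols), len(c_cols)) < 2:
        raise ValueError("the t-test needs >= 2 replicates in at least one condition")

    df = em.values
    if min_expression is not None:
        detected = df.max(axis=1) >= min_expression
        n_drop = int((~detected).sum())
        if n_drop:
            logger.info("detection floor %.3g removed %d features",
                        min_expression, n_drop)
        df = df.loc[detected]

    t_vals = df[t_cols].to_numpy(float)
    c_vals = df[c_cols].to_numpy(float)
    g = t_vals.mean(axis=1) - c_vals.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (near-)zero-variance features are handled explicitly below
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        result = stats.ttest_ind(t_vals, c_vals, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)

    zero_var = (t_vals.var(axis=1) == 0) & (c_vals.var(axis=1) == 0)
    if zero_var.any():
        for gid in df.index[zero_var]:
            logger.warning("feature %s has zero variance in both groups; excluded", gid)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)

    p_used = stats.false_discovery_control(p, method="bh") if fdr else p

    log2_fc = np.log2(fc_threshold) if fc_threshold > 0 else 0.0
    keep = (p_used < p_threshold) & (np.abs(g) > log2_fc) & ~zero_var
    out = [
        DifferentialGene(
            gene_id=str(gid),
            g=float(g[i]),
            p_value=float(p_used[i]),
            fold_change=float(np.sign(g[i]) * 2.0 ** abs(g[i])),
        )
        for i, gid in enumerate(df.index)
        if keep[i]
    ]
    logger.info("selected %d differential features of %d tested", len(out), len(df))
    return out


def expression_vector(
    degenes: Sequence[DifferentialGene],
    gene_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Assemble Z = (g_k) in the ordering used by the indicator matrix rows."""
    if not degenes:
        raise EmptyInputError("no differential genes supplied")
    by_id = {d.gene_id: d.g for d in degenes}
    if gene_order is None:
        return np.array([d.g for d in degenes])
    if sorted(by_id) != sorted(gene_order):
        missing = sorted(set(gene_order) ^ set(by_id))
        raise AlignmentError(
            f"gene ordering does not match differential set (first few: {missing[:5]})"
        )
    return np.array([by_id[g] for g in gene_order])


def read_expression(matrix_path, conditions_path) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix plus a sample->condition map."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t")
    if cond.shape[1] < 2:
        raise EmptyInputError(f"{conditions_path}: need sample and condition columns")
    conditions = dict(zip(cond.iloc[:, 0].astype(str), cond.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, conditions=conditions)


def write_differential(degenes: Sequence[DifferentialGene], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [d.gene_id for d in degenes],
            "g": [d.g for d in degenes],
            "p_value": [d.p_value for d in degenes],
            "fold_change": [d.fold_change for d in degenes],
            "direction": [d.direction for d in degenes],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_differential(path) -> list[DifferentialGene]:
    df = pd.read_csv(path, sep="\t")
    return [
        DifferentialGene(str(r.gene_id), float(r.g), float(r.p_value),
                         float(r.fold_change))
        for r in df.itertuples(index=False)
    ]
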