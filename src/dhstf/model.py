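"""Linear model of differential expression and Monte-Carlo TF scoring.

The model assumes the log2 expression change of gene k is a linear
combination of the aggregate binding affinities of the active factors in its
regulatory DHS sites:

    g_k = sum_i A[k, i] * x_i,      A = C . D

where C marks DHS membership in regulatory regions, D holds thresholded max
match scores and x_i is the unknown functional level of factor i. Because
thousands of PWMs cannot be fit jointly to a few hundred genes, small random
subsets of n_t PWMs are fit by least squares over many iterations; each
selected PWM accumulates a contribution score TFCV += 1/Err^2 (Err the
residual sum of squares of that subset fit) and a functional level
TFL += x_i. Factors that consistently shrink the residual rise to the top of
the TFCV ranking, and the sign of TFL indicates up- versus downregulation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyInputError, ParameterError
from .pwm import AffinityMatrix
from .regions import IndicatorMatrix

logger = logging.getLogger(__name__)

#: relative singular-value cutoff for rank-deficient subset designs
RCOND = 1e-10


@dataclass
class DesignMatrix:
    """Gene x PWM aggregate affinity, A = C . D."""

    gene_ids: list[str]
    pwm_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.pwm_ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read(cls, path) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy(float))


@dataclass
class SubsetFit:
    subset: list[int]
    x: np.ndarray
    err: float  # residual sum of squares


@dataclass
class TFScoreTable:
    """Cumulative TFCV / TFL scores over Monte-Carlo iterations."""

    pwm_ids: list[str]
    tfcv: np.ndarray
    tfl: np.ndarray
    n_selected: np.ndarray
    n_iterations: int
    seed: int | None = None

    def to_frame(self, factor_names: dict[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pwm_id": self.pwm_ids,
                "tfcv": self.tfcv,
                "tfl": self.tfl,
                "n_selected": self.n_selected,
            }
        )
        if factor_names:
            df.insert(1, "factor_name",
                      [factor_names.get(p, "") for p in self.pwm_ids])
        return df

    def write(self, path, factor_names: dict[str, str] | None = None) -> None:
        self.to_frame(factor_names).to_csv(path, sep="\t", index=False,
                                           float_format="%.12g")

    @classmethod
    def read(cls, path) -> "TFScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            pwm_ids=[str(p) for p in df["pwm_id"]],
            tfcv=df["tfcv"].to_numpy(float),
            tfl=df["tfl"].to_numpy(float),
            n_selected=df["n_selected"].to_numpy(int),
            n_iterations=int(df["n_selected"].sum()),
        )


def design_matrix(C: IndicatorMatrix, D: AffinityMatrix) -> DesignMatrix:
    """Multiply C (genes x DHS) by D (DHS x PWMs) after id alignment."""
    if C.dhs_ids != D.dhs_ids:
        for k, (a, b) in enumerate(itertools.zip_longest(C.dhs_ids, D.dhs_ids)):
            if a != b:
                raise AlignmentError(
                    f"C/D DHS id mismatch at position {k}: {a!r} != {b!r}"
                )
    values = C.values.astype(float) @ D.scores
    return DesignMatrix(gene_ids=list(C.gene_ids), pwm_ids=list(D.pwm_ids),
                        values=values)


def fit_subset(
    A: DesignMatrix | np.ndarray, Z: np.ndarray, subset: Sequence[int]
) -> SubsetFit:
    """Least-squares fit of Z on the selected PWM columns.

    Rank-deficient designs get the minimum-norm solution (pseudoinverse
    semantics with relative cutoff RCOND); an all-zero design returns x = 0
    with err = ||Z||^2.
    """
    values = A.values if isinstance(A, DesignMatrix) else np.asarray(A, float)
    subset = list(subset)
    if len(set(subset)) != len(subset):
        raise ParameterError("subset indices must be distinct")
    if subset and (min(subset) < 0 or max(subset) >= values.shape[1]):
        raise ParameterError("subset index out of range")
    Z = np.asarray(Z, dtype=float)
    A_s = values[:, subset]
    if not A_s.any():
        return SubsetFit(subset, np.zeros(len(subset)), float(Z @ Z))
    x, *_ = np.linalg.lstsq(A_s, Z, rcond=RCOND)
    resid = Z - A_s @ x
    return SubsetFit(subset, x, float(resid @ resid))


def run_monte_carlo(
    A: DesignMatrix | np.ndarray,
    Z: np.ndarray,
    n_t: int = 5,
    n_iter: int = 1_000_000,
    seed: int = 0,
    epsilon: float = 1e-12,
    pwm_ids: Sequence[str] | None = None,
    chunk_size: int = 4096,
) -> TFScoreTable:
    """Accumulate TFCV and TFL over random PWM subsets.

    Per iteration, n_t distinct PWM columns are drawn uniformly without
    replacement and fit by least squares; every selected PWM receives the
    full increment 1/max(err, epsilon)^2 to its TFCV and its estimated
    coefficient to its TFL. Deterministic for a fixed seed.

    Subset solutions use the normal equations G x = b (G = A_s'A_s,
    b = A_s'Z) with a batched pseudoinverse, which gives the same
    minimum-norm least-squares solution as fitting A_s directly; residuals
    are evaluated against A_s itself.
    """
    values = A.values if isinstance(A, DesignMatrix) else np.asarray(A, float)
    if pwm_ids is None:
        pwm_ids = A.pwm_ids if isinstance(A, DesignMatrix) else [
            str(i) for i in range(values.shape[1])
        ]
    n_genes, n_pwms = values.shape
    if n_t > n_pwms:
        raise ParameterError(f"n_t={n_t} exceeds the {n_pwms} available PWM columns")
    if n_t < 1 or n_iter < 1:
        raise ParameterError("n_t and n_iter must be >= 1")
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (n_genes,):
        raise AlignmentError(f"Z has shape {Z.shape}, expected ({n_genes},)")

    rng = np.random.default_rng(seed)
    AtA = values.T @ values
    AtZ = values.T @ Z

    tfcv = np.zeros(n_pwms)
    tfl = np.zeros(n_pwms)
    n_selected = np.zeros(n_pwms, dtype=np.int64)
    n_clamped = 0

    done = 0
    while done < n_iter:
        m = min(chunk_size, n_iter - done)
        # uniform random n_t-subsets: smallest n_t keys of i.i.d. uniforms
        keys = rng.random((m, n_pwms))
        ix = np.argpartition(keys, n_t - 1, axis=1)[:, :n_t]

        G = AtA[ix[:, :, None], ix[:, None, :]]  # (m, n_t, n_t)
        b = AtZ[ix]  # (m, n_t)
        x = np.einsum("mij,mj->mi", np.linalg.pinv(G, rcond=RCOND), b)
        # residuals against the actual subset columns
        A_sub = values[:, ix]  # (n_genes, m, n_t)
        resid = Z[:, None] - np.einsum("gmj,mj->gm", A_sub, x)
        err = np.einsum("gm,gm->m", resid, resid)

        clamped = err < epsilon
        n_clamped += int(clamped.sum())
        w = 1.0 / np.maximum(err, epsilon) ** 2

        np.add.at(tfcv, ix, w[:, None])
        np.add.at(tfl, ix, x)
        np.add.at(n_selected, ix, 1)
        done += m

    if n_clamped:
        logger.info("clamped %d near-zero residuals at epsilon=%g", n_clamped, epsilon)
    return TFScoreTable(
        pwm_ids=list(pwm_ids), tfcv=tfcv, tfl=tfl, n_selected=n_selected,
        n_iterations=n_iter, seed=seed,
    )


def run_exhaustive(
    A: DesignMatrix | np.ndarray,
    Z: np.ndarray,
    n_t: int,
    epsilon: float = 1e-12,
    pwm_ids: Sequence[str] | None = None,
) -> TFScoreTable:
    """TFCV/TFL accumulated over every n_t-subset exactly once.

    Reference mode for small PWM sets: Monte-Carlo scores converge to
    n_iter / C(n_pwms, n_t) times these values.
    """
    values = A.values if isinstance(A, DesignMatrix) else np.asarray(A, float)
    if pwm_ids is None:
        pwm_ids = A.pwm_ids if isinstance(A, DesignMatrix) else [
            str(i) for i in range(values.shape[1])
        ]
    n_pwms = values.shape[1]
    if n_t > n_pwms:
        raise ParameterError(f"n_t={n_t} exceeds the {n_pwms} available PWM columns")
    tfcv = np.zeros(n_pwms)
    tfl = np.zeros(n_pwms)
    n_selected = np.zeros(n_pwms, dtype=np.int64)
    n_subsets = 0
    for subset in itertools.combinations(range(n_pwms), n_t):
        fit = fit_subset(values, Z, subset)
        w = 1.0 / max(fit.err, epsilon) ** 2
        for pos, i in enumerate(subset):
            tfcv[i] += w
            tfl[i] += fit.x[pos]
            n_selected[i] += 1
        n_subsets += 1
    return TFScoreTable(
        pwm_ids=list(pwm_ids), tfcv=tfcv, tfl=tfl, n_selected=n_selected,
        n_iterations=n_subsets, seed=None,
    )


def rank_tfs(
    table: TFScoreTable,
    top_n: int = 10,
    factor_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Sort PWMs by TFCV descending; ties break on pwm_id lexicographically."""
    if top_n < 1:
        raise ParameterError("top_n must be >= 1")
    df = table.to_frame(factor_names)
    df = df.sort_values(["tfcv", "pwm_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    if top_n > len(df):
        logger.warning("top_n=%d exceeds the %d PWMs; returning the full ranking",
                       top_n, len(df))
        return df
    return df.head(top_n)


def compare_thresholds(tables: Sequence[TFScoreTable]) -> pd.DataFrame:
    """Pairwise Pearson correlation of TFCV profiles across runs.

    All tables must share the same PWM ordering; a constant TFCV vector has
    undefined correlation and is reported as NaN off the diagonal.
    """
    if len(tables) < 2:
        raise EmptyInputError("need at least two score tables to compare")
    ids = tables[0].pwm_ids
    for t in tables[1:]:
        if t.pwm_ids != ids:
            raise AlignmentError("score tables have different PWM orderings")
    n = len(tables)
    out = np.full((n, n), np.nan)
    vecs = [t.tfcv for t in tables]
    stds = [float(np.std(v)) for v in vecs]
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if stds[i] == 0 or stds[j] == 0:
                continue
            r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
            out[i, j] = out[j, i] = r
    labels = [f"run{i + 1}" for i in range(n)]
    return pd.DataFrame(out, index=labels, columns=labels)


def mc_standard_errors(
    A: DesignMatrix | np.ndarray, Z: np.ndarray, n_t: int, n_iter: int,
    epsilon: float = 1e-12,
) -> np.ndarray:
    """Exact per-PWM standard error of the Monte-Carlo TFCV estimator.

    Each iteration contributes y_i = 1[i in S] / err_S^2 with S uniform over
    all n_t-subsets; the SE of the n_iter-iteration sum follows from the
    exact first and second moments of y_i computed by enumeration.
    """
    values = A.values if isinstance(A, DesignMatrix) else np.asarray(A, float)
    n_pwms = values.shape[1]
    subsets = list(itertools.combinations(range(n_pwms), n_t))
    n_subsets = len(subsets)
    m1 = np.zeros(n_pwms)
    m2 = np.zeros(n_pwms)
    for subset in subsets:
        w = 1.0 / max(fit_subset(values, Z, subset).err, epsilon) ** 2
        for i in subset:
            m1[i] += w / n_subsets
            m2[i] += w * w / n_subsets
    var_per_iter = m2 - m1**2
    return np.sqrt(n_iter * var_per_iter)
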