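"""End-to-end orchestration: expression -> regions -> scan -> model -> ranking.

Mirrors the eight-step procedure of the method: compute the per-gene log2
ratio vector Z from normalised expression, build the indicator matrix C
from regulatory windows and DHS sites, scan PWMs over DHS sequences and
threshold to the genome-wide top K to get the affinity matrix D, then run
the Monte-Carlo subset regression and rank factors by TFCV. Every
intermediate artifact is written to the run directory along with a
machine-readable manifest, so a run is fully reproducible from its inputs,
parameters and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .errors import DhstfError, EmptyInputError, ParameterError
from .expression import (
    CONTROL,
    TREATMENT,
    ExpressionMatrix,
    expression_vector,
    quantile_normalize,
    read_expression,
    scaling_normalize,
    select_differential,
    write_differential,
)
from .model import design_matrix, rank_tfs, run_monte_carlo
from .pwm import build_affinity_matrix, parse_transfac, to_scoring_matrix
from .regions import build_indicator_matrix, read_bed, read_gene_table, regulatory_region

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    Parameter defaults are the reference settings of the method: a
    -1000/+500 bp TSS window, genome-wide top 5000 sites per PWM, P < 0.05
    with linear fold change > 2, and subsets of n_t = 5 PWMs per
    Monte-Carlo iteration.
    """

    pwms: str = ""
    fasta: str = ""
    dhs_bed: str = ""
    genes: str = ""
    expression: str = ""
    conditions: str = ""
    out_dir: str = "run"

    upstream: int = 1000
    downstream: int = 500
    top_k: int = 5000
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    min_expression: float | None = 4.0
    fdr: bool = False
    trim: float = 0.02
    overlap_mode: str = "any"
    strip_chr: bool = False
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 1.0
    n_t: int = 5
    n_iter: int = 1_000_000
    seed: int = 0
    epsilon: float = 1e-12
    top_n: int = 10

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "background" in data:
            data["background"] = tuple(data["background"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background"] = list(self.background)
        return d


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except DhstfError:
        logger.error("stage %s failed", name)
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise DhstfError(f"stage {name} failed: {exc}") from exc
    logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_z(Z: np.ndarray, gene_ids, path) -> None:
    pd.DataFrame({"gene_id": gene_ids, "g": Z}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_z(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df["g"].to_numpy(float), [str(g) for g in df["gene_id"]]


def load_dhs_sequences(fasta_path, dhs_intervals) -> dict[str, str]:
    """Extract DHS sequences from a FASTA; IDs follow chrom:start-end."""
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    out = {}
    for iv in dhs_intervals:
        if iv.chrom not in fasta:
            raise DhstfError(f"chromosome {iv.chrom} missing from {fasta_path}")
        out[iv.id] = str(fasta[iv.chrom][iv.start : iv.end])
    return out


def normalize_expression(em: ExpressionMatrix, trim: float = 0.02) -> ExpressionMatrix:
    """Quantile-normalise replicates per condition, then scale treatment
    onto control with one additive log2 shift."""
    treat = quantile_normalize(em.subset(TREATMENT))
    ctrl = quantile_normalize(em.subset(CONTROL))
    treat = scaling_normalize(treat, ctrl, trim=trim)
    values = pd.concat([treat.values, ctrl.values], axis=1)
    return ExpressionMatrix(values=values[em.values.columns], conditions=dict(em.conditions))


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    with _stage("parse"):
        pwms = parse_transfac(Path(config.pwms).read_text())
        counts["pwms"] = len(pwms)
        if config.n_t > len(pwms):
            raise ParameterError(
                f"n_t={config.n_t} exceeds the {len(pwms)} supplied PWMs"
            )
        dhs = read_bed(config.dhs_bed, strip_chr=config.strip_chr)
        counts["dhs_sites"] = len(dhs)
        genes = read_gene_table(config.genes, strip_chr=config.strip_chr)
        counts["genes_annotated"] = len(genes)

    with _stage("de"):
        em = read_expression(config.expression, config.conditions)
        em = normalize_expression(em, trim=config.trim)
        degenes = select_differential(
            em,
            p_threshold=config.p_threshold,
            fc_threshold=config.fc_threshold,
            min_expression=config.min_expression,
            fdr=config.fdr,
        )
        if not degenes:
            raise EmptyInputError("no differentially expressed genes selected")
        counts["de_genes"] = len(degenes)
        write_differential(degenes, out / "de_genes.tsv")

    with _stage("regions"):
        by_id = {g.gene_id: g for g in genes}
        missing = [d.gene_id for d in degenes if d.gene_id not in by_id]
        if missing:
            logger.warning(
                "%d DE genes missing from the annotation (e.g. %s); dropped",
                len(missing), missing[:3],
            )
        degenes = [d for d in degenes if d.gene_id in by_id]
        if not degenes:
            raise EmptyInputError("no DE gene has a gene model in the annotation")
        regions = {
            d.gene_id: regulatory_region(
                by_id[d.gene_id], config.upstream, config.downstream
            )
            for d in degenes
        }
        C = build_indicator_matrix(regions, dhs, mode=config.overlap_mode)
        counts["de_genes_with_model"] = len(degenes)
        counts["indicator_nonzero"] = int(C.values.sum())
        C.write(out / "indicator.tsv")

    with _stage("scan"):
        sequences = load_dhs_sequences(config.fasta, dhs)
        sms = [
            to_scoring_matrix(p, background=config.background,
                              pseudocount=config.pseudocount)
            for p in pwms
        ]
        D = build_affinity_matrix(sms, sequences, config.top_k)
        counts["affinity_nonzero"] = int(np.count_nonzero(D.scores))
        D.write(out / "affinity.tsv", out / "thresholds.tsv")

    with _stage("matrices"):
        A = design_matrix(C, D)
        Z = expression_vector(degenes, gene_order=C.gene_ids)
        A.write(out / "design.tsv")
        write_z(Z, C.gene_ids, out / "z.tsv")

    with _stage("run"):
        table = run_monte_carlo(
            A, Z, n_t=config.n_t, n_iter=config.n_iter, seed=config.seed,
            epsilon=config.epsilon,
        )
        names = {p.id: p.factor_name for p in pwms}
        table.write(out / "tf_scores.tsv", factor_names=names)

    with _stage("rank"):
        ranked = rank_tfs(table, top_n=config.top_n, factor_names=names)
        ranked.to_csv(out / "ranked.tsv", sep="\t", index=False,
                      float_format="%.12g")

    manifest = {
        "package": "dhstf",
        "version": __version__,
        "parameters": config.to_dict(),
        "inputs": {
            key: {"path": str(getattr(config, key)),
                  "sha256": _sha256(getattr(config, key))}
            for key in ("pwms", "fasta", "dhs_bed", "genes", "expression",
                        "conditions")
        },
        "counts": counts,
        "outputs": sorted(
            p.name for p in out.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
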