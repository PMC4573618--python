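"""End-to-end synthetic fixtures: genome, DHS sites, motifs, expression.

The generator emulates the study design the pipeline expects — a small
random genome with non-overlapping genes, DNase I hypersensitive sites
partly placed inside TSS regulatory windows, a motif library in which a few
"planted" PWMs are sharp and have their consensus embedded into the DHS
sites of chosen target genes, and a replicated two-condition expression
matrix in which the treatment/control log2 difference of each gene is the
linear-model signal

    g_k = sum_m sum_i C[k, m] * d[m, i] * x_i

of the planted factors plus Gaussian noise. Every stage of the pipeline can
therefore be tested against known ground truth without any download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FeasibilityError
from .expression import CONTROL, TREATMENT, ExpressionMatrix
from .pwm import (
    BASES,
    PWM,
    AffinityMatrix,
    build_affinity_matrix,
    to_scoring_matrix,
    write_transfac,
)
from .regions import (
    GeneModel,
    GenomicInterval,
    IndicatorMatrix,
    build_indicator_matrix,
    regulatory_region,
)

logger = logging.getLogger(__name__)

_CHROM_MARGIN = 2000  # bp kept free at each chromosome end


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the desk-scale benchmark: 150 genes and 400 DHS sites
    on a 2 x 500 kb genome, 50 PWMs of which 3 are planted with effects
    (+0.12, +0.10, -0.10), and expression noise with SD equal to 25% of the
    SD of the planted signal (``noise_relative=True``).
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 150
    n_dhs: int = 400
    n_pwms: int = 50
    pwm_length_range: tuple[int, int] = (8, 12)
    planted_pwms: tuple[tuple[int, float], ...] = ((0, 0.12), (1, 0.10), (2, -0.10))
    noise_sd: float = 0.25
    noise_relative: bool = True  # noise_sd is a fraction of the signal SD
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    dhs_length: int = 200
    in_window_fraction: float = 0.4
    targets_per_pwm: int = 25
    n_treatment: int = 2
    n_control: int = 3
    replicate_sd: float = 0.15
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    upstream: int = 1000
    downstream: int = 500
    top_k: int = 100
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if any(i >= self.n_pwms or i < 0 for i, _ in self.planted_pwms):
            raise ValueError("planted PWM index out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if not (0 <= self.in_window_fraction <= 1):
            raise ValueError("in_window_fraction must be in [0, 1]")


@dataclass
class FixtureBundle:
    """In-memory fixture plus writers for the on-disk formats."""

    spec: SyntheticSpec
    genome: dict[str, str]
    genes: list[GeneModel]
    dhs: list[GenomicInterval]
    dhs_sequences: dict[str, str]
    pwms: list[PWM]
    expression: ExpressionMatrix
    truth_sites: pd.DataFrame  # gene_id, pwm_id, dhs_id, position, effect
    truth_effects: pd.DataFrame  # pwm_id, pwm_index, effect
    signal: pd.Series  # per-gene noise-free treatment-minus-control signal
    planted_affinity: AffinityMatrix = field(repr=False, default=None)  # type: ignore

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "dhs_bed": out / "dhs.bed",
            "genes": out / "genes.tsv",
            "pwms": out / "pwms.transfac",
            "expression": out / "expression.tsv",
            "conditions": out / "conditions.tsv",
            "truth_sites": out / "truth_sites.tsv",
            "truth_effects": out / "truth_effects.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k : k + 80] + "\n")
        with open(paths["dhs_bed"], "w") as fh:
            for iv in self.dhs:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")
        pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
            }
        ).to_csv(paths["genes"], sep="\t", index=False)
        paths["pwms"].write_text(write_transfac(self.pwms))
        self.expression.write(paths["expression"])
        pd.DataFrame(
            {
                "sample_id": list(self.expression.values.columns),
                "condition": [
                    self.expression.conditions[s]
                    for s in self.expression.values.columns
                ],
            }
        ).to_csv(paths["conditions"], sep="\t", index=False)
        self.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        self.truth_effects.to_csv(paths["truth_effects"], sep="\t", index=False,
                                  float_format="%.10g")
        return paths


def _place_genes(spec: SyntheticSpec, rng: np.random.Generator) -> list[GeneModel]:
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    per_chrom = [
        spec.n_genes // spec.n_chromosomes
        + (1 if i < spec.n_genes % spec.n_chromosomes else 0)
        for i in range(spec.n_chromosomes)
    ]
    reach = max(spec.upstream, spec.downstream)
    genes: list[GeneModel] = []
    k = 0
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        slot = (spec.chrom_length - 2 * _CHROM_MARGIN) // count
        if slot < 2 * reach + spec.dhs_length:
            raise FeasibilityError(
                f"{count} genes do not fit on a {spec.chrom_length} bp chromosome "
                f"with {2 * reach} bp regulatory spans"
            )
        for s in range(count):
            # keep the whole window inside this gene's slot on either strand
            tss = (_CHROM_MARGIN + s * slot + reach
                   + int(rng.integers(0, slot - 2 * reach + 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"G{k + 1:04d}", chrom, strand, tss))
            k += 1
    return genes


def _place_dhs(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    windows: dict[str, GenomicInterval],
    genes: list[GeneModel],
) -> tuple[list[GenomicInterval], dict[str, list[int]]]:
    """Place non-overlapping DHS; a fraction inside regulatory windows."""
    occupied: dict[str, list[tuple[int, int]]] = {}

    def free(chrom: str, start: int, end: int) -> bool:
        return all(
            not (start < e and s < end) for s, e in occupied.get(chrom, ())
        )

    dhs: list[GenomicInterval] = []
    gene_dhs: dict[str, list[int]] = {g.gene_id: [] for g in genes}
    n_in = int(round(spec.in_window_fraction * spec.n_dhs))
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]

    for j in range(spec.n_dhs):
        placed = False
        for _ in range(200):
            if j < n_in:
                gene = genes[j % len(genes)]
                w = windows[gene.gene_id]
                if len(w) < spec.dhs_length:
                    break
                start = int(rng.integers(w.start, w.end - spec.dhs_length + 1))
                chrom = w.chrom
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                start = int(
                    rng.integers(0, spec.chrom_length - spec.dhs_length + 1)
                )
            end = start + spec.dhs_length
            if free(chrom, start, end):
                occupied.setdefault(chrom, []).append((start, end))
                iv = GenomicInterval(chrom, start, end)
                if j < n_in:
                    gene_dhs[genes[j % len(genes)].gene_id].append(len(dhs))
                dhs.append(iv)
                placed = True
                break
        if not placed:
            logger.warning("could not place DHS %d without overlap; skipped", j)
    return dhs, gene_dhs


def _draw_pwms(spec: SyntheticSpec, rng: np.random.Generator) -> list[PWM]:
    """Planted PWMs are sharp (90% majority base); decoys are flatter."""
    planted = {i for i, _ in spec.planted_pwms}
    pwms = []
    lo, hi = spec.pwm_length_range
    for i in range(spec.n_pwms):
        length = int(rng.integers(lo, hi + 1))
        if i in planted:
            counts = np.full((length, 4), 20.0 * 0.10 / 3.0)
            for pos in range(length):
                counts[pos, int(rng.integers(0, 4))] = 20.0 * 0.90
        else:
            counts = rng.dirichlet([2.0, 2.0, 2.0, 2.0], size=length) * 20.0
            counts = np.maximum(counts, 0.05)
        kind = "planted" if i in planted else "decoy"
        pwms.append(
            PWM(
                id=f"M{i + 1:05d}",
                factor_name=f"TF{i + 1}",
                description=f"synthetic {kind} motif",
                counts=counts,
            )
        )
    return pwms


def generate_fixture(spec: SyntheticSpec, out_dir=None) -> FixtureBundle:
    """Build one deterministic fixture; optionally write it to ``out_dir``."""
    ss = np.random.SeedSequence(spec.seed)
    rng_genome, rng_layout, rng_pwm, rng_embed, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    genome = {
        c: rng_genome.choice(4, size=spec.chrom_length,
                             p=np.asarray(spec.base_composition)).astype(np.int8)
        for c in chroms
    }

    genes = _place_genes(spec, rng_layout)
    windows = {
        g.gene_id: regulatory_region(g, spec.upstream, spec.downstream)
        for g in genes
    }
    dhs, gene_dhs = _place_dhs(spec, rng_layout, windows, genes)
    pwms = _draw_pwms(spec, rng_pwm)

    # embed planted consensus sequences into target genes' in-window DHS
    truth_rows = []
    base_idx = {b: k for k, b in enumerate(BASES)}
    embedded: dict[int, list[tuple[int, int]]] = {}
    eligible = [g.gene_id for g in genes if gene_dhs[g.gene_id]]
    for pwm_index, effect in spec.planted_pwms:
        pwm = pwms[pwm_index]
        consensus = np.array([base_idx[b] for b in pwm.consensus], dtype=np.int8)
        n_targets = min(spec.targets_per_pwm, len(eligible))
        targets = rng_embed.choice(len(eligible), size=n_targets, replace=False)
        for t in targets:
            gene_id = eligible[int(t)]
            dhs_idx = gene_dhs[gene_id][
                int(rng_embed.integers(0, len(gene_dhs[gene_id])))
            ]
            site = dhs[dhs_idx]
            spans = embedded.setdefault(dhs_idx, [])
            offset = None
            for _ in range(50):
                cand = int(rng_embed.integers(0, len(site) - len(consensus) + 1))
                if all(not (cand < e and s < cand + len(consensus))
                       for s, e in spans):
                    offset = cand
                    break
            if offset is None:
                logger.warning("no free slot for %s in %s; site skipped",
                               pwm.id, site.id)
                continue
            spans.append((offset, offset + len(consensus)))
            pos = site.start + offset
            genome[site.chrom][pos : pos + len(consensus)] = consensus
            truth_rows.append(
                {"gene_id": gene_id, "pwm_id": pwm.id, "dhs_id": site.id,
                 "position": pos, "effect": effect}
            )

    genome_str = {
        c: "".join(BASES[b] for b in arr.tolist()) for c, arr in genome.items()
    }
    dhs_sequences = {
        iv.id: genome_str[iv.chrom][iv.start : iv.end] for iv in dhs
    }

    # noise-free signal through the linear model, using the true (thresholded)
    # affinities of the planted PWMs only
    planted_order = [i for i, _ in spec.planted_pwms]
    effects = np.array([e for _, e in spec.planted_pwms])
    planted_sms = [
        to_scoring_matrix(pwms[i], pseudocount=spec.pseudocount)
        for i in planted_order
    ]
    D_planted = build_affinity_matrix(planted_sms, dhs_sequences, spec.top_k)
    C_all = build_indicator_matrix(windows, dhs)
    signal = C_all.values.astype(float) @ (D_planted.scores @ effects)

    if spec.noise_relative:
        sd = spec.noise_sd * float(np.std(signal))
    else:
        sd = spec.noise_sd
    noise = rng_expr.normal(0.0, sd, spec.n_genes) if sd > 0 else np.zeros(spec.n_genes)

    baseline = rng_expr.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    control_mean = baseline
    treatment_mean = baseline + signal + noise

    def replicates(mean: np.ndarray, n_rep: int) -> np.ndarray:
        dev = rng_expr.normal(0.0, spec.replicate_sd, (spec.n_genes, n_rep))
        dev -= dev.mean(axis=1, keepdims=True)  # group means stay exact
        return mean[:, None] + dev

    t_cols = [f"trt_{r + 1}" for r in range(spec.n_treatment)]
    c_cols = [f"ctl_{r + 1}" for r in range(spec.n_control)]
    values = np.hstack(
        [replicates(treatment_mean, spec.n_treatment),
         replicates(control_mean, spec.n_control)]
    )
    gene_ids = [g.gene_id for g in genes]
    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=t_cols + c_cols),
        conditions={**{s: TREATMENT for s in t_cols},
                    **{s: CONTROL for s in c_cols}},
    )

    truth_sites = pd.DataFrame(
        truth_rows, columns=["gene_id", "pwm_id", "dhs_id", "position", "effect"]
    )
    truth_effects = pd.DataFrame(
        {
            "pwm_id": [pwms[i].id for i in planted_order],
            "pwm_index": planted_order,
            "effect": effects,
        }
    )
    bundle = FixtureBundle(
        spec=spec,
        genome=genome_str,
        genes=genes,
        dhs=dhs,
        dhs_sequences=dhs_sequences,
        pwms=pwms,
        expression=expression,
        truth_sites=truth_sites,
        truth_effects=truth_effects,
        signal=pd.Series(signal, index=gene_ids, name="signal"),
        planted_affinity=D_planted,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def toy_matrices(
    n_genes: int = 30,
    n_dhs: int = 40,
    n_pwms: int = 10,
    seed: int = 0,
    n_planted: int = 2,
    noise_sd: float = 0.1,
) -> tuple[IndicatorMatrix, AffinityMatrix, np.ndarray, dict]:
    """Small C/D/Z matrices with known planted x, skipping the sequence level.

    Z = C . D . x_true + N(0, noise_sd); planted coefficients occupy the
    first ``n_planted`` PWM columns with alternating signs.
    """
    if min(n_genes, n_dhs, n_pwms) < 1:
        raise ValueError("n_genes, n_dhs and n_pwms must all be >= 1")
    rng = np.random.default_rng(seed)
    C = np.zeros((n_genes, n_dhs), dtype=np.uint8)
    for i in range(n_genes):
        k = min(n_dhs, int(rng.integers(1, 4)))
        C[i, rng.choice(n_dhs, size=k, replace=False)] = 1
    D = np.abs(rng.normal(5.0, 2.0, (n_dhs, n_pwms)))
    D[rng.random((n_dhs, n_pwms)) < 0.6] = 0.0
    x_true = np.zeros(n_pwms)
    n_planted = min(n_planted, n_pwms)
    for j in range(n_planted):
        x_true[j] = (1.0 if j % 2 == 0 else -1.0) * rng.uniform(0.5, 1.5)
    Z = C.astype(float) @ D @ x_true
    if noise_sd > 0:
        Z = Z + rng.normal(0.0, noise_sd, n_genes)
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    dhs_ids = [f"chr1:{1000 * j}-{1000 * j + 200}" for j in range(n_dhs)]
    pwm_ids = [f"M{j + 1:05d}" for j in range(n_pwms)]
    thresholds = np.where(
        (D > 0).any(axis=0),
        np.where(D > 0, D, np.inf).min(axis=0),
        0.0,
    )
    return (
        IndicatorMatrix(gene_ids, dhs_ids, C),
        AffinityMatrix(dhs_ids, pwm_ids, D, thresholds),
        Z,
        {"x_true": x_true, "planted": list(range(n_planted))},
    )
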