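"""Position weight matrices: TRANSFAC parsing, log-odds scoring, DHS affinity.

A PWM describes a transcription factor's sequence preference as per-position
nucleotide counts. To score a sequence the counts are converted to log2-odds
weights against a background composition, every window on both strands is
summed, and the maximum window score is the binding affinity of that factor
for that sequence. Per factor, only the genome-wide top-K affinities are kept
(everything below the K-th highest score is zeroed), giving the sparse
DHS x PWM affinity matrix used downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyInputError,
    ParseError,
    SequenceLengthError,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
# index 4 is the ambiguity code N, scored as the background expectation
# (weight 0 under log-odds)
_BASE_INDEX = {ord(b): i for i, b in enumerate(BASES + "N")}
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class PWM:
    """A positional nucleotide count matrix with TRANSFAC-style metadata.

    ``counts`` has shape (L, 4) in A, C, G, T column order; entries are
    nonnegative and every position has at least one strictly positive count.
    """

    id: str
    factor_name: str
    description: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"PWM {self.id}: counts must be L x 4 with L >= 1")
        if np.any(counts < 0):
            raise ValueError(f"PWM {self.id}: negative counts")
        if np.any(counts.max(axis=1) <= 0):
            raise ValueError(f"PWM {self.id}: a position has no positive count")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-count base at each position (ties -> first in ACGT order)."""
        return "".join(BASES[b] for b in np.argmax(self.counts, axis=1))


@dataclass(frozen=True)
class ScoringMatrix:
    """Log2-odds weights derived from a PWM, ready for scanning."""

    pwm_id: str
    weights: np.ndarray  # (L, 4)
    max_score: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(weights)):
            raise ValueError(f"ScoringMatrix {self.pwm_id}: non-finite weights")
        object.__setattr__(self, "weights", weights)
        if self.max_score is None:
            object.__setattr__(self, "max_score", float(weights.max(axis=1).sum()))

    @property
    def length(self) -> int:
        return self.weights.shape[0]


_ROW_RE = re.compile(r"^(\d+)\s+(.*)$")


def parse_transfac(text: str) -> list[PWM]:
    """Parse a concatenation of TRANSFAC matrix records.

    Supported fields: AC (accession, used as the PWM id), ID (fallback id),
    NA (factor name), DE (description), a P0/PO header giving the nucleotide
    column order, numbered matrix rows with four numeric columns (a trailing
    consensus letter is ignored), and ``//`` record terminators. Anything
    else is skipped. Records with no matrix body are dropped with a warning.
    """
    if not text.strip():
        raise EmptyInputError("no TRANSFAC records in input")

    pwms: list[PWM] = []
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    col_order = list(BASES)
    saw_record = False

    def flush() -> None:
        nonlocal meta, rows, col_order
        if meta or rows:
            pwm_id = meta.get("AC") or meta.get("ID") or f"PWM{len(pwms) + 1:04d}"
            if not rows:
                logger.warning("TRANSFAC record %s has no matrix body; skipped", pwm_id)
            else:
                counts = np.zeros((len(rows), 4))
                perm = [col_order.index(b) for b in BASES]
                counts[:, :] = np.asarray(rows, dtype=float)[:, perm]
                pwms.append(
                    PWM(
                        id=pwm_id,
                        factor_name=meta.get("NA", ""),
                        description=meta.get("DE", ""),
                        counts=counts,
                    )
                )
        meta = {}
        rows = []
        col_order = list(BASES)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("//"):
            flush()
            continue
        tag, _, rest = line.partition(" ")
        rest = rest.strip()
        if tag in {"AC", "ID", "NA", "DE"}:
            saw_record = True
            meta[tag] = rest.split(";")[0].strip() if tag == "AC" else rest
            continue
        if tag in {"P0", "PO"}:
            letters = [t.upper() for t in rest.split()]
            if sorted(letters) != sorted(BASES):
                raise ParseError(
                    f"line {lineno}: P0 header must list A C G T, got {rest!r}"
                )
            col_order = letters
            continue
        m = _ROW_RE.match(line)
        if m:
            saw_record = True
            fields = m.group(2).split()
            numeric = fields[:4]
            try:
                values = [float(v) for v in numeric]
            except ValueError as exc:
                rec = meta.get("AC") or meta.get("ID") or "<unnamed>"
                raise ParseError(
                    f"record {rec}, line {lineno}: malformed matrix row {line!r}"
                ) from exc
            if len(values) != 4:
                rec = meta.get("AC") or meta.get("ID") or "<unnamed>"
                raise ParseError(
                    f"record {rec}, line {lineno}: expected 4 numeric columns"
                )
            rows.append(values)
        # other tags (XX, BF, CC, ...) are ignored

    flush()
    if not pwms:
        if saw_record:
            raise EmptyInputError("no TRANSFAC record contained a matrix body")
        raise EmptyInputError("no TRANSFAC records in input")
    return pwms


def to_scoring_matrix(
    pwm: PWM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1.0,
) -> ScoringMatrix:
    """Convert counts to log2-odds weights against a background composition.

    weights[l, b] = log2( (counts[l, b] + pseudocount * background[b])
                          / (rowsum_l + pseudocount) / background[b] )
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    counts = pwm.counts
    if pseudocount == 0 and np.any(counts == 0):
        raise DomainError(
            f"PWM {pwm.id}: zero count with zero pseudocount (log of zero)"
        )
    rowsum = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * bg) / (rowsum + pseudocount)
    weights = np.log2(probs / bg)
    return ScoringMatrix(pwm_id=pwm.id, weights=weights)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an ACGTN string (case-insensitive) to indices 0..4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    idx = np.full(arr.shape, -1, dtype=np.int8)
    for code, i in _BASE_INDEX.items():
        idx[arr == code] = i
    if np.any(idx < 0):
        bad = chr(arr[int(np.argmax(idx < 0))])
        raise ValueError(f"unsupported nucleotide {bad!r} (alphabet is ACGTN)")
    return idx


def _padded_weights(sm: ScoringMatrix) -> np.ndarray:
    """Weights with a fifth zero column so N contributes 0."""
    return np.hstack([sm.weights, np.zeros((sm.length, 1))])


def _windows_max(w5: np.ndarray, idx: np.ndarray) -> float:
    length = w5.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(idx, length)
    scores = w5[np.arange(length)[None, :], windows].sum(axis=1)
    return float(scores.max())


def scan_max_score(
    sm: ScoringMatrix, sequence: str | np.ndarray, sequence_id: str = "<sequence>"
) -> float:
    """Maximum summed weight over all windows on both strands.

    TF binding is strand-agnostic, so the reverse complement of the sequence
    is scanned as well. ``sequence`` may be a string or an array pre-encoded
    with :func:`encode_sequence`.
    """
    idx = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    if idx.size < sm.length:
        raise SequenceLengthError(
            f"PWM {sm.pwm_id} (length {sm.length}) does not fit in sequence "
            f"{sequence_id} (length {idx.size})"
        )
    w5 = _padded_weights(sm)
    idx_rc = _COMPLEMENT[idx][::-1]
    return max(_windows_max(w5, idx), _windows_max(w5, idx_rc))


@dataclass
class AffinityMatrix:
    """DHS x PWM matrix of max match scores, zeroed below per-PWM thresholds.

    For each PWM the threshold ``ts`` is the K-th highest max score across
    all DHS sites (ties at ts are all retained); nonzero entries are the raw
    max window scores, entries below ts are 0.
    """

    dhs_ids: list[str]
    pwm_ids: list[str]
    scores: np.ndarray  # (n_dhs, n_pwms)
    thresholds: np.ndarray  # (n_pwms,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.dhs_ids, columns=self.pwm_ids)

    def write(self, scores_path, thresholds_path=None) -> None:
        self.to_frame().to_csv(scores_path, sep="\t", float_format="%.10g")
        if thresholds_path is not None:
            pd.DataFrame(
                {"pwm_id": self.pwm_ids, "threshold": self.thresholds}
            ).to_csv(thresholds_path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, scores_path, thresholds_path=None) -> "AffinityMatrix":
        df = pd.read_csv(scores_path, sep="\t", index_col=0)
        if thresholds_path is not None:
            ts = pd.read_csv(thresholds_path, sep="\t")["threshold"].to_numpy(float)
        else:
            ts = np.where(
                (df.values > 0).any(axis=0),
                np.where(df.values > 0, df.values, np.inf).min(axis=0),
                0.0,
            )
        return cls(
            dhs_ids=[str(i) for i in df.index],
            pwm_ids=[str(c) for c in df.columns],
            scores=df.to_numpy(float),
            thresholds=np.asarray(ts, dtype=float),
        )


def build_affinity_matrix(
    pwms: Iterable[ScoringMatrix],
    dhs_sequences: Mapping[str, str],
    top_k: int,
) -> AffinityMatrix:
    """Scan every PWM over every DHS sequence and keep the top-K per PWM.

    A (PWM, DHS) pair where the sequence is shorter than the motif has no
    valid window; its score is absent and therefore below any threshold.
    If fewer than K sites have a score, ts falls back to the minimum score.
    """
    sms = list(pwms)
    if not sms:
        raise EmptyInputError("no scoring matrices supplied")
    if not dhs_sequences:
        raise EmptyInputError("no DHS sequences supplied")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")

    dhs_ids = list(dhs_sequences)
    encoded = [encode_sequence(dhs_sequences[d]) for d in dhs_ids]
    n_dhs, n_pwms = len(dhs_ids), len(sms)
    scores = np.zeros((n_dhs, n_pwms))
    thresholds = np.zeros(n_pwms)

    for j, sm in enumerate(sms):
        col = np.full(n_dhs, -np.inf)
        for m, idx in enumerate(encoded):
            if idx.size < sm.length:
                continue  # no valid window for this pair
            col[m] = scan_max_score(sm, idx, dhs_ids[m])
        present = col[np.isfinite(col)]
        if present.size == 0:
            logger.warning("PWM %s is longer than every DHS sequence", sm.pwm_id)
            thresholds[j] = 0.0
            continue
        if present.size <= top_k:
            ts = float(present.min())
        else:
            ts = float(np.sort(present)[::-1][top_k - 1])
        thresholds[j] = ts
        keep = col >= ts  # -inf never passes; ties at ts retained
        scores[keep, j] = col[keep]

    return AffinityMatrix(
        dhs_ids=dhs_ids, pwm_ids=[sm.pwm_id for sm in sms],
        scores=scores, thresholds=thresholds,
    )


def write_transfac(pwms: Iterable[PWM]) -> str:
    """Serialise PWMs back to the minimal TRANSFAC dialect."""
    blocks = []
    for pwm in pwms:
        lines = [f"AC  {pwm.id}", "XX", f"ID  {pwm.id}", "XX",
                 f"NA  {pwm.factor_name}", "XX"]
        if pwm.description:
            lines += [f"DE  {pwm.description}", "XX"]
        lines.append("P0      A      C      G      T")
        for pos, row in enumerate(pwm.counts, start=1):
            vals = "  ".join(f"{v:7.3f}" for v in row)
            lines.append(f"{pos:02d}  {vals}")
        lines += ["XX", "//"]
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"
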