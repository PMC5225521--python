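"""Position weight matrices: construction, calibration and scanning.

A motif starts life as a weighted position count matrix (WPCM): per-column
base counts x[b,i] with a constant column total W. The log-odds PWM is

    S[b,i] = ln( (x[b,i] + a q_b) / ((W + a) q_b) ),   a = ln W,

with background base frequencies q. Match-score thresholds at a target
tail probability are calibrated exactly: the distribution of the window
score M = sum_i S[b(i), i] over i.i.d. background w-mers is computed by
dynamic programming on a discretized score grid (default 1e-4 natural-log
units), so the threshold is the smallest achievable score whose upper tail
is <= p. Scanning uses the same discretization, which keeps threshold and
scan decisions mutually consistent.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
SCORE_EPS = 1e-4

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class WPCM:
    """Weighted position count matrix: counts[i, b] over columns i, ACGT b."""

    motif_id: str
    counts: np.ndarray  # shape (w, 4)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValueError(f"{self.motif_id}: WPCM must be (w, 4) with w >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative WPCM entries")
        sums = self.counts.sum(axis=1)
        if np.any(np.abs(sums - sums[0]) > 1e-6 * max(sums[0], 1.0)):
            raise ValueError(f"{self.motif_id}: column sums are not constant")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.counts[0].sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass
class PWM:
    """Log-odds matrix derived from a WPCM (natural-log units)."""

    motif_id: str
    scores: np.ndarray  # shape (w, 4)
    background: np.ndarray  # q_b, shape (4,)
    pseudocount: float  # a = ln W

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())

    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.scores[::-1, ::-1].copy(), self.background, self.pseudocount)


def read_wpcm(path: str | Path) -> WPCM:
    """Parse a plain-text count matrix: header line, then w rows of 4 numbers.

    HOCOMOCO-style; a leading '>' on the header is accepted.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    motif_id = lines[0].lstrip(">").split()[0]
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 4:
            raise ValueError(f"{path}: expected 4 columns per row, got {ln!r}")
        rows.append([float(x) for x in parts])
    if not rows:
        raise ValueError(f"{path}: matrix has no count rows")
    return WPCM(motif_id, np.array(rows))


def write_wpcm(wpcm: WPCM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{wpcm.motif_id}\n")
        for row in wpcm.counts:
            fh.write("\t".join(f"{x:g}" for x in row) + "\n")


def bundled_motif_paths() -> list[Path]:
    """Paths of the synthetic position count matrices shipped for testing."""
    from importlib.resources import files

    root = files("chromreg") / "data" / "motifs"
    return sorted(Path(str(root)).glob("*.pcm"))


def estimate_background(sequences: Mapping[str, str] | Iterable[str]) -> np.ndarray:
    """Base frequencies over forward strands, ambiguous bases excluded.

    Uniform fallback for an empty sequence set.
    """
    if isinstance(sequences, Mapping):
        sequences = sequences.values()
    counts = np.zeros(4)
    for seq in sequences:
        for b in seq.upper():
            i = _BASE_INDEX.get(b)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def build_pwm(wpcm: WPCM, background: Sequence[float] | None = None) -> PWM:
    """Log-odds PWM with pseudocount a = ln(W); W must exceed 1."""
    q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if q.shape != (4,) or (q <= 0).any() or abs(q.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 strictly positive frequencies summing to 1")
    W = wpcm.total_weight
    if W <= 1:
        raise ValueError(f"{wpcm.motif_id}: total weight {W} <= 1 gives a non-positive pseudocount")
    a = math.log(W)
    scores = np.log((wpcm.counts + a * q[None, :]) / ((W + a) * q[None, :]))
    return PWM(wpcm.motif_id, scores, q, a)


def _int_scores(pwm: PWM, eps: float) -> np.ndarray:
    return np.rint(pwm.scores / eps).astype(np.int64)


def score_distribution(
    pwm: PWM, background: Sequence[float] | None = None, eps: float = SCORE_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the window score over i.i.d. background w-mers.

    Scores are discretized to multiples of `eps`. Returns (scores, tail)
    with scores ascending (in eps units converted back to floats) and
    tail[k] = P(M >= scores[k]).
    """
    q = pwm.background if background is None else np.asarray(background, dtype=float)
    ints = _int_scores(pwm, eps)
    dist: dict[int, float] = {0: 1.0}
    for i in range(pwm.width):
        nxt: dict[int, float] = {}
        for s, prob in dist.items():
            for b in range(4):
                key = s + int(ints[i, b])
                nxt[key] = nxt.get(key, 0.0) + prob * q[b]
        dist = nxt
    scores = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[s] for s in scores])
    tail = probs[::-1].cumsum()[::-1]
    return scores * eps, tail


def score_threshold(
    pwm: PWM,
    background: Sequence[float] | None = None,
    p: float = 0.001,
    eps: float = SCORE_EPS,
) -> float:
    """Smallest achievable score t with P(M >= t) <= p under the background.

    Returns +inf (with a warning) when even the maximal word is more
    probable than p.
    """
    if not 0 < p <= 1:
        raise ValueError("tail probability p must be in (0, 1]")
    scores, tail = score_distribution(pwm, background, eps)
    ok = tail <= p
    if not ok.any():
        log.warning("%s: no score has tail probability <= %g; threshold is +inf", pwm.motif_id, p)
        return math.inf
    return float(scores[ok.argmax()])


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_INDEX.get(ch, -1)
    return out


def _scan_one_strand(
    codes: np.ndarray, ints: np.ndarray, floats: np.ndarray, t_int: int
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and float scores of windows whose discretized score >= t_int."""
    w = ints.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0)
    valid = np.ones(n, dtype=bool)
    iscore = np.zeros(n, dtype=np.int64)
    fscore = np.zeros(n)
    for i in range(w):
        col = codes[i : i + n]
        bad = col < 0
        valid &= ~bad
        safe = np.where(bad, 0, col)
        iscore += ints[i, safe]
        fscore += floats[i, safe]
    hit = valid & (iscore >= t_int)
    return np.nonzero(hit)[0], fscore[hit]


def scan(
    sequences: Mapping[str, str],
    pwm: PWM,
    threshold: float,
    both_strands: bool = True,
    eps: float = SCORE_EPS,
) -> pd.DataFrame:
    """Report every motif match at or above the calibrated threshold.

    Windows containing an ambiguous base yield no hit. Reverse-strand hits
    (matches of the reverse-complemented motif) are reported in forward
    coordinates. Returns a BED-like frame
    (sequence_id, start, end, motif_id, score, strand).
    """
    t_int = np.int64(np.rint(threshold / eps)) if math.isfinite(threshold) else None
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    rows = []
    if t_int is not None:
        for seq_id, seq in sequences.items():
            codes = _encode(seq)
            for strand, mat in strands:
                ints = _int_scores(mat, eps)
                offs, scores = _scan_one_strand(codes, ints, mat.scores, int(t_int))
                for j, s in zip(offs, scores):
                    rows.append((seq_id, int(j), int(j) + pwm.width, pwm.motif_id, float(s), strand))
    out = pd.DataFrame(
        rows, columns=["sequence_id", "start", "end", "motif_id", "score", "strand"]
    )
    return out.sort_values(["sequence_id", "start", "strand"]).reset_index(drop=True)


def _iupac_regex(pattern: str) -> re.Pattern:
    try:
        body = "".join(
            f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch]
            for ch in pattern.upper()
        )
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol in pattern {pattern!r}") from exc
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def find_consensus(
    sequences: Mapping[str, str], patterns: Sequence[str], both_strands: bool = True
) -> pd.DataFrame:
    """Exact IUPAC-consensus occurrences, both strands, forward coordinates.

    A reverse-strand occurrence of a pattern is a forward-strand match of
    its reverse complement; it is reported at that forward position.
    """
    rows = []
    for pattern in patterns:
        variants = [("+", _iupac_regex(pattern))]
        if both_strands:
            rc = reverse_complement(pattern)
            variants.append(("-", _iupac_regex(rc)))
        for seq_id, seq in sequences.items():
            s = seq.upper()
            for strand, rx in variants:
                for m in rx.finditer(s):
                    rows.append(
                        (seq_id, m.start(), m.start() + len(pattern), pattern, strand)
                    )
    out = pd.DataFrame(rows, columns=["sequence_id", "start", "end", "pattern", "strand"])
    return (
        out.drop_duplicates()
        .sort_values(["pattern", "sequence_id", "start"])
        .reset_index(drop=True)
    )
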