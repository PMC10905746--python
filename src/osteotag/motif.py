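"""PWM scanning and bound-vs-background motif enrichment.

A position weight matrix is scored in log2-odds bits against a background
base composition, with a small pseudocount per cell; a region "contains"
the motif when at least one offset on either strand reaches the score
threshold (by default 80% of the maximum achievable score).  Enrichment of
containment in bound versus background regions is a 2x2 Fisher exact test,
the implemented stand-in for a known-motif enrichment scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cooccupancy import ContingencyTable2x2, fisher_exact_2x2

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities with background and score threshold."""

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.001
    threshold: float | None = None  # None -> 80% of the maximum score

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 5) log2-odds; the 5th column scores N as background (0)."""
        pc = self.pseudocount
        p = (self.probs + pc) / (1 + 4 * pc)
        bg = (self.background + pc) / (1 + 4 * pc)
        lo = np.log2(p / bg)
        return np.column_stack([lo, np.zeros(self.width)])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def score_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return 0.8 * self.max_score

    @classmethod
    def from_consensus(cls, consensus: str, **kwargs) -> "PositionWeightMatrix":
        probs = np.zeros((len(consensus), 4))
        for i, b in enumerate(consensus.upper()):
            probs[i, _CODE[b]] = 1.0
        return cls(probs, **kwargs)

    @classmethod
    def from_text(cls, path, **kwargs) -> "PositionWeightMatrix":
        """Read a plain matrix: one row per position, 4 columns A C G T."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", ">")):
                    continue
                rows.append([float(x) for x in line.split()])
        return cls(np.array(rows), **kwargs)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# A C G T\n")
            for row in self.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


#: Illustrative RUNX-family matrix built from the TGTGGTTT consensus.
#: This is a documented example matrix, not a database motif.
RUNX_EXAMPLE_PWM = PositionWeightMatrix.from_consensus("TGTGGTTT")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)  # default: N
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def _forward_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    for i in range(w):
        scores += lo[i, codes[i : i + n]]
    return scores


def scan(seq: str, pwm: PositionWeightMatrix) -> list[tuple[int, str, float]]:
    """All offsets where the PWM score reaches the threshold, both strands.

    Returns ``(offset, strand, score)`` with offsets on the forward
    coordinate of the region (a reverse-strand hit at offset ``o`` covers
    ``seq[o : o + width]``).  Unknown bases (N) score as background.
    """
    w = pwm.width
    if len(seq) < w:
        return []
    lo = pwm.log_odds
    thr = pwm.score_threshold()
    hits = []
    fwd = _forward_scores(_encode(seq), lo)
    for o in np.flatnonzero(fwd >= thr):
        hits.append((int(o), "+", float(fwd[o])))
    rev = _forward_scores(_encode(reverse_complement(seq)), lo)
    L = len(seq)
    for o in np.flatnonzero(rev >= thr):
        hits.append((int(L - w - o), "-", float(rev[o])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def contains_motif(seq: str, pwm: PositionWeightMatrix) -> bool:
    return len(scan(seq, pwm)) > 0


@dataclass(frozen=True)
class MotifEnrichment:
    fraction_bound: float
    fraction_background: float
    odds_ratio: float
    pvalue: float
    table: ContingencyTable2x2


def motif_enrichment(
    bound_seqs: Sequence[str],
    background_seqs: Sequence[str],
    pwm: PositionWeightMatrix,
) -> MotifEnrichment:
    """Presence/absence motif enrichment in bound vs background regions."""
    if not bound_seqs or not background_seqs:
        raise ValueError("both sequence sets must be nonempty")
    hit_b = sum(contains_motif(s, pwm) for s in bound_seqs)
    hit_g = sum(contains_motif(s, pwm) for s in background_seqs)
    table = ContingencyTable2x2(
        hit_b, len(bound_seqs) - hit_b, hit_g, len(background_seqs) - hit_g
    )
    odds, p = fisher_exact_2x2(table)
    return MotifEnrichment(
        hit_b / len(bound_seqs), hit_g / len(background_seqs), odds, p, table
    )


def read_fasta(path) -> dict[str, str]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as fh:
        return {name.split()[0]: seq for name, seq in SimpleFastaParser(fh)}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
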