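"""PWM scanning, sequence shuffling and empirical threshold calibration.

Score thresholds are not derived from an analytic score distribution.
Instead, each PWM is assigned the most permissive cutoff at which its
randomized occurrence frequency on a shuffled copy of the input set,

    OF_r = fP / (N * L),

stays at or below a target (default 1e-4, i.e. on average one false hit per
10,000 shuffled sequences at each position). Here ``fP`` is the number of
hits in the shuffled set (both strands), ``N`` the number of shuffled
sequences and ``L`` the sequence length minus the PWM length. The cutoff
starts at the PWM's maximum achievable score and is lowered on a grid with
step 0.1 (natural-log score units) until the next step would push OF_r over
the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .motif_io import PWM

__all__ = [
    "SequenceRecord",
    "Hit",
    "CalibrationResult",
    "encode_sequence",
    "decode_sequence",
    "reverse_complement",
    "window_scores",
    "scan_sequence",
    "scan_set",
    "count_hits_in_set",
    "shuffle_sequence",
    "shuffle_set",
    "compute_occurrence_frequency",
    "calibrate_threshold",
    "read_fasta",
    "write_fasta",
    "write_hits_bed",
    "read_hits_bed",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_LETTERS = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass
class SequenceRecord:
    """A promoter or ChIP-region sequence with a declared reference point.

    ``anchor_offset`` is the 0-based position of the reference point (TSS or
    region center) within the sequence.
    """

    seq_id: str
    sequence: str
    anchor_offset: int = 0

    def __post_init__(self):
        if not (0 <= self.anchor_offset <= len(self.sequence)):
            raise ValueError(
                f"{self.seq_id}: anchor_offset {self.anchor_offset} outside "
                f"sequence of length {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Hit:
    """One motif match, reported at its forward-strand start."""

    seq_id: str
    start: int
    strand: str  # '+' or '-'
    score: float
    factor_id: str


@dataclass
class CalibrationResult:
    """Outcome of empirical threshold calibration for one PWM."""

    factor_id: str
    threshold: float
    of_r: float
    fP: int
    N: int
    L: int
    at_floor: bool = False
    at_start: bool = False


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode A,C,G,T,N (case-insensitive) as uint8 codes 0..4."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    if (codes == 255).any():
        bad = sequence[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGTN character in sequence: {bad!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def reverse_complement(sequence: str) -> str:
    return decode_sequence(_COMPLEMENT[encode_sequence(sequence)][::-1])


def _weights_with_n(pwm_weights: np.ndarray) -> np.ndarray:
    """Extend a (L, 4) weight matrix with an N column of -inf.

    Windows overlapping an N run score -inf and can never reach a finite
    threshold, implementing the rule that such windows are discarded.
    """
    L = pwm_weights.shape[0]
    w = np.full((L, 5), -np.inf)
    w[:, :4] = pwm_weights
    return w


def window_scores(codes: np.ndarray, pwm: PWM, strand: str = "+") -> np.ndarray:
    """Scores of every window of the encoded sequence on one strand.

    The reverse-strand score at forward start ``s`` is the forward score of
    the reverse complement of the covered window; it is computed by scanning
    with the reverse-complemented weight matrix, so one pass per strand
    suffices.
    """
    m = pwm.length
    n = codes.shape[0] - m + 1
    if n <= 0:
        return np.empty(0, dtype=float)
    w = pwm.weights
    if strand == "-":
        w = w[::-1, ::-1]
    w5 = _weights_with_n(w)
    scores = np.zeros(n, dtype=float)
    with np.errstate(invalid="ignore"):
        for i in range(m):
            scores += w5[i, codes[i:i + n]]
    return scores


def scan_sequence(rec: SequenceRecord, pwm: PWM, threshold: float | None = None,
                  strands: str = "both") -> list[Hit]:
    """All windows scoring at or above the threshold, sorted by start.

    A PWM longer than the sequence yields an empty list. The threshold
    defaults to the PWM's calibrated threshold.
    """
    if threshold is None:
        threshold = pwm.threshold
    if threshold is None:
        raise ValueError(f"{pwm.factor_id}: no threshold given and PWM is uncalibrated")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    codes = encode_sequence(rec.sequence)
    hits: list[Hit] = []
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for strand in strand_list:
        scores = window_scores(codes, pwm, strand)
        for s in np.flatnonzero(scores >= threshold):
            hits.append(Hit(rec.seq_id, int(s), strand, float(scores[s]),
                            pwm.factor_id))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_set(records: Sequence[SequenceRecord], pwm: PWM,
             threshold: float | None = None, strands: str = "both") -> list[Hit]:
    """Scan every record; concatenated hit lists in record order."""
    out: list[Hit] = []
    for rec in records:
        out.extend(scan_sequence(rec, pwm, threshold, strands))
    return out


def count_hits_in_set(records: Sequence[SequenceRecord], pwm: PWM,
                      threshold: float, strands: str = "both") -> int:
    """Number of windows at or above threshold, without materializing hits."""
    total = 0
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    for rec in records:
        codes = encode_sequence(rec.sequence)
        for strand in strand_list:
            total += int((window_scores(codes, pwm, strand) >= threshold).sum())
    return total


# ---------------------------------------------------------------------------
# Shuffling (null model)


def shuffle_sequence(sequence: str, rng: np.random.Generator, k: int = 1) -> str:
    """Shuffle one sequence preserving k-mer composition (k = 1 or 2).

    ``k=1`` is a plain per-sequence permutation of the letters, preserving
    the relative proportion of each nucleotide. ``k=2`` preserves the
    dinucleotide composition using the Altschul-Erickson Euler-path shuffle.
    """
    if k == 1:
        codes = encode_sequence(sequence)
        return decode_sequence(rng.permutation(codes))
    if k != 2:
        raise ValueError("only k=1 (mononucleotide) and k=2 (dinucleotide) supported")
    codes = encode_sequence(sequence)
    n = codes.shape[0]
    if n < 3:
        return sequence
    # multigraph: vertex = letter, edge i -> codes[i] -> codes[i+1]
    out_edges: dict[int, list[int]] = {}
    for i in range(n - 1):
        out_edges.setdefault(int(codes[i]), []).append(int(codes[i + 1]))
    first, last = int(codes[0]), int(codes[n - 1])
    vertices = sorted(out_edges.keys() | {last})
    for _ in range(10000):
        # pick a random candidate last-edge for every vertex except `last`
        last_edge = {}
        for v in vertices:
            if v == last or not out_edges.get(v):
                continue
            last_edge[v] = out_edges[v][rng.integers(len(out_edges[v]))]
        # the chosen last-edges must form a tree oriented toward `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                if cur not in last_edge:
                    ok = False
                    break
                cur = last_edge[cur]
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to find an Euler path")
    # arrange edge lists: shuffle, then move the designated last edge to the end
    walk_lists: dict[int, list[int]] = {}
    for v, edges in out_edges.items():
        edges = list(edges)
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = [edges[j] for j in rng.permutation(len(edges))]
        if v in last_edge:
            perm.append(last_edge[v])
        walk_lists[v] = perm
    ptr = {v: 0 for v in walk_lists}
    out = [first]
    cur = first
    for _ in range(n - 1):
        nxt = walk_lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return decode_sequence(np.array(out, dtype=np.uint8))


def shuffle_set(records: Sequence[SequenceRecord], seed: int,
                k: int = 1) -> list[SequenceRecord]:
    """Shuffle every record; same number and per-record length as the input."""
    if not records:
        raise ValueError("cannot shuffle an empty sequence set")
    rng = np.random.default_rng(seed)
    return [SequenceRecord(rec.seq_id, shuffle_sequence(rec.sequence, rng, k),
                           rec.anchor_offset)
            for rec in records]


# ---------------------------------------------------------------------------
# Occurrence frequency and calibration


def compute_occurrence_frequency(fP: int, N: int, L: int) -> float:
    """Randomized occurrence frequency OF_r = fP / (N * L)."""
    if L == 0:
        raise ValueError("PWM spans full sequence (L = 0)")
    if N < 1 or L < 1:
        raise ValueError("N and L must be >= 1")
    if fP < 0:
        raise ValueError("fP must be >= 0")
    return fP / (N * L)


def calibrate_threshold(pwm: PWM, shuffled: Sequence[SequenceRecord],
                        target: float = 1e-4, start_cutoff: float | None = None,
                        step: float = 0.1, floor: float = 0.0,
                        strands: str = "both") -> CalibrationResult:
    """Find the most permissive grid cutoff with OF_r at or below the target.

    Starting from ``start_cutoff`` (default: the PWM's maximum achievable
    score) the cutoff is lowered in ``step`` decrements; the returned
    threshold is the smallest grid value whose OF_r <= target such that one
    further decrement would exceed the target (minimality), unless the grid
    floor is reached first (reported via ``at_floor``). If even the starting
    cutoff exceeds the target the start is returned with ``at_start`` set.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    if not shuffled:
        raise ValueError("shuffled sequence set is empty")
    lengths = {len(rec) for rec in shuffled}
    if len(lengths) != 1:
        raise ValueError("calibration requires sequences of uniform length")
    L = lengths.pop() - pwm.length
    if L <= 0:
        raise ValueError("PWM spans full sequence (L <= 0)")
    N = len(shuffled)

    if start_cutoff is None:
        start_cutoff = pwm.max_score
    # score every window once; the grid sweep is then pure counting
    strand_list = ["+"] if strands == "forward" else ["+", "-"]
    chunks = []
    for rec in shuffled:
        codes = encode_sequence(rec.sequence)
        for strand in strand_list:
            s = window_scores(codes, pwm, strand)
            chunks.append(s[np.isfinite(s)])
    scores = np.sort(np.concatenate(chunks))
    del chunks

    def of_at(cutoff: float) -> tuple[int, float]:
        fP = int(scores.size - np.searchsorted(scores, cutoff, side="left"))
        return fP, compute_occurrence_frequency(fP, N, L)

    fP, of_r = of_at(start_cutoff)
    if of_r > target:
        return CalibrationResult(pwm.factor_id, float(start_cutoff), of_r, fP,
                                 N, L, at_start=True)
    k = 0
    best = (float(start_cutoff), fP, of_r)
    while True:
        nxt = start_cutoff - (k + 1) * step
        if nxt < floor:
            return CalibrationResult(pwm.factor_id, best[0], best[2], best[1],
                                     N, L, at_floor=True)
        fP_n, of_n = of_at(nxt)
        if of_n > target:
            return CalibrationResult(pwm.factor_id, best[0], best[2], best[1], N, L)
        k += 1
        best = (float(nxt), fP_n, of_n)


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path: str | Path, tss_at: int | None = None,
               offsets: dict[str, int] | None = None) -> list[SequenceRecord]:
    """Read a FASTA sequence set.

    ``anchor_offset`` comes from the ``offsets`` mapping (seq_id -> position)
    when given, else from the fixed convention ``tss_at`` (e.g. 1000 for
    promoters spanning -1000..+200 around the TSS), else defaults to the
    sequence midpoint (ChIP-region convention).
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if offsets is not None and rec.id in offsets:
            off = offsets[rec.id]
        elif tss_at is not None:
            off = tss_at
        else:
            off = len(seq) // 2
        records.append(SequenceRecord(rec.id, seq, off))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def write_hits_bed(hits: Iterable[Hit], path: str | Path,
                   motif_lengths: dict[str, int]) -> None:
    """BED6-like TSV: seq_id, start, end, factor_id, score, strand (0-based,
    half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            end = h.start + motif_lengths[h.factor_id]
            fh.write(f"{h.seq_id}\t{h.start}\t{end}\t{h.factor_id}\t"
                     f"{h.score:.6g}\t{h.strand}\n")


def read_hits_bed(path: str | Path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seq_id, start, _end, factor_id, score, strand = line.rstrip("\n").split("\t")[:6]
            hits.append(Hit(seq_id, int(start), strand, float(score), factor_id))
    return hits
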