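"""Frequency matrices, background models and position weight matrices.

Transcription factor binding preferences arrive as base frequency tables
(TRANSFAC flat files or JASPAR-style count matrices). Scanning works on
log-odds position weight matrices (PWMs): the weight of base *b* at matrix
column *i* is

    w(b, i) = ln( (c_bi + q * p_b) / ((N_i + q) * p_b) )

where ``c_bi`` is the observed count, ``N_i`` the column total, ``p_b`` the
background probability of *b* and ``q`` a pseudocount (default 1). The
pseudocount is distributed proportionally to the background, which keeps
every weight finite and normalizes the implied foreground model: for every
column, ``sum_b p_b * exp(w(b, i)) == 1``.

PWM score thresholds are not set here; they are calibrated empirically on
shuffled sequences (see :mod:`crmscan.scanner`).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "FrequencyMatrix",
    "BackgroundModel",
    "PWM",
    "MatrixParseError",
    "parse_transfac_matrices",
    "parse_jaspar_matrices",
    "write_transfac",
    "write_matrix_tsv",
    "write_pwm_tsv",
    "read_pwm_tsv",
    "estimate_background",
    "build_pwm",
    "pwm_similarity",
    "reverse_complement_counts",
]


class MatrixParseError(ValueError):
    """A matrix record could not be parsed.

    Carries the accession of the offending record (when known) and the
    1-based line number of the offending line.
    """

    def __init__(self, message: str, accession: str | None = None,
                 line_number: int | None = None):
        self.accession = accession
        self.line_number = line_number
        prefix = []
        if accession:
            prefix.append(f"record {accession}")
        if line_number is not None:
            prefix.append(f"line {line_number}")
        if prefix:
            message = f"{', '.join(prefix)}: {message}"
        super().__init__(message)


@dataclass
class FrequencyMatrix:
    """Per-position nucleotide counts for one transcription factor."""

    factor_id: str
    factor_name: str
    counts: np.ndarray  # shape (L, 4), order A,C,G,T, non-negative
    consensus: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (L, 4)")
        if self.counts.shape[0] < 1:
            raise ValueError("matrix must have at least one position")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.counts.sum(axis=1) > 0).any():
            raise ValueError("at least one column must have a positive total")
        if self.consensus is not None and len(self.consensus) != len(self):
            raise ValueError("consensus length must equal matrix length")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        """Column-normalized frequencies; zero-total columns become uniform."""
        totals = self.counts.sum(axis=1, keepdims=True)
        out = np.where(totals > 0, self.counts / np.where(totals > 0, totals, 1.0), 0.25)
        return out


@dataclass(frozen=True)
class BackgroundModel:
    """Genome/promoter-set background base probabilities (A, C, G, T)."""

    p: tuple[float, float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (4,):
            raise ValueError("background must have four probabilities")
        if (arr < 0).any():
            raise ValueError("background probabilities must be non-negative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


UNIFORM_BACKGROUND = BackgroundModel((0.25, 0.25, 0.25, 0.25))


@dataclass
class PWM:
    """Log-odds position weight matrix with an optional calibrated threshold."""

    factor_id: str
    weights: np.ndarray  # shape (L, 4)
    threshold: float | None = None
    factor_name: str = ""

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must have shape (L, 4)")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable score: sum over positions of column maxima."""
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())


# ---------------------------------------------------------------------------
# Parsing


_POSITION_ROW = re.compile(r"^\s*(\d+)\s+(.*)$")


def parse_transfac_matrices(text: str, on_error: str = "raise"
                            ) -> list[FrequencyMatrix] | tuple[list[FrequencyMatrix], list[MatrixParseError]]:
    """Parse TRANSFAC flat-file matrix records.

    Accepts ``AC``/``ID``/``NA``-tagged records terminated by ``//`` as well
    as bare matrices (numbered position rows with four counts). Unknown tag
    lines are ignored. With ``on_error="collect"`` the return value is a
    ``(matrices, errors)`` pair and malformed records are reported rather
    than silently dropped; with the default ``"raise"`` the first malformed
    record raises :class:`MatrixParseError`.
    """
    if on_error not in ("raise", "collect"):
        raise ValueError("on_error must be 'raise' or 'collect'")
    matrices: list[FrequencyMatrix] = []
    errors: list[MatrixParseError] = []

    acc: str | None = None
    name: str | None = None
    rows: list[list[float]] = []
    consensus_chars: list[str] = []
    record_error: MatrixParseError | None = None
    saw_content = False

    def flush(line_number: int):
        nonlocal acc, name, rows, consensus_chars, record_error, saw_content
        if record_error is not None:
            if on_error == "raise":
                raise record_error
            errors.append(record_error)
        elif rows:
            consensus = "".join(consensus_chars) if len(consensus_chars) == len(rows) else None
            matrices.append(FrequencyMatrix(
                factor_id=acc or f"MATRIX_{len(matrices) + len(errors) + 1}",
                factor_name=name or "",
                counts=np.array(rows, dtype=float),
                consensus=consensus,
            ))
        elif saw_content and acc is not None:
            err = MatrixParseError("record has no position rows", acc, line_number)
            if on_error == "raise":
                raise err
            errors.append(err)
        acc, name, rows, consensus_chars = None, None, [], []
        record_error = None
        saw_content = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.startswith("//"):
            flush(lineno)
            continue
        tag = line[:2]
        if tag == "AC":
            if rows or acc is not None:  # bare record boundary
                flush(lineno)
            acc = line[2:].strip()
            saw_content = True
            continue
        if tag == "NA":
            name = line[2:].strip()
            saw_content = True
            continue
        if tag == "ID":
            if name is None:
                name = line[2:].strip()
            saw_content = True
            continue
        if tag == "P0" or tag == "PO":
            saw_content = True
            continue
        m = _POSITION_ROW.match(line)
        if m:
            saw_content = True
            if record_error is not None:
                continue
            fields = m.group(2).split()
            values = fields[:4]
            if len(values) < 4:
                record_error = MatrixParseError(
                    f"position row has {len(values)} count columns, expected 4",
                    acc, lineno)
                continue
            try:
                counts = [float(v) for v in values]
            except ValueError:
                record_error = MatrixParseError(
                    f"non-numeric count in position row: {line!r}", acc, lineno)
                continue
            if any(c < 0 for c in counts):
                record_error = MatrixParseError(
                    f"negative count in position row: {line!r}", acc, lineno)
                continue
            rows.append(counts)
            if len(fields) >= 5 and len(fields[4]) == 1 and fields[4].isalpha():
                consensus_chars.append(fields[4])
            continue
        # unknown tag line: ignored
        if re.match(r"^[A-Z0-9]{2}\s", line) or line[:2].isalpha():
            saw_content = True
            continue
    flush(len(text.splitlines()))

    if on_error == "collect":
        return matrices, errors
    return matrices


def parse_jaspar_matrices(text: str) -> list[FrequencyMatrix]:
    """Parse a JASPAR-style count matrix file.

    Records start with a ``>id name`` header followed by four rows, one per
    base in A/C/G/T order, e.g. ``A [ 3 10 2 ]`` or bare ``3 10 2``.
    """
    matrices: list[FrequencyMatrix] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush(lineno: int):
        nonlocal header, rows, order
        if header is None:
            return
        if set(rows) != set(BASES):
            raise MatrixParseError(
                f"expected 4 base rows, got {sorted(rows)}", header[0], lineno)
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise MatrixParseError("base rows have unequal lengths", header[0], lineno)
        counts = np.column_stack([rows[b] for b in BASES])
        matrices.append(FrequencyMatrix(header[0], header[1], counts))
        header, rows, order = None, {}, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(lineno)
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1].strip() if len(parts) > 1 else "")
            continue
        if header is None:
            raise MatrixParseError("count row before any '>' header",
                                   line_number=lineno)
        m = re.match(r"^([ACGT])\s*\[?\s*([-\d.\s]+?)\s*\]?$", line)
        if m:
            base, body = m.group(1), m.group(2)
        else:
            base = BASES[len(order)] if len(order) < 4 else "?"
            body = line.strip("[] ")
        if base not in _BASE_INDEX:
            raise MatrixParseError(f"unexpected row: {raw!r}", header[0], lineno)
        try:
            values = [float(v) for v in body.split()]
        except ValueError:
            raise MatrixParseError(f"non-numeric count in row: {raw!r}",
                                   header[0], lineno) from None
        if any(v < 0 for v in values):
            raise MatrixParseError(f"negative count in row: {raw!r}",
                                   header[0], lineno)
        rows[base] = values
        order.append(base)
    flush(len(text.splitlines()))
    return matrices


# ---------------------------------------------------------------------------
# Serialization


def write_transfac(matrices: Iterable[FrequencyMatrix]) -> str:
    """Serialize matrices to the TRANSFAC flat format (round-trip safe)."""
    out = io.StringIO()
    for m in matrices:
        out.write(f"AC  {m.factor_id}\nXX\nNA  {m.factor_name}\nXX\n")
        out.write("P0      A      C      G      T\n")
        for i, row in enumerate(m.counts, start=1):
            cells = "  ".join(f"{v:g}" for v in row)
            cons = f"  {m.consensus[i - 1]}" if m.consensus else ""
            out.write(f"{i:02d}  {cells}{cons}\n")
        out.write("XX\n//\n")
    return out.getvalue()


def write_matrix_tsv(m: FrequencyMatrix) -> str:
    lines = [f"# factor_id={m.factor_id}\tfactor_name={m.factor_name}",
             "pos\tA\tC\tG\tT"]
    for i, row in enumerate(m.counts, start=1):
        lines.append(f"{i}\t" + "\t".join(f"{v:g}" for v in row))
    return "\n".join(lines) + "\n"


def write_pwm_tsv(pwm: PWM) -> str:
    thr = "" if pwm.threshold is None else f"\tthreshold={pwm.threshold:.10g}"
    lines = [f"# factor_id={pwm.factor_id}{thr}", "pos\tA\tC\tG\tT"]
    for i, row in enumerate(pwm.weights, start=1):
        lines.append(f"{i}\t" + "\t".join(f"{v:.10g}" for v in row))
    return "\n".join(lines) + "\n"


def read_pwm_tsv(text: str) -> PWM:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#"):
        raise MatrixParseError("PWM TSV must start with a '# factor_id=' header")
    header = dict(kv.split("=", 1) for kv in lines[0][1:].split("\t") if "=" in kv)
    factor_id = header.get("factor_id", header.get(" factor_id", "")).strip()
    threshold = float(header["threshold"]) if "threshold" in header else None
    rows = []
    for ln in lines[2:]:
        rows.append([float(v) for v in ln.split("\t")[1:5]])
    return PWM(factor_id=factor_id, weights=np.array(rows), threshold=threshold)


# ---------------------------------------------------------------------------
# Background and PWM construction


def estimate_background(sequences: Iterable[str], pseudocount: float = 1.0
                        ) -> BackgroundModel:
    """Estimate background base probabilities from a sequence set.

    N characters are excluded from counting. ``p_b = (n_b + q) / (n + 4q)``
    with pseudocount ``q`` (default 1).
    """
    counts = np.zeros(4, dtype=float)
    total = 0
    for seq in sequences:
        s = seq.upper()
        for i, b in enumerate(BASES):
            c = s.count(b)
            counts[i] += c
            total += c
        bad = len(s) - s.count("N") - sum(s.count(b) for b in BASES)
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {seq[:30]!r}...")
    if total == 0 and pseudocount == 0:
        raise ValueError("no countable bases")
    if total == 0:
        raise ValueError("no countable bases (all-N input)")
    p = (counts + pseudocount) / (total + 4 * pseudocount)
    return BackgroundModel(tuple(p))


def build_pwm(m: FrequencyMatrix, bg: BackgroundModel = UNIFORM_BACKGROUND,
              pseudocount: float = 1.0) -> PWM:
    """Build a log-odds PWM from a frequency matrix.

    ``w(b, i) = ln((c_bi + q p_b) / ((N_i + q) p_b))`` with pseudocount
    ``q > 0`` shared across the column proportionally to the background.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if (bg.as_array() <= 0).any():
        raise ValueError("PWM construction requires strictly positive background")
    totals = m.counts.sum(axis=1, keepdims=True)
    if pseudocount == 0:
        if (totals == 0).any() or (m.counts == 0).any():
            raise ValueError("pseudocount 0 requires strictly positive counts")
    p = bg.as_array()[None, :]
    weights = np.log((m.counts + pseudocount * p) / ((totals + pseudocount) * p))
    return PWM(factor_id=m.factor_id, weights=weights, factor_name=m.factor_name)


# ---------------------------------------------------------------------------
# Matrix similarity (redundancy filtering)


def reverse_complement_counts(counts: np.ndarray) -> np.ndarray:
    """Reverse-complement a count matrix: reverse columns, swap A<->T, C<->G."""
    return counts[::-1, ::-1]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        # degenerate (constant) profile: identical => perfectly similar
        return 1.0 if np.allclose(x, y) else 0.0
    return float((xc * yc).sum() / (sx * sy))


def pwm_similarity(a: FrequencyMatrix, b: FrequencyMatrix,
                   min_overlap: int = 5) -> float:
    """Maximum Pearson correlation between column-normalized frequencies.

    The maximum is taken over all ungapped alignment offsets of *b* (and of
    the reverse complement of *b*) against *a*, requiring an overlap of at
    least ``min_overlap`` columns. Used to drop partner matrices redundant
    with the anchor (e.g. E-box-like matrices vs a MyoD anchor).
    """
    fa = a.frequencies()
    best = -1.0
    found = False
    for fb in (b.frequencies(), reverse_complement_counts(b.frequencies())):
        la, lb = fa.shape[0], fb.shape[0]
        for offset in range(-(lb - 1), la):
            lo_a, hi_a = max(0, offset), min(la, offset + lb)
            k = hi_a - lo_a
            if k < min_overlap:
                continue
            found = True
            sub_a = fa[lo_a:hi_a].ravel()
            sub_b = fb[lo_a - offset:hi_a - offset].ravel()
            r = _pearson(sub_a, sub_b)
            if r > best:
                best = r
    if not found:
        raise ValueError("matrices too short to compare "
                         f"(need >= {min_overlap} overlapping columns)")
    return min(1.0, max(-1.0, best))
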