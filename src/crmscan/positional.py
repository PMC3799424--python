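"""Anchor-centered positional distributions and their significance.

The central objects are *anchor profiles*: for a chosen anchor factor
(MyoD-style) and one partner factor, the number of promoters in which at
least one anchor-partner hit pair realizes each start-to-start offset
``d = partner.start - anchor.start`` within a symmetric window (default
+/-100 bp). Offsets are taken in promoter coordinates with strands
aggregated, so reverse-strand matches produce the familiar symmetric
+/-k signatures.

Two tests compare an observed profile against the profile built by the
identical procedure on a shuffled copy of the sequence set:

* co-occurrence: is the fraction of anchor-containing promoters that also
  carry the partner anywhere within the window higher than on the shuffled
  set? A binomial-proportion z-score with the shuffled-set rate as the null
  rate; factors with z > 3 are retained.
* positional preference: per offset, the same z-score plus a one-sided
  exact binomial p-value (over-representation alternative). An offset is a
  preferred location when z >= 10 and p < 0.005.

Counting is promoter-level throughout: a promoter contributes at most once
per offset and once to the co-occurrence count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .scanner import Hit, SequenceRecord, encode_sequence

__all__ = [
    "AnchorProfile",
    "CooccurrenceResult",
    "PositionCall",
    "build_anchor_profile",
    "cooccurrence_test",
    "positional_preference_test",
    "window_sweep",
    "classify_cpg",
    "exact_binomial_pvalue",
]


@dataclass
class AnchorProfile:
    """Promoter counts of a partner factor at each offset from the anchor."""

    anchor_id: str
    partner_id: str
    window: int
    counts: np.ndarray  # length 2*window + 1, index d + window
    n_anchor_promoters: int
    n_cooccur: int
    smoothed: np.ndarray | None = None  # running mean of 3, reporting only

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2 * self.window + 1,):
            raise ValueError("counts must cover exactly 2W+1 offsets")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    def count_at(self, d: int) -> float:
        if abs(d) > self.window:
            raise KeyError(f"offset {d} outside +/-{self.window} window")
        return float(self.counts[d + self.window])


@dataclass
class CooccurrenceResult:
    partner_id: str
    observed: int
    background_fraction: float
    z: float
    retained: bool  # z > 3


@dataclass
class PositionCall:
    partner_id: str
    offset: int
    observed: float
    expected: float
    z: float
    p: float
    significant: bool  # z >= z_min and p < p_max
    background_zero: bool = False


def _group_starts(hits: Iterable[Hit]) -> dict[str, list[int]]:
    by_seq: dict[str, list[int]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h.start)
    return by_seq


def _pair_offsets_by_promoter(anchor_hits: Iterable[Hit],
                              partner_hits: Iterable[Hit]
                              ) -> tuple[int, dict[str, np.ndarray]]:
    """Unique pair offsets per promoter, plus the anchor-promoter count."""
    anchors = _group_starts(anchor_hits)
    partners = _group_starts(partner_hits)
    offsets: dict[str, np.ndarray] = {}
    for seq_id, a_starts in anchors.items():
        p_starts = partners.get(seq_id)
        if not p_starts:
            continue
        a = np.asarray(a_starts)[:, None]
        p = np.asarray(p_starts)[None, :]
        offsets[seq_id] = np.unique(p - a)
    return len(anchors), offsets


def build_anchor_profile(anchor_hits: Iterable[Hit],
                         partner_hits: Iterable[Hit],
                         window: int = 100,
                         smooth: str | None = None,
                         anchor_id: str | None = None,
                         partner_id: str | None = None) -> AnchorProfile:
    """Build the per-offset promoter-count profile of a partner factor.

    ``smooth="running_mean_3"`` attaches a running average of 3 as a
    reporting copy; the tested counts are never smoothed.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    anchor_hits = list(anchor_hits)
    partner_hits = list(partner_hits)
    if anchor_id is None:
        anchor_id = anchor_hits[0].factor_id if anchor_hits else ""
    if partner_id is None:
        partner_id = partner_hits[0].factor_id if partner_hits else ""
    n_anchor, per_promoter = _pair_offsets_by_promoter(anchor_hits, partner_hits)
    counts = np.zeros(2 * window + 1, dtype=float)
    n_cooccur = 0
    for ds in per_promoter.values():
        in_win = ds[np.abs(ds) <= window]
        if in_win.size:
            counts[in_win + window] += 1
            n_cooccur += 1
    smoothed = None
    if smooth == "running_mean_3":
        kernel = np.ones(3) / 3.0
        smoothed = np.convolve(counts, kernel, mode="same")
    elif smooth not in (None, "none"):
        raise ValueError(f"unknown smoothing mode: {smooth!r}")
    return AnchorProfile(anchor_id, partner_id, window, counts,
                         n_anchor, n_cooccur, smoothed)


def _binomial_z(observed: float, n: int, p_hat: float) -> tuple[float, float]:
    """Binomial-proportion z against a fixed null rate; returns (z, expected)."""
    expected = n * p_hat
    sd = np.sqrt(n * p_hat * (1.0 - p_hat))
    z = (observed - expected) / sd if sd > 0 else np.nan
    return float(z), float(expected)


def cooccurrence_test(observed_profile: AnchorProfile,
                      background_profile: AnchorProfile,
                      z_min: float = 3.0,
                      continuity: bool = False) -> CooccurrenceResult:
    """Test whether the partner co-occurs with the anchor above chance.

    The null rate is the co-occurrence fraction among anchor-containing
    promoters of the shuffled set. A degenerate background (no anchor
    promoters, or a rate of exactly 0 or 1) raises unless ``continuity``
    applies a 0.5 pseudocount to the background count.
    """
    _check_compatible(observed_profile, background_profile)
    n_bg = background_profile.n_anchor_promoters
    if n_bg == 0:
        raise ValueError("degenerate background: no anchor-containing promoters")
    p_hat = background_profile.n_cooccur / n_bg
    if p_hat in (0.0, 1.0):
        if not continuity:
            raise ValueError(
                f"degenerate background co-occurrence rate {p_hat}; "
                "pass continuity=True to apply a 0.5 pseudocount")
        p_hat = 0.5 / n_bg if p_hat == 0.0 else (n_bg - 0.5) / n_bg
    n = observed_profile.n_anchor_promoters
    if n == 0:
        return CooccurrenceResult(observed_profile.partner_id, 0,
                                  p_hat, 0.0, False)
    z, _ = _binomial_z(observed_profile.n_cooccur, n, p_hat)
    return CooccurrenceResult(observed_profile.partner_id,
                              observed_profile.n_cooccur, p_hat, z, z > z_min)


def exact_binomial_pvalue(k: int, n: int, p: float) -> float:
    """One-sided (greater) exact binomial p-value, P(X >= k | n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def positional_preference_test(observed_profile: AnchorProfile,
                               background_profile: AnchorProfile,
                               z_min: float = 10.0,
                               p_max: float = 0.005) -> list[PositionCall]:
    """Per-offset preferred-location calls against the shuffled background.

    For each offset d: null rate p_d = background count / background anchor
    promoters; z_d is the binomial-proportion z and p_d the one-sided exact
    binomial upper tail for the observed promoter count among n observed
    anchor promoters. Offsets observed above a zero background are evaluated
    with the pseudocounted rate 0.5/background_n and flagged.
    """
    _check_compatible(observed_profile, background_profile)
    n_bg = background_profile.n_anchor_promoters
    if n_bg == 0:
        raise ValueError("degenerate background: no anchor-containing promoters")
    n = observed_profile.n_anchor_promoters
    calls: list[PositionCall] = []
    W = observed_profile.window
    for idx, d in enumerate(range(-W, W + 1)):
        k = observed_profile.counts[idx]
        p_hat = background_profile.counts[idx] / n_bg
        background_zero = False
        if p_hat == 0.0:
            if k > 0:
                p_hat = 0.5 / n_bg
                background_zero = True
            else:
                calls.append(PositionCall(observed_profile.partner_id, d,
                                          0.0, 0.0, 0.0, 1.0, False))
                continue
        if p_hat >= 1.0:
            p_hat = (n_bg - 0.5) / n_bg
        z, expected = _binomial_z(k, n, p_hat)
        p = exact_binomial_pvalue(int(k), n, p_hat)
        significant = bool(z >= z_min and p < p_max)
        calls.append(PositionCall(observed_profile.partner_id, d, float(k),
                                  expected, z, p, significant, background_zero))
    return calls


def _check_compatible(a: AnchorProfile, b: AnchorProfile) -> None:
    if a.window != b.window:
        raise ValueError("profiles have different windows")
    if a.anchor_id != b.anchor_id or a.partner_id != b.partner_id:
        raise ValueError("profiles compare different factor pairs")


def window_sweep(anchor_hits: Iterable[Hit], partner_hits: Iterable[Hit],
                 windows: Sequence[int] = (100, 200, 500, 1000),
                 halfwidth: bool = False) -> dict[int, int]:
    """Co-occurring promoter counts across nested windows.

    By default each window value is a *total* width centered on the anchor
    (half-width = window // 2), matching the window-sweep convention; with
    ``halfwidth=True`` the values are half-widths (+/-W), matching the main
    +/-100 bp analysis.
    """
    if list(windows) != sorted(windows):
        raise ValueError("windows must be sorted ascending")
    _, per_promoter = _pair_offsets_by_promoter(anchor_hits, partner_hits)
    min_abs = np.array([np.abs(ds).min() for ds in per_promoter.values()]
                       if per_promoter else [], dtype=float)
    out = {}
    for w in windows:
        half = w if halfwidth else w // 2
        out[int(w)] = int((min_abs <= half).sum())
    return out


def classify_cpg(rec: SequenceRecord | str, window: int = 200,
                 gc_min: float = 0.5, oe_min: float = 0.6) -> str:
    """Classify a promoter as CpG island containing ("CpG+") or not ("CpG-").

    A promoter is CpG+ when some sliding window (default 200 bp) has GC
    fraction >= 0.5 and observed/expected CpG >= 0.6, where
    obs/exp = (#CG dinucleotides * window) / (#C * #G) - the classical
    Gardiner-Garden and Frommer criteria. Windows containing N are skipped;
    sequences shorter than one window are CpG-.
    """
    seq = rec.sequence if isinstance(rec, SequenceRecord) else rec
    if len(seq) < window:
        return "CpG-"
    codes = encode_sequence(seq)
    is_c = (codes == 1).astype(np.int64)
    is_g = (codes == 2).astype(np.int64)
    is_n = (codes == 4).astype(np.int64)
    cg = (is_c[:-1] & is_g[1:]).astype(np.int64)

    def window_sums(x: np.ndarray, w: int) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[w:] - c[:-w]

    n_in = window_sums(is_n, window)
    c_in = window_sums(is_c, window)
    g_in = window_sums(is_g, window)
    # CG dinucleotide starts fully inside the window: positions i..i+w-2
    cg_in = window_sums(cg, window - 1)[: len(n_in)]
    valid = n_in == 0
    gc_frac = (c_in + g_in) / window
    denom = c_in * g_in
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, cg_in * window / np.where(denom > 0, denom, 1), 0.0)
    if bool(np.any(valid & (gc_frac >= gc_min) & (oe >= oe_min))):
        return "CpG+"
    return "CpG-"
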