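"""ChIP-region analyses: center-constrained anchors, condition comparison,
and bound/unbound enrichment ranking.

In ChIP-derived regions the immunoprecipitated factor is expected to sit
near the region center, so anchor motif matches are only trusted within a
band around it (default +/-20 bp); partner hits stay unconstrained.

Two comparative statistics are provided:

* condition comparison (myoblast vs myotube style): a pooled two-proportion
  z-score of the partner's co-occurrence rate in condition A vs B, positive
  when A exceeds B.
* bound/unbound enrichment: the ratio of co-occurring promoter counts in
  anchor-bound vs unbound region sets (pseudocounted), together with a
  binomial z treating the unbound rate as the null. Factors are ranked
  under both scoring schemes (rank 1 = strongest) and kept when the two
  ranks are high and congruent (both <= top, |rank difference| <= 10).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .positional import AnchorProfile, _binomial_z
from .scanner import Hit, SequenceRecord

__all__ = [
    "RegionSet",
    "ConditionComparison",
    "EnrichmentResult",
    "select_center_anchor_hits",
    "compare_conditions",
    "compute_enrichment",
    "enrichment_z",
    "rank_and_select",
]


@dataclass
class RegionSet:
    """A labelled set of regions with anchor_offset at the region center."""

    label: str
    records: list[SequenceRecord]

    def __len__(self) -> int:
        return len(self.records)

    def centers(self) -> dict[str, int]:
        return {rec.seq_id: rec.anchor_offset for rec in self.records}


@dataclass
class ConditionComparison:
    factor_id: str
    count_a: int
    n_a: int
    count_b: int
    n_b: int
    z: float
    degenerate: bool = False

    def __post_init__(self):
        if not (0 <= self.count_a <= self.n_a and 0 <= self.count_b <= self.n_b):
            raise ValueError("counts must lie within their totals")


@dataclass
class EnrichmentResult:
    factor_id: str
    bound_count: int
    unbound_count: int
    enrichment: float
    z: float
    rank_enrichment: int = 0
    rank_z: int = 0
    selected: bool = False


def select_center_anchor_hits(hits: Iterable[Hit], regions: RegionSet,
                              band: int = 20) -> list[Hit]:
    """Keep anchor hits whose start lies within [center - band, center + band].

    Idempotent and never enlarges the hit set. Hits on regions absent from
    the set are dropped (their center is unknown).
    """
    centers = regions.centers()
    out = []
    for h in hits:
        center = centers.get(h.seq_id)
        if center is not None and abs(h.start - center) <= band:
            out.append(h)
    return out


def compare_conditions(a: AnchorProfile | tuple[int, int],
                       b: AnchorProfile | tuple[int, int],
                       factor_id: str | None = None) -> ConditionComparison:
    """Pooled two-proportion z of co-occurrence in condition A vs B.

    Accepts anchor-profile summaries or raw ``(count, n)`` pairs. With a
    pooled rate of exactly 0 or 1 the z-score is 0 by convention and the
    result is flagged degenerate.
    """
    count_a, n_a = _summary(a)
    count_b, n_b = _summary(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both conditions need at least one anchor promoter")
    if factor_id is None:
        factor_id = a.partner_id if isinstance(a, AnchorProfile) else ""
    pooled = (count_a + count_b) / (n_a + n_b)
    if pooled in (0.0, 1.0):
        return ConditionComparison(factor_id, count_a, n_a, count_b, n_b,
                                   0.0, degenerate=True)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b))
    z = (count_a / n_a - count_b / n_b) / se
    return ConditionComparison(factor_id, count_a, n_a, count_b, n_b, float(z))


def _summary(x: AnchorProfile | tuple[int, int]) -> tuple[int, int]:
    if isinstance(x, AnchorProfile):
        return x.n_cooccur, x.n_anchor_promoters
    count, n = x
    return int(count), int(n)


def compute_enrichment(bound_count: int, unbound_count: int,
                       pseudocount: float = 1.0) -> float:
    """Bound/unbound co-occurring promoter-count ratio, pseudocounted."""
    if bound_count < 0 or unbound_count < 0:
        raise ValueError("counts must be non-negative")
    if pseudocount == 0 and unbound_count == 0:
        raise ValueError("unbound count 0 requires a positive pseudocount")
    return (bound_count + pseudocount) / (unbound_count + pseudocount)


def enrichment_z(bound_count: int, n_bound: int, unbound_count: int,
                 n_unbound: int) -> float:
    """Binomial z of the bound co-occurrence count with the unbound rate as null.

    The unbound co-occurrence rate plays the role of the shuffled-set rate in
    the promoter co-occurrence test; a zero or saturated unbound rate is
    continuity-corrected with a 0.5 pseudocount.
    """
    if n_unbound < 1 or n_bound < 1:
        raise ValueError("region sets must be non-empty")
    p_hat = unbound_count / n_unbound
    if p_hat == 0.0:
        p_hat = 0.5 / n_unbound
    elif p_hat >= 1.0:
        p_hat = (n_unbound - 0.5) / n_unbound
    z, _ = _binomial_z(bound_count, n_bound, p_hat)
    return z


def rank_and_select(results: Sequence[EnrichmentResult], top: int = 100,
                    max_rank_diff: int = 10) -> list[EnrichmentResult]:
    """Rank factors under both scoring schemes and apply the congruence rule.

    Rank 1 is the strongest signal under each scheme (highest enrichment,
    highest z); ties break lexicographically by factor_id. A factor is
    selected when both ranks are <= ``top`` and the ranks differ by at most
    ``max_rank_diff``. The output is sorted by enrichment rank.
    """
    if not results:
        return []
    by_enrichment = sorted(results, key=lambda r: (-r.enrichment, r.factor_id))
    by_z = sorted(results, key=lambda r: (-r.z, r.factor_id))
    rank_e = {r.factor_id: i + 1 for i, r in enumerate(by_enrichment)}
    rank_z = {r.factor_id: i + 1 for i, r in enumerate(by_z)}
    out = []
    for r in results:
        re_, rz = rank_e[r.factor_id], rank_z[r.factor_id]
        selected = re_ <= top and rz <= top and abs(re_ - rz) <= max_rank_diff
        out.append(replace(r, rank_enrichment=re_, rank_z=rz, selected=selected))
    out.sort(key=lambda r: r.rank_enrichment)
    return out
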