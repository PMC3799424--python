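"""Full-pipeline orchestration: calibrate -> scan -> co-occur -> enrich.

The stages mirror the discovery protocol: frequency tables become PWMs, each
PWM gets an empirically calibrated threshold on a shuffled copy of the
input set, PWMs are mapped to both the observed and the shuffled sequences,
partners redundant with the anchor are removed, co-occurring factors are
retained at z > 3, and preferred positions are called at z >= 10 with exact
binomial p < 0.005. Optional region sets add the bound/unbound enrichment
ranking and a two-condition comparison.

Outputs are plain TSV tables plus a JSON run manifest (seed, parameters,
input digests, stage counts). Given one seed, two runs produce byte-identical
outputs; nothing time- or host-dependent is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chip_analysis, motif_io, positional, scanner

logger = logging.getLogger("crmscan")

__all__ = ["PipelineConfig", "run_pipeline", "write_calibration_tsv",
           "read_calibration_tsv", "cooccurrence_count", "PairDiscovery",
           "discover_pair"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Parameter defaults are the protocol's reference values: OF_r target
    1e-4, grid step 0.1, +/-100 bp window, co-occurrence gate z > 3,
    positional gate z >= 10 and p < 0.005, ChIP center band +/-20 bp,
    anchor-similarity cutoff 0.80, congruent-rank selection with top 100
    and max rank difference 10.
    """

    matrices: str
    fasta: str
    anchor: str
    tss_at: int | None = None
    bound_fasta: str | None = None
    unbound_fasta: str | None = None
    condition_a_fasta: str | None = None
    condition_b_fasta: str | None = None
    of_target: float = 1e-4
    step: float = 0.1
    window: int = 100
    z_cooccur: float = 3.0
    z_position: float = 10.0
    p_position: float = 0.005
    center_band: int = 20
    similarity_cutoff: float = 0.80
    top_rank: int = 100
    max_rank_diff: int = 10
    strands: str = "both"
    shuffle_k: int = 1
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("of_target", "step", "z_cooccur", "z_position",
                     "p_position", "similarity_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window < 0:
            raise ValueError("window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_calibration_tsv(results: Sequence[scanner.CalibrationResult],
                          path: str | Path) -> None:
    df = pd.DataFrame([{
        "factor_id": r.factor_id, "threshold": r.threshold, "of_r": r.of_r,
        "fP": r.fP, "N": r.N, "L": r.L, "at_floor": r.at_floor,
        "at_start": r.at_start,
    } for r in results])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_calibration_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["factor_id"], df["threshold"]))


def cooccurrence_count(anchor_hits, partner_hits, window: int) -> tuple[int, int]:
    """(promoters with >=1 pair within +/-window, promoters with >=1 anchor)."""
    profile = positional.build_anchor_profile(anchor_hits, partner_hits, window)
    return profile.n_cooccur, profile.n_anchor_promoters


@dataclass
class PairDiscovery:
    """In-memory result of the core anchor/partner discovery path."""

    anchor_calibration: scanner.CalibrationResult
    partner_calibration: scanner.CalibrationResult
    observed: positional.AnchorProfile
    background: positional.AnchorProfile
    cooccurrence: positional.CooccurrenceResult
    position_calls: list[positional.PositionCall]


def discover_pair(records: Sequence[scanner.SequenceRecord],
                  anchor: motif_io.FrequencyMatrix,
                  partner: motif_io.FrequencyMatrix,
                  seed: int,
                  window: int = 100,
                  of_target: float = 1e-4,
                  step: float = 0.1,
                  z_cooccur: float = 3.0,
                  z_position: float = 10.0,
                  p_position: float = 0.005,
                  strands: str = "both",
                  shuffle_k: int = 1) -> PairDiscovery:
    """Run the core discovery path for one anchor/partner pair in memory.

    Shuffles the set, calibrates both PWMs on the shuffled copy, scans both
    sets, builds the anchor-centered profiles and computes the co-occurrence
    and positional-preference statistics (with the continuity pseudocount on
    degenerate backgrounds).
    """
    bg = motif_io.estimate_background([r.sequence for r in records])
    anchor_pwm = motif_io.build_pwm(anchor, bg)
    partner_pwm = motif_io.build_pwm(partner, bg)
    shuffled = scanner.shuffle_set(records, seed, k=shuffle_k)
    cal_a = scanner.calibrate_threshold(anchor_pwm, shuffled, target=of_target,
                                        step=step, strands=strands)
    cal_p = scanner.calibrate_threshold(partner_pwm, shuffled, target=of_target,
                                        step=step, strands=strands)
    obs = positional.build_anchor_profile(
        scanner.scan_set(records, anchor_pwm, cal_a.threshold, strands),
        scanner.scan_set(records, partner_pwm, cal_p.threshold, strands),
        window, anchor_id=anchor.factor_id, partner_id=partner.factor_id)
    ref = positional.build_anchor_profile(
        scanner.scan_set(shuffled, anchor_pwm, cal_a.threshold, strands),
        scanner.scan_set(shuffled, partner_pwm, cal_p.threshold, strands),
        window, anchor_id=anchor.factor_id, partner_id=partner.factor_id)
    cooccur = positional.cooccurrence_test(obs, ref, z_cooccur, continuity=True)
    calls = positional.positional_preference_test(obs, ref, z_position,
                                                  p_position)
    return PairDiscovery(cal_a, cal_p, obs, ref, cooccur, calls)


def _scan_all(records, pwms: dict[str, motif_io.PWM], thresholds: dict[str, float],
              strands: str) -> dict[str, list[scanner.Hit]]:
    return {fid: scanner.scan_set(records, pwm, thresholds[fid], strands)
            for fid, pwm in pwms.items()}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "inputs": {}, "stages": {}}

    def stage(name: str, **info):
        manifest["stages"][name] = info
        logger.info("stage %-12s %s", name,
                    " ".join(f"{k}={v}" for k, v in info.items()))

    # 1. matrices
    text = Path(config.matrices).read_text()
    manifest["inputs"]["matrices"] = _sha256(config.matrices)
    matrices, errors = motif_io.parse_transfac_matrices(text, on_error="collect")
    if config.anchor not in {m.factor_id for m in matrices}:
        raise ValueError(f"stage parse: anchor matrix {config.anchor!r} "
                         "not found in matrix file")
    stage("parse", matrices=len(matrices), errors=len(errors))

    # 2. sequences
    records = scanner.read_fasta(config.fasta, tss_at=config.tss_at)
    manifest["inputs"]["fasta"] = _sha256(config.fasta)
    if not records:
        raise ValueError("stage read: empty sequence set")
    stage("read", sequences=len(records))

    # 3. background + PWMs
    bg = motif_io.estimate_background([r.sequence for r in records])
    pwms = {m.factor_id: motif_io.build_pwm(m, bg, config.pseudocount)
            for m in matrices}
    manifest["background"] = [round(p, 8) for p in bg.p]
    stage("pwm", pwms=len(pwms))

    # 4. shuffle + calibrate
    shuffled = scanner.shuffle_set(records, config.seed, k=config.shuffle_k)
    calib = [scanner.calibrate_threshold(pwms[fid], shuffled,
                                         target=config.of_target,
                                         step=config.step,
                                         strands=config.strands)
             for fid in sorted(pwms)]
    thresholds = {c.factor_id: c.threshold for c in calib}
    write_calibration_tsv(calib, out / "calibration.tsv")
    stage("calibrate", factors=len(calib),
          at_floor=sum(c.at_floor for c in calib))

    # 5. scan observed and shuffled sets
    obs_hits = _scan_all(records, pwms, thresholds, config.strands)
    bg_hits = _scan_all(shuffled, pwms, thresholds, config.strands)
    motif_lengths = {fid: pwm.length for fid, pwm in pwms.items()}
    scanner.write_hits_bed(
        [h for fid in sorted(obs_hits) for h in obs_hits[fid]],
        out / "hits.bed", motif_lengths)
    stage("scan", hits=sum(len(v) for v in obs_hits.values()),
          shuffled_hits=sum(len(v) for v in bg_hits.values()))

    # 6. redundancy filter against the anchor
    anchor_matrix = next(m for m in matrices if m.factor_id == config.anchor)
    partners, removed = [], []
    for m in matrices:
        if m.factor_id == config.anchor:
            continue
        sim = motif_io.pwm_similarity(anchor_matrix, m)
        (removed if sim > config.similarity_cutoff else partners).append(
            (m.factor_id, sim))
    manifest["redundant_with_anchor"] = [fid for fid, _ in removed]
    stage("similarity", partners=len(partners), removed=len(removed))

    # 7. co-occurrence + positional preference
    cooccur_rows, position_rows = [], []
    for fid, sim in partners:
        obs = positional.build_anchor_profile(
            obs_hits[config.anchor], obs_hits[fid], config.window,
            anchor_id=config.anchor, partner_id=fid)
        ref = positional.build_anchor_profile(
            bg_hits[config.anchor], bg_hits[fid], config.window,
            anchor_id=config.anchor, partner_id=fid)
        res = positional.cooccurrence_test(obs, ref, config.z_cooccur,
                                           continuity=True)
        cooccur_rows.append({
            "factor_id": fid, "n_promoters": res.observed,
            "background_fraction": res.background_fraction,
            "z": res.z, "retained": res.retained, "similarity_to_anchor": sim,
        })
        if res.retained:
            for call in positional.positional_preference_test(
                    obs, ref, config.z_position, config.p_position):
                position_rows.append({
                    "factor_id": fid, "offset": call.offset,
                    "observed": call.observed, "expected": call.expected,
                    "z": call.z, "p": call.p, "significant": call.significant,
                    "background_zero": call.background_zero,
                })
    pd.DataFrame(cooccur_rows).to_csv(out / "cooccurrence.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    pd.DataFrame(position_rows, columns=[
        "factor_id", "offset", "observed", "expected", "z", "p",
        "significant", "background_zero",
    ]).to_csv(out / "positions.tsv", sep="\t", index=False,
              float_format="%.6g")
    stage("cooccur", retained=sum(r["retained"] for r in cooccur_rows),
          significant_positions=sum(r["significant"] for r in position_rows))

    # 8. optional bound/unbound enrichment
    if config.bound_fasta and config.unbound_fasta:
        enrich_df = _enrichment_stage(config, pwms, thresholds, partners, out,
                                      manifest)
        stage("enrich", factors=len(enrich_df),
              selected=int(enrich_df["selected"].sum()))

    # 9. optional condition comparison
    if config.condition_a_fasta and config.condition_b_fasta:
        cond_df = _condition_stage(config, pwms, thresholds, partners, out,
                                   manifest)
        stage("conditions", factors=len(cond_df))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    return manifest


def _region_cooccur_counts(config: PipelineConfig, fasta: str,
                           pwms, thresholds, partner_ids,
                           center_filter: bool, manifest_key: str,
                           manifest: dict) -> tuple[dict[str, int], int]:
    records = scanner.read_fasta(fasta)  # anchor_offset = region center
    manifest["inputs"][manifest_key] = _sha256(fasta)
    regions = chip_analysis.RegionSet(manifest_key, records)
    anchor_hits = scanner.scan_set(records, pwms[config.anchor],
                                   thresholds[config.anchor], config.strands)
    if center_filter:
        anchor_hits = chip_analysis.select_center_anchor_hits(
            anchor_hits, regions, config.center_band)
    counts = {}
    for fid in partner_ids:
        hits = scanner.scan_set(records, pwms[fid], thresholds[fid],
                                config.strands)
        counts[fid], _ = cooccurrence_count(anchor_hits, hits, config.window)
    n_anchor = len({h.seq_id for h in anchor_hits})
    return counts, n_anchor


def _enrichment_stage(config, pwms, thresholds, partners, out, manifest):
    partner_ids = [fid for fid, _ in partners]
    bound_counts, n_bound = _region_cooccur_counts(
        config, config.bound_fasta, pwms, thresholds, partner_ids,
        center_filter=True, manifest_key="bound_fasta", manifest=manifest)
    unbound_counts, n_unbound = _region_cooccur_counts(
        config, config.unbound_fasta, pwms, thresholds, partner_ids,
        center_filter=False, manifest_key="unbound_fasta", manifest=manifest)
    results = []
    for fid in partner_ids:
        b, u = bound_counts[fid], unbound_counts[fid]
        results.append(chip_analysis.EnrichmentResult(
            fid, b, u, chip_analysis.compute_enrichment(b, u),
            chip_analysis.enrichment_z(b, max(n_bound, 1), u,
                                       max(n_unbound, 1))))
    ranked = chip_analysis.rank_and_select(results, config.top_rank,
                                           config.max_rank_diff)
    df = pd.DataFrame([{
        "factor_id": r.factor_id, "bound_count": r.bound_count,
        "unbound_count": r.unbound_count, "enrichment": r.enrichment,
        "z": r.z, "rank_enrichment": r.rank_enrichment, "rank_z": r.rank_z,
        "selected": r.selected,
    } for r in ranked])
    df.to_csv(out / "enrichment.tsv", sep="\t", index=False,
              float_format="%.6g")
    return df


def _condition_stage(config, pwms, thresholds, partners, out, manifest):
    partner_ids = [fid for fid, _ in partners]
    counts_a, n_a = _region_cooccur_counts(
        config, config.condition_a_fasta, pwms, thresholds, partner_ids,
        center_filter=True, manifest_key="condition_a_fasta",
        manifest=manifest)
    counts_b, n_b = _region_cooccur_counts(
        config, config.condition_b_fasta, pwms, thresholds, partner_ids,
        center_filter=True, manifest_key="condition_b_fasta",
        manifest=manifest)
    rows = []
    for fid in partner_ids:
        cmp_ = chip_analysis.compare_conditions(
            (counts_a[fid], max(n_a, 1)), (counts_b[fid], max(n_b, 1)),
            factor_id=fid)
        rows.append({"factor_id": fid, "count_a": cmp_.count_a,
                     "n_a": cmp_.n_a, "count_b": cmp_.count_b,
                     "n_b": cmp_.n_b, "z": cmp_.z,
                     "degenerate": cmp_.degenerate})
    df = pd.DataFrame(rows).sort_values("z", ascending=False,
                                        kind="mergesort")
    df.to_csv(out / "conditions.tsv", sep="\t", index=False,
              float_format="%.6g")
    return df
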