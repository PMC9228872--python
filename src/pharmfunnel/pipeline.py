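"""The two-stage virtual-screening funnel.

Stage 1 screens every library compound conformationally against the
hypothesis (``match_aligned`` over a generated ensemble). Compounds passing
stage 1 are docked *externally*; their poses, supplied as an SDF in the
receptor frame, are re-screened in place (``match_inplace``), with no
conformer generation and no realignment — the more restrictive step.

The funnel counts are monotone by construction:
``n_in >= n_stage1_pass >= n_posed >= n_stage2_pass``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chemio import EmptyInputError, Hypothesis, Molecule, read_hypothesis, read_molecules
from .features import DEFAULT_RULES, Feature, RuleSet, perceive_features
from .matcher import MatchParams, MatchResult, match_aligned, match_inplace, screen_conformers

logger = logging.getLogger(__name__)


@dataclass
class FeatureCompound:
    """A library entry given directly as feature clouds (synthetic fixtures).

    ``feature_sets`` plays the role of a conformer ensemble: stage 1 tries
    each set; a pose for stage 2 is a single set already in the frame.
    """

    id: str
    feature_sets: list[list[Feature]]


@dataclass
class ScreenRecord:
    """Per-compound funnel outcome."""

    compound_id: str
    stage1_pass: bool = False
    stage1_best: MatchResult | None = None
    docked: bool = False
    stage2_pass: bool = False
    stage2_best: MatchResult | None = None


@dataclass
class FunnelConfig:
    """File-level funnel configuration (CLI/YAML mirror of `run_funnel`)."""

    library: str
    hypothesis: str
    out: str
    poses: str | None = None
    stage1: MatchParams = field(default_factory=lambda: MatchParams(mode="aligned"))
    stage2: MatchParams = field(default_factory=lambda: MatchParams(mode="inplace"))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FunnelConfig":
        doc = yaml.safe_load(Path(path).read_text())
        kwargs = dict(doc)
        for stage in ("stage1", "stage2"):
            if stage in kwargs and isinstance(kwargs[stage], dict):
                kwargs[stage] = MatchParams(**kwargs[stage])
        return cls(**kwargs)


def ingest_poses(path: str | Path) -> dict[str, list[Molecule]]:
    """Read docking poses from an SDF keyed by record title (compound id).

    Multiple poses per compound are kept (no truncation); untitled records
    are skipped with a warning. An empty file yields an empty map and a
    warning, not an error.
    """
    path = Path(path)
    try:
        mols = read_molecules(path, "sdf")
    except EmptyInputError:
        logger.warning("poses file %s contains no parseable records", path)
        return {}
    poses: dict[str, list[Molecule]] = {}
    for m in mols:
        titled = m.mol.HasProp("_Name") and m.mol.GetProp("_Name").strip()
        if not titled:
            logger.warning("skipping untitled pose record from %s", path)
            continue
        poses.setdefault(m.id, []).append(m)
    return poses


def _stage1_best(
    entry: Molecule | FeatureCompound,
    hyp: Hypothesis,
    params: MatchParams,
    rules: RuleSet,
) -> MatchResult | None:
    if isinstance(entry, FeatureCompound):
        best = None
        for k, feats in enumerate(entry.feature_sets):
            res = match_aligned(feats, hyp, params.min_match)
            if res is None:
                continue
            res.conformer_id = k
            if best is None or (res.matched_count, res.fit_score) > (
                best.matched_count, best.fit_score
            ):
                best = res
        return best
    return screen_conformers(entry, hyp, params, rules)


def _pose_feature_sets(
    pose: Molecule | FeatureCompound, rules: RuleSet
) -> list[tuple[object, list[Feature]]]:
    if isinstance(pose, FeatureCompound):
        return [(k, fs) for k, fs in enumerate(pose.feature_sets)]
    return [
        (conf.GetId(), perceive_features(pose, rules, conf_id=conf.GetId()))
        for conf in pose.mol.GetConformers()
    ]


def run_funnel(
    library: list[Molecule | FeatureCompound],
    hyp: Hypothesis,
    stage1: MatchParams,
    poses: dict[str, list[Molecule | FeatureCompound]] | None = None,
    stage2: MatchParams | None = None,
    rules: RuleSet = DEFAULT_RULES,
) -> tuple[list[ScreenRecord], pd.DataFrame]:
    """Run the full funnel and build the per-compound report.

    Stage 1 screens every compound; only stage-1 passers are looked up in
    the pose map; stage 2 screens each pose in place and keeps the best pose
    by (matched_count, fit_score). Pose ids absent from the library draw a
    warning. Raises on an empty library.
    """
    if not library:
        raise EmptyInputError("funnel library is empty")
    poses = poses or {}
    stage2 = stage2 or MatchParams(min_match=stage1.min_match, mode="inplace")
    lib_ids = {e.id for e in library}
    orphans = sorted(set(poses) - lib_ids)
    if orphans:
        logger.warning("%d pose compound id(s) not in library: %s", len(orphans), orphans)

    records: list[ScreenRecord] = []
    for entry in library:
        rec = ScreenRecord(compound_id=entry.id)
        best1 = _stage1_best(entry, hyp, stage1, rules)
        rec.stage1_best = best1
        rec.stage1_pass = best1 is not None
        if rec.stage1_pass and entry.id in poses:
            rec.docked = True
            best2: MatchResult | None = None
            for pose in poses[entry.id]:
                for pose_id, feats in _pose_feature_sets(pose, rules):
                    res = match_inplace(feats, hyp, stage2.min_match)
                    if res is None:
                        continue
                    res.conformer_id = pose_id
                    if best2 is None or (res.matched_count, res.fit_score) > (
                        best2.matched_count, best2.fit_score
                    ):
                        best2 = res
            rec.stage2_best = best2
            rec.stage2_pass = best2 is not None
        records.append(rec)

    counts = funnel_counts(records)
    logger.info(
        "funnel: %(n_in)d in -> %(n_stage1)d stage-1 pass -> "
        "%(n_posed)d posed -> %(n_stage2)d stage-2 pass", counts,
    )
    return records, report_frame(records)


def funnel_counts(records: list[ScreenRecord]) -> dict[str, int]:
    return {
        "n_in": len(records),
        "n_stage1": sum(r.stage1_pass for r in records),
        "n_posed": sum(r.docked for r in records),
        "n_stage2": sum(r.stage2_pass for r in records),
    }


def report_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    """Flat per-compound report (one row per compound, stable order)."""
    rows = []
    for r in records:
        row = {
            "compound_id": r.compound_id,
            "stage1_pass": r.stage1_pass,
            "docked": r.docked,
            "stage2_pass": r.stage2_pass,
        }
        for stage, res in (("stage1", r.stage1_best), ("stage2", r.stage2_best)):
            row[f"{stage}_matched"] = res.matched_count if res else 0
            row[f"{stage}_rmsd"] = round(res.rmsd_match, 6) if res else float("nan")
            row[f"{stage}_score"] = round(res.fit_score, 6) if res else float("nan")
            row[f"{stage}_id"] = res.conformer_id if res else ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def write_manifest(config: FunnelConfig, counts: dict[str, int], path: str | Path) -> None:
    """JSON run manifest with a parameter hash for auditability."""
    payload = {
        "library": config.library,
        "hypothesis": config.hypothesis,
        "poses": config.poses,
        "stage1": vars(config.stage1) if hasattr(config.stage1, "__dict__") else str(config.stage1),
        "stage2": vars(config.stage2) if hasattr(config.stage2, "__dict__") else str(config.stage2),
        "seed": config.seed,
        "counts": counts,
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["param_hash"] = digest
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_funnel_config(config: FunnelConfig, rules: RuleSet = DEFAULT_RULES):
    """File-level funnel entry point used by the CLI."""
    fmt = "sdf" if Path(config.library).suffix.lower() == ".sdf" else "smiles"
    library = read_molecules(config.library, fmt)
    hyp = read_hypothesis(config.hypothesis)
    poses = ingest_poses(config.poses) if config.poses else {}
    stage1 = MatchParams(
        min_match=config.stage1.min_match, mode="aligned",
        max_confs=config.stage1.max_confs, seed=config.seed,
    )
    records, frame = run_funnel(library, hyp, stage1, poses, config.stage2, rules)
    write_report(frame, config.out)
    counts = funnel_counts(records)
    write_manifest(config, counts, str(config.out) + ".manifest.json")
    return records, frame
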