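"""End-to-end orchestration with the standard reporting thresholds.

A run scores every variant in the table as a center (neighbors = all other
table variants inside its window, contexts exhaustively enumerated), builds
the background null, applies the operating thresholds
(|log-odds change| >= 1 and e-value <= 0.05), contrasts effects across LD
groups, summarizes the across-context effect distribution per variant, and
tests declared SNP pairs for case/control epistasis.  Every output table is
tab-delimited with a config-fingerprint header line; a rerun with identical
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotator import SyntheticAnnotator, load_feature_subset
from .context_enum import enumerate_contexts, observed_contexts
from .effect_stats import (
    BackgroundNull, build_background, records_to_frame, score_variant,
    reversed_pass_discrepancy, uniform_snv_sampler,
)
from .epistasis import GenotypeTable, carrier_group_proportions, epistasis_test
from .ld_analysis import HaplotypeMatrix, compare_group_effects, correlated_group
from .sequence_windows import Genome, Variant, load_reference, load_variants, window_span

DEFAULT_LOC_THRESHOLD = 1.0
DEFAULT_E_THRESHOLD = 0.05
DEFAULT_STABILITY_FRACTION = 0.25


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one full run."""

    fasta: str
    variants: str
    annotator: str
    outdir: str
    feature_subset: str | None = None
    haplotypes: str | None = None
    dosages: str | None = None
    phenotypes: str | None = None
    epistasis_pairs: tuple = ()         # (id_a, id_b) pairs to test
    L: int = 2000
    background_n: int = 999
    seed: int = 7
    loc_threshold: float = DEFAULT_LOC_THRESHOLD
    e_threshold: float = DEFAULT_E_THRESHOLD
    ld_threshold: float = 0.8
    max_neighbors: int = 12
    stability_fraction: float = DEFAULT_STABILITY_FRACTION
    reversed_pass: bool = False
    observed_only: bool = False
    background_exclude: tuple = ()      # (chrom, start0, end0) spans

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epistasis_pairs"] = [list(p) for p in self.epistasis_pairs]
        d["background_exclude"] = [list(z) for z in self.background_exclude]
        return d

    def fingerprint(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, fingerprint: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# caism {__version__} config={fingerprint}\n")
        df.to_csv(fh, sep="\t", index=False)


def neighbors_in_window(center: Variant, variants: list[Variant],
                        L: int) -> list[Variant]:
    """All other table variants inside the center's window span."""
    start, end = window_span(center.pos, L)
    return [v for v in variants
            if v.id != center.id and v.chrom == center.chrom
            and start <= v.pos - 1 < end]


def score_all_variants(
    genome: Genome,
    variants: list[Variant],
    annotator,
    null: BackgroundNull | None,
    feature_subset=None,
    L: int = 2000,
    max_neighbors: int = 12,
    haplotypes: HaplotypeMatrix | None = None,
    observed_only: bool = False,
) -> pd.DataFrame:
    """Score every variant as a center across its exhaustive context set."""
    records = []
    for center in variants:
        nbrs = neighbors_in_window(center, variants, L)
        contexts = enumerate_contexts(center, nbrs, "minor",
                                      max_neighbors=max_neighbors)
        if observed_only and haplotypes is not None:
            contexts = observed_contexts(contexts, haplotypes)
        records.extend(score_variant(
            genome, center, nbrs, annotator, null, contexts,
            feature_subset=feature_subset, L=L))
    return records_to_frame(records)


def no_context_effects(df: pd.DataFrame) -> pd.DataFrame:
    """Rows of the all-major (no-context) assignment per variant."""
    # the center is always contrasted; "no context" means every neighbor major
    def is_all_major(label: str) -> bool:
        parts = label.split(";")[1:]
        return all(p.endswith("=major") for p in parts)
    return df[df["context_label"].map(is_all_major)]


def report_flagged(
    effects: pd.DataFrame,
    loc_threshold: float = DEFAULT_LOC_THRESHOLD,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    stability_fraction: float = DEFAULT_STABILITY_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the operating thresholds and label context stability.

    Returns ``(flagged_rows, variant_summary)``.  A variant/feature pair is
    flagged when any of its contexts passes both |log-odds change| >=
    ``loc_threshold`` and e-value <= ``e_threshold``.  Its effect is labeled
    context-stable when the spread of the log-odds change across contexts is
    below ``stability_fraction`` of its median magnitude, context-dependent
    otherwise — an explicit operationalization of "similar effect regardless
    of genetic context".
    """
    if effects.empty:
        empty = effects.iloc[0:0]
        return empty, pd.DataFrame(
            columns=["variant_id", "feature", "loc_min", "loc_max",
                     "loc_range", "loc_median_abs", "context_stability"])
    mask = (effects["log_odds_change"].abs() >= loc_threshold)
    if effects["e_value"].notna().any():
        mask &= (effects["e_value"] <= e_threshold)
    flagged = effects[mask].copy()

    summaries = []
    for (vid, feat), sub in effects.groupby(["variant_id", "feature"], sort=True):
        if not mask[sub.index].any():
            continue
        locs = sub["log_odds_change"]
        rng_ = float(locs.max() - locs.min())
        med = float(locs.abs().median())
        summaries.append({
            "variant_id": vid, "feature": feat,
            "loc_min": float(locs.min()), "loc_max": float(locs.max()),
            "loc_range": rng_, "loc_median_abs": med,
            "context_stability": ("context-stable"
                                  if rng_ < stability_fraction * med
                                  else "context-dependent"),
        })
    return flagged, pd.DataFrame(summaries)


def context_distribution_summary(effects: pd.DataFrame) -> pd.DataFrame:
    """Across-context distribution of the log-odds change per variant/feature."""
    rows = []
    for (vid, feat), sub in effects.groupby(["variant_id", "feature"], sort=True):
        locs = sub["log_odds_change"]
        rows.append({
            "variant_id": vid, "feature": feat, "n_contexts": len(sub),
            "loc_min": float(locs.min()), "loc_median": float(locs.median()),
            "loc_max": float(locs.max()),
            "loc_range": float(locs.max() - locs.min()),
        })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the result tables keyed by name.

    Output files land in ``config.outdir``; any stage failure leaves a
    ``FAILED`` marker naming the stage, with earlier outputs retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fp = config.fingerprint()
    results: dict = {}
    stage = "load_inputs"
    try:
        genome = load_reference(config.fasta)
        variants = load_variants(config.variants)
        annot = SyntheticAnnotator.load(config.annotator)
        subset = (load_feature_subset(config.feature_subset)
                  if config.feature_subset else None)
        hap = (HaplotypeMatrix.load(config.haplotypes)
               if config.haplotypes else None)

        stage = "background_null"
        sampler = uniform_snv_sampler(
            genome, seed=config.seed, L=config.L,
            exclude=list(config.background_exclude))
        null = build_background(genome, sampler, annot, n=config.background_n,
                                seed=config.seed, L=config.L,
                                feature_subset=subset)
        null.save(outdir / "background_null.tsv")
        results["null"] = null

        stage = "effect_scoring"
        effects = score_all_variants(
            genome, variants, annot, null, feature_subset=subset, L=config.L,
            max_neighbors=config.max_neighbors, haplotypes=hap,
            observed_only=config.observed_only)
        _write_table(effects, outdir / "effects.tsv", fp)
        results["effects"] = effects

        stage = "reporting"
        flagged, summary = report_flagged(
            effects, config.loc_threshold, config.e_threshold,
            config.stability_fraction)
        _write_table(flagged, outdir / "flagged_effects.tsv", fp)
        _write_table(summary, outdir / "variant_summary.tsv", fp)
        ctx = context_distribution_summary(effects)
        _write_table(ctx, outdir / "context_distributions.tsv", fp)
        results["flagged"], results["summary"], results["contexts"] = flagged, summary, ctx

        if config.reversed_pass:
            stage = "reversed_pass"
            rows = []
            for center in variants:
                nbrs = neighbors_in_window(center, variants, config.L)
                ctxs = enumerate_contexts(center, nbrs, "minor",
                                          max_neighbors=config.max_neighbors)
                rows.append({
                    "variant_id": center.id,
                    "max_abs_probability_discrepancy": reversed_pass_discrepancy(
                        genome, center, nbrs, annot, ctxs, L=config.L),
                })
            rev = pd.DataFrame(rows)
            _write_table(rev, outdir / "reversed_pass.tsv", fp)
            results["reversed_pass"] = rev

        if hap is not None:
            stage = "ld_contrasts"
            nc = no_context_effects(effects)
            anchors = sorted(set(flagged["variant_id"]) & set(hap.variant_ids))
            frames = []
            for anchor in anchors:
                group = correlated_group(hap, anchor, config.ld_threshold)
                if len(group.member_ids) > 1:
                    frames.append(compare_group_effects(
                        group, nc, effect_threshold=config.loc_threshold))
            ld = (pd.concat(frames, ignore_index=True) if frames
                  else pd.DataFrame())
            _write_table(ld, outdir / "ld_group_contrasts.tsv", fp)
            results["ld_contrasts"] = ld

        if config.dosages and config.phenotypes and config.epistasis_pairs:
            stage = "epistasis"
            gt = GenotypeTable.load(config.dosages, config.phenotypes)
            rows, props = [], []
            for a, b in config.epistasis_pairs:
                res = epistasis_test(gt, a, b)
                rows.append(dataclasses.asdict(res))
                p4 = carrier_group_proportions(gt, a, b)
                p4.insert(0, "pair", f"{a}/{b}")
                props.append(p4)
            epi = pd.DataFrame(rows)
            _write_table(epi, outdir / "epistasis.tsv", fp)
            _write_table(pd.concat(props, ignore_index=True),
                         outdir / "carrier_proportions.tsv", fp)
            results["epistasis"] = epi

        stage = "run_log"
        (outdir / "run_log.json").write_text(json.dumps({
            "caism_version": __version__,
            "config": config.to_dict(),
            "config_fingerprint": fp,
            "annotator_fingerprint": annot.fingerprint(),
            "background_metadata": null.metadata,
        }, indent=2))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise PipelineStageError(stage, exc) from exc
    return results
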