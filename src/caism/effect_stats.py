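"""Allele-specific effect statistics and their empirical calibration.

For one variant and one chromatin feature, with annotator probabilities
``p_ref`` (window carrying the major allele) and ``p_alt`` (minor allele),
the effect measures are

    log_odds_change = logit(p_ref) - logit(p_alt)          (natural log)
    e_stat          = log_odds_change * (p_ref - p_alt)

Because logit is strictly increasing, both factors share a sign and the
E statistic is non-negative; it is zero iff the two probabilities are equal.
It folds relative change (log odds) and absolute change (probability
difference) into one magnitude.

Significance is empirical: the same statistic is computed for a large sample
of random background variants, giving one null distribution per feature, and
a candidate's e-value is its add-one tail rank (r + 1) / (n + 1), where r is
the number of background values >= the observed statistic (ties counted,
conservative).  The smallest achievable e-value is therefore 1 / (n + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit

from .context_enum import ContextAssignment
from .sequence_windows import (
    Genome, Variant, WindowBoundaryError, build_window, window_span,
)


def log_odds_change(p_ref: float, p_alt: float) -> float:
    """logit(p_ref) - logit(p_alt); both probabilities strictly in (0, 1)."""
    p_ref, p_alt = float(p_ref), float(p_alt)
    if not (0.0 < p_ref < 1.0 and 0.0 < p_alt < 1.0):
        raise ValueError(
            f"probabilities must be strictly inside (0, 1); "
            f"got p_ref={p_ref}, p_alt={p_alt} — clamp upstream"
        )
    return float(logit(p_ref) - logit(p_alt))


def e_statistic(p_ref: float, p_alt: float) -> float:
    """Product of the log-odds change and the probability change; >= 0."""
    return log_odds_change(p_ref, p_alt) * (float(p_ref) - float(p_alt))


def direction(loc: float) -> str:
    """Effect direction of the minor allele implied by the log-odds change.

    Positive log-odds change means the minor-allele window has the lower
    predicted probability: a loss of the feature for minor-allele carriers.
    """
    if loc > 0:
        return "loss"
    if loc < 0:
        return "gain"
    return "none"


@dataclass(frozen=True)
class EffectRecord:
    """Per-variant, per-feature, per-context effect statistics."""

    variant_id: str
    context_label: str
    feature: str
    p_ref: float
    p_alt: float
    log_odds_change: float
    e_stat: float
    e_value: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def direction(self) -> str:
        return direction(self.log_odds_change)


def records_to_frame(records: Sequence[EffectRecord]) -> pd.DataFrame:
    """Tabulate effect records (tab-delimited friendly)."""
    return pd.DataFrame([
        {
            "variant_id": r.variant_id, "context_label": r.context_label,
            "feature": r.feature, "p_ref": r.p_ref, "p_alt": r.p_alt,
            "log_odds_change": r.log_odds_change, "e_stat": r.e_stat,
            "e_value": r.e_value, "direction": r.direction,
            "flags": ",".join(sorted(r.flags)),
        }
        for r in records
    ])


def add_bh_column(df: pd.DataFrame) -> pd.DataFrame:
    """Supplementary Benjamini–Hochberg adjustment of e-values across rows.

    The core reporting applies no multiple-testing correction; this column is
    an explicitly labeled extension for users who want one.
    """
    from statsmodels.stats.multitest import multipletests

    out = df.copy()
    mask = out["e_value"].notna()
    if mask.any():
        out.loc[mask, "e_value_bh_extension"] = multipletests(
            out.loc[mask, "e_value"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# background null
# ---------------------------------------------------------------------------

@dataclass
class BackgroundNull:
    """Per-feature sorted null distributions of the E statistic."""

    values: dict[str, np.ndarray]  # feature -> sorted ascending, length n
    n_background: int
    metadata: dict

    def __post_init__(self) -> None:
        for feat, v in self.values.items():
            if len(v) != self.n_background:
                raise ValueError(f"feature {feat!r}: {len(v)} values != n={self.n_background}")

    @property
    def features(self) -> list[str]:
        return list(self.values)

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.metadata, sort_keys=True) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundNull":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
            df = pd.read_csv(fh, sep="\t")
        return cls(
            values={c: np.sort(df[c].to_numpy(float)) for c in df.columns},
            n_background=len(df), metadata=meta,
        )


def uniform_snv_sampler(
    genome: Genome,
    seed: int,
    L: int = 2000,
    exclude: Sequence[tuple[str, int, int]] = (),
) -> Iterator[Variant]:
    """Endless stream of random background SNVs away from contig edges.

    Positions are uniform over eligible sites (at least a half-window from
    every contig edge and outside ``exclude`` spans, 0-based half-open); the
    reference base is the major allele and the minor allele is drawn uniformly
    from the three other bases.  Sites whose reference base is N are skipped.
    """
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome.contig_names if genome.contig_length(c) >= L]
    if not chroms:
        raise ValueError(f"no contig long enough for L={L}")
    lengths = np.array([genome.contig_length(c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    up = (L - 1) // 2
    i = 0
    while True:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        lo, hi = up + 1, genome.contig_length(chrom) - (L - 1 - up)
        pos = int(rng.integers(lo, hi + 1))  # 1-based
        if any(c == chrom and s <= pos - 1 < e for c, s, e in exclude):
            continue
        ref = genome.base(chrom, pos)
        if ref == "N":
            continue
        minor = rng.choice([b for b in "ACGT" if b != ref])
        yield Variant(id=f"bg{i}", chrom=chrom, pos=pos, major=ref, minor=str(minor))
        i += 1


def build_background(
    genome: Genome,
    variant_sampler: Iterator[Variant] | Callable[[], Iterator[Variant]],
    annotator,
    n: int,
    seed: int,
    L: int = 2000,
    feature_subset: Sequence[str] | None = None,
) -> BackgroundNull:
    """Null distribution of the E statistic from n random variants.

    For each sampled variant the no-context reference/alternate window pair is
    annotated and the E statistic recorded per feature.  Variants whose
    windows cross a contig boundary are skipped and counted.  ``seed`` is
    provenance metadata (the sampler should be constructed from it).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    it = variant_sampler() if callable(variant_sampler) else variant_sampler
    names = list(feature_subset) if feature_subset is not None else list(annotator.feature_names)
    acc: dict[str, list[float]] = {f: [] for f in names}
    kept, skipped, attempts = 0, 0, 0
    max_attempts = 1000 * n + 1000
    while kept < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"sampler exhausted: {kept}/{n} valid variants after {attempts} draws"
            )
        try:
            v = next(it)
        except StopIteration:
            raise RuntimeError(
                f"sampler exhausted: {kept}/{n} valid variants"
            ) from None
        try:
            w_ref = build_window(genome, v, allele_choice={v.id: "major"}, L=L)
            w_alt = build_window(genome, v, allele_choice={v.id: "minor"}, L=L)
        except WindowBoundaryError:
            skipped += 1
            continue
        prof_ref = annotator.annotate(w_ref.seq)
        prof_alt = annotator.annotate(w_alt.seq)
        for f in names:
            acc[f].append(e_statistic(prof_ref[f], prof_alt[f]))
        kept += 1
    meta = {
        "seed": int(seed), "n": int(n), "L": int(L),
        "skipped_boundary": int(skipped),
        "variant_source": "uniform synthetic background sampler",
        "annotator_fingerprint": getattr(annotator, "fingerprint", lambda: "external")(),
    }
    return BackgroundNull(
        values={f: np.sort(np.array(acc[f])) for f in names},
        n_background=n, metadata=meta,
    )


def empirical_e_value(e_stat: float, null: BackgroundNull, feature: str) -> float:
    """Add-one empirical tail probability (r + 1) / (n + 1), ties inclusive."""
    if feature not in null.values:
        raise KeyError(f"feature {feature!r} absent from background null")
    v = null.values[feature]
    r = len(v) - int(np.searchsorted(v, e_stat, side="left"))
    return (r + 1) / (len(v) + 1)


# ---------------------------------------------------------------------------
# end-to-end scoring of one variant
# ---------------------------------------------------------------------------

def score_variant(
    genome: Genome,
    center: Variant,
    neighbors: list[Variant],
    annotator,
    null: BackgroundNull | None,
    contexts: Sequence[ContextAssignment],
    feature_subset: Sequence[str] | None = None,
    L: int = 2000,
) -> list[EffectRecord]:
    """Effect records for every (context, feature) pair of one center variant.

    Each context fixes the neighbor alleles in BOTH windows of the contrast;
    the reference window sets the center to major and the alternate window to
    minor (the context modifies the sequence background, the ref/alt contrast
    is always the center allele).  With zero neighbors this reduces exactly to
    the no-context analysis.
    """
    names = list(feature_subset) if feature_subset is not None else list(annotator.feature_names)
    records = []
    for ctx in contexts:
        choice = dict(ctx.neighbor_alleles)
        w_ref = build_window(genome, center, neighbors,
                             {**choice, center.id: "major"}, L=L)
        w_alt = build_window(genome, center, neighbors,
                             {**choice, center.id: "minor"}, L=L)
        prof_ref = annotator.annotate(w_ref.seq)
        prof_alt = annotator.annotate(w_alt.seq)
        for f in names:
            p_ref, p_alt = prof_ref[f], prof_alt[f]
            loc = log_odds_change(p_ref, p_alt)
            es = loc * (p_ref - p_alt)
            records.append(EffectRecord(
                variant_id=center.id, context_label=ctx.label, feature=f,
                p_ref=p_ref, p_alt=p_alt, log_odds_change=loc, e_stat=es,
                e_value=(empirical_e_value(es, null, f) if null is not None else None),
                flags=w_ref.flags | w_alt.flags,
            ))
    return records


def reversed_pass_discrepancy(
    genome: Genome,
    center: Variant,
    neighbors: list[Variant],
    annotator,
    contexts: Sequence[ContextAssignment],
    L: int = 2000,
) -> float:
    """Max |Δ probability| between forward and reverse-complement windows.

    A strand-symmetric annotator returns exactly 0; a strand-naive one
    quantifies how far the forward-only analysis is from its mirrored twin.
    """
    from .sequence_windows import reverse_complement_window

    worst = 0.0
    for ctx in contexts:
        for allele in ("major", "minor"):
            choice = dict(ctx.neighbor_alleles)
            w = build_window(genome, center, neighbors,
                             {**choice, center.id: allele}, L=L)
            fwd = annotator.annotate(w.seq).probs
            rev = annotator.annotate(reverse_complement_window(w).seq).probs
            worst = max(worst, float(np.max(np.abs(fwd - rev))))
    return worst
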