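"""Linkage disequilibrium from phased haplotypes and effect contrasts.

r² between two loci is computed from haplotype frequencies:
D = f(minor, minor) - p_a * p_b and r² = D² / (p_a (1-p_a) p_b (1-p_b)),
with frequencies taken over haplotype rows.  Groups are anchor-centered
threshold sets (all variants with r² >= threshold to the anchor), the reading
of "highly correlated SNPs in the same LD block" that needs no block-calling
algorithm.  The contrast step then asks the question the grouping exists for:
do variants in near-perfect LD receive similar predicted regulatory effects?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .effect_stats import EffectRecord

DEFAULT_LD_THRESHOLD = 0.8


class MonomorphicVariantError(ValueError):
    """LD is undefined for a column with no variation."""


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: rows = haplotypes, columns = variants, 0=major 1=minor."""

    variant_ids: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[1] != len(self.variant_ids):
            raise ValueError("column count must match variant_ids")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 (major) or 1 (minor); "
                             "phased input only, no missing entries")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in haplotype matrix") from None
        return self.haplotypes[:, j]

    def columns(self, variant_ids: list[str]) -> np.ndarray:
        return np.column_stack([self.column(v) for v in variant_ids])

    # -- IO -------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        pd.DataFrame(self.haplotypes, columns=self.variant_ids).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "HaplotypeMatrix":
        """Plain 0/1 matrix with a header row of variant ids."""
        df = pd.read_csv(path, sep="\t")
        return cls(list(df.columns), df.to_numpy(dtype=np.int8))

    @classmethod
    def from_vcf(cls, path: str | Path, variants=None) -> "HaplotypeMatrix":
        """Phased VCF -> two haplotype rows per sample.

        Allele 1 in the VCF is taken as minor unless a matching
        :class:`~caism.sequence_windows.Variant` (by id) says the REF allele
        is the minor one, in which case the coding is flipped.
        """
        from cyvcf2 import VCF

        by_id = {v.id: v for v in (variants or [])}
        ids, cols = [], []
        vcf = VCF(str(path))
        for rec in vcf:
            ph = rec.genotype.array()
            if np.any(ph[:, :2] < 0):
                raise ValueError(f"{rec.ID or rec.POS}: missing genotypes; "
                                 "phased complete input required for LD")
            if not np.all(ph[:, 2]):
                raise ValueError(f"{rec.ID or rec.POS}: unphased genotypes")
            col = ph[:, :2].reshape(-1)
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            v = by_id.get(vid)
            if v is not None and v.major == rec.ALT[0]:
                col = 1 - col
            ids.append(vid)
            cols.append(col.astype(np.int8))
        return cls(ids, np.column_stack(cols))


@dataclass(frozen=True)
class LDGroup:
    """Anchor-centered set of correlated variants."""

    anchor_id: str
    member_ids: tuple[str, ...]
    r2_to_anchor: dict[str, float]
    threshold: float


def r_squared(hap: HaplotypeMatrix, a: str, b: str) -> float:
    """Pairwise r² from haplotype frequencies; both loci must be polymorphic."""
    xa, xb = hap.column(a), hap.column(b)
    pa, pb = float(xa.mean()), float(xb.mean())
    for name, p in ((a, pa), (b, pb)):
        if p in (0.0, 1.0):
            raise MonomorphicVariantError(
                f"variant {name!r} is monomorphic in the haplotype matrix; "
                "r² undefined")
    d = float((xa & xb).mean()) - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def correlated_group(
    hap: HaplotypeMatrix,
    anchor: str,
    threshold: float = DEFAULT_LD_THRESHOLD,
) -> LDGroup:
    """All variants with r² >= threshold to the anchor, anchor included.

    Monomorphic variants are excluded with a warning rather than silently
    assigned r² = 0.
    """
    hap.column(anchor)  # existence check
    members, r2 = [anchor], {anchor: 1.0}
    for vid in hap.variant_ids:
        if vid == anchor:
            continue
        try:
            val = r_squared(hap, anchor, vid)
        except MonomorphicVariantError:
            warnings.warn(f"excluding monomorphic variant {vid!r} from LD group "
                          f"of {anchor!r}", stacklevel=2)
            continue
        if val >= threshold:
            members.append(vid)
            r2[vid] = val
    return LDGroup(anchor_id=anchor, member_ids=tuple(members),
                   r2_to_anchor=r2, threshold=threshold)


def compare_group_effects(
    group: LDGroup,
    effects: list[EffectRecord] | pd.DataFrame,
    effect_threshold: float = 1.0,
    high_ld: float = 0.9,
) -> pd.DataFrame:
    """Contrast no-context log-odds changes across an LD group, per feature.

    Returns one row per (feature, member) with the member's log-odds change,
    its r² to the anchor, the group-level divergence for that feature (max
    pairwise absolute difference of log-odds changes), and a flag marking the
    phenomenon of interest: the anchor exceeds the effect threshold while a
    member in near-perfect LD (r² >= ``high_ld``) does not.
    """
    from .effect_stats import records_to_frame

    df = effects if isinstance(effects, pd.DataFrame) else records_to_frame(effects)
    df = df[df["variant_id"].isin(group.member_ids)]
    missing = set(group.member_ids) - set(df["variant_id"])
    if missing:
        raise ValueError(f"no effect records for LD group member(s): {sorted(missing)}")

    rows = []
    for feature, sub in df.groupby("feature", sort=True):
        by_member = sub.set_index("variant_id")["log_odds_change"].to_dict()
        vals = [by_member.get(m, np.nan) for m in group.member_ids]
        finite = [v for v in vals if np.isfinite(v)]
        div = float(max(finite) - min(finite)) if finite else np.nan
        anchor_loc = by_member.get(group.anchor_id, np.nan)
        for m in group.member_ids:
            loc = by_member.get(m, np.nan)
            flagged = bool(
                m != group.anchor_id
                and abs(anchor_loc) >= effect_threshold
                and group.r2_to_anchor[m] >= high_ld
                and abs(loc) < effect_threshold
            )
            rows.append({
                "feature": feature, "member_id": m,
                "r2_to_anchor": group.r2_to_anchor[m],
                "log_odds_change": loc,
                "divergence": div,
                "anchor_id": group.anchor_id,
                "discordant_high_ld": flagged,
            })
    return pd.DataFrame(rows)
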