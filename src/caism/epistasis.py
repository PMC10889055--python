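"""Case/control validation of candidate SNP pairs.

Two complementary views of a pair:

* carrier-group case proportions — samples dichotomized per locus into
  carrier (>= 1 minor allele) vs non-carrier, and the fraction of cases
  reported in each of the four genotype groups;

* an allele-based epistasis test — within cases and within controls
  separately, the joint 2x2 minor/major allele-pair table is formed for the
  two loci and the log odds ratios compared:

      Z = (ln OR_case - ln OR_control) / sqrt(Var_case + Var_control)

  with a two-sided p-value from the standard normal.  For unphased genotypes
  the joint table uses the expected within-individual allele pairing
  (n_minor,minor = sum g_a * g_b / 2, etc.), the standard allelic
  approximation.  Because the table cells are products of genotype dosages
  rather than 2n independent alleles, the textbook sum-of-inverse-cell
  variance is badly conservative here; each group's Var(ln OR) is instead
  estimated by the delta method over the per-individual contributions
  (g_a g_b, g_a, g_b), which is asymptotically correct without assuming
  Hardy–Weinberg.  Zero cells get the Haldane–Anscombe 0.5 correction and
  are flagged.  A logistic-regression interaction test (Wald, dosage coding)
  is available as a labeled alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class GenotypeTable:
    """Unphased minor-allele dosages plus case/control labels.

    ``dosage`` is samples x variants with entries 0/1/2 and -1 for missing;
    ``phenotype`` is boolean, True = case.  Every retained sample must have a
    phenotype.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=bool)
        ns, nv = self.dosage.shape
        if ns != len(self.sample_ids) or nv != len(self.variant_ids):
            raise ValueError("dosage shape must be (samples, variants)")
        if len(self.phenotype) != ns:
            raise ValueError("phenotype required for every sample")
        if not np.isin(self.dosage, (-1, 0, 1, 2)).all():
            raise ValueError("dosages must be 0/1/2 or -1 for missing")

    def dosages(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not genotyped") from None
        return self.dosage[:, j]

    # -- IO -------------------------------------------------------------

    def save(self, dosage_path: str | Path, pheno_path: str | Path) -> None:
        pd.DataFrame(self.dosage, index=self.sample_ids,
                     columns=self.variant_ids).to_csv(
            dosage_path, sep="\t", index_label="sample_id")
        pd.DataFrame({"sample_id": self.sample_ids,
                      "status": np.where(self.phenotype, "case", "control")}
                     ).to_csv(pheno_path, sep="\t", index=False)

    @classmethod
    def load(cls, dosage_path: str | Path, pheno_path: str | Path) -> "GenotypeTable":
        dos = pd.read_csv(dosage_path, sep="\t", index_col="sample_id")
        ph = pd.read_csv(pheno_path, sep="\t", dtype=str).set_index("sample_id")
        missing = set(dos.index) - set(ph.index)
        if missing:
            raise ValueError(f"samples without phenotype: {sorted(missing)[:5]} ...")
        status = ph.loc[dos.index, "status"].str.lower()
        bad = set(status) - {"case", "control"}
        if bad:
            raise ValueError(f"phenotype status must be case/control, got {bad}")
        return cls(list(dos.index), list(dos.columns),
                   dos.to_numpy(np.int8), (status == "case").to_numpy())

    @classmethod
    def from_vcf(cls, vcf_path: str | Path, pheno_path: str | Path) -> "GenotypeTable":
        from cyvcf2 import VCF

        vcf = VCF(str(vcf_path))
        samples = list(vcf.samples)
        ids, cols = [], []
        for rec in vcf:
            gt = rec.genotype.array()[:, :2]
            col = np.where((gt < 0).any(axis=1), -1, gt.clip(min=0).sum(axis=1))
            ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            cols.append(col.astype(np.int8))
        ph = pd.read_csv(pheno_path, sep="\t", dtype=str).set_index("sample_id")
        status = ph.loc[samples, "status"].str.lower()
        return cls(samples, ids, np.column_stack(cols), (status == "case").to_numpy())


def _complete_cases(gt: GenotypeTable, a: str, b: str):
    ga, gb = gt.dosages(a), gt.dosages(b)
    keep = (ga >= 0) & (gb >= 0)
    return ga[keep], gb[keep], gt.phenotype[keep], int((~keep).sum())


def carrier_group_proportions(gt: GenotypeTable, a: str, b: str) -> pd.DataFrame:
    """Case proportion in each carrier/non-carrier genotype group.

    Rows are the four (carrier_a, carrier_b) groups coded 0/1 for
    absence/presence of at least one minor allele; empty groups report n = 0
    and an undefined (NaN) proportion.  Samples missing either genotype are
    excluded and counted in the frame's ``attrs["n_excluded_missing"]``.
    """
    ga, gb, pheno, n_excl = _complete_cases(gt, a, b)
    ca, cb = (ga >= 1).astype(int), (gb >= 1).astype(int)
    rows = []
    for ia in (0, 1):
        for ib in (0, 1):
            m = (ca == ia) & (cb == ib)
            n = int(m.sum())
            rows.append({
                "carrier_a": ia, "carrier_b": ib, "n": n,
                "n_cases": int(pheno[m].sum()),
                "case_proportion": float(pheno[m].mean()) if n else np.nan,
            })
    out = pd.DataFrame(rows)
    out.attrs["variant_a"] = a
    out.attrs["variant_b"] = b
    out.attrs["n_excluded_missing"] = n_excl
    return out


@dataclass(frozen=True)
class EpistasisResult:
    variant_a: str
    variant_b: str
    z: float
    p_value: float
    ln_or_case: float
    ln_or_control: float
    n_cases: int
    n_controls: int
    n_excluded_missing: int
    zero_cell_corrected: bool
    method: str = "allelic_fast_epistasis"


def _allele_pair_table(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Expected joint 2x2 allele-pair counts [[mm, mM], [Mm, MM]] (m = minor)."""
    ga = ga.astype(float)
    gb = gb.astype(float)
    return 0.5 * np.array([
        [np.sum(ga * gb), np.sum(ga * (2 - gb))],
        [np.sum((2 - ga) * gb), np.sum((2 - ga) * (2 - gb))],
    ])


def _group_lnor(ga: np.ndarray, gb: np.ndarray) -> tuple[float, float, bool]:
    """(ln OR, delta-method variance, zero-cell-corrected) for one group.

    ln OR is from the expected allele-pair table; the variance comes from the
    gradient of ln OR in the per-individual moments (mean g_a g_b, mean g_a,
    mean g_b) with their empirical covariance.
    """
    n = len(ga)
    z = np.column_stack([ga * gb, ga, gb]).astype(float)
    mxy, mx, my = z.mean(axis=0)
    # cells of the expected table, per individual (sum to 4)
    u, v = mxy, 2 * mx - mxy
    t, w = 2 * my - mxy, 4 - 2 * mx - 2 * my + mxy
    corrected = False
    if min(u, v, t, w) <= 0:
        # Haldane–Anscombe: half an allele pair added to each cell
        u, v, t, w = (c + 0.5 / n for c in (u, v, t, w))
        corrected = True
    lnor = float(np.log(u) - np.log(v) - np.log(t) + np.log(w))
    grad = np.array([1 / u + 1 / v + 1 / t + 1 / w,
                     -2 / v - 2 / w,
                     -2 / t - 2 / w])
    cov = np.cov(z, rowvar=False)
    var = float(grad @ cov @ grad) / n
    return lnor, var, corrected


def epistasis_test(gt: GenotypeTable, a: str, b: str) -> EpistasisResult:
    """Allele-based case/control interaction test for one SNP pair.

    Symmetric in (a, b).  Raises for monomorphic loci or a group with fewer
    than two samples; zero cells are 0.5-corrected and flagged.
    """
    ga, gb, pheno, n_excl = _complete_cases(gt, a, b)
    for name, g in ((a, ga), (b, gb)):
        if len(np.unique(g)) < 2:
            raise ValueError(f"variant {name!r} is monomorphic among retained "
                             "samples; epistasis test undefined")
    if pheno.sum() < 2 or (~pheno).sum() < 2:
        raise ValueError("need at least two cases and two controls")
    corrected = False
    lors, variances = [], []
    for mask in (pheno, ~pheno):
        lnor, var, corr = _group_lnor(ga[mask], gb[mask])
        lors.append(lnor)
        variances.append(var)
        corrected |= corr
    z = (lors[0] - lors[1]) / np.sqrt(variances[0] + variances[1])
    return EpistasisResult(
        variant_a=a, variant_b=b, z=float(z),
        p_value=float(2 * norm.sf(abs(z))),
        ln_or_case=float(lors[0]), ln_or_control=float(lors[1]),
        n_cases=int(pheno.sum()), n_controls=int((~pheno).sum()),
        n_excluded_missing=n_excl, zero_cell_corrected=corrected,
    )


def logistic_interaction_test(gt: GenotypeTable, a: str, b: str) -> EpistasisResult:
    """Labeled alternative: logistic regression Wald test of g_a x g_b.

    Fits logit P(case) = b0 + b1 g_a + b2 g_b + b3 g_a g_b on dosages and
    tests b3 = 0.
    """
    import statsmodels.api as sm

    ga, gb, pheno, n_excl = _complete_cases(gt, a, b)
    X = sm.add_constant(np.column_stack([ga, gb, ga * gb]).astype(float))
    fit = sm.Logit(pheno.astype(float), X).fit(disp=False)
    z = float(fit.params[3] / fit.bse[3])
    return EpistasisResult(
        variant_a=a, variant_b=b, z=z, p_value=float(2 * norm.sf(abs(z))),
        ln_or_case=float(fit.params[3]), ln_or_control=0.0,
        n_cases=int(pheno.sum()), n_controls=int((~pheno).sum()),
        n_excluded_missing=n_excl, zero_cell_corrected=False,
        method="logistic_interaction",
    )
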