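"""Ground-truth synthetic inputs for the whole pipeline.

Everything the analysis consumes can be generated here from a single seed:
a reference genome with motif instances planted at declared variant
positions, the variant table, a motif-occupancy annotator spec whose planted
effects are known in closed form, phased haplotypes with tunable pairwise r²,
and a case/control cohort with a planted gene–gene interaction.  The
generator also emits a machine-readable answer key (which variant/feature
pairs truly have an effect, which pairs truly interact) so downstream checks
compare against construction, not against the pipeline itself.

Planting logic
--------------
A planted site ties one motif to one variant: the motif instance is written
into the background sequence so the variant position falls at a declared
offset inside it.  If the motif is "present with major", the reference genome
carries a complete instance and the minor allele destroys it (loss of
function); if "present with minor", the reference carries a one-base-broken
instance that the minor allele completes (gain of function).

After planting, the background is sanitized: every other position of the
genome is pushed to Hamming distance >= 2 from every motif (and reverse
complement) used by the annotator.  A single-nucleotide substitution can
close at most one mismatch, so no background variant — and no unintended
allele of a candidate variant — can create or destroy a motif match anywhere
outside the planted footprints.  Planted scores are therefore exact integers
and background E statistics for motif features are exactly zero.

LD is induced by a two-component mixture: the partner column copies the
anchor with probability sqrt(r²_target) and is drawn independently otherwise,
giving exact control of expected pairwise r² without a coalescent simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logit as _logit

from .annotator import FeatureSpec, SyntheticAnnotator
from .epistasis import GenotypeTable
from .ld_analysis import HaplotypeMatrix
from .sequence_windows import Genome, Variant, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """One motif instance anchored at a variant position."""

    variant_id: str
    motif: str
    present_allele: str  # which allele completes the motif: "major" | "minor"
    motif_offset: int = 4  # 0-based index of the variant within the motif

    def __post_init__(self) -> None:
        if self.present_allele not in ("major", "minor"):
            raise ValueError(f"present_allele must be major/minor, got {self.present_allele!r}")
        if not (0 <= self.motif_offset < len(self.motif)):
            raise ValueError("motif_offset outside motif")


@dataclass(frozen=True)
class PlantedFeature:
    """One annotator feature and the sites (0, 1 or 2) that drive it."""

    name: str
    mode: str  # single | cooperative
    motifs: tuple[str, ...]
    sites: tuple[PlantedSite, ...] = ()

    def __post_init__(self) -> None:
        if self.mode == "single" and len(self.motifs) != 1:
            raise ValueError(f"{self.name}: single mode needs 1 motif")
        if self.mode == "cooperative" and len(self.motifs) != 2:
            raise ValueError(f"{self.name}: cooperative mode needs 2 motifs")
        for s in self.sites:
            if s.motif not in self.motifs:
                raise ValueError(f"{self.name}: site motif {s.motif!r} not declared")


@dataclass(frozen=True)
class CohortSpec:
    """Logistic disease model for the synthetic case/control cohort."""

    n_samples: int = 2000
    baseline_rate: float = 0.35
    main_or: dict = field(default_factory=dict)         # variant id -> OR per allele
    interactions: tuple = ()                            # (id_a, id_b, OR) triples


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete, single-seed description of a synthetic study."""

    seed: int = 7
    contig_name: str = "chr1"
    contig_length: int = 120_000
    L: int = 2000
    steepness: float = 4.0
    offset: float = 0.5
    default_maf: float = 0.3
    n_haplotypes: int = 2000
    variants: tuple[Variant, ...] = ()
    features: tuple[PlantedFeature, ...] = ()
    ld_pairs: tuple = ()                                # (id_a, id_b, target_r2)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def variant(self, vid: str) -> Variant:
        for v in self.variants:
            if v.id == vid:
                return v
        raise KeyError(vid)


# ---------------------------------------------------------------------------
# the default scenario
# ---------------------------------------------------------------------------

# Non-palindromic 10-mers, pairwise far apart in Hamming distance, used as
# planted and decoy motifs.  Position 4 of each overlaps its variant.
_MOTIF_LOF = "ATCGATTACG"      # complete with major allele of rs_lof
_MOTIF_COOP_C = "GGATCCGTTA"   # completed by minor allele of rs_coop_center
_MOTIF_COOP_N = "TTGACGCAAT"   # completed by minor allele of rs_coop_neighbor
_MOTIF_LD = "CCTAAGGTCA"       # complete with major allele of rs_ld_anchor
_DECOY_MOTIFS = {
    "DNase_NHA": "AGGCTTAACG",
    "DNase_monocyte_CD14": "CATGGACTTG",
    "H3K27ac_astrocyte": "TCCAGATGCA",
    "H3K23ac_NPC": "GTACCTGAAC",
    "CTCF_neuron": "ACTGGTACGT",
}


def default_scenario(seed: int = 7) -> ScenarioSpec:
    """The default study: one dominant loss-of-function variant, one
    cooperative (context-dependent) pair, one high-LD pair with divergent
    effects, and a protective epistatic pair in the cohort.

    Major/minor alleles are chosen so that the motif base at each planted
    site belongs to the allele declared to complete it.
    """
    def other(base: str) -> str:
        return "T" if base != "T" else "A"

    v_lof = Variant("rs_lof", "chr1", 10_000, major=_MOTIF_LOF[4],
                    minor=other(_MOTIF_LOF[4]), maf=0.25)
    v_coop_c = Variant("rs_coop_center", "chr1", 30_000,
                       major=other(_MOTIF_COOP_C[4]), minor=_MOTIF_COOP_C[4],
                       maf=0.2)
    v_coop_n = Variant("rs_coop_neighbor", "chr1", 30_400,
                       major=other(_MOTIF_COOP_N[4]), minor=_MOTIF_COOP_N[4],
                       maf=0.3)
    v_ld_a = Variant("rs_ld_anchor", "chr1", 50_000, major=_MOTIF_LD[4],
                     minor=other(_MOTIF_LD[4]), maf=0.3)
    v_ld_b = Variant("rs_ld_partner", "chr1", 50_300, major="A", minor="G",
                     maf=0.3)
    v_null1 = Variant("rs_null_1", "chr1", 70_000, major="C", minor="T", maf=0.4)
    v_null2 = Variant("rs_null_2", "chr1", 90_000, major="G", minor="A", maf=0.15)

    features = (
        PlantedFeature(
            "DNase_glioblastoma", "single", (_MOTIF_LOF,),
            (PlantedSite("rs_lof", _MOTIF_LOF, "major"),),
        ),
        PlantedFeature(
            "CTCF_glioblastoma", "cooperative", (_MOTIF_COOP_C, _MOTIF_COOP_N),
            (PlantedSite("rs_coop_center", _MOTIF_COOP_C, "minor"),
             PlantedSite("rs_coop_neighbor", _MOTIF_COOP_N, "minor")),
        ),
        PlantedFeature(
            "H3K18ac_NPC", "single", (_MOTIF_LD,),
            (PlantedSite("rs_ld_anchor", _MOTIF_LD, "major"),),
        ),
    ) + tuple(
        PlantedFeature(name, "single", (motif,))
        for name, motif in _DECOY_MOTIFS.items()
    )

    return ScenarioSpec(
        seed=seed,
        variants=(v_lof, v_coop_c, v_coop_n, v_ld_a, v_ld_b, v_null1, v_null2),
        features=features,
        ld_pairs=(("rs_ld_anchor", "rs_ld_partner", 0.98),
                  ("rs_coop_center", "rs_coop_neighbor", 0.5)),
        cohort=CohortSpec(
            n_samples=2000, baseline_rate=0.35,
            main_or={"rs_coop_center": 0.6, "rs_coop_neighbor": 0.7},
            interactions=(("rs_coop_center", "rs_coop_neighbor", 0.5),),
        ),
    )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _all_patterns(spec: ScenarioSpec) -> list[str]:
    pats = []
    for f in spec.features:
        for m in f.motifs:
            for p in (m, revcomp(m)):
                if p not in pats:
                    pats.append(p)
    return pats


def make_genome(spec: ScenarioSpec) -> Genome:
    """Random background with planted motif instances; byte-deterministic.

    Raises if planted motifs overlap contradictorily, if a window would run
    off the contig, or if a planted site's motif base disagrees with the
    allele declared to complete it.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.contig_length
    arr = rng.choice(_BASES, size=n)

    margin = spec.L  # ample room for windows around every variant
    written: dict[int, str] = {}
    footprints: list[tuple[int, int]] = []
    for feat in spec.features:
        for site in feat.sites:
            v = spec.variant(site.variant_id)
            if site.motif[site.motif_offset] != v.allele(site.present_allele):
                raise ValueError(
                    f"{feat.name}/{v.id}: motif base "
                    f"{site.motif[site.motif_offset]!r} does not match the "
                    f"{site.present_allele} allele {v.allele(site.present_allele)!r}"
                )
            start = v.pos - 1 - site.motif_offset
            if start < margin or start + len(site.motif) > n - margin:
                raise ValueError(f"{v.id}: planted motif too close to contig edge")
            for j, base in enumerate(site.motif):
                gpos = start + j
                if written.get(gpos, base) != base:
                    raise ValueError(
                        f"overlapping planted motifs contradict at {gpos}: "
                        f"{written[gpos]!r} vs {base!r}")
                written[gpos] = base
                arr[gpos] = base
            footprints.append((start, start + len(site.motif)))
    for v in spec.variants:
        if not (margin <= v.pos - 1 < n - margin):
            raise ValueError(f"{v.id}: variant too close to contig edge")
        gpos = v.pos - 1
        if gpos in written and written[gpos] != v.major:
            # a minor-completed site: reference intentionally breaks the motif
            pass
        arr[gpos] = v.major

    protected = np.zeros(n, dtype=bool)
    for s, e in footprints:
        protected[s:e] = True
    for v in spec.variants:
        protected[v.pos - 1] = True

    _sanitize(arr, _all_patterns(spec), protected, rng)
    return Genome({spec.contig_name: "".join(arr)})


def _sanitize(arr: np.ndarray, patterns: Sequence[str], protected: np.ndarray,
              rng: np.random.Generator, max_rounds: int = 20) -> None:
    """Push every unprotected window to Hamming distance >= 2 from every pattern."""
    n = len(arr)
    for _ in range(max_rounds):
        dirty = False
        for pat in patterns:
            m = len(pat)
            mism = np.zeros(n - m + 1, dtype=np.int32)
            for j, ch in enumerate(pat):
                mism += arr[j:n - m + 1 + j] != ch
            for start in np.flatnonzero(mism <= 1):
                if protected[start:start + m].any():
                    continue
                # mutate one agreeing, unprotected position
                cands = [j for j in range(m)
                         if arr[start + j] == pat[j] and not protected[start + j]]
                if not cands:
                    continue
                j = int(rng.choice(cands))
                choices = [b for b in "ACGT"
                           if b != arr[start + j] and b != pat[j]]
                arr[start + j] = rng.choice(choices)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("sanitization did not converge; motifs too repetitive")


def make_annotator(spec: ScenarioSpec) -> SyntheticAnnotator:
    """The scenario's deterministic motif-occupancy annotator."""
    feats = [FeatureSpec(name=f.name, mode=f.mode, motifs=f.motifs)
             for f in spec.features]
    return SyntheticAnnotator(feats, L=spec.L, steepness=spec.steepness,
                              offset=spec.offset, strand_symmetric=True)


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def make_haplotypes(spec: ScenarioSpec) -> HaplotypeMatrix:
    """Phased haplotypes realizing the declared pairwise r² targets.

    Partner columns copy the anchor with probability sqrt(r²_target), else
    are drawn independently at the same minor-allele frequency; unpaired
    variants are independent draws at their own frequency.
    """
    if spec.n_haplotypes < 100:
        raise ValueError("need at least 100 haplotypes")
    rng = np.random.default_rng(spec.seed + 1)
    paired: dict[str, tuple[str, float]] = {}
    seen: set[str] = set()
    for a, b, r2 in spec.ld_pairs:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"target r² must be in [0,1], got {r2}")
        if a in seen or b in seen:
            raise ValueError(
                f"variant in multiple LD pairs ({a}, {b}); joint targets "
                "are not supported")
        seen |= {a, b}
        paired[b] = (a, r2)

    cols: dict[str, np.ndarray] = {}
    H = spec.n_haplotypes
    for v in spec.variants:
        if v.id in paired:
            continue
        maf = v.maf if v.maf is not None else spec.default_maf
        cols[v.id] = (rng.random(H) < maf).astype(np.int8)
    for b, (a, r2) in paired.items():
        vb = spec.variant(b)
        maf = vb.maf if vb.maf is not None else spec.default_maf
        copy = rng.random(H) < np.sqrt(r2)
        fresh = (rng.random(H) < maf).astype(np.int8)
        cols[b] = np.where(copy, cols[a], fresh).astype(np.int8)

    ids = [v.id for v in spec.variants]
    return HaplotypeMatrix(ids, np.column_stack([cols[i] for i in ids]))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_pair_cohort(
    n_samples: int,
    maf_a: float,
    maf_b: float,
    baseline_rate: float,
    or_a: float = 1.0,
    or_b: float = 1.0,
    or_interaction: float = 1.0,
    seed: int = 0,
    ids: tuple[str, str] = ("snpA", "snpB"),
) -> GenotypeTable:
    """Two-locus case/control cohort under a logistic disease model.

    logit P(case) = logit(baseline) + ln(or_a) g_a + ln(or_b) g_b
                    + ln(or_interaction) g_a g_b,
    with Hardy–Weinberg genotypes at the given minor-allele frequencies.
    Used both for the default scenario and for power / type-I simulation
    studies.
    """
    for name, x in (("maf_a", maf_a), ("maf_b", maf_b)):
        if not (0.0 < x < 1.0):
            raise ValueError(f"{name} must be in (0,1), got {x}")
    if not (0.0 < baseline_rate < 1.0):
        raise ValueError("baseline_rate must be in (0,1)")
    for name, x in (("or_a", or_a), ("or_b", or_b),
                    ("or_interaction", or_interaction)):
        if x <= 0:
            raise ValueError(f"{name} must be > 0")
    rng = np.random.default_rng(seed)
    ga = rng.binomial(2, maf_a, size=n_samples)
    gb = rng.binomial(2, maf_b, size=n_samples)
    eta = (_logit(baseline_rate) + np.log(or_a) * ga + np.log(or_b) * gb
           + np.log(or_interaction) * ga * gb)
    case = rng.random(n_samples) < 1.0 / (1.0 + np.exp(-eta))
    return GenotypeTable(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        variant_ids=list(ids),
        dosage=np.column_stack([ga, gb]).astype(np.int8),
        phenotype=case,
    )


def make_cohort(spec: ScenarioSpec) -> GenotypeTable:
    """Scenario cohort over all variants with the declared disease model."""
    c = spec.cohort
    rng = np.random.default_rng(spec.seed + 2)
    ids = [v.id for v in spec.variants]
    mafs = np.array([v.maf if v.maf is not None else spec.default_maf
                     for v in spec.variants])
    dos = rng.binomial(2, mafs, size=(c.n_samples, len(ids)))
    eta = np.full(c.n_samples, _logit(c.baseline_rate))
    for vid, orr in c.main_or.items():
        eta += np.log(orr) * dos[:, ids.index(vid)]
    for a, b, orr in c.interactions:
        eta += np.log(orr) * dos[:, ids.index(a)] * dos[:, ids.index(b)]
    case = rng.random(c.n_samples) < 1.0 / (1.0 + np.exp(-eta))
    return GenotypeTable([f"s{i}" for i in range(c.n_samples)], ids,
                         dos.astype(np.int8), case)


# ---------------------------------------------------------------------------
# ground truth + scenario output
# ---------------------------------------------------------------------------

def answer_key(spec: ScenarioSpec) -> dict:
    """Closed-form ground truth: expected no-context log-odds changes, the
    cooperative margin, the designated null variants, LD targets and the
    truly interacting cohort pairs."""
    k = spec.steepness
    effects: dict[str, dict[str, float]] = {}
    context_dependent: dict[str, dict] = {}
    for feat in spec.features:
        if not feat.sites:
            continue
        if feat.mode == "single":
            site = feat.sites[0]
            # ref score is 1 when the major allele completes the motif
            s_ref = 1.0 if site.present_allele == "major" else 0.0
            s_alt = 1.0 - s_ref
            effects.setdefault(site.variant_id, {})[feat.name] = k * (s_ref - s_alt)
        else:  # cooperative: site 0 = center motif M1, site 1 = neighbor motif M2
            c_site, n_site = feat.sites
            c1_ref = 1.0 if c_site.present_allele == "major" else 0.0
            c1_alt = 1.0 - c1_ref
            c2_nmaj = 1.0 if n_site.present_allele == "major" else 0.0
            loc_nmaj = k * (1.0 + c2_nmaj) * (c1_ref - c1_alt)
            loc_nmin = k * (2.0 - c2_nmaj) * (c1_ref - c1_alt)
            effects.setdefault(c_site.variant_id, {})[feat.name] = loc_nmaj
            context_dependent[c_site.variant_id] = {
                "feature": feat.name,
                "neighbor": n_site.variant_id,
                "loc_neighbor_major": loc_nmaj,
                "loc_neighbor_minor": loc_nmin,
                "margin": abs(loc_nmin) - abs(loc_nmaj),  # = steepness
            }
    nulls = [v.id for v in spec.variants if v.id not in effects]
    dominant = [vid for vid in effects if vid not in context_dependent]
    # a cooperative neighbor acquires an effect of its own once the center
    # carries minor in its context set, so it is flagged by the full
    # with-context pipeline despite being null in the no-context analysis
    flagged = sorted(set(effects)
                     | {d["neighbor"] for d in context_dependent.values()})
    return {
        "expected_flagged_with_context": flagged,
        "expected_log_odds_change": effects,
        "context_dependent": context_dependent,
        "dominant_variants": dominant,
        "null_variants": nulls,
        "ld_pairs": [{"anchor": a, "partner": b, "target_r2": r2}
                     for a, b, r2 in spec.ld_pairs],
        "interacting_pairs": [{"a": a, "b": b, "interaction_or": orr}
                              for a, b, orr in spec.cohort.interactions],
        "steepness": k,
    }


def candidate_exclusion_zones(spec: ScenarioSpec) -> list[tuple[str, int, int]]:
    """0-based half-open spans (one window around each candidate variant)
    excluded from background sampling, so the background null measures
    genuinely unplanted positions."""
    from .sequence_windows import window_span

    zones = []
    for v in spec.variants:
        s, e = window_span(v.pos, spec.L)
        zones.append((v.chrom, max(0, s - spec.L // 2), e + spec.L // 2))
    return zones


def write_scenario(spec: ScenarioSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialize every pipeline input plus the answer key; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = make_genome(spec)
    paths = {
        "fasta": outdir / "reference.fa",
        "variants": outdir / "variants.tsv",
        "haplotypes": outdir / "haplotypes.tsv",
        "phased_vcf": outdir / "haplotypes.vcf",
        "dosages": outdir / "cohort_dosages.tsv",
        "phenotypes": outdir / "cohort_phenotypes.tsv",
        "annotator": outdir / "annotator.yaml",
        "feature_subset": outdir / "feature_subset.txt",
        "answer_key": outdir / "answer_key.json",
        "scenario": outdir / "scenario.json",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{spec.contig_name}\n")
        seq = genome.extract(spec.contig_name, 0, spec.contig_length)
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")

    import pandas as pd
    pd.DataFrame([{
        "id": v.id, "chrom": v.chrom, "pos": v.pos,
        "major": v.major, "minor": v.minor, "maf": v.maf,
    } for v in spec.variants]).to_csv(paths["variants"], sep="\t", index=False)

    hap = make_haplotypes(spec)
    hap.save(paths["haplotypes"])
    _write_phased_vcf(spec, hap, paths["phased_vcf"])

    cohort = make_cohort(spec)
    cohort.save(paths["dosages"], paths["phenotypes"])

    annot = make_annotator(spec)
    annot.save(paths["annotator"])
    subset = [f.name for f in spec.features][:max(3, len(spec.features) - 2)]
    paths["feature_subset"].write_text("\n".join(subset) + "\n")
    paths["answer_key"].write_text(json.dumps(answer_key(spec), indent=2))
    paths["scenario"].write_text(json.dumps(
        {"seed": spec.seed, "contig": spec.contig_name,
         "contig_length": spec.contig_length, "L": spec.L,
         "steepness": spec.steepness, "offset": spec.offset,
         "n_haplotypes": spec.n_haplotypes,
         "cohort": asdict(spec.cohort) | {"interactions": list(map(list, spec.cohort.interactions))},
         "ld_pairs": list(map(list, spec.ld_pairs))}, indent=2))
    return paths


def _write_phased_vcf(spec: ScenarioSpec, hap: HaplotypeMatrix,
                      path: Path) -> None:
    """Minimal phased VCF: two haplotype columns per synthetic sample,
    REF = major, ALT = minor."""
    n_samples = hap.n_haplotypes // 2
    samples = [f"h{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={spec.contig_name},length={spec.contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = sorted(range(len(spec.variants)),
                       key=lambda i: spec.variants[i].pos)
        for i in order:
            v = spec.variants[i]
            col = hap.column(v.id)
            gts = "\t".join(f"{col[2 * s]}|{col[2 * s + 1]}"
                            for s in range(n_samples))
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.major}\t{v.minor}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")
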