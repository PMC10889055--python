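"""Fixed-length sequence windows around variants, with controlled allele substitution.

The in-silico mutagenesis procedure operates on 2000-bp windows centered on a
candidate SNV: the reference window carries the major allele at every known
variant position, and alternate windows substitute minor alleles at the center
and/or at neighboring variants inside the window.  Window geometry for a center
at 1-based position ``p`` with length ``L`` covers 1-based positions
``[p - (L-1)//2, p + L - 1 - (L-1)//2]`` — for the default L = 2000 that is
999 bp upstream and 1000 bp downstream, center at 0-based offset 999.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

NUCLEOTIDES = frozenset("ACGT")
_VALID_CHARS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class WindowBoundaryError(ValueError):
    """Window would run off the end of the contig."""


class NeighborOutsideWindowError(ValueError):
    """A declared neighbor does not fall inside the window span."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNV with major/minor alleles and optional GWAS metadata.

    Positions are 1-based genomic coordinates (VCF convention).  ``major`` is
    the population-major allele used to build reference windows; ``minor`` is
    substituted in alternate windows.  The minor-allele frequency, when known,
    must be ≤ 0.5 by definition.
    """

    id: str
    chrom: str
    pos: int
    major: str
    minor: str
    maf: float | None = None
    gwas_p: float | None = None
    gwas_beta: float | None = None

    def __post_init__(self) -> None:
        if self.major not in NUCLEOTIDES or self.minor not in NUCLEOTIDES:
            raise ValueError(
                f"{self.id}: alleles must be single nucleotides in ACGT, "
                f"got major={self.major!r} minor={self.minor!r} (SNVs only)"
            )
        if self.major == self.minor:
            raise ValueError(f"{self.id}: major and minor alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.id}: maf must be in (0, 0.5], got {self.maf}")

    def allele(self, which: str) -> str:
        if which not in ("major", "minor"):
            raise ValueError(f"allele choice must be 'major' or 'minor', got {which!r}")
        return self.major if which == "major" else self.minor


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-length nucleotide window with a designated center variant.

    ``origin`` is ``(chrom, start)`` with ``start`` the 0-based genomic
    coordinate of ``seq[0]``; ``carried_alleles`` records which allele
    (``"major"``/``"minor"``) each variant inside the window carries, always
    reported on the forward strand regardless of ``strand``.
    """

    seq: str
    center_offset: int
    center_id: str
    carried_alleles: Mapping[str, str]
    origin: tuple[str, int]
    strand: str = "+"
    flags: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """Read-only indexed genome backed by a FASTA file.

    Substring extraction uses 0-based half-open coordinates.  Sequences are
    validated at load time: any character outside A/C/G/T/N is rejected with
    the contig name and offset.
    """

    def __init__(self, contigs: dict[str, str]):
        for name, seq in contigs.items():
            bad = re.search(f"[^{''.join(sorted(_VALID_CHARS))}]", seq)
            if bad:
                raise ValueError(
                    f"contig {name!r}: invalid character {bad.group()!r} "
                    f"at 0-based offset {bad.start()}"
                )
        self._contigs = contigs

    @property
    def contig_names(self) -> list[str]:
        return list(self._contigs)

    def contig_length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def extract(self, chrom: str, start: int, end: int) -> str:
        """Substring of a contig, 0-based half-open [start, end)."""
        if chrom not in self._contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        if start < 0 or end > len(self._contigs[chrom]) or start > end:
            raise WindowBoundaryError(
                f"[{start}, {end}) outside contig {chrom!r} "
                f"of length {len(self._contigs[chrom])}"
            )
        return self._contigs[chrom][start:end]

    def base(self, chrom: str, pos1: int) -> str:
        """Single base at a 1-based position."""
        return self.extract(chrom, pos1 - 1, pos1)


def load_reference(fasta_path: str | Path) -> Genome:
    """Load and validate a reference genome from FASTA.

    A ``.fai`` sidecar index is created if absent.  Duplicate contig names and
    non-IUPAC characters (anything outside A/C/G/T/N, case-insensitive) are
    rejected.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True,
               duplicate_action="stop")
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return Genome(contigs)


def load_variants(path: str | Path) -> list[Variant]:
    """Load biallelic SNVs from a tab-delimited table or a VCF.

    Tab-delimited input needs columns ``id, chrom, pos, major, minor`` and
    optionally ``maf, gwas_p, gwas_beta``.  VCF input (``.vcf``/``.vcf.gz``)
    takes REF as the major allele unless INFO/AF > 0.5, in which case ALT is
    major.  Indels and multiallelic records are rejected.
    """
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _load_variants_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "pos", "major", "minor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    variants = []
    for row in df.itertuples(index=False):
        variants.append(Variant(
            id=str(row.id), chrom=str(row.chrom), pos=int(row.pos),
            major=str(row.major), minor=str(row.minor),
            maf=_opt_float(getattr(row, "maf", None)),
            gwas_p=_opt_float(getattr(row, "gwas_p", None)),
            gwas_beta=_opt_float(getattr(row, "gwas_beta", None)),
        ))
    _check_unique_ids(variants)
    return variants


def _opt_float(x) -> float | None:
    if x is None or pd.isna(x):
        return None
    return float(x)


def _load_variants_vcf(path: Path) -> list[Variant]:
    from cyvcf2 import VCF

    variants = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(
                f"{rec.ID or rec.POS}: only biallelic SNVs are supported "
                f"(REF={rec.REF}, ALT={rec.ALT})"
            )
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        af = rec.INFO.get("AF")
        if af is not None and float(af) > 0.5:
            major, minor, maf = alt, ref, 1.0 - float(af)
        else:
            major, minor = ref, alt
            maf = float(af) if af is not None else None
        variants.append(Variant(
            id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            chrom=rec.CHROM, pos=rec.POS, major=major, minor=minor,
            maf=maf if (maf is None or maf > 0) else None,
        ))
    _check_unique_ids(variants)
    return variants


def _check_unique_ids(variants: Iterable[Variant]) -> None:
    seen: set[str] = set()
    for v in variants:
        if v.id in seen:
            raise ValueError(f"duplicate variant id {v.id!r}")
        seen.add(v.id)


def window_span(pos: int, L: int) -> tuple[int, int]:
    """0-based half-open genomic span of the window centered at 1-based pos."""
    up = (L - 1) // 2
    start = pos - 1 - up
    return start, start + L


def center_offset(L: int) -> int:
    """0-based offset of the center position within a length-L window."""
    return (L - 1) // 2


def build_window(
    genome: Genome,
    center: Variant,
    neighbors: list[Variant] | None = None,
    allele_choice: Mapping[str, str] | None = None,
    L: int = 2000,
) -> SequenceWindow:
    """Build one allele-substituted window centered on a variant.

    Every variant (center and neighbors) is set to the allele named in
    ``allele_choice`` (``"major"``/``"minor"``); variants not listed default to
    major, so an empty choice yields the all-major reference window.  Declared
    alleles always win: if the assembly base at a variant position matches
    neither allele the substitution still proceeds and the window is flagged
    ``ref_mismatch:<id>``.  Windows containing N are flagged ``contains_N``.
    """
    neighbors = neighbors or []
    allele_choice = dict(allele_choice or {})

    known = {center.id} | {v.id for v in neighbors}
    unknown = set(allele_choice) - known
    if unknown:
        raise ValueError(f"allele_choice names unknown variants: {sorted(unknown)}")
    for v in neighbors:
        if v.chrom != center.chrom:
            raise ValueError(
                f"neighbor {v.id} on {v.chrom} but center {center.id} on {center.chrom}"
            )

    start, end = window_span(center.pos, L)
    if start < 0 or end > genome.contig_length(center.chrom):
        raise WindowBoundaryError(
            f"window [{start}, {end}) for {center.id} at {center.chrom}:{center.pos} "
            f"exceeds contig of length {genome.contig_length(center.chrom)}"
        )

    seq = list(genome.extract(center.chrom, start, end))
    flags: set[str] = set()
    carried: dict[str, str] = {}
    for v in [center] + neighbors:
        off = v.pos - 1 - start
        if not (0 <= off < L):
            raise NeighborOutsideWindowError(
                f"neighbor {v.id} at {v.chrom}:{v.pos} outside window "
                f"[{start + 1}, {end}] of {center.id}"
            )
        choice = allele_choice.get(v.id, "major")
        if seq[off] not in (v.major, v.minor):
            flags.add(f"ref_mismatch:{v.id}")
        seq[off] = v.allele(choice)
        carried[v.id] = choice

    out = "".join(seq)
    if "N" in out:
        flags.add("contains_N")
    return SequenceWindow(
        seq=out,
        center_offset=center_offset(L),
        center_id=center.id,
        carried_alleles=carried,
        origin=(center.chrom, start),
        flags=frozenset(flags),
    )


def reverse_complement_window(w: SequenceWindow) -> SequenceWindow:
    """Reverse-complement a window; an involution.

    ``center_offset`` is remapped to ``L - 1 - center_offset``;
    ``carried_alleles`` keep reporting alleles on the original forward strand.
    """
    return replace(
        w,
        seq=revcomp(w.seq),
        center_offset=len(w.seq) - 1 - w.center_offset,
        strand="-" if w.strand == "+" else "+",
    )


def write_windows_fasta(windows: list[SequenceWindow], labels: list[str],
                        path: str | Path) -> None:
    """Write windows as FASTA with ``id|label|allele-choice`` headers."""
    if len(windows) != len(labels):
        raise ValueError("one label per window required")
    with open(path, "w") as fh:
        for w, label in zip(windows, labels):
            choice = ",".join(f"{k}={v}" for k, v in w.carried_alleles.items())
            fh.write(f">{w.center_id}|{label}|{choice}\n")
            for i in range(0, len(w.seq), 80):
                fh.write(w.seq[i:i + 80] + "\n")
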