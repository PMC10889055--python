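"""Enumeration of genetic contexts: all major/minor combinations of neighbors.

A "context" fixes the allele carried by every neighboring variant inside the
scoring window while the center allele is contrasted major vs minor.  For k
neighbors there are exactly 2^k contexts; enumeration is deterministic
(lexicographic over neighbors sorted by genomic position, major < minor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .sequence_windows import Genome, SequenceWindow, Variant, build_window

DEFAULT_MAX_NEIGHBORS = 12


class ContextExplosionError(ValueError):
    """Too many neighbors for exhaustive enumeration."""


@dataclass(frozen=True)
class ContextAssignment:
    """One point of the {major,minor}^k context lattice for a center variant.

    ``neighbor_alleles`` is ordered by genomic position ascending.  ``label``
    is a bijective string encoding used as a join key throughout reporting.
    """

    center_id: str
    center_allele: str
    neighbor_alleles: tuple[tuple[str, str], ...]

    @property
    def label(self) -> str:
        parts = [f"center={self.center_allele}"]
        parts += [f"{nid}={allele}" for nid, allele in self.neighbor_alleles]
        return ";".join(parts)

    def allele_choice(self) -> dict[str, str]:
        """Mapping variant id -> allele, suitable for build_window."""
        out = {self.center_id: self.center_allele}
        out.update(dict(self.neighbor_alleles))
        return out


def parse_context_label(label: str, center_id: str) -> ContextAssignment:
    """Invert ``ContextAssignment.label`` (round-trip exact)."""
    parts = label.split(";")
    head, center_allele = parts[0].split("=")
    if head != "center":
        raise ValueError(f"malformed context label: {label!r}")
    neighbor_alleles = tuple(tuple(p.split("=", 1)) for p in parts[1:])
    return ContextAssignment(center_id, center_allele, neighbor_alleles)  # type: ignore[arg-type]


def enumerate_contexts(
    center: Variant,
    neighbors: list[Variant],
    center_allele: str = "minor",
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
) -> list[ContextAssignment]:
    """All 2^k major/minor assignments over the neighbors, center fixed.

    Refuses with :class:`ContextExplosionError` when k exceeds
    ``max_neighbors`` (default 12, i.e. 4096 sequences): exhaustive
    enumeration grows exponentially and a loud refusal beats silent
    truncation.  The first assignment is all-major and the last all-minor.
    """
    if center_allele not in ("major", "minor"):
        raise ValueError(f"center_allele must be 'major' or 'minor', got {center_allele!r}")
    if max_neighbors < 0:
        raise ValueError("max_neighbors must be >= 0")
    ids = [v.id for v in neighbors]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate neighbor ids")
    if center.id in ids:
        raise ValueError("center listed among its own neighbors")
    k = len(neighbors)
    if k > max_neighbors:
        raise ContextExplosionError(
            f"{k} neighbors of {center.id} would produce 2^{k} = {2 ** k} contexts "
            f"(cap: {max_neighbors}); restrict the neighbor list or raise the cap"
        )
    ordered = sorted(neighbors, key=lambda v: (v.pos, v.id))
    out = []
    for combo in itertools.product(("major", "minor"), repeat=k):
        out.append(ContextAssignment(
            center_id=center.id,
            center_allele=center_allele,
            neighbor_alleles=tuple(zip((v.id for v in ordered), combo)),
        ))
    return out


def contexts_to_windows(
    genome: Genome,
    center: Variant,
    neighbors: list[Variant],
    assignments: list[ContextAssignment],
    L: int = 2000,
) -> list[SequenceWindow]:
    """One allele-substituted window per context assignment, order preserved."""
    return [
        build_window(genome, center, neighbors, a.allele_choice(), L=L)
        for a in assignments
    ]


def observed_contexts(
    assignments: list[ContextAssignment],
    haplotypes: "HaplotypeMatrix",  # noqa: F821 - forward ref, ld_analysis
) -> list[ContextAssignment]:
    """Restrict enumerated contexts to neighbor-allele patterns observed in
    phased haplotypes.

    Exhaustive enumeration includes combinations that may not exist in any
    real haplotype; when a phased matrix is available the context set can be
    limited to observed patterns.  Neighbors absent from the matrix are left
    unconstrained.
    """
    import numpy as np

    keep = []
    for a in assignments:
        ids = [nid for nid, _ in a.neighbor_alleles
               if nid in haplotypes.variant_ids]
        if not ids:
            keep.append(a)
            continue
        want = np.array([1 if dict(a.neighbor_alleles)[nid] == "minor" else 0
                         for nid in ids])
        cols = haplotypes.columns(ids)
        if np.any(np.all(cols == want, axis=1)):
            keep.append(a)
    return keep
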