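"""Sequence -> chromatin-feature-probability annotators.

The scoring contract is deliberately small: an annotator declares a fixed
input length and an ordered feature list, and maps a nucleotide string to one
probability per feature, deterministically.  The pipeline treats any object
honoring this contract as interchangeable; shipping a pretrained deep model is
out of scope, so the package provides a synthetic annotator whose ground truth
is known by construction.

The synthetic annotator scores motif occupancy.  Each feature is one of:

``single``
    raw score s = number of occurrences of its motif in the window
    (both strands when strand-symmetric).

``cooperative``
    two motifs M1, M2 combined as s = count(M1) * (1 + count(M2)):
    M2 occupancy doubles M1's contribution, so the effect of an allele that
    creates/destroys M1 genuinely depends on whether M2 is present — a planted
    haplotype-context effect.

``dense``
    a seeded per-position, per-base affinity landscape; s is the sum of
    weights over the window.  Every substitution shifts s by a continuous
    amount, which makes this mode the right null model for calibration
    studies of the empirical e-value machinery.

The raw score is squashed to a probability by a logistic function
p = sigmoid(steepness * (s - offset)), then clamped to [1e-6, 1 - 1e-6] so
logits are always finite.  Because logit(sigmoid(x)) = x away from the clamp,
planted log-odds changes are computable in closed form:
logit(p_ref) - logit(p_alt) = steepness * (s_ref - s_alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.special import expit

from .sequence_windows import revcomp

PROB_FLOOR = 1e-6

_BASE_INDEX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


@dataclass(frozen=True)
class FeatureProfile:
    """Per-feature probabilities for one sequence, order fixed."""

    feature_names: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.probs):
            raise ValueError("feature_names and probs length mismatch")

    def __getitem__(self, feature: str) -> float:
        try:
            return float(self.probs[self.feature_names.index(feature)])
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None


def subset_features(profile: FeatureProfile, keep: Sequence[str]) -> FeatureProfile:
    """Restrict a profile to a feature subset, preserving the original order.

    This is how a curated tissue-relevant feature list (one name per line)
    is applied to a full profile.
    """
    unknown = [k for k in keep if k not in profile.feature_names]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    keep_set = set(keep)
    idx = [i for i, n in enumerate(profile.feature_names) if n in keep_set]
    return FeatureProfile(
        feature_names=tuple(profile.feature_names[i] for i in idx),
        probs=profile.probs[idx],
    )


def load_feature_subset(path: str | Path) -> list[str]:
    """Read a plain-text feature list, one name per line, '#' comments allowed."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one synthetic feature."""

    name: str
    mode: str  # single | cooperative | dense
    motifs: tuple[str, ...] = ()
    dense_seed: int | None = None
    dense_scale: float = 0.02

    def __post_init__(self) -> None:
        if self.mode not in ("single", "cooperative", "dense"):
            raise ValueError(f"{self.name}: unknown mode {self.mode!r}")
        if self.mode == "single" and len(self.motifs) != 1:
            raise ValueError(f"{self.name}: single mode needs exactly 1 motif")
        if self.mode == "cooperative" and len(self.motifs) != 2:
            raise ValueError(f"{self.name}: cooperative mode needs exactly 2 motifs")
        if self.mode == "dense" and self.dense_seed is None:
            raise ValueError(f"{self.name}: dense mode needs dense_seed")
        for m in self.motifs:
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"{self.name}: motif {m!r} must be nonempty A/C/G/T")


def count_occurrences(seq: str, motif: str) -> int:
    """Occurrences of motif in seq, overlapping counted."""
    n, i = 0, seq.find(motif)
    while i != -1:
        n += 1
        i = seq.find(motif, i + 1)
    return n


class SyntheticAnnotator:
    """Deterministic motif-occupancy annotator with planted ground truth.

    Parameters
    ----------
    features
        Ordered feature declarations; names must be unique.
    L
        Declared input length; sequences of any other length are rejected.
    steepness, offset
        Logistic squashing parameters shared by all features: a window with a
        single motif match scores sigmoid(steepness * (1 - offset)), a window
        with none sigmoid(-steepness * offset).  The default (4.0, 0.5) puts
        one match at p ≈ 0.88 and zero matches at p ≈ 0.12, well inside the
        clamp, so a variant toggling one match has log-odds change exactly
        ±steepness.
    strand_symmetric
        When true (default), motif occurrences are counted on both strands and
        dense scores are averaged with the reverse complement, so
        annotate(seq) == annotate(revcomp(seq)) exactly.
    allow_n
        N bases carry zero affinity (they never match a motif and have zero
        dense weight); when false, sequences containing N are rejected.
    """

    def __init__(
        self,
        features: Sequence[FeatureSpec],
        L: int = 2000,
        steepness: float = 4.0,
        offset: float = 0.5,
        strand_symmetric: bool = True,
        allow_n: bool = True,
        prob_floor: float = PROB_FLOOR,
    ):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        self.features = tuple(features)
        self.feature_names = tuple(names)
        self.L = int(L)
        self.steepness = float(steepness)
        self.offset = float(offset)
        self.strand_symmetric = bool(strand_symmetric)
        self.allow_n = bool(allow_n)
        self.prob_floor = float(prob_floor)
        self._dense_cache: dict[str, np.ndarray] = {}

    # -- scoring --------------------------------------------------------

    def _dense_weights(self, spec: FeatureSpec) -> np.ndarray:
        """(L, 5) weight table; column 4 (N) is zero affinity."""
        w = self._dense_cache.get(spec.name)
        if w is None:
            rng = np.random.default_rng(spec.dense_seed)
            w = np.zeros((self.L, 5))
            w[:, :4] = rng.normal(0.0, spec.dense_scale, size=(self.L, 4))
            self._dense_cache[spec.name] = w
        return w

    def _motif_count(self, seq: str, seq_rc: str, motif: str) -> int:
        n = count_occurrences(seq, motif)
        if self.strand_symmetric:
            n += count_occurrences(seq_rc, motif)
        return n

    def raw_score(self, seq: str, feature: str | FeatureSpec) -> float:
        """Raw (pre-squashing) score of one feature; pure function of seq."""
        spec = (feature if isinstance(feature, FeatureSpec)
                else self.features[self.feature_names.index(feature)])
        seq_rc = revcomp(seq)
        if spec.mode == "single":
            return float(self._motif_count(seq, seq_rc, spec.motifs[0]))
        if spec.mode == "cooperative":
            c1 = self._motif_count(seq, seq_rc, spec.motifs[0])
            c2 = self._motif_count(seq, seq_rc, spec.motifs[1])
            return float(c1 * (1 + c2))
        # dense
        w = self._dense_weights(spec)
        idx = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
        s = float(w[np.arange(self.L), idx].sum())
        if self.strand_symmetric:
            idx_rc = _BASE_INDEX[np.frombuffer(seq_rc.encode(), dtype=np.uint8)]
            s = 0.5 * (s + float(w[np.arange(self.L), idx_rc].sum()))
        return s

    def squash(self, score: float | np.ndarray) -> np.ndarray:
        """Logistic score -> probability map with clamping to (0, 1)."""
        p = expit(self.steepness * (np.asarray(score, dtype=float) - self.offset))
        return np.clip(p, self.prob_floor, 1.0 - self.prob_floor)

    def expected_log_odds_change(self, score_ref: float, score_alt: float) -> float:
        """Closed-form logit(p_ref) - logit(p_alt) for unclamped scores."""
        return self.steepness * (score_ref - score_alt)

    # -- contract -------------------------------------------------------

    def _check(self, seq: str) -> None:
        if len(seq) != self.L:
            raise ValueError(f"sequence length {len(seq)} != declared {self.L}")
        bad = set(seq) - set("ACGTN" if self.allow_n else "ACGT")
        if bad:
            raise ValueError(f"disallowed characters in sequence: {sorted(bad)}")

    def annotate(self, seq: str) -> FeatureProfile:
        """One probability per declared feature; deterministic."""
        self._check(seq)
        scores = np.array([self.raw_score(seq, f) for f in self.features])
        return FeatureProfile(self.feature_names, self.squash(scores))

    def annotate_batch(self, seqs: Sequence[str]) -> list[FeatureProfile]:
        """Elementwise annotate, order preserved; failures named by index."""
        out = []
        for i, s in enumerate(seqs):
            try:
                out.append(self.annotate(s))
            except ValueError as exc:
                raise ValueError(f"sequence {i}: {exc}") from exc
        return out

    # -- (de)serialization ----------------------------------------------

    def fingerprint(self) -> str:
        """Stable short identifier for provenance headers."""
        import hashlib
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "annotator": "synthetic",
            "L": self.L,
            "steepness": self.steepness,
            "offset": self.offset,
            "strand_symmetric": self.strand_symmetric,
            "allow_n": self.allow_n,
            "features": [
                {"name": f.name, "mode": f.mode, "motifs": list(f.motifs),
                 **({"dense_seed": f.dense_seed, "dense_scale": f.dense_scale}
                    if f.mode == "dense" else {})}
                for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticAnnotator":
        if d.get("annotator", "synthetic") != "synthetic":
            raise ValueError(
                "only the synthetic annotator can be constructed from a spec; "
                "external annotators plug in through the same annotate_batch "
                "contract"
            )
        feats = [
            FeatureSpec(
                name=f["name"], mode=f["mode"], motifs=tuple(f.get("motifs", ())),
                dense_seed=f.get("dense_seed"),
                dense_scale=f.get("dense_scale", 0.02),
            )
            for f in d["features"]
        ]
        return cls(
            feats, L=d.get("L", 2000), steepness=d.get("steepness", 4.0),
            offset=d.get("offset", 0.5),
            strand_symmetric=d.get("strand_symmetric", True),
            allow_n=d.get("allow_n", True),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticAnnotator":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
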