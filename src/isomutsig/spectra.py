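"""Mutation-channel classification and spectrum construction.

Single base substitutions are classified into the standard 96 triplet
channels: the substitution is expressed on the pyrimidine strand (purine
reference bases are reverse-complemented together with their flanks),
giving six substitution blocks C>A, C>G, C>T, T>A, T>C, T>G, each split by
the 5' and 3' neighbouring base in alphabetical order.

Short insertions and deletions are classified into the 83 channels of the
COSMIC v3 indel scheme: 1 bp events by the deleted/inserted base (C or T
pyrimidine representation) and the length of the homopolymer run at the
site; longer events by length (2/3/4/5+) and the number of tandem copies
of the indel sequence in the reference; deletions without a tandem copy
additionally by the length of microhomology at the breakpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContextUnavailableError, UndefinedSpectrumError, ValidationError
from .io import GenomicLocus, MutationRecord, _slice_genome, fetch_context

__all__ = [
    "SBS96_LABELS",
    "ID83_LABELS",
    "Spectrum",
    "sbs96_channel",
    "sbs96_label",
    "classify_indel",
    "build_spectrum",
    "cosine",
    "context_logo",
    "ContextLogo",
    "revcomp",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_LABELS: list[str] = [
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
]


def _id83_labels() -> list[str]:
    labels = []
    for base in ("C", "T"):  # 1 bp deletions by homopolymer length 1..6+
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):  # 1 bp insertions by homopolymer length 0..5+
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for L in (2, 3, 4, 5):  # >=2 bp deletions at repeats, copies 1..6+
        labels += [f"{L}:Del:R:{i}" for i in range(6)]
    for L in (2, 3, 4, 5):  # >=2 bp insertions at repeats, copies 0..5+
        labels += [f"{L}:Ins:R:{i}" for i in range(6)]
    for L, max_m in ((2, 1), (3, 2), (4, 3), (5, 5)):  # microhomology deletions
        labels += [f"{L}:Del:M:{m}" for m in range(1, max_m + 1)]
    return labels


ID83_LABELS: list[str] = _id83_labels()
assert len(ID83_LABELS) == 83


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class Spectrum:
    """A fixed-order channel vector of mutation counts or frequencies."""

    labels: Sequence[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) not in (96, 83):
            raise ValidationError("spectrum must have 96 (SBS) or 83 (indel) channels")
        if self.values.shape != (len(self.labels),):
            raise ValidationError("labels and values length mismatch")
        if (self.values < 0).any():
            raise ValidationError("spectrum values must be non-negative")
        if self.normalized and not math.isclose(self.values.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("normalized spectrum must sum to 1")

    @property
    def kind(self) -> str:
        return "SBS96" if len(self.labels) == 96 else "ID83"

    def normalize(self) -> "Spectrum":
        total = self.values.sum()
        if total == 0:
            raise UndefinedSpectrumError("cannot normalize an all-zero spectrum")
        return Spectrum(self.labels, self.values / total, normalized=True)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if list(self.labels) != list(other.labels):
            raise ValidationError("channel sets differ")
        return Spectrum(self.labels, self.values + other.values)

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, index=list(self.labels))


def _check_base(b: str) -> str:
    b = b.upper()
    if b not in _BASES:
        raise ValidationError(f"non-ACGT base {b!r}")
    return b


def sbs96_channel(ref: str, alt: str, fivep: str, threep: str) -> int:
    """Index of the 96-channel triplet class of a substitution.

    Purine reference bases are reverse-complemented to the pyrimidine
    representation; the flanks swap and complement accordingly.
    """
    ref, alt, fivep, threep = (_check_base(b) for b in (ref, alt, fivep, threep))
    if ref == alt:
        raise ValidationError("ref and alt must differ")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        fivep, threep = _COMPLEMENT[threep], _COMPLEMENT[fivep]
    block = _SUBS.index(f"{ref}>{alt}")
    return block * 16 + _BASES.index(fivep) * 4 + _BASES.index(threep)


def sbs96_label(ref: str, alt: str, fivep: str, threep: str) -> str:
    return SBS96_LABELS[sbs96_channel(ref, alt, fivep, threep)]


# ---------------------------------------------------------------------------
# indel classification
# ---------------------------------------------------------------------------


def _count_copies_right(seq: str, unit: str) -> int:
    """Tandem copies of ``unit`` at the start of ``seq`` (brute scan)."""
    n, k = 0, len(unit)
    while seq[n * k:(n + 1) * k] == unit:
        n += 1
    return n


def _homopolymer_run(flank_right: str, base: str) -> int:
    run = 0
    for b in flank_right:
        if b == base:
            run += 1
        else:
            break
    return run


def _microhomology(deleted: str, right_flank: str, left_flank: str) -> int:
    """Longest partial match of the deleted sequence with adjacent
    reference sequence: prefix of the deletion vs the sequence after it,
    or suffix of the deletion vs the sequence before it."""
    L = len(deleted)
    pre = 0
    for i in range(L - 1):
        if i < len(right_flank) and deleted[i] == right_flank[i]:
            pre += 1
        else:
            break
    suf = 0
    for i in range(L - 1):
        if i < len(left_flank) and deleted[L - 1 - i] == left_flank[len(left_flank) - 1 - i]:
            suf += 1
        else:
            break
    return max(pre, suf)


def classify_indel(record: MutationRecord, genome, max_flank: int = 400) -> str:
    """COSMIC ID83 channel label of a VCF-anchored short indel (<=50 bp).

    The indel is left-aligned against the reference first (repeat-unit
    counting is representation-dependent), then repeat copies are counted
    scanning rightward from the anchored position.
    """
    if record.mut_class not in ("INS", "DEL"):
        raise ValidationError("classify_indel requires an INS or DEL record")
    unit = record.indel_sequence.upper()
    L = len(unit)
    if L == 0 or L > 50:
        raise ValidationError(f"indel length {L} outside 1..50")
    chrom, anchor = record.locus.chrom, record.locus.pos
    up = _slice_genome(genome, chrom, max(1, anchor - max_flank), anchor) or ""
    # left-align: rotate the unit leftward while the preceding base matches
    n_shift = 0
    upp = up
    while upp and upp[-1] == unit[-1]:
        unit = upp[-1] + unit[:-1]
        upp = upp[:-1]
        n_shift += 1
    event_start = anchor + 1 - n_shift  # first reference base of the (deleted) unit

    if record.mut_class == "DEL":
        right_start = event_start + L
    else:
        right_start = event_start  # insertion: compare against reference from the site
    try:
        chrom_len = len(genome[chrom])
    except KeyError as exc:
        raise ContextUnavailableError(f"chromosome {chrom} absent from genome") from exc
    right = _slice_genome(genome, chrom, right_start, min(chrom_len, right_start + max_flank - 1)) \
        if right_start <= chrom_len else ""
    left = _slice_genome(genome, chrom, max(1, event_start - max_flank), event_start - 1) \
        if event_start > 1 else ""
    right = right or ""
    left = left or ""

    copies_right = _count_copies_right(right, unit)
    if record.mut_class == "DEL":
        copies = copies_right + 1  # include the deleted copy itself
    else:
        copies = copies_right

    if L == 1:
        base = unit if unit in ("C", "T") else _COMPLEMENT[unit]
        if record.mut_class == "DEL":
            run = copies  # homopolymer length including the deleted base
            sub = min(run, 6) - 1
        else:
            run = copies  # reference run length at the insertion site
            sub = min(run, 5)
        return f"1:{'Del' if record.mut_class == 'DEL' else 'Ins'}:{base}:{sub}"

    Lc = min(L, 5)
    if record.mut_class == "INS":
        return f"{Lc}:Ins:R:{min(copies, 5)}"
    if copies >= 2:
        return f"{Lc}:Del:R:{min(copies, 6) - 1}"
    deleted = unit
    mh = _microhomology(deleted, right, left)
    if mh == 0:
        return f"{Lc}:Del:R:0"
    max_m = {2: 1, 3: 2, 4: 3, 5: 5}[Lc]
    return f"{Lc}:Del:M:{min(mh, max_m)}"


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def build_spectrum(
    mutations: Iterable[MutationRecord], genome, kind: str = "SBS96"
) -> tuple[Spectrum, int]:
    """Count mutations per channel; returns (spectrum, n_unclassified).

    Records whose reference context is unavailable (chromosome edge,
    missing chromosome) are excluded and counted in ``n_unclassified``.
    """
    if kind == "SBS96":
        labels = SBS96_LABELS
    elif kind == "ID83":
        labels = ID83_LABELS
    else:
        raise ValidationError(f"unknown spectrum kind {kind!r}")
    values = np.zeros(len(labels))
    skipped = 0
    index = {lab: i for i, lab in enumerate(labels)}
    for rec in mutations:
        try:
            if kind == "SBS96":
                if rec.mut_class != "SBS":
                    continue
                ctx = rec.context or fetch_context(genome, rec.locus, 1)
                values[sbs96_channel(rec.ref, rec.alt, ctx[0], ctx[2])] += 1
            else:
                if rec.mut_class not in ("INS", "DEL"):
                    continue
                values[index[classify_indel(rec, genome)]] += 1
        except (ContextUnavailableError, ValidationError):
            skipped += 1
    return Spectrum(labels, values), skipped


def cosine(a: Spectrum | np.ndarray, b: Spectrum | np.ndarray) -> float:
    """Cosine similarity of two spectra on the same channel set."""
    va = a.values if isinstance(a, Spectrum) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, Spectrum) else np.asarray(b, dtype=float)
    if isinstance(a, Spectrum) and isinstance(b, Spectrum):
        if list(a.labels) != list(b.labels):
            raise ValidationError("channel sets differ")
    if va.shape != vb.shape:
        raise ValidationError("vector length mismatch")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise UndefinedSpectrumError("cosine undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


# ---------------------------------------------------------------------------
# extended-context enrichment logo
# ---------------------------------------------------------------------------


@dataclass
class ContextLogo:
    """Per-position, per-base enrichment/depletion scores around a
    mutation class.  Scores are log2 observed-over-background frequency
    ratios, median-centred over the four bases at each position."""

    positions: list[int]
    scores: np.ndarray  # len(positions) x 4, base order A C G T
    n_observed: int
    n_background: int


def context_logo(
    mutations: Sequence[MutationRecord],
    genome,
    flank: int = 5,
    rng_seed: int | np.random.Generator = 0,
    background_per_mutation: int = 10,
    background_window: int = 1000,
    epsilon: float = 0.5,
) -> ContextLogo:
    """Enrichment logo of the +/-``flank`` context of a mutation set.

    The background is ``background_per_mutation`` (default 10) random
    positions per mutation drawn uniformly within +/-``background_window``
    (1 kb) of it, which controls for local composition.  Background draws
    whose context window would leave the chromosome are redrawn, keeping
    observed and background context lengths identical.  Per position and
    base, the raw score is ``log2((f_obs+eps')/(f_bg+eps'))`` with a
    pseudo-count of ``epsilon`` observations; scores are then centred on
    the median over the four bases.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    obs_contexts = []
    centers = []
    for rec in mutations:
        try:
            obs_contexts.append(fetch_context(genome, rec.locus, flank))
            centers.append(rec.locus)
        except ContextUnavailableError:
            continue
    if not obs_contexts:
        raise ValidationError("no mutation has a full context window")
    bg_contexts = []
    for locus in centers:
        drawn = 0
        attempts = 0
        while drawn < background_per_mutation and attempts < background_per_mutation * 50:
            attempts += 1
            offset = int(rng.integers(-background_window, background_window + 1))
            pos = locus.pos + offset
            if pos < 1:
                continue
            try:
                bg_contexts.append(
                    fetch_context(genome, GenomicLocus(locus.chrom, pos), flank)
                )
                drawn += 1
            except ContextUnavailableError:
                continue
    positions = [p for p in range(-flank, flank + 1)]
    scores = np.zeros((len(positions), 4))
    for j, p in enumerate(positions):
        col = flank + p
        f_obs = _base_freqs([c[col] for c in obs_contexts], epsilon)
        f_bg = _base_freqs([c[col] for c in bg_contexts], epsilon)
        raw = np.log2(f_obs / f_bg)
        scores[j] = raw - np.median(raw)
    return ContextLogo(positions, scores, len(obs_contexts), len(bg_contexts))


def _base_freqs(bases: Sequence[str], epsilon: float) -> np.ndarray:
    counts = np.array([sum(1 for b in bases if b == base) for base in _BASES], dtype=float)
    counts += epsilon
    return counts / counts.sum()
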