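"""Replication timing, fork direction, transcription and genic context.

Relates called mutations to genome-scale covariates: replication-timing
scores (interpolated from array/sequencing tracks and binned into
deciles), replication fork directionality (RFD, the normalized difference
between rightward- and leftward-moving fork evidence per 1 kb window),
transcriptional strand, and genic/intergenic territory.  Strand-bias
statistics use one-degree-of-freedom chi-square tests against a 50:50
expectation, aggregated over mutation classes.

Strand conventions: mutations are always expressed in the pyrimidine
representation.  A positive RFD means a rightward-moving fork, in which
case the plus (sense) strand is the lagging-strand template; the call
flips when the pyrimidine of the mutation sits on the minus strand.  For
transcription, a pyrimidine on the template (transcribed) strand of the
overlapping gene labels the mutation "transcribed".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GeneInterval, GenomicTrack, MutationRecord

__all__ = [
    "StrandAssignment",
    "timing_at",
    "decile_bins",
    "assign_decile",
    "compute_rfd",
    "replication_strand",
    "transcription_strand",
    "strand_bias_test",
    "rfd_stratified_bias",
    "genic_density",
    "annotate_mutations",
]

_PYRIMIDINES = ("C", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SBS_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass
class StrandAssignment:
    """Per-mutation context annotation."""

    mutation: MutationRecord
    replication_strand: str  # leading / lagging / unassigned
    transcription_strand: str  # transcribed / untranscribed / intergenic / ambiguous
    rfd_value: float
    timing_score: float
    timing_decile: int | None


def timing_at(track: GenomicTrack, chrom: str, pos: float) -> float | None:
    """Replication-timing score at a position by linear interpolation
    between the nearest track points (clamped beyond the ends); None when
    the chromosome is absent from the track."""
    if chrom not in track:
        return None
    return track.interpolate(chrom, pos)


def decile_bins(scores: Sequence[float]) -> np.ndarray:
    """Nine cut points (empirical 0.1..0.9 quantiles) dividing a
    reference score set into deciles."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise ValidationError("need at least 10 reference scores for deciles")
    if len(np.unique(scores)) < 10:
        raise ValidationError("need at least 10 distinct scores for deciles")
    return np.quantile(scores, np.arange(1, 10) / 10)


def assign_decile(score: float | np.ndarray, cuts: np.ndarray) -> int | np.ndarray:
    """Decile 1..10 of a score given the nine cut points; bins are
    left-closed (a score equal to a cut falls in the upper bin)."""
    out = np.searchsorted(np.asarray(cuts), score, side="right") + 1
    return int(out) if np.isscalar(score) else out


def compute_rfd(
    ok_counts: pd.DataFrame, window_size: int = 1000
) -> GenomicTrack:
    """Replication fork directionality per window from OK-seq counts.

    ``ok_counts`` columns: chrom, start (1-based window start), rightward,
    leftward.  RFD = (R - L) / (R + L) in [-1, 1]; windows without reads
    get NaN (a defined gap).
    """
    for col in ("chrom", "start", "rightward", "leftward"):
        if col not in ok_counts.columns:
            raise ValidationError(f"ok_counts missing column {col!r}")
    if (ok_counts[["rightward", "leftward"]].to_numpy() < 0).any():
        raise ValidationError("read counts must be non-negative")
    track = GenomicTrack(kind="rfd", window_size=window_size)
    for chrom, sub in ok_counts.groupby("chrom", sort=True):
        sub = sub.sort_values("start", kind="stable")
        r = sub["rightward"].to_numpy(dtype=float)
        l = sub["leftward"].to_numpy(dtype=float)
        total = r + l
        with np.errstate(invalid="ignore", divide="ignore"):
            rfd = np.where(total > 0, (r - l) / np.maximum(total, 1e-300), np.nan)
        mid = sub["start"].to_numpy(dtype=float) + (window_size - 1) / 2
        track.add_chromosome(str(chrom), mid, rfd)
    return track


def _pyrimidine_strand(record: MutationRecord) -> str:
    """Strand carrying the pyrimidine of the substitution ('+' or '-')."""
    if record.mut_class != "SBS":
        raise ValidationError("strand assignment is defined for SBS records")
    return "+" if record.ref in _PYRIMIDINES else "-"


def pyrimidine_class(record: MutationRecord) -> str:
    """The six-class substitution type in pyrimidine representation."""
    ref, alt = record.ref, record.alt
    if ref not in _PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def replication_strand(record: MutationRecord, rfd: float) -> str:
    """Leading/lagging assignment of an SBS given the local RFD.

    Positive RFD = rightward fork, plus strand is the lagging template;
    the label refers to the strand carrying the mutation's pyrimidine.
    """
    if rfd is None or np.isnan(rfd) or rfd == 0:
        return "unassigned"
    pyr_plus = _pyrimidine_strand(record) == "+"
    rightward = rfd > 0
    if pyr_plus == rightward:
        return "lagging"
    return "leading"


def transcription_strand(
    record: MutationRecord, genes: Sequence[GeneInterval]
) -> str:
    """Transcribed/untranscribed assignment of an SBS against gene
    footprints.

    For a gene on the plus strand the template (transcribed) strand is
    the minus strand: a pyrimidine on the plus strand is then on the
    non-template strand -> "untranscribed".  Positions under genes on
    both strands are "ambiguous"; positions under no gene "intergenic".
    """
    strands = {
        g.strand
        for g in genes
        if g.chrom == record.locus.chrom and g.start <= record.locus.pos <= g.end
    }
    if not strands:
        return "intergenic"
    if strands == {"+", "-"}:
        return "ambiguous"
    gene_strand = strands.pop()
    template = "-" if gene_strand == "+" else "+"
    return "transcribed" if _pyrimidine_strand(record) == template else "untranscribed"


def strand_bias_test(n_strand1: int, n_strand2: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square of two strand counts against the
    50:50 expectation; returns (chi2, two-sided p)."""
    n = n_strand1 + n_strand2
    if n == 0:
        raise ValidationError("cannot test zero counts")
    expected = n / 2
    chi2 = (n_strand1 - expected) ** 2 / expected + (n_strand2 - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def annotate_mutations(
    mutations: Sequence[MutationRecord],
    timing_track: GenomicTrack | None = None,
    rfd_track: GenomicTrack | None = None,
    genes: Sequence[GeneInterval] = (),
    decile_cuts: np.ndarray | None = None,
) -> list[StrandAssignment]:
    """Full per-mutation context annotation (timing, decile, RFD,
    replication strand, transcription strand).

    The source-track convention (higher timing score = earlier
    replication) is preserved, and deciles are reported with decile 1 =
    earliest-replicating (highest score) through decile 10 = latest.
    """
    out = []
    for rec in mutations:
        chrom, pos = rec.locus.chrom, rec.locus.pos
        timing = timing_at(timing_track, chrom, pos) if timing_track else None
        decile = (
            11 - assign_decile(timing, decile_cuts)  # 1 = earliest (highest score)
            if timing is not None and decile_cuts is not None
            else None
        )
        if rfd_track is not None and chrom in rfd_track:
            rfd = rfd_track.value_at(chrom, pos)
        else:
            rfd = float("nan")
        out.append(
            StrandAssignment(
                mutation=rec,
                replication_strand=replication_strand(rec, rfd),
                transcription_strand=transcription_strand(rec, genes),
                rfd_value=rfd,
                timing_score=float("nan") if timing is None else timing,
                timing_decile=decile,
            )
        )
    return out


DEFAULT_RFD_STRATA = (("rfd<=-0.5", -np.inf, -0.5), ("-0.5<rfd<0.5", -0.5, 0.5),
                      ("rfd>=0.5", 0.5, np.inf))


def rfd_stratified_bias(
    assignments: Sequence[StrandAssignment],
    strata=DEFAULT_RFD_STRATA,
) -> pd.DataFrame:
    """Transcriptional strand bias per RFD stratum and substitution class.

    Mutations are partitioned into RFD strata (the middle stratum is the
    open interval (-0.5, 0.5); boundary values fall in the flanking
    strata); within each stratum, transcribed/untranscribed counts per
    six-class substitution type and the chi-square test.  Ambiguous and
    intergenic mutations are excluded from the tests; NaN-RFD mutations
    are excluded from the partition.
    """
    rows = []
    for name, lo, hi in strata:
        in_stratum = [
            a
            for a in assignments
            if np.isfinite(a.rfd_value)
            and (
                (lo == -np.inf and a.rfd_value <= hi)
                or (hi == np.inf and a.rfd_value >= lo)
                or (lo < a.rfd_value < hi)
            )
        ]
        for klass in SBS_CLASSES:
            sub = [
                a
                for a in in_stratum
                if pyrimidine_class(a.mutation) == klass
                and a.transcription_strand in ("transcribed", "untranscribed")
            ]
            n_t = sum(1 for a in sub if a.transcription_strand == "transcribed")
            n_u = len(sub) - n_t
            if n_t + n_u > 0:
                chi2, p = strand_bias_test(n_t, n_u)
            else:
                chi2, p = float("nan"), float("nan")
            rows.append(
                {
                    "stratum": name,
                    "class": klass,
                    "transcribed": n_t,
                    "untranscribed": n_u,
                    "chi2": chi2,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def _merge_intervals(genes: Sequence[GeneInterval]) -> dict[str, list[tuple[int, int]]]:
    """Strandless union of gene footprints per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    merged = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [tuple(x) for x in out]
    return merged


def genic_density(
    mutations: Sequence[MutationRecord],
    genes: Sequence[GeneInterval],
    genome_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Mutation densities (per Mb) over genic vs intergenic territory.

    Territory is the strandless union of transcript footprints and its
    complement within the given chromosome lengths; each mutation counts
    exactly once.
    """
    merged = _merge_intervals(genes)
    genic_len = sum(e - s + 1 for spans in merged.values() for s, e in spans)
    total_len = sum(genome_lengths.values())
    intergenic_len = total_len - genic_len
    if genic_len == 0 or intergenic_len == 0:
        raise ValidationError("both genic and intergenic territory must be non-empty")
    n_genic = 0
    for rec in mutations:
        spans = merged.get(rec.locus.chrom, [])
        starts = np.array([s for s, _ in spans])
        ends = np.array([e for _, e in spans])
        i = np.searchsorted(starts, rec.locus.pos, side="right") - 1
        if i >= 0 and rec.locus.pos <= ends[i]:
            n_genic += 1
    n_inter = len(mutations) - n_genic
    return pd.DataFrame(
        {
            "territory": ["genic", "intergenic"],
            "length_mb": [genic_len / 1e6, intergenic_len / 1e6],
            "mutations": [n_genic, n_inter],
            "density_per_mb": [n_genic / (genic_len / 1e6), n_inter / (intergenic_len / 1e6)],
        }
    )
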