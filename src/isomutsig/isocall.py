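"""Unique-mutation calling within an isogenic sample set.

Mutations that arose in a single descendant clone are detected by comparing
all samples of an isogenic set at every covered genomic position: a
candidate is emitted for sample *s* when *s* shows a sufficiently frequent
non-reference allele while every other sample remains essentially pure
reference.  Each candidate carries a hypergeometric quality score computed
against the least-clean other sample, and score thresholds are calibrated
so that ancestral clones (which by construction carry no true unique
mutations) retain almost no calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .io import COUNTS_COLUMNS, GenomicLocus, MutationRecord

__all__ = [
    "CallerConfig",
    "AncestryMap",
    "call_candidates",
    "fisher_score",
    "calibrate_threshold",
    "apply_threshold",
    "call_unique_mutations",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class CallerConfig:
    """Filter and threshold settings of the unique-mutation caller.

    Defaults are the optimized whole-genome settings: a candidate needs
    alt-allele frequency >= 0.2 and coverage >= 5 in the mutated sample,
    and reference-allele frequency >= 0.93 in every other sample.  Score
    thresholds (SBS 3.5, insertions 2.1, deletions 3.1) are on the
    -log10 Fisher scale.  The base-quality >= 30 read filter is the
    responsibility of whoever produced the count tables and is recorded
    here for provenance only.
    """

    min_alt_vaf: float = 0.2
    min_cov: int = 5
    min_other_ref_af: float = 0.93
    score_threshold_sbs: float = 3.5
    score_threshold_ins: float = 2.1
    score_threshold_del: float = 3.1
    ancestral_fp_fraction: float = 0.01
    ancestral_indel_cap: int = 5
    producer_base_quality: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.min_alt_vaf <= 1):
            raise ValidationError("min_alt_vaf must lie in (0, 1]")
        if not (0 < self.min_other_ref_af <= 1):
            raise ValidationError("min_other_ref_af must lie in (0, 1]")
        for name in ("score_threshold_sbs", "score_threshold_ins", "score_threshold_del"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def threshold_for(self, mut_class: str) -> float:
        return {
            "SBS": self.score_threshold_sbs,
            "INS": self.score_threshold_ins,
            "DEL": self.score_threshold_del,
        }[mut_class]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AncestryMap:
    """Ancestor -> descendants relations within the sample set."""

    pairs: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for anc, desc in self.pairs.items():
            if anc in desc:
                raise ValidationError(f"sample {anc} cannot be its own descendant")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "AncestryMap":
        """Build from a two-column table (ancestor, descendant)."""
        pairs: dict[str, set[str]] = {}
        for anc, desc in zip(df.iloc[:, 0], df.iloc[:, 1]):
            pairs.setdefault(str(anc), set()).add(str(desc))
        return cls(pairs)

    @property
    def ancestors(self) -> list[str]:
        return list(self.pairs)


def fisher_score(
    mut_sample: tuple[int, int], worst_other: tuple[int, int]
) -> tuple[float, bool]:
    """-log10 one-tailed Fisher exact probability of the mutated sample's
    alt count, against the other sample with the lowest reference-allele
    frequency.

    The 2x2 table is [alt, ref] x [mutated, other]; the one-tailed
    probability is the hypergeometric upper tail P(X >= alt_mut) with
    population ``cov_mut + cov_other``, ``alt_mut + alt_other`` successes
    and ``cov_mut`` draws.  The tail is directional: when the mutated
    sample's alt frequency does not exceed the other sample's there is no
    evidence of a difference and p = 1 (score 0), so identical count
    pairs score 0.  Returns ``(score, degenerate)``; zero coverage in
    either sample yields score 0 with the degenerate flag set.
    """
    alt_m, cov_m = mut_sample
    alt_o, cov_o = worst_other
    if alt_m > cov_m or alt_o > cov_o or min(alt_m, alt_o) < 0:
        raise ValidationError("alt counts must satisfy 0 <= alt <= coverage")
    if cov_m == 0 or cov_o == 0:
        return 0.0, True
    if alt_m * cov_o <= alt_o * cov_m:  # alt frequency not above the other sample's
        return 0.0, False
    # upper tail P(X >= alt_m), X ~ Hypergeom(M=cov_m+cov_o, n=alt_m+alt_o, N=cov_m)
    p = float(hypergeom.sf(alt_m - 1, cov_m + cov_o, alt_m + alt_o, cov_m))
    p = min(max(p, 5e-324), 1.0)
    return -math.log10(p), False


def call_candidates(counts: pd.DataFrame, cfg: CallerConfig | None = None) -> list[MutationRecord]:
    """Scan a counts table and emit unique-mutation candidates.

    At every (chrom, pos) all samples are compared; a record is emitted for
    sample *s* iff (i) *s*'s most frequent non-reference allele (or its
    ins/del evidence) reaches frequency >= ``min_alt_vaf``, (ii) *s*'s
    coverage >= ``min_cov``, and (iii) every other sample's reference-allele
    frequency is >= ``min_other_ref_af``.  A sample missing at a position
    counts as coverage 0 and fails (iii), so absence of evidence never
    supports a call.  Each emitted record carries the hypergeometric score
    against the worst (lowest ref-AF) other sample.

    SBS candidates report the single most frequent alt allele (ties broken
    alphabetically).  Indel candidates are reported with placeholder
    one-base anchors; the indel allele sequence is not part of the count
    format, so indel records carry class and VAF only.

    The scan is vectorized over a positions x samples pivot, so whole-
    chromosome tables are handled in seconds.
    """
    cfg = cfg or CallerConfig()
    if counts.empty:
        return []
    if counts.duplicated(subset=["sample", "chrom", "pos"]).any():
        raise ValidationError("duplicated (sample, chrom, pos) rows")
    ref_check = counts.groupby(["chrom", "pos"])["ref"].nunique()
    if (ref_check > 1).any():
        chrom, pos = ref_check.index[ref_check > 1][0]
        raise ValidationError(f"reference base mismatch at {chrom}:{pos}")

    samples = sorted(counts["sample"].unique())
    wide = counts.pivot(index=["chrom", "pos"], columns="sample",
                        values=["cov", "nA", "nC", "nG", "nT", "n_ins", "n_del"])
    wide = wide.reindex(columns=samples, level=1).fillna(0)
    positions = wide.index  # sorted (chrom, pos)
    refs = counts.drop_duplicates(["chrom", "pos"]).set_index(["chrom", "pos"])["ref"]
    refs = refs.reindex(positions).to_numpy()
    ref_idx = np.searchsorted(np.array(_BASES), refs)

    cov = wide["cov"].to_numpy(dtype=float)  # P x S
    base_counts = np.stack([wide[f"n{b}"].to_numpy(dtype=float) for b in _BASES], axis=2)
    P, S = cov.shape
    # reference-base count per (position, sample)
    ref_n = np.take_along_axis(base_counts, ref_idx[:, None, None].repeat(S, axis=1), axis=2)[:, :, 0]
    masked = base_counts.copy()
    np.put_along_axis(masked, ref_idx[:, None, None].repeat(S, axis=1), -1.0, axis=2)
    alt_base_idx = masked.argmax(axis=2)  # first max = alphabetical tie-break
    alt_n_sbs = masked.max(axis=2)
    alt_n_sbs[alt_n_sbs < 0] = 0

    records: list[MutationRecord] = []
    chroms = positions.get_level_values(0).to_numpy()
    poss = positions.get_level_values(1).to_numpy()

    class_data = {
        "SBS": (alt_n_sbs, ref_n),
        "INS": (wide["n_ins"].to_numpy(dtype=float), None),
        "DEL": (wide["n_del"].to_numpy(dtype=float), None),
    }
    for klass, (alt_n, klass_ref_n) in class_data.items():
        if klass_ref_n is None:
            klass_ref_n = cov - alt_n  # reads not supporting the event
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(cov > 0, alt_n / np.maximum(cov, 1), 0.0)
            raf = np.where(cov > 0, klass_ref_n / np.maximum(cov, 1), -1.0)
        below = raf < cfg.min_other_ref_af  # P x S
        n_below = below.sum(axis=1)
        self_ok = (vaf >= cfg.min_alt_vaf) & (cov >= max(cfg.min_cov, 1))
        others_ok = (n_below[:, None] - below.astype(int)) == 0
        hits = np.argwhere(self_ok & others_ok)
        for p, s in hits:
            raf_row = raf.copy()[p]
            raf_row[s] = np.inf
            o = int(np.argmin(raf_row))
            score, _ = fisher_score(
                (int(alt_n[p, s]), int(cov[p, s])),
                (int(alt_n[p, o]), int(cov[p, o])),
            )
            ref = refs[p]
            if klass == "SBS":
                rec_ref, rec_alt = ref, _BASES[alt_base_idx[p, s]]
            elif klass == "INS":
                rec_ref, rec_alt = ref, ref + "N"
            else:
                rec_ref, rec_alt = ref + "N", ref
            records.append(
                MutationRecord(
                    sample_id=samples[s],
                    locus=GenomicLocus(str(chroms[p]), int(poss[p])),
                    ref=rec_ref,
                    alt=rec_alt,
                    mut_class=klass,
                    vaf=float(vaf[p, s]),
                    score=score,
                )
            )
    records.sort(key=lambda r: (r.locus.chrom, r.locus.pos, r.sample_id, r.mut_class))
    return records


def _surviving_counts(
    records: Sequence[MutationRecord], threshold: float
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        if r.score >= threshold:
            counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
    return counts


def calibrate_threshold(
    records: Sequence[MutationRecord],
    ancestry: AncestryMap,
    mut_class: str,
    cfg: CallerConfig | None = None,
) -> float:
    """Choose the minimal score threshold bounding ancestral false calls.

    Candidate thresholds are 0 plus every observed score of the class
    (anything between two observed scores filters identically).  For SBS
    the accepted threshold is the smallest for which every ancestor's
    surviving call count is at most ``ancestral_fp_fraction`` times each of
    its descendants' surviving counts; for insertions and deletions every
    ancestor must keep at most ``ancestral_indel_cap`` calls.  Returns
    ``inf`` with a warning when no threshold satisfies the constraint.
    """
    cfg = cfg or CallerConfig()
    if not ancestry.pairs:
        raise ValidationError("ancestry map is empty")
    recs = [r for r in records if r.mut_class == mut_class]
    candidates = sorted({0.0, *(r.score for r in recs)})
    for t in candidates:
        counts = _surviving_counts(recs, t)
        ok = True
        for anc, descendants in ancestry.pairs.items():
            n_anc = counts.get(anc, 0)
            if mut_class == "SBS":
                for d in descendants:
                    if n_anc > cfg.ancestral_fp_fraction * counts.get(d, 0):
                        ok = False
                        break
            else:
                if n_anc > cfg.ancestral_indel_cap:
                    ok = False
            if not ok:
                break
        if ok:
            return t
    warnings.warn(
        f"no score threshold bounds ancestral {mut_class} calls; returning inf",
        stacklevel=2,
    )
    return math.inf


def apply_threshold(
    records: Iterable[MutationRecord], thresholds: Mapping[str, float]
) -> list[MutationRecord]:
    """Keep records whose score reaches their class threshold."""
    return [r for r in records if r.score >= thresholds[r.mut_class]]


def call_unique_mutations(
    counts: pd.DataFrame,
    cfg: CallerConfig | None = None,
    ancestry: AncestryMap | None = None,
    calibrate: bool = False,
) -> list[MutationRecord]:
    """Full calling pipeline: candidates, scoring, score thresholding.

    With ``calibrate=True`` (requires ``ancestry``) class thresholds are
    recalibrated on the observed scores; otherwise the configured defaults
    are applied.
    """
    cfg = cfg or CallerConfig()
    candidates = call_candidates(counts, cfg)
    if calibrate:
        if ancestry is None:
            raise ValidationError("calibration requires an ancestry map")
        thresholds = {
            k: calibrate_threshold(candidates, ancestry, k, cfg)
            for k in ("SBS", "INS", "DEL")
        }
    else:
        thresholds = {k: cfg.threshold_for(k) for k in ("SBS", "INS", "DEL")}
    return apply_threshold(candidates, thresholds)
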