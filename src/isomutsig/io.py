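"""Readers, writers and the domain types shared by the whole pipeline.

Coordinate conventions
----------------------
Internally every position is 1-based inclusive (the VCF convention).
BED and bedGraph inputs, which are 0-based half-open, are converted at the
boundary when read.  Indel records use VCF anchoring: ``ref`` and ``alt``
share their first base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContextUnavailableError, ParseError, ValidationError

__all__ = [
    "GenomicLocus",
    "MutationRecord",
    "CountsRow",
    "GenomicTrack",
    "GeneInterval",
    "read_counts_table",
    "fetch_context",
    "read_track",
    "read_bed",
    "write_vcf",
    "read_vcf",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
]

COUNTS_COLUMNS = ["sample", "chrom", "pos", "ref", "cov", "nA", "nC", "nG", "nT", "n_ins", "n_del"]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GenomicLocus:
    """A 1-based genomic position with an optional strand."""

    chrom: str
    pos: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.strand not in (None, "+", "-"):
            raise ValidationError(f"strand must be '+', '-' or None, got {self.strand!r}")


@dataclass(frozen=True)
class MutationRecord:
    """One called mutation, unique to a single sample of an isogenic set.

    ``mut_class`` is one of ``SBS`` (single base substitution), ``INS`` or
    ``DEL``; indels are VCF-anchored so ref and alt share the first base.
    """

    sample_id: str
    locus: GenomicLocus
    ref: str
    alt: str
    mut_class: str
    vaf: float
    score: float = 0.0
    context: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValidationError(f"vaf must lie in [0,1], got {self.vaf}")
        lr, la = len(self.ref), len(self.alt)
        expected = "SBS" if lr == la == 1 else ("INS" if la > lr else "DEL")
        if self.mut_class != expected:
            raise ValidationError(
                f"mut_class {self.mut_class} inconsistent with ref={self.ref} alt={self.alt}"
            )

    @property
    def indel_sequence(self) -> str:
        """The inserted or deleted bases (without the shared anchor base)."""
        if self.mut_class == "INS":
            return self.alt[len(self.ref):]
        if self.mut_class == "DEL":
            return self.ref[len(self.alt):]
        raise ValidationError("indel_sequence is defined for INS/DEL records only")


@dataclass(frozen=True)
class CountsRow:
    """Per-sample, per-position allele counts (the caller's input unit)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    cov: int
    nA: int
    nC: int
    nG: int
    nT: int
    n_ins: int
    n_del: int

    def base_count(self, base: str) -> int:
        return getattr(self, f"n{base}")

    @property
    def ref_count(self) -> int:
        return self.base_count(self.ref)


@dataclass(frozen=True)
class GeneInterval:
    """A 1-based inclusive transcript footprint with its coding strand."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"interval start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be '+' or '-', got {self.strand!r}")


class GenomicTrack:
    """A position-indexed scalar field (replication timing or RFD).

    Per chromosome the track stores strictly increasing positions with one
    value each.  ``kind`` records the semantics: ``timing`` scores are
    unitless (the source convention, higher = earlier, is preserved);
    ``rfd`` values are constrained to [-1, 1] and may be NaN where no fork
    evidence exists.
    """

    def __init__(self, kind: str = "timing", window_size: int | None = None) -> None:
        if kind not in ("timing", "rfd"):
            raise ValidationError(f"track kind must be 'timing' or 'rfd', got {kind!r}")
        self.kind = kind
        self.window_size = window_size
        self._pos: dict[str, np.ndarray] = {}
        self._val: dict[str, np.ndarray] = {}

    @classmethod
    def from_arrays(
        cls,
        data: Mapping[str, tuple[Sequence[float], Sequence[float]]],
        kind: str = "timing",
        window_size: int | None = None,
    ) -> "GenomicTrack":
        track = cls(kind=kind, window_size=window_size)
        for chrom, (pos, val) in data.items():
            track.add_chromosome(chrom, pos, val)
        return track

    def add_chromosome(self, chrom: str, pos: Sequence[float], val: Sequence[float]) -> None:
        p = np.asarray(pos, dtype=float)
        v = np.asarray(val, dtype=float)
        if p.shape != v.shape:
            raise ValidationError("positions and values must have equal length")
        order = np.argsort(p, kind="stable")
        if not np.array_equal(order, np.arange(len(p))):
            warnings.warn(f"track positions for {chrom} were unsorted; sorting", stacklevel=2)
            p, v = p[order], v[order]
        if len(p) > 1 and np.any(np.diff(p) <= 0):
            raise ValidationError(f"duplicate track positions on {chrom}")
        if self.kind == "rfd":
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1 or finite.max() > 1):
                raise ValidationError("RFD values must lie in [-1, 1]")
        self._pos[chrom] = p
        self._val[chrom] = v

    @property
    def chromosomes(self) -> list[str]:
        return list(self._pos)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._pos[chrom], self._val[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._pos

    def interpolate(self, chrom: str, pos: float) -> float:
        """Linear interpolation between the nearest data points, clamped
        to the endpoint values beyond the first/last point."""
        if chrom not in self._pos:
            raise KeyError(chrom)
        return float(np.interp(pos, self._pos[chrom], self._val[chrom]))

    def value_at(self, chrom: str, pos: float) -> float:
        """Nearest-window lookup for windowed tracks (step function).

        For a windowed RFD track the value of the window containing ``pos``
        is returned; positions outside any window get the nearest window's
        value."""
        if chrom not in self._pos:
            raise KeyError(chrom)
        p, v = self._pos[chrom], self._val[chrom]
        idx = int(np.argmin(np.abs(p - pos)))
        return float(v[idx])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Read a per-sample allele-count table (TSV with a named header).

    Enforces ``cov >= nA+nC+nG+nT`` and uniqueness of (sample, chrom, pos);
    a violation raises naming the offending line.  Returns a DataFrame with
    the canonical column order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "ref": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[COUNTS_COLUMNS]
    if df.empty:
        return df
    for col in ("pos", "cov", "nA", "nC", "nG", "nT", "n_ins", "n_del"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric {col!r} on line {line}")
        df[col] = df[col].astype(int)
    base_sum = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    bad = df.index[df["cov"] < base_sum]
    if len(bad):
        raise ValidationError(
            f"{path}: coverage below base-count sum on line {int(bad[0]) + 2}"
        )
    bad_ref = df.index[~df["ref"].isin(_BASES)]
    if len(bad_ref):
        raise ParseError(f"{path}: invalid reference base on line {int(bad_ref[0]) + 2}")
    dup = df.duplicated(subset=["sample", "chrom", "pos"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValidationError(f"{path}: duplicated (sample, chrom, pos) on line {line}")
    return df.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True)


def counts_rows(df: pd.DataFrame) -> list[CountsRow]:
    """Materialize a counts DataFrame as :class:`CountsRow` objects."""
    return [CountsRow(**rec) for rec in df.to_dict("records")]


def _chrom_sequence(genome, chrom: str) -> str | None:
    """Return the full sequence of ``chrom`` from a dict-like genome or a
    pyfaidx.Fasta handle; None if absent."""
    try:
        seq = genome[chrom]
    except KeyError:
        return None
    return str(seq[:]) if not isinstance(seq, str) else seq


def _slice_genome(genome, chrom: str, start1: int, end1: int) -> str | None:
    """1-based inclusive slice; None when out of bounds or chrom missing."""
    if start1 < 1:
        return None
    try:
        seq = genome[chrom]
    except KeyError:
        return None
    n = len(seq)
    if end1 > n:
        return None
    if isinstance(seq, str):
        return seq[start1 - 1:end1].upper()
    return str(seq[start1 - 1:end1]).upper()


def fetch_context(genome, locus: GenomicLocus, flank: int) -> str:
    """Return the 2*flank+1 bp reference context centred on ``locus``.

    ``genome`` may be a ``pyfaidx.Fasta`` handle or any mapping from
    chromosome name to sequence string.  Raises
    :class:`ContextUnavailableError` when the window runs off the
    chromosome; callers exclude such mutations from context analyses and
    count them.
    """
    ctx = _slice_genome(genome, locus.chrom, locus.pos - flank, locus.pos + flank)
    if ctx is None:
        raise ContextUnavailableError(
            f"context +/-{flank} at {locus.chrom}:{locus.pos} out of bounds"
        )
    return ctx


def read_track(
    paths: str | Path | Sequence[str | Path],
    kind: str = "timing",
    window_size: int | None = None,
) -> GenomicTrack:
    """Read one or more bedGraph-like files into a :class:`GenomicTrack`.

    Intervals are 0-based half-open on disk; each becomes a track point at
    its midpoint (1-based).  When several timing files are given their
    values are averaged per interval after an inner join on identical
    intervals (the files must share their interval grid).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if kind == "rfd" and len(paths) != 1:
        raise ValidationError("RFD tracks are read from a single file")
    frames = []
    for path in paths:
        path = Path(path)
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}: expected 4 columns on line {i}")
                chrom, start, end, value = parts[:4]
                try:
                    rows.append((chrom, int(start), int(end), float(value)))
                except ValueError as exc:
                    raise ParseError(f"{path}: non-numeric field on line {i}") from exc
        frames.append(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))
    merged = frames[0]
    for extra in frames[1:]:
        merged = merged.merge(extra, on=["chrom", "start", "end"], suffixes=("", "_r"))
        merged["value"] = (merged["value"] + merged.pop("value_r")) / 2
    if merged.empty:
        raise ParseError(f"{paths[0]}: no data lines")
    if kind == "rfd" and ((merged["value"].abs() > 1).any()):
        raise ValidationError("RFD values outside [-1, 1]")
    # midpoint of the 0-based half-open interval, expressed 1-based
    merged["mid"] = (merged["start"] + merged["end"] + 1) / 2
    track = GenomicTrack(kind=kind, window_size=window_size)
    for chrom, sub in merged.groupby("chrom", sort=True):
        sub = sub.sort_values("mid", kind="stable")
        track.add_chromosome(str(chrom), sub["mid"].to_numpy(), sub["value"].to_numpy())
    return track


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read gene/transcript intervals from a BED6 file (0-based half-open
    on disk, converted to 1-based inclusive)."""
    intervals = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}: expected 6 BED columns on line {i}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric coordinate on line {i}") from exc
            intervals.append(GeneInterval(chrom, start_i + 1, end_i, strand, name))
    return intervals


_VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample carrying the unique mutation">',
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##INFO=<ID=CLASS,Number=1,Type=String,Description="Mutation class (SBS/INS/DEL)">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
]


def write_vcf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write mutation records as a minimal VCF 4.2 (sorted by chrom, pos)."""
    recs = sorted(records, key=lambda r: (r.locus.chrom, r.locus.pos, r.sample_id))
    with open(path, "w") as fh:
        fh.write("\n".join(_VCF_HEADER) + "\n")
        for r in recs:
            info = f"SAMPLE={r.sample_id};VAF={r.vaf:.6g};CLASS={r.mut_class}"
            fh.write(
                f"{r.locus.chrom}\t{r.locus.pos}\t.\t{r.ref}\t{r.alt}"
                f"\t{r.score:.4f}\tPASS\t{info}\n"
            )


def read_vcf(path: str | Path) -> list[MutationRecord]:
    """Read back mutation records written by :func:`write_vcf`."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ParseError(f"{path}: short VCF line {i}")
            chrom, pos, _id, ref, alt, qual, _filt, info = parts[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            lr, la = len(ref), len(alt)
            mut_class = "SBS" if lr == la == 1 else ("INS" if la > lr else "DEL")
            records.append(
                MutationRecord(
                    sample_id=fields.get("SAMPLE", "."),
                    locus=GenomicLocus(chrom, int(pos)),
                    ref=ref,
                    alt=alt,
                    mut_class=fields.get("CLASS", mut_class),
                    vaf=float(fields.get("VAF", "0")),
                    score=float(qual) if qual != "." else 0.0,
                )
            )
    return records


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-layout signature matrix TSV.

    First column holds channel labels (e.g. ``A[C>A]A`` or ``1:Del:C:0``),
    remaining columns one signature each.  No normalization checks are
    applied here; wrap the result in
    :class:`~isomutsig.signatures.SignatureMatrix` for validation.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "channel"
    return df


def write_signature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="channel")


def read_spectrum_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (channel, value) spectrum TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: spectrum TSV needs two columns")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))


def write_spectrum_tsv(values: pd.Series, path: str | Path) -> None:
    values.rename("value").to_csv(path, sep="\t", index_label="channel")
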