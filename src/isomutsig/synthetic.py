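"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study design the pipeline targets: isogenic
clone sets (one ancestor, several descendants) sequenced at ~30x mean
depth with a per-base error rate of 0.001, mutation catalogs drawn
multinomially from signature mixtures, smooth replication-timing
profiles, alternating fork-direction fields with known orientation, and
bimodal clonal/subclonal VAF distributions.  Every generator is a pure
function of its configuration (seed included), so repeated runs are
byte-identical.

The shipped signature fixture (``data/synthetic_sbs96_signatures.tsv``)
is synthetic: three hand-constructed 96-channel distributions — a broad
background, an MMRd-like component heavy in C>T and T>C, and an
oxygen-like component concentrated on the ATA/GTA/GTT/TTA T>C contexts
that respond most to oxygen in MMRd cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import COUNTS_COLUMNS, GenomicLocus, GenomicTrack, MutationRecord
from .spectra import SBS96_LABELS

__all__ = [
    "SimulationConfig",
    "gen_genome",
    "write_fasta",
    "gen_isogenic_counts",
    "gen_catalog",
    "gen_fork_field",
    "gen_timing",
    "timing_wave",
    "gen_vaf_mixture",
    "load_synthetic_signatures",
    "gen_two_condition_cohort",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SimulationConfig:
    """Study-design parameters of the isogenic-clone simulation.

    Defaults mirror the emulated experiment: one ancestral clone and four
    descendants, 30x mean depth, per-base error rate 0.001, heterozygous
    unique mutations (VAF 0.5), 60 days of culture.
    """

    rng_seed: int = 0
    genome_length: int = 100_000
    n_descendants: int = 4
    ancestor: str = "anc"
    planted_per_sample: int = 100
    n_shared_variants: int = 50
    depth_mean: float = 30.0
    error_rate: float = 0.001
    background_positions: int = 2000
    days: float = 60.0
    doubling_time_hours: float = 20.0

    def __post_init__(self) -> None:
        if self.planted_per_sample < 0 or self.n_descendants < 1:
            raise ValidationError("counts must be non-negative, >=1 descendant")
        if not (0 <= self.error_rate < 1):
            raise ValidationError("error rate must lie in [0, 1)")

    @property
    def samples(self) -> list[str]:
        return [self.ancestor] + [f"d{i + 1}" for i in range(self.n_descendants)]


def gen_genome(length: int, gc_fraction: float = 0.4, seed: int = 0) -> str:
    """Random genome sequence with the stated GC content."""
    if length < 1000:
        raise ValidationError("genome length must be >= 1000")
    if not (0 <= gc_fraction <= 1):
        raise ValidationError("gc fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2,
                  (1 - gc_fraction) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def gen_isogenic_counts(
    genome: str,
    cfg: SimulationConfig,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, list[MutationRecord]]:
    """Simulate per-sample allele counts for an isogenic clone set.

    Each descendant carries ``planted_per_sample`` private heterozygous
    mutations (binomial alt counts at VAF 0.5 over Poisson-distributed
    depth); all samples share ``n_shared_variants`` ancestral
    heterozygous variants (these must never be called as unique);
    sequencing noise hits every sample at the per-base error rate.
    ``background_positions`` extra reference-only positions exercise the
    false-positive path.  Returns the counts table and the planted truth
    (unique mutations only).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    L = len(genome)
    n_priv = cfg.planted_per_sample * cfg.n_descendants
    n_total = n_priv + cfg.n_shared_variants + cfg.background_positions
    if n_total > L - 2:
        raise ValidationError("planted positions exceed genome length")
    positions = np.sort(rng.choice(np.arange(2, L), size=n_total, replace=False))
    # carrier: index of the descendant carrying a private mutation,
    # -2 for a shared ancestral variant, -1 for a pure-reference position
    carrier = np.full(n_total, -1)
    marks = rng.permutation(n_total)
    for d in range(cfg.n_descendants):
        carrier[marks[d * cfg.planted_per_sample:(d + 1) * cfg.planted_per_sample]] = d
    carrier[marks[n_priv:n_priv + cfg.n_shared_variants]] = -2

    samples = cfg.samples
    S = len(samples)
    P = n_total
    base_to_idx = {b: i for i, b in enumerate("ACGT")}
    ref_idx = np.array([base_to_idx[genome[p - 1].upper()] for p in positions])
    alt_idx = (ref_idx + 1 + rng.integers(0, 3, size=P)) % 4

    depth = rng.poisson(cfg.depth_mean, size=(P, S))
    variant = np.zeros((P, S), dtype=bool)
    variant[carrier == -2, :] = True
    priv = carrier >= 0
    variant[np.nonzero(priv)[0], carrier[priv] + 1] = True
    n_alt = np.where(variant, rng.binomial(depth, 0.5), 0)
    n_err = rng.binomial(depth - n_alt, cfg.error_rate)
    err_idx = (ref_idx[:, None] + 1 + rng.integers(0, 3, size=(P, S))) % 4

    base_counts = np.zeros((P, S, 4), dtype=int)
    rows_i = np.repeat(np.arange(P), S)
    cols_i = np.tile(np.arange(S), P)
    np.add.at(base_counts, (rows_i, cols_i, np.repeat(ref_idx, S)),
              (depth - n_alt - n_err).ravel())
    np.add.at(base_counts, (rows_i, cols_i, np.repeat(alt_idx, S)), n_alt.ravel())
    np.add.at(base_counts, (rows_i, cols_i, err_idx.ravel()), n_err.ravel())

    bases = np.array(list("ACGT"))
    df = pd.DataFrame(
        {
            "sample": np.tile(np.array(samples, dtype=object), P),
            "chrom": chrom,
            "pos": np.repeat(positions, S),
            "ref": np.repeat(bases[ref_idx], S),
            "cov": depth.ravel(),
            "nA": base_counts[:, :, 0].ravel(),
            "nC": base_counts[:, :, 1].ravel(),
            "nG": base_counts[:, :, 2].ravel(),
            "nT": base_counts[:, :, 3].ravel(),
            "n_ins": 0,
            "n_del": 0,
        }
    )[COUNTS_COLUMNS]
    truth = [
        MutationRecord(
            sample_id=samples[carrier[i] + 1],
            locus=GenomicLocus(chrom, int(positions[i])),
            ref=str(bases[ref_idx[i]]),
            alt=str(bases[alt_idx[i]]),
            mut_class="SBS",
            vaf=0.5,
        )
        for i in np.nonzero(carrier >= 0)[0]
    ]
    return df.sort_values(["chrom", "pos", "sample"], kind="stable").reset_index(drop=True), truth


# ---------------------------------------------------------------------------
# signature-mixture catalogs
# ---------------------------------------------------------------------------


def _context_index(genome: str) -> dict[str, np.ndarray]:
    """Map each pyrimidine-centred triplet to the 1-based positions whose
    plus-strand base is that pyrimidine with that context."""
    idx: dict[str, list[int]] = {}
    g = genome.upper()
    for i in range(1, len(g) - 1):
        if g[i] in "CT":
            idx.setdefault(g[i - 1:i + 2], []).append(i + 1)
    return {k: np.asarray(v) for k, v in idx.items()}


def gen_catalog(
    signatures: pd.DataFrame,
    exposures,
    n: int,
    genome: str,
    seed: int = 0,
    chrom: str = "chr1",
    vaf: float = 0.5,
) -> list[MutationRecord]:
    """Draw ``n`` substitutions multinomially from a signature mixture and
    realize each at a genome position whose triplet context matches its
    channel.  Positions are unique within the catalog.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.sum() <= 0:
        raise ValidationError("exposures must sum to a positive value")
    if list(signatures.index) != SBS96_LABELS:
        raise ValidationError("signature matrix must use the 96 standard channels")
    rng = np.random.default_rng(seed)
    mix = signatures.to_numpy(dtype=float) @ (exposures / exposures.sum())
    mix = mix / mix.sum()
    channel_draws = rng.multinomial(n, mix)
    ctx_index = _context_index(genome)
    used: set[int] = set()
    records: list[MutationRecord] = []
    for ch, count in enumerate(channel_draws):
        if count == 0:
            continue
        label = SBS96_LABELS[ch]
        fivep, ref, alt, threep = label[0], label[2], label[4], label[6]
        triplet = fivep + ref + threep
        pool = ctx_index.get(triplet)
        if pool is None:
            raise ValidationError(f"context {triplet} absent from the toy genome")
        avail = [p for p in pool if p not in used]
        if len(avail) < count:
            raise ValidationError(f"not enough {triplet} sites for {count} draws")
        chosen = rng.choice(np.asarray(avail), size=count, replace=False)
        for pos in chosen:
            used.add(int(pos))
            records.append(
                MutationRecord(
                    sample_id="catalog",
                    locus=GenomicLocus(chrom, int(pos)),
                    ref=ref,
                    alt=alt,
                    mut_class="SBS",
                    vaf=vaf,
                    context=triplet,
                )
            )
    return records


# ---------------------------------------------------------------------------
# replication tracks
# ---------------------------------------------------------------------------


def timing_wave(pos, wavelength: float) -> np.ndarray:
    """Closed-form smooth timing profile (higher = earlier)."""
    return np.cos(2 * np.pi * np.asarray(pos, dtype=float) / wavelength)


def gen_timing(
    genome_length: int, wavelength: float, spacing: int = 1000, seed: int = 0
) -> GenomicTrack:
    """Smooth replication-timing wave sampled every ``spacing`` bp."""
    pos = np.arange(spacing // 2, genome_length, spacing, dtype=float)
    track = GenomicTrack(kind="timing")
    track.add_chromosome("chr1", pos, timing_wave(pos, wavelength))
    return track


def gen_fork_field(
    genome_length: int,
    wavelength: float,
    seed: int = 0,
    window: int = 1000,
    reads_per_window: int = 100,
    amplitude: float = 0.9,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Alternating replication fork field with known orientation.

    Forks move rightward (+1) on the first half of every wavelength and
    leftward (-1) on the second; per 1 kb window, rightward read counts
    are binomial around ``(1 + amplitude * orientation) / 2``.  Returns
    the OK-seq style count table (chrom, start, rightward, leftward) and
    the true orientation per window.
    """
    if wavelength > genome_length:
        raise ValidationError("wavelength must not exceed the genome length")
    rng = np.random.default_rng(seed)
    starts = np.arange(1, genome_length - window + 2, window)
    mids = starts + (window - 1) / 2
    orientation = np.where(np.sin(2 * np.pi * mids / wavelength) >= 0, 1, -1)
    p_right = (1 + amplitude * orientation) / 2
    r = rng.binomial(reads_per_window, p_right)
    counts = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "rightward": r,
            "leftward": reads_per_window - r,
        }
    )
    return counts, orientation


# ---------------------------------------------------------------------------
# VAF mixtures
# ---------------------------------------------------------------------------


def gen_vaf_mixture(
    n: int,
    clonal_fraction: float,
    centers: tuple[float, float] = (0.25, 0.5),
    depth: int = 60,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomially read-sampled VAFs around a subclonal and a clonal
    centre; returns (vafs, labels) with label 1 = clonal (upper centre).
    """
    sub_c, clon_c = sorted(centers)
    if sub_c == clon_c:
        raise ValidationError("centres must be distinct")
    if not (0 < sub_c < 1 and 0 < clon_c < 1):
        raise ValidationError("centres must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < clonal_fraction).astype(int)
    p = np.where(labels == 1, clon_c, sub_c)
    vafs = rng.binomial(depth, p) / depth
    return vafs, labels


# ---------------------------------------------------------------------------
# shipped synthetic signatures and the two-condition cohort
# ---------------------------------------------------------------------------


def load_synthetic_signatures() -> pd.DataFrame:
    """Load the shipped synthetic SBS96 signature set.

    Columns: ``syn_background`` (broad, near-uniform), ``syn_mmrd``
    (C>T/T>C-heavy MMRd-like component), ``syn_oxygen`` (T>C component
    concentrated on the ATA, GTA, GTT and TTA contexts).  All columns
    sum to 1.
    """
    path = resources.files("isomutsig").joinpath("data/synthetic_sbs96_signatures.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t").set_index("channel")
    return df.loc[SBS96_LABELS]


def gen_two_condition_cohort(
    genome: str,
    n_per_condition: int = 5,
    n_low: int = 1500,
    n_extra_high: int = 1200,
    seed: int = 0,
) -> dict[str, list[list[MutationRecord]]]:
    """Two-condition cohort mirroring the low/high-oxygen design.

    Low-condition samples draw ``n_low`` mutations from a background +
    MMRd-like mixture; high-condition samples add ``n_extra_high`` draws
    from the synthetic oxygen-like component on top of the same baseline.
    Returns catalogs per condition; the planted truth is that the
    difference between conditions is exactly the oxygen-like component.
    """
    sigs = load_synthetic_signatures()
    base_expo = np.array([0.15, 0.85, 0.0])  # background, mmrd, oxygen
    ox_expo = np.array([0.0, 0.0, 1.0])
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[list[MutationRecord]]] = {"low": [], "high": []}
    for i in range(n_per_condition):
        cohort["low"].append(
            gen_catalog(sigs, base_expo, n_low, genome, seed=int(rng.integers(2**31)))
        )
    for i in range(n_per_condition):
        muts = gen_catalog(sigs, base_expo, n_low, genome, seed=int(rng.integers(2**31)))
        muts += gen_catalog(sigs, ox_expo, n_extra_high, genome, seed=int(rng.integers(2**31)))
        cohort["high"].append(muts)
    return cohort
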