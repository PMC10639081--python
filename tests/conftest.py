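"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive results from first
principles (literal filter inequalities, exhaustive enumeration, naive
string scanning) so the tests check the package implementation against
an independent path, not against itself.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from isomutsig.io import COUNTS_COLUMNS

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@pytest.fixture(scope="session")
def toy_genome():
    from isomutsig import gen_genome

    return {"chr1": gen_genome(200_000, gc_fraction=0.4, seed=11)}


@pytest.fixture(scope="session")
def synthetic_signatures():
    from isomutsig import load_synthetic_signatures

    return load_synthetic_signatures()


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def naive_caller_filter(counts: pd.DataFrame, cfg) -> set[tuple]:
    """Literal re-implementation of the three filter inequalities.

    Returns the set of (sample, chrom, pos, class) tuples that pass, by
    looping over positions and samples with no vectorization tricks.
    """
    passed = set()
    samples = sorted(counts["sample"].unique())
    for (chrom, pos), grp in counts.groupby(["chrom", "pos"]):
        rows = {r["sample"]: r for r in grp.to_dict("records")}
        ref = grp["ref"].iloc[0]
        for klass in ("SBS", "INS", "DEL"):
            for s in samples:
                row = rows.get(s)
                if row is None:
                    continue
                cov = row["cov"]
                if cov < cfg.min_cov or cov == 0:
                    continue
                if klass == "SBS":
                    alts = {b: row[f"n{b}"] for b in BASES if b != ref}
                    alt_n = max(alts.values())
                    if alt_n == 0:
                        continue
                else:
                    alt_n = row["n_ins"] if klass == "INS" else row["n_del"]
                if alt_n / cov < cfg.min_alt_vaf:
                    continue
                ok = True
                for o in samples:
                    if o == s:
                        continue
                    orow = rows.get(o)
                    ocov = orow["cov"] if orow else 0
                    if ocov == 0:
                        ok = False
                        break
                    if klass == "SBS":
                        oref = orow[f"n{ref}"]
                    else:
                        oref = ocov - (orow["n_ins"] if klass == "INS" else orow["n_del"])
                    if oref / ocov < cfg.min_other_ref_af:
                        ok = False
                        break
                if ok:
                    passed.add((s, chrom, pos, klass))
    return passed


def fisher_tail_enumeration(alt_m: int, cov_m: int, alt_o: int, cov_o: int) -> float:
    """Exact directional hypergeometric tail probability by direct
    enumeration of the probability mass function with integer
    combinatorics (math.comb), independent of scipy."""
    if cov_m == 0 or cov_o == 0:
        return 1.0
    if alt_m * cov_o <= alt_o * cov_m:
        return 1.0
    N = cov_m + cov_o
    K = alt_m + alt_o
    denom = math.comb(N, cov_m)
    total = 0
    for x in range(alt_m, min(K, cov_m) + 1):
        if cov_m - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, cov_m - x)
    return total / denom


def classify_indel_oracle(record, genome) -> str:
    """Brute-force indel classifier working directly on the chromosome
    string: left-aligns by repeated single-base rotation, counts tandem
    copies by string comparison, and scans microhomology naively."""
    seq = genome[record.locus.chrom]
    seq = seq if isinstance(seq, str) else str(seq[:])
    seq = seq.upper()
    anchor = record.locus.pos  # 1-based; ref/alt share this first base
    unit = record.indel_sequence.upper()
    L = len(unit)
    # left-align (0-based index of first base of the unit is `start0`)
    start0 = anchor  # deleted/inserted unit begins right after the anchor
    while start0 > 0 and seq[start0 - 1] == unit[-1]:
        unit = seq[start0 - 1] + unit[:-1]
        start0 -= 1
    if record.mut_class == "DEL":
        after0 = start0 + L
    else:
        after0 = start0
    copies = 0
    i = after0
    while seq[i:i + L] == unit:
        copies += 1
        i += L
    if record.mut_class == "DEL":
        copies += 1
    if L == 1:
        base = unit if unit in "CT" else COMPLEMENT[unit]
        if record.mut_class == "DEL":
            return f"1:Del:{base}:{min(copies, 6) - 1}"
        return f"1:Ins:{base}:{min(copies, 5)}"
    Lc = min(L, 5)
    if record.mut_class == "INS":
        return f"{Lc}:Ins:R:{min(copies, 5)}"
    if copies >= 2:
        return f"{Lc}:Del:R:{min(copies, 6) - 1}"
    right = seq[after0:]
    left = seq[:start0]
    pre = 0
    while pre < L - 1 and pre < len(right) and unit[pre] == right[pre]:
        pre += 1
    suf = 0
    while suf < L - 1 and suf < len(left) and unit[L - 1 - suf] == left[len(left) - 1 - suf]:
        suf += 1
    mh = max(pre, suf)
    if mh == 0:
        return f"{Lc}:Del:R:0"
    max_m = {2: 1, 3: 2, 4: 3, 5: 5}[Lc]
    return f"{Lc}:Del:M:{min(mh, max_m)}"


def exhaustive_two_means(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Globally optimal 1-D 2-means by scanning all n-1 sorted split
    points; returns (border, labels) with label 1 = upper cluster."""
    v = np.sort(np.asarray(values, dtype=float))
    best = None
    for i in range(1, len(v)):
        lo, hi = v[:i], v[i:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0]:
            best = (sse, lo.mean(), hi.mean())
    _, c_lo, c_hi = best
    border = (c_lo + c_hi) / 2
    return border, (np.asarray(values) >= border).astype(int)


def nnls_projected_gradient(y: np.ndarray, A: np.ndarray, n_iter: int = 200_000,
                            lr: float | None = None) -> np.ndarray:
    """Projected-gradient non-negative least squares, an independent
    (slow) route to the same optimum as the production solver."""
    AtA = A.T @ A
    Aty = A.T @ y
    if lr is None:
        lr = 1.0 / (np.linalg.eigvalsh(AtA).max() + 1e-12)
    x = np.zeros(A.shape[1])
    for _ in range(n_iter):
        x = np.clip(x - lr * (AtA @ x - Aty), 0, None)
    return x


def random_counts_table(rng: np.random.Generator, n_positions: int, samples: list[str],
                        mutated_fraction: float = 0.2) -> pd.DataFrame:
    """Random allele-count table mixing clean, noisy and mutated sites."""
    rows = []
    for i in range(n_positions):
        pos = 100 + i
        ref = BASES[rng.integers(0, 4)]
        alt = [b for b in BASES if b != ref][rng.integers(0, 3)]
        mut_sample = None
        if rng.random() < mutated_fraction:
            mut_sample = samples[rng.integers(0, len(samples))]
        for s in samples:
            cov = int(rng.integers(0, 40))
            counts = {b: 0 for b in BASES}
            if s == mut_sample and cov > 0:
                n_alt = int(rng.binomial(cov, 0.5))
            else:
                n_alt = int(rng.binomial(cov, 0.05)) if cov > 0 else 0
            counts[alt] = n_alt
            counts[ref] = cov - n_alt
            rows.append(
                dict(sample=s, chrom="chr1", pos=pos, ref=ref, cov=cov,
                     nA=counts["A"], nC=counts["C"], nG=counts["G"], nT=counts["T"],
                     n_ins=int(rng.integers(0, 3)) if cov > 2 else 0,
                     n_del=int(rng.integers(0, 3)) if cov > 2 else 0)
            )
    return pd.DataFrame(rows)[COUNTS_COLUMNS]
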