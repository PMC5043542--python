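"""Composite LD, long-range LD-block detection, and distance pruning.

Composite LD between two SNPs is the squared Pearson correlation of their
unphased allele-dosage vectors (the Burrows-composite correlation under the
usual scaling), so no phasing is required.  An inversion appears as a block of
SNPs that stay mutually in LD (r2 above a threshold) over a span far beyond
the background LD range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LDBlock:
    """A long-range LD region (candidate inversion)."""

    chromosome: str
    first_snp: str
    last_snp: str
    first_pos: int
    last_pos: int
    max_r2_first: float  # boundary SNP's maximal r2 into the block
    max_r2_last: float
    n_snps_in_block: int
    snp_indices: tuple
    fraction_of_chromosome: float = np.nan

    @property
    def span_bp(self) -> int:
        return self.last_pos - self.first_pos


def composite_ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    Returns ``nan`` (undefined LD, distinguishable from 0) when fewer than two
    complete pairs remain or either vector is constant on the complete subset.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return min(float(r * r), 1.0)


def ld_matrix(gm, chromosome=None) -> np.ndarray:
    """All-pairs composite r2 for SNPs on one chromosome.

    Symmetric with unit diagonal where defined; columns that are constant (or
    all-missing) give ``nan`` rows/columns.
    """
    sub = gm if chromosome is None else gm.chromosome(chromosome)
    if sub.n_snps < 2:
        raise ValueError("need at least 2 SNPs for an LD matrix")
    d = sub.dosages
    if np.isnan(d).any():
        r = pd.DataFrame(d).corr(min_periods=2).to_numpy()  # pairwise complete
    else:
        sd = d.std(axis=0)
        r = np.full((d.shape[1], d.shape[1]), np.nan)
        ok = sd > 0
        if ok.sum() >= 2:
            r[np.ix_(ok, ok)] = np.corrcoef(d[:, ok], rowvar=False)
        # a constant column correlates with nothing, including itself
    r2 = r * r
    np.clip(r2, 0.0, 1.0, out=r2)
    return r2


def detect_long_range_blocks(
    ld: np.ndarray,
    positions,
    snp_ids=None,
    chromosome: str = "1",
    r2_threshold: float = 0.1,
    min_span_bp: float = 1_000_000,
    min_connect_frac: float = 0.8,
) -> list:
    """Find clusters of SNPs mutually in LD over long physical spans.

    Greedy quasi-clique growth: seed at the SNP with the most above-threshold
    partners, then repeatedly admit the SNP connected (r2 > threshold) to at
    least ``min_connect_frac`` of current members, preferring the candidate
    with the highest mean r2 into the block.  Clusters whose physical span
    exceeds ``min_span_bp`` are reported as blocks, boundary SNPs being the
    first and last members by position.
    """
    positions = np.asarray(positions)
    n = positions.size
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(n)]
    snp_ids = list(snp_ids)
    chrom_len = float(positions[-1] - positions[0]) if n > 1 else np.nan

    adj = np.nan_to_num(np.asarray(ld, dtype=float), nan=0.0) > r2_threshold
    np.fill_diagonal(adj, False)
    ld0 = np.nan_to_num(np.asarray(ld, dtype=float), nan=0.0)

    unused = np.ones(n, dtype=bool)
    blocks = []
    while True:
        degree = (adj & unused[None, :]).sum(axis=1) * unused
        seed = int(np.argmax(degree))
        if degree[seed] < 1:
            break
        members = [seed]
        in_block = np.zeros(n, dtype=bool)
        in_block[seed] = True
        while True:
            cand = unused & ~in_block
            if not cand.any():
                break
            conn = adj[:, in_block].mean(axis=1)
            conn[~cand] = -1.0
            eligible = conn >= min_connect_frac
            if not eligible.any():
                break
            mean_r2 = ld0[:, in_block].mean(axis=1)
            mean_r2[~eligible] = -1.0
            nxt = int(np.argmax(mean_r2))
            members.append(nxt)
            in_block[nxt] = True
        unused[in_block] = False
        if len(members) < 2:
            continue
        idx = np.sort(members)
        span = positions[idx[-1]] - positions[idx[0]]
        if span <= min_span_bp:
            continue
        inner_first = ld0[idx[0], idx[1:]]
        inner_last = ld0[idx[-1], idx[:-1]]
        blocks.append(
            LDBlock(
                chromosome=chromosome,
                first_snp=snp_ids[idx[0]],
                last_snp=snp_ids[idx[-1]],
                first_pos=int(positions[idx[0]]),
                last_pos=int(positions[idx[-1]]),
                max_r2_first=float(inner_first.max()),
                max_r2_last=float(inner_last.max()),
                n_snps_in_block=len(idx),
                snp_indices=tuple(int(j) for j in idx),
                fraction_of_chromosome=float(span / chrom_len) if chrom_len else np.nan,
            )
        )
    blocks.sort(key=lambda b: b.first_pos)
    return blocks


def prune_by_distance(positions, min_gap_bp: float = 185_000) -> np.ndarray:
    """Earliest-finish-time greedy SNP thinning.

    Keeps the first SNP, then every subsequent SNP whose gap to the last kept
    SNP strictly exceeds ``min_gap_bp``.  For points on a line this greedy
    rule attains the maximum number of retained SNPs.
    """
    positions = np.asarray(positions)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if positions.size == 0:
        return np.array([], dtype=int)
    keep = [0]
    for j in range(1, positions.size):
        if positions[j] - positions[keep[-1]] > min_gap_bp:
            keep.append(j)
    return np.asarray(keep, dtype=int)


def interlocus_ld_multiallele(calls_a, calls_b, min_overlap: int = 10):
    """Association between two (possibly multi-allelic) inversion loci.

    Builds the two-locus genotype-class contingency table over individuals
    called at both loci and reports a chi-square test with an r2-analogue,
    chi2 / (n * min(rows-1, cols-1)) (squared Cramer's V); for two biallelic
    loci in perfect coupling this equals 1.

    ``calls_a``/``calls_b`` map individual id -> genotype label (pandas Series
    indexed by id, or dict); no-calls must already be absent/NaN.
    """
    sa = pd.Series(calls_a).dropna()
    sb = pd.Series(calls_b).dropna()
    common = sa.index.intersection(sb.index)
    if len(common) < min_overlap:
        raise ValueError(f"need >= {min_overlap} individuals called at both loci")
    table = pd.crosstab(sa.loc[common], sb.loc[common]).to_numpy()
    if min(table.shape) < 2:
        return np.nan, np.nan  # monomorphic locus: LD undefined
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    n = table.sum()
    r2 = chi2 / (n * (min(table.shape) - 1))
    return float(min(r2, 1.0)), float(p)
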