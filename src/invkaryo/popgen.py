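"""Allele frequencies, Hardy-Weinberg tests, and segregation distortion.

Works on karyotype genotype labels ("AA", "AB", ..., single letters for
hemizygotes) rather than raw SNPs, so the same machinery serves inversion
loci with two or three arrangements on autosomes or the Z chromosome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AlleleFreqs:
    frequencies: dict  # allele letter -> frequency
    copy_counts: dict  # allele letter -> allele copies observed
    n_individuals: int
    sex_linked: bool = False

    def __post_init__(self) -> None:
        tot = sum(self.frequencies.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")


@dataclass
class HWEResult:
    chi2: float
    df: int
    p_value: float
    observed: dict  # genotype -> count
    expected: dict
    direction: str  # "heterozygote excess" | "heterozygote deficit" | "none"


@dataclass
class TransmissionCounts:
    """Major/minor transmissions from heterokaryotypic parents."""

    n_major: int
    n_minor: int
    subset: str = "both"

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0:
            raise ValueError("counts must be non-negative")


def _genotype_labels(calls):
    """Accept a KaryotypeCalls, Series, or iterable of genotype labels."""
    if hasattr(calls, "genotypes"):
        s = calls.genotypes
    else:
        s = pd.Series(list(calls))
    s = s.dropna()
    return [g for g in s if isinstance(g, str) and g != "NN"]


def allele_frequencies(calls, sex_linked: bool = False) -> AlleleFreqs:
    """Allele frequencies from genotype labels.

    Diploid labels ("AA") contribute two copies; hemizygous single-letter
    labels contribute one.  No-calls are excluded.
    """
    labels = _genotype_labels(calls)
    if not labels:
        raise ValueError("no called individuals")
    copies: Counter = Counter()
    for g in labels:
        copies.update(g)
    total = sum(copies.values())
    freqs = {a: c / total for a, c in sorted(copies.items())}
    return AlleleFreqs(freqs, dict(sorted(copies.items())), len(labels), sex_linked)


def hwe_chi_square(genotype_counts: dict, n_alleles: int | None = None) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts`` maps diploid genotype labels (e.g. "AA", "AB") to
    counts; allele frequencies are estimated from these same counts.
    Degrees of freedom = genotype classes - alleles (1 for biallelic, 3 for
    triallelic diploids).
    """
    alleles = sorted({a for g in genotype_counts for a in g})
    if n_alleles is not None and len(alleles) != n_alleles:
        # absent alleles can't be tested; classes are defined by observed alleles
        alleles = sorted(alleles)
    n = sum(genotype_counts.values())
    if n < 1:
        raise ValueError("no individuals")
    copies = Counter()
    for g, c in genotype_counts.items():
        for ch in g:
            copies[ch] += c
    total = 2 * n
    p = {a: copies[a] / total for a in alleles}
    observed, expected = {}, {}
    for a, b in combinations_with_replacement(alleles, 2):
        g = a + b
        observed[g] = genotype_counts.get(g, 0)
        expected[g] = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
    for g, e in expected.items():
        if e == 0 and observed[g] > 0:
            raise ValueError(f"expected count 0 for observed class {g}")
    chi2 = sum(
        (observed[g] - e) ** 2 / e for g, e in expected.items() if e > 0
    )
    df = len(expected) - len(alleles)
    if df < 1:
        raise ValueError("not enough genotype classes for a HWE test")
    pval = float(stats.chi2.sf(chi2, df))
    obs_het = sum(c for g, c in observed.items() if g[0] != g[1])
    exp_het = sum(e for g, e in expected.items() if g[0] != g[1])
    direction = (
        "heterozygote excess"
        if obs_het > exp_het
        else "heterozygote deficit"
        if obs_het < exp_het
        else "none"
    )
    return HWEResult(float(chi2), df, pval, observed, expected, direction)


def hwe_exact(genotype_counts) -> float:
    """Exact conditional HWE test for a biallelic locus.

    ``genotype_counts`` is (n_AA, n_AB, n_BB).  The P value enumerates all
    heterozygote counts compatible with the observed allele counts and sums
    the probabilities of configurations no more likely than the observed one
    (the standard conditional exact test).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n == 0:
        return 1.0
    rare = min(n_a, n_b)

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = (max(n_a, n_b) - het) // 2
        return (
            lgamma(n + 1)
            - lgamma(hom_rare + 1)
            - lgamma(het + 1)
            - lgamma(hom_common + 1)
            + het * np.log(2)
            + lgamma(n_a + 1)
            + lgamma(n_b + 1)
            - lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = list(hets).index(n_ab)
    return float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())


def segregation_binomial(transmissions: TransmissionCounts) -> float:
    """Exact two-sided binomial test of fair (50:50) transmission.

    Two-sidedness follows the minimum-likelihood convention (sum of outcome
    probabilities no larger than the observed outcome's).
    """
    n = transmissions.n_major + transmissions.n_minor
    if n < 1:
        raise ValueError("no transmissions")
    return float(stats.binomtest(transmissions.n_major, n, 0.5).pvalue)


def count_transmissions(pedigree, calls, parent: str = "both",
                        allele_pair: tuple | None = None) -> TransmissionCounts:
    """Count major/minor allele transmissions from heterokaryotypic parents.

    For each trio whose focal parent is heterozygous (for ``allele_pair`` when
    given, e.g. ("A", "B") on a triallelic locus), the transmitted allele is
    the focal parent's allele consistent with the offspring genotype, using
    the other parent's genotype to resolve which allele the offspring's second
    copy came from.  Trios that remain ambiguous (e.g. both parents AB with an
    AB offspring) are skipped.
    """
    geno = calls.genotypes if hasattr(calls, "genotypes") else pd.Series(calls)
    n_major = n_minor = 0
    freqs = allele_frequencies(geno)

    def _candidates(g_par: str, g_off: str, g_other) -> set:
        cands = set()
        for a in set(g_par):
            if a not in g_off:
                continue
            remaining = g_off.replace(a, "", 1)
            if g_other is None or not isinstance(g_other, str) or remaining in g_other:
                cands.add(a)
        return cands

    for trio in pedigree.trios.itertuples(index=False):
        focal = {"sire": [(trio.sire, trio.dam)], "dam": [(trio.dam, trio.sire)]}.get(
            parent, [(trio.sire, trio.dam), (trio.dam, trio.sire)]
        )
        for par, other in focal:
            g_par = geno.get(par) if par else None
            g_off = geno.get(trio.id)
            g_other = geno.get(other) if other else None
            if not isinstance(g_par, str) or not isinstance(g_off, str):
                continue
            if len(g_par) != 2 or g_par[0] == g_par[1] or len(g_off) != 2:
                continue
            pair = tuple(sorted(g_par))
            if allele_pair is not None and pair != tuple(sorted(allele_pair)):
                continue
            cands = _candidates(g_par, g_off, g_other)
            if len(cands) != 1:
                continue  # untransmittable or ambiguous
            a, b = pair
            major = a if freqs.frequencies.get(a, 0) >= freqs.frequencies.get(b, 0) else b
            if cands.pop() == major:
                n_major += 1
            else:
                n_minor += 1
    return TransmissionCounts(n_major, n_minor, subset=parent)
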