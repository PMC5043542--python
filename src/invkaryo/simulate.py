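"""Synthetic data with the statistical structure of a segregating inversion.

The generator emulates a chromosome carrying an inverted region in which 2 or
3 non-recombining haplotype classes segregate at configured frequencies.
Class-diagnostic SNPs are concentrated near the breakpoints (where
recombination in heterokaryotypes is fully suppressed); interior diagnostic
SNPs are eroded by gene flux, modelled as an independent per-copy,
per-SNP class exchange.  Collinear background SNPs carry short-range LD from a
latent Gaussian AR(1) copying process whose correlation decays with physical
distance, so that background r2 > 0.1 does not extend beyond a couple of
hundred kb.

All generators derive independent substreams from a single seed via
``numpy.random.SeedSequence.spawn`` and are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from invkaryo.genio import GenotypeMatrix, PhenotypeTable, PooledCounts

CLASS_LABELS = "ABC"


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome.

    Defaults describe a 1000-individual sample genotyped at 200 evenly spaced
    SNPs on a 20-Mb chromosome, with a 10-Mb inversion segregating at
    frequency 0.6/0.4, fully diagnostic breakpoint SNPs and 5% interior gene
    flux.
    """

    n_individuals: int = 1000
    n_snps: int = 200
    chrom_length: int = 20_000_000
    inv_start: int = 5_000_000
    inv_end: int = 15_000_000
    n_haplotype_classes: int = 2
    class_freqs: tuple = (0.6, 0.4)
    breakpoint_divergence: float = 1.0
    gene_flux_rate: float = 0.05
    collinear_recomb: float = 1.0 / 100_000  # latent AR(1) decay rate per bp
    breakpoint_frac: float = 0.15  # fraction of inversion length forming each breakpoint zone
    sex_linked: bool = False
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not (0 < self.inv_start < self.inv_end <= self.chrom_length):
            raise ValueError("require 0 < inv_start < inv_end <= chrom_length")
        if self.n_haplotype_classes not in (2, 3):
            raise ValueError("n_haplotype_classes must be 2 or 3")
        if len(self.class_freqs) != self.n_haplotype_classes and len(self.class_freqs) != 1:
            raise ValueError("class_freqs length must match n_haplotype_classes (or be (1.0,))")
        if abs(sum(self.class_freqs) - 1.0) > 1e-9:
            raise ValueError("class_freqs must sum to 1")
        for p in (
            *self.class_freqs,
            self.breakpoint_divergence,
            self.gene_flux_rate,
            self.missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for recovery tests."""

    karyotypes: list  # per individual: e.g. "AB" (diploid) or "A" (hemizygous)
    class_copies: np.ndarray  # n_individuals x 2 class indices (-1 = absent copy)
    block_snp_range: tuple  # (first, last) SNP index inside the inversion
    block_bp: tuple  # (inv_start, inv_end)
    diagnostic: np.ndarray  # per SNP: True if class-diagnostic
    breakpoint_zone: np.ndarray  # per SNP: True if in a breakpoint-proximal zone
    haplotypes: np.ndarray  # haplotype copies x SNPs (0/1 alleles)
    copy_classes: np.ndarray = None  # per haplotype copy: its class index
    class_order: list = field(default_factory=list)  # class index sorted by descending freq
    effects: dict = field(default_factory=dict)


def _class_label(cfg_order, class_idx) -> str:
    return CLASS_LABELS[cfg_order.index(class_idx)]


def simulate_inversion_genotypes(config: SimConfig):
    """Simulate a dosage matrix for one chromosome carrying an inversion.

    Returns ``(GenotypeMatrix, SimTruth)``.  Individuals receive two haplotype
    copies (one for hemizygous females when ``sex_linked``) whose classes are
    drawn independently from ``class_freqs`` (random mating).
    """
    cfg = config
    rng_struct, rng_hap, rng_bg, rng_miss = [
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(4)
    ]
    positions = np.unique(
        np.round(np.linspace(1, cfg.chrom_length, cfg.n_snps)).astype(int)
    )
    if positions.size != cfg.n_snps:
        raise ValueError("chromosome too short to place distinct SNP positions")
    inv_mask = (positions >= cfg.inv_start) & (positions <= cfg.inv_end)
    if inv_mask.sum() < 2:
        raise ValueError("fewer than 2 SNPs fall inside the inversion; increase n_snps")
    zone = cfg.breakpoint_frac * (cfg.inv_end - cfg.inv_start)
    bp_zone = inv_mask & (
        (positions <= cfg.inv_start + zone) | (positions >= cfg.inv_end - zone)
    )

    n = cfg.n_individuals
    sexes = np.array(["M", "F"])[np.arange(n) % 2]
    hemi = (sexes == "F") & cfg.sex_linked
    n_copies = np.where(hemi, 1, 2)
    copy_owner = np.repeat(np.arange(n), n_copies)
    n_hap = copy_owner.size

    freqs = np.asarray(cfg.class_freqs, dtype=float)
    k = freqs.size
    hap_class = rng_struct.choice(k, size=n_hap, p=freqs)

    # Diagnostic status and target class per inversion SNP.
    diagnostic = np.zeros(positions.size, dtype=bool)
    diagnostic[inv_mask] = rng_struct.random(inv_mask.sum()) < cfg.breakpoint_divergence
    target_class = np.full(positions.size, -1)
    target_class[diagnostic] = rng_struct.integers(0, k, size=diagnostic.sum())

    H = np.zeros((n_hap, positions.size), dtype=np.int8)

    # Class-diagnostic columns: allele 1 marks the SNP's target class.
    diag_idx = np.flatnonzero(diagnostic)
    if diag_idx.size:
        H[:, diag_idx] = (hap_class[:, None] == target_class[diag_idx][None, :]).astype(np.int8)
        # Gene flux erodes interior (non-breakpoint) diagnostic SNPs: a copy
        # exchanges its allele with a uniformly drawn other class.
        interior = diag_idx[~bp_zone[diag_idx]]
        if interior.size and cfg.gene_flux_rate > 0 and k > 1:
            flux = rng_hap.random((n_hap, interior.size)) < cfg.gene_flux_rate
            shift = rng_hap.integers(1, k, size=(n_hap, interior.size))
            donor = (hap_class[:, None] + shift) % k
            fluxed = (donor == target_class[interior][None, :]).astype(np.int8)
            H[:, interior] = np.where(flux, fluxed, H[:, interior])

    # Background SNPs (collinear region + non-diagnostic interior SNPs):
    # latent AR(1) per haplotype copy thresholded at each SNP's allele
    # frequency, giving distance-decaying LD.  Non-diagnostic SNPs inside a
    # breakpoint zone stay monomorphic: recombination suppression is near
    # total there, so the zone carries no shared polymorphism, only
    # class-diagnostic divergence (this reproduces the slight dip in
    # diversity at breakpoints relative to the flux-exposed interior).
    bg_idx = np.flatnonzero(~diagnostic & ~bp_zone)
    if bg_idx.size:
        p_bg = rng_struct.uniform(0.1, 0.5, size=bg_idx.size)
        z = np.empty((n_hap, bg_idx.size))
        z[:, 0] = rng_bg.standard_normal(n_hap)
        gaps = np.diff(positions[bg_idx]).astype(float)
        rho = np.exp(-gaps * cfg.collinear_recomb)
        for t in range(1, bg_idx.size):
            e = rng_bg.standard_normal(n_hap)
            z[:, t] = rho[t - 1] * z[:, t - 1] + np.sqrt(1 - rho[t - 1] ** 2) * e
        H[:, bg_idx] = (z <= stats.norm.ppf(p_bg)[None, :]).astype(np.int8)

    # Collapse copies to dosages.
    dosages = np.zeros((n, positions.size))
    np.add.at(dosages, copy_owner, H.astype(float))
    if cfg.missing_rate > 0:
        miss = rng_miss.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan

    samples = pd.DataFrame({"id": [f"ind{i:05d}" for i in range(n)], "sex": sexes})
    snps = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(positions.size)],
            "chrom": cfg.chrom,
            "pos": positions,
        }
    )
    gm = GenotypeMatrix(samples, snps, dosages, sex_linked=cfg.sex_linked)

    # Class labels ordered by descending configured frequency (A = most common).
    order = list(np.argsort(-freqs, kind="stable"))
    class_copies = np.full((n, 2), -1)
    first_copy = np.searchsorted(copy_owner, np.arange(n))
    for i in range(n):
        cls = sorted(
            hap_class[first_copy[i] : first_copy[i] + n_copies[i]],
            key=lambda c: order.index(c),
        )
        class_copies[i, : len(cls)] = cls
    karyotypes = [
        "".join(_class_label(order, c) for c in row if c >= 0) for row in class_copies
    ]
    inv_idx = np.flatnonzero(inv_mask)
    truth = SimTruth(
        karyotypes=karyotypes,
        class_copies=class_copies,
        block_snp_range=(int(inv_idx[0]), int(inv_idx[-1])),
        block_bp=(cfg.inv_start, cfg.inv_end),
        diagnostic=diagnostic,
        breakpoint_zone=bp_zone,
        haplotypes=H,
        copy_classes=hap_class,
        class_order=order,
    )
    return gm, truth


def simulate_pooled_counts(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    coverage: float,
    seed: int,
    chrom: str = "1",
) -> PooledCounts:
    """Pooled-sequencing read counts over a pool of haplotypes.

    Depth per site is Poisson(``coverage``); reads carrying the alternative
    allele are binomial at the pooled allele frequency.  Counts are reported
    major/minor per site.
    """
    H = np.asarray(haplotypes)
    if H.size == 0:
        raise ValueError("empty haplotype pool")
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    freq = H.mean(axis=0)
    depth = rng.poisson(coverage, size=freq.size)
    alt = rng.binomial(depth, freq)
    ref = depth - alt
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=int),
            "n_maj": np.maximum(alt, ref),
            "n_min": np.minimum(alt, ref),
        }
    )
    return PooledCounts(sites)


def simulate_phenotypes(
    karyotypes,
    a: float,
    d: float,
    noise_sd: float,
    seed: int,
    sexes=None,
    ids=None,
) -> PhenotypeTable:
    """Phenotypes with additive and dominance inversion effects plus noise.

    y = a*X_add + d*X_dom + Normal(0, noise_sd^2), with X_add coded
    1/0/-1 for major-hom/het/minor-hom and X_dom = 1 for heterokaryotypes.
    Effects are in units of the phenotype's residual standard deviation when
    ``noise_sd`` is 1.
    """
    from invkaryo.assoc import code_additive_dominance

    karyotypes = list(karyotypes)
    coding = code_additive_dominance(karyotypes)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    y = (
        a * np.where(np.isnan(coding.x_add), 0.0, coding.x_add)
        + d * np.where(np.isnan(coding.x_dom), 0.0, coding.x_dom)
        + rng.normal(0.0, noise_sd, size=len(karyotypes))
    )
    n = len(karyotypes)
    data = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"ind{i:05d}" for i in range(n)],
            "sex": sexes if sexes is not None else np.array(["M", "F"])[np.arange(n) % 2],
            "karyotype": karyotypes,
            "trait": y,
        }
    )
    return PhenotypeTable(data, trait_columns=("trait",))


def simulate_breeding_records(
    pairs: pd.DataFrame,
    baseline_mortality: float,
    or_het_sire: float,
    or_het_dam: float,
    eggs_per_pair: int,
    seed: int,
) -> pd.DataFrame:
    """Per-egg death records with parent-heterokaryotype odds ratios.

    ``pairs`` needs boolean columns ``sire_het`` and ``dam_het``.  Each egg
    dies with probability expit(logit(baseline) + log(OR_sire)*sire_het +
    log(OR_dam)*dam_het); infertile eggs are outside this model by
    construction.
    """
    if not 0.0 < baseline_mortality < 1.0:
        raise ValueError("baseline mortality must be in (0, 1)")
    if or_het_sire <= 0 or or_het_dam <= 0:
        raise ValueError("odds ratios must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    logit = np.log(baseline_mortality / (1 - baseline_mortality))
    eta = (
        logit
        + np.log(or_het_sire) * pairs["sire_het"].to_numpy(dtype=float)
        + np.log(or_het_dam) * pairs["dam_het"].to_numpy(dtype=float)
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    records = pairs.loc[pairs.index.repeat(eggs_per_pair)].reset_index(drop=True)
    records["died"] = rng.random(len(records)) < np.repeat(p, eggs_per_pair)
    records["died"] = records["died"].astype(int)
    return records


def simulate_transmissions(
    n_het_parents: int,
    offspring_per_parent: int,
    distortion_k: float,
    seed: int,
    label: str = "both",
):
    """Transmission counts from heterokaryotypic parents.

    ``distortion_k`` is the probability a parent transmits its major allele;
    0.5 is fair Mendelian segregation.  Per-parent binomial draws are summed.
    """
    from invkaryo.popgen import TransmissionCounts

    if not 0.0 <= distortion_k <= 1.0:
        raise ValueError("distortion_k must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    major = int(rng.binomial(offspring_per_parent, distortion_k, size=n_het_parents).sum())
    total = n_het_parents * offspring_per_parent
    return TransmissionCounts(n_major=major, n_minor=total - major, subset=label)


def simulate_aviaries(
    karyotypes,
    n_aviaries: int,
    slope: float,
    seed: int,
    noise_sd: float = 1.0,
    intercept: float = 0.0,
    sexes=None,
    ids=None,
) -> pd.DataFrame:
    """Aviary groups with fitness tied to the frequency-sum predictor.

    Individuals are randomly partitioned into ``n_aviaries`` groups; fitness is
    intercept + slope * (sum of aviary-specific frequencies of the bird's two
    inversion alleles) + Gaussian noise.
    """
    from invkaryo.assoc import freq_dep_predictor

    karyotypes = list(karyotypes)
    n = len(karyotypes)
    if n < 2 * n_aviaries:
        raise ValueError("need at least 2 birds per aviary")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    aviary = np.arange(n) % n_aviaries
    rng.shuffle(aviary)
    df = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"ind{i:05d}" for i in range(n)],
            "sex": sexes if sexes is not None else ["M"] * n,
            "karyotype": karyotypes,
            "aviary": aviary,
        }
    )
    pred = freq_dep_predictor(
        df["karyotype"], df["aviary"], sexes=df["sex"], focal_sex=None
    )
    df["freq_sum"] = pred.predictor
    df["fitness"] = intercept + slope * df["freq_sum"] + rng.normal(0, noise_sd, n)
    return df
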