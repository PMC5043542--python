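"""Genotype, pooled-count, pedigree, and phenotype I/O plus genotype QC.

Containers are thin dataclasses around pandas/numpy objects.  Coordinates are
1-based inclusive throughout (VCF convention); BED export converts to 0-based
half-open.  Missing genotypes are stored as ``NaN`` in a float dosage matrix
and are excluded pairwise in all downstream correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = np.nan

SEXES = ("M", "F", "U")


class GenotypeIOError(ValueError):
    """Malformed genotype input (carries the offending line number)."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-dosage matrix with sample sex and SNP positions.

    ``dosages[i, j]`` counts copies of the coded (ALT) allele carried by sample
    ``i`` at SNP ``j``: {0, 1, 2} for diploid entries, {0, 1} for hemizygous
    females at sex-linked loci, ``NaN`` for missing.
    """

    samples: pd.DataFrame  # columns: id, sex
    snps: pd.DataFrame  # columns: id, chrom, pos
    dosages: np.ndarray  # float, n_samples x n_snps
    sex_linked: bool = False

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if self.snps["id"].duplicated().any():
            raise ValueError("duplicate SNP identifiers")
        for _, sub in self.snps.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValueError("dosages out of [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def hemizygous_mask(self) -> np.ndarray:
        """Boolean per sample: single-copy carrier (female at a sex-linked locus)."""
        if not self.sex_linked:
            return np.zeros(self.n_samples, dtype=bool)
        return (self.samples["sex"] == "F").to_numpy()

    def ploidy(self) -> np.ndarray:
        return np.where(self.hemizygous_mask(), 1, 2)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        sj = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=self.samples.iloc[si],
            snps=self.snps.iloc[sj],
            dosages=self.dosages[np.ix_(si, sj)],
            sex_linked=self.sex_linked,
        )

    def chromosome(self, chrom) -> "GenotypeMatrix":
        idx = np.flatnonzero((self.snps["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise ValueError(f"no SNPs on chromosome {chrom!r}")
        return self.subset(snp_idx=idx)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def missing_fraction_per_snp(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class PooledCounts:
    """Per-site major/minor read counts from pooled sequencing.

    ``sites`` columns: chrom, pos, n_maj, n_min with n_maj >= n_min >= 0.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        req = {"chrom", "pos", "n_maj", "n_min"}
        if not req.issubset(self.sites.columns):
            raise ValueError(f"pooled counts need columns {sorted(req)}")
        if (self.sites["n_min"] < 0).any() or (self.sites["n_maj"] < self.sites["n_min"]).any():
            raise ValueError("require n_maj >= n_min >= 0 at every site")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class Pedigree:
    """Offspring-sire-dam trios with an optional inbreeding coefficient F."""

    trios: pd.DataFrame  # columns: id, sire, dam, optional F; founders have NA parents

    def __post_init__(self) -> None:
        self.trios = self.trios.reset_index(drop=True)
        if self.trios["id"].duplicated().any():
            raise ValueError("duplicate individual in pedigree")
        parent = {}
        for row in self.trios.itertuples(index=False):
            parent[row.id] = [p for p in (row.sire, row.dam) if isinstance(p, str) and p]
        for start in parent:
            seen, stack = set(), list(parent[start])
            while stack:
                node = stack.pop()
                if node == start:
                    raise ValueError(f"{start} is its own ancestor")
                if node in seen:
                    continue
                seen.add(node)
                stack.extend(parent.get(node, []))


@dataclass
class PhenotypeTable:
    """Per-individual trait values with sex and covariates."""

    data: pd.DataFrame  # columns: id, sex, trait columns, covariates
    trait_columns: tuple = ()

    def z_transform(self, trait: str, by: str | None = None) -> pd.Series:
        """Z-transform a trait, optionally within groups (e.g. per population)."""

        def _z(x: pd.Series) -> pd.Series:
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"trait {trait!r} has no finite variance")
            return (x - x.mean()) / sd

        col = self.data[trait]
        if by is None:
            return _z(col)
        return col.groupby(self.data[by]).transform(_z)


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _gt_to_dosage(gt: str, hemizygous: bool, lineno: int):
    """Decode a VCF GT field to a dosage; returns (dosage, het_conflict_flag)."""
    gt = gt.split(":", 1)[0].replace("|", "/")
    alleles = gt.split("/")
    if alleles in (["."], [".", "."]):
        return MISSING, False
    try:
        vals = [int(a) for a in alleles]
    except ValueError as exc:
        raise GenotypeIOError(f"line {lineno}: unparsable GT {gt!r}") from exc
    if any(v not in (0, 1) for v in vals):
        raise GenotypeIOError(f"line {lineno}: non-biallelic allele index in GT {gt!r}")
    if hemizygous:
        if len(vals) == 1:
            return float(vals[0]), False
        if vals[0] != vals[1]:  # het call impossible with one chromosome copy
            return MISSING, True
        return float(vals[0]), False
    if len(vals) == 1:  # haploid-coded entry for a diploid sample
        raise GenotypeIOError(f"line {lineno}: haploid GT {gt!r} for diploid sample")
    return float(sum(vals)), False


def read_vcf(path, sex_map=None, sex_linked: bool = False):
    """Read a (plain-text) VCF with GT calls into a GenotypeMatrix.

    Multi-allelic sites are rejected and reported.  Heterozygous calls in
    hemizygous females at sex-linked loci are set missing and counted in the
    report under ``het_in_hemizygous``.
    """
    sex_map = sex_map or {}
    sample_ids: list[str] = []
    snp_rows, dosage_cols = [], []
    report = {"multiallelic_skipped": 0, "het_in_hemizygous": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            if not sample_ids:
                raise GenotypeIOError(f"line {lineno}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 10:
                raise GenotypeIOError(f"line {lineno}: fewer than 10 VCF columns")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                report["multiallelic_skipped"] += 1
                continue
            try:
                pos = int(pos)
            except ValueError as exc:
                raise GenotypeIOError(f"line {lineno}: bad position {fields[1]!r}") from exc
            hemi = [sex_linked and sex_map.get(s, "U") == "F" for s in sample_ids]
            col = np.empty(len(sample_ids))
            for i, raw in enumerate(fields[9:]):
                col[i], conflict = _gt_to_dosage(raw, hemi[i], lineno)
                report["het_in_hemizygous"] += conflict
            snp_rows.append((vid if vid != "." else f"{chrom}:{pos}", chrom, pos, ref, alt))
            dosage_cols.append(col)
    snps = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    samples = pd.DataFrame(
        {"id": sample_ids, "sex": [sex_map.get(s, "U") for s in sample_ids]}
    )
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(sample_ids), 0))
    gm = GenotypeMatrix(samples, snps, dosages, sex_linked=sex_linked)
    return gm, report


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF 4.2 file (lossless with read_vcf)."""
    hemi = gm.hemizygous_mask()
    has_alleles = {"ref", "alt"}.issubset(gm.snps.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["id"])
            + "\n"
        )
        for j, snp in enumerate(gm.snps.itertuples(index=False)):
            ref = snp.ref if has_alleles else "A"
            alt = snp.alt if has_alleles else "T"
            gts = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    gts.append("." if hemi[i] else "./.")
                elif hemi[i]:
                    gts.append(str(int(d)))
                else:
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    """Write the TSV dosage dialect.

    Layout: ``#snp <id> <chrom> <pos>`` metadata line per SNP, a ``#sexlinked``
    flag line, then a header row ``sample <sex> <snp ids...>`` and one dosage
    row per sample (missing as ``NA``).
    """
    with open(path, "w") as fh:
        fh.write(f"#sexlinked\t{int(gm.sex_linked)}\n")
        for snp in gm.snps.itertuples(index=False):
            fh.write(f"#snp\t{snp.id}\t{snp.chrom}\t{snp.pos}\n")
        fh.write("sample\tsex\t" + "\t".join(gm.snps["id"]) + "\n")
        for i, s in enumerate(gm.samples.itertuples(index=False)):
            row = ["NA" if np.isnan(d) else str(int(d)) for d in gm.dosages[i]]
            fh.write(f"{s.id}\t{s.sex}\t" + "\t".join(row) + "\n")


def read_dosage_tsv(path) -> GenotypeMatrix:
    snp_rows, body = [], []
    sex_linked = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#sexlinked"):
                sex_linked = bool(int(line.split("\t")[1]))
            elif line.startswith("#snp"):
                parts = line.split("\t")
                if len(parts) != 4:
                    raise GenotypeIOError(f"line {lineno}: malformed #snp line")
                snp_rows.append((parts[1], parts[2], int(parts[3])))
            elif line:
                body.append(line)
    if not body:
        raise GenotypeIOError("no sample rows found")
    header = body[0].split("\t")
    snps = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos"])
    if header[2:] != list(snps["id"]):
        raise GenotypeIOError("header SNP order disagrees with #snp metadata")
    ids, sexes, rows = [], [], []
    for lineno, line in enumerate(body[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise GenotypeIOError(f"sample row {lineno}: wrong field count")
        ids.append(parts[0])
        sexes.append(parts[1])
        rows.append([MISSING if v == "NA" else float(v) for v in parts[2:]])
    samples = pd.DataFrame({"id": ids, "sex": sexes})
    return GenotypeMatrix(samples, snps, np.asarray(rows), sex_linked=sex_linked)


def read_genotypes(path, format: str = "vcf", sex_map=None, sex_linked: bool = False):
    """Read genotypes from ``vcf`` or ``tsv``; returns (GenotypeMatrix, report)."""
    if format == "vcf":
        return read_vcf(path, sex_map=sex_map, sex_linked=sex_linked)
    if format == "tsv":
        return read_dosage_tsv(path), {}
    raise ValueError(f"unknown format {format!r}")


def write_pooled_counts(pc: PooledCounts, path) -> None:
    pc.sites.to_csv(path, sep="\t", index=False)


def read_pooled_counts(path) -> PooledCounts:
    return PooledCounts(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_blocks_bed(blocks, path) -> None:
    """Write LD blocks as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.first_pos - 1}\t{b.last_pos}\t{b.first_snp};{b.last_snp}\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter_individuals(gm: GenotypeMatrix, max_missing: float = 0.05):
    """Drop individuals whose missing call rate is strictly larger than the cutoff.

    Returns the filtered matrix and a report DataFrame of removed individuals.
    """
    frac = gm.missing_fraction_per_sample()
    drop = frac > max_missing
    if drop.all():
        raise ValueError("all individuals fail the missingness filter")
    report = pd.DataFrame(
        {"id": gm.samples["id"][drop], "missing_fraction": frac[drop], "reason": "missing_rate"}
    )
    return gm.subset(sample_idx=np.flatnonzero(~drop)), report


def qc_filter_snps(
    gm: GenotypeMatrix,
    max_missing: float = 0.1,
    hwe_alpha: float = 0.05,
    bonferroni: bool = True,
):
    """Drop SNPs with missing rate > cutoff, monomorphic SNPs, and strong HWE deviants.

    The exact HWE test (conditional on allele counts) is applied to diploid
    genotype counts; the significance threshold is ``hwe_alpha`` divided by the
    number of SNPs tested when ``bonferroni`` is set.
    """
    from invkaryo.popgen import hwe_exact

    n = gm.n_snps
    alpha = hwe_alpha / n if bonferroni else hwe_alpha
    miss = gm.missing_fraction_per_snp()
    diploid = ~gm.hemizygous_mask()
    reasons = {}
    for j in range(n):
        if miss[j] > max_missing:
            reasons[j] = "missing_rate"
            continue
        col = gm.dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0 or np.all(obs == obs[0]) or obs.mean() in (0.0, 2.0):
            reasons[j] = "monomorphic"
            continue
        dip = gm.dosages[diploid, j]
        dip = dip[~np.isnan(dip)]
        counts = (int((dip == 0).sum()), int((dip == 1).sum()), int((dip == 2).sum()))
        if sum(counts) > 0 and hwe_exact(counts) < alpha:
            reasons[j] = "hwe"
    keep = np.array([j for j in range(n) if j not in reasons], dtype=int)
    report = pd.DataFrame(
        {
            "id": gm.snps["id"].iloc[list(reasons)].to_numpy(),
            "reason": list(reasons.values()),
        }
    )
    return gm.subset(snp_idx=keep), report


def recode_to_minor_allele(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip dosage columns so that dosage counts the minor allele.

    Minor status is computed on the current (post-QC) sample; at a 50/50 tie
    the alphabetically first allele (or the current coding when allele labels
    are absent) is kept as the counted allele.
    """
    ploidy = gm.ploidy()[:, None].astype(float)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(gm.dosages, axis=0) / np.nansum(
            np.where(np.isnan(gm.dosages), 0, ploidy), axis=0
        )
    flip = freq > 0.5
    if {"ref", "alt"}.issubset(gm.snps.columns):
        ties = freq == 0.5
        flip = flip | (ties & (gm.snps["alt"].to_numpy() > gm.snps["ref"].to_numpy()))
    dos = gm.dosages.copy()
    dos[:, flip] = np.where(np.isnan(dos[:, flip]), np.nan, ploidy - dos[:, flip])
    snps = gm.snps.copy()
    if {"ref", "alt"}.issubset(snps.columns):
        r, a = snps.loc[flip, "ref"].copy(), snps.loc[flip, "alt"].copy()
        snps.loc[flip, "ref"], snps.loc[flip, "alt"] = a.to_numpy(), r.to_numpy()
    return GenotypeMatrix(gm.samples, snps, dos, sex_linked=gm.sex_linked)
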