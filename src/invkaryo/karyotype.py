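"""Per-chromosome PCA, karyotype-cluster calling, tag SNPs, tag-based calls.

An inversion polymorphism shows up in a chromosome-wide PCA as discrete
clusters along PC1 (and PC2 for three-arrangement loci): the inversion
homozygotes sit at the extremes with heterokaryotypes in between, because the
arrangements barely recombine and act as a localized population substructure.
Cluster membership therefore yields a per-individual inversion genotype, which
can then be reproduced from a handful of tag SNPs in high LD with the PC
eigenvector.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from invkaryo.ldscan import composite_ld_r2

NO_CALL = "NN"


@dataclass
class PCAResult:
    scores: np.ndarray  # individuals x components
    loadings: np.ndarray  # SNPs x components
    explained_variance_ratio: np.ndarray
    sample_ids: list
    snp_ids: list


@dataclass
class KaryotypeCalls:
    """Per-individual inversion genotype labels.

    ``genotype`` uses letters ordered by descending population frequency
    (A = major arrangement); hemizygous individuals get a single letter;
    no-calls are ``NN`` with ``no_call`` set.
    """

    data: pd.DataFrame  # columns: id, genotype, cluster, no_call, hemizygous
    allele_labels: tuple = ("A", "B")
    diagnostics: dict = field(default_factory=dict)

    @property
    def genotypes(self) -> pd.Series:
        s = self.data.set_index("id")["genotype"]
        return s.mask(self.data.set_index("id")["no_call"])

    @property
    def called(self) -> pd.DataFrame:
        return self.data[~self.data["no_call"]]


@dataclass
class TagPanel:
    """Tag SNPs that proxy the inversion genotype.

    ``vote_map`` maps (snp id, observed dosage) -> genotype label learned from
    the PCA calls; ``decision_rule`` is ``majority`` or ``unanimity``.
    """

    tags: pd.DataFrame  # columns: id, pos, r2_pc1 (and r2_pc2 where used)
    vote_map: dict
    decision_rule: str = "majority"
    allele_labels: tuple = ("A", "B")

    def __len__(self) -> int:
        return len(self.tags)


def _pca_input(gm, chromosome=None) -> tuple:
    sub = gm if chromosome is None else gm.chromosome(chromosome)
    X = sub.dosages.copy()
    hemi = sub.hemizygous_mask()
    # Hemizygous females are doubled (0 -> 0, 1 -> 2) so they co-locate with
    # the corresponding homozygous males in PC space.
    X[hemi] = X[hemi] * 2
    return sub, X, hemi


def chromosome_pca(gm, chromosome=None, standardize: bool = True, n_components: int = 10):
    """PCA of the dosage matrix of one chromosome.

    Missing dosages are mean-imputed per SNP for the decomposition only.
    With ``standardize`` each SNP is scaled by sqrt(2p(1-p)) (allele-frequency
    standardization); otherwise columns are only centered.  Deterministic:
    full SVD with the sign of each component fixed so its largest-magnitude
    loading is positive.
    """
    sub, X, _ = _pca_input(gm, chromosome)
    if sub.n_snps < 2 or sub.n_samples < 3:
        raise ValueError("PCA needs >= 2 SNPs and >= 3 individuals")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    Xc = X - col_mean
    sd_ok = Xc.std(axis=0) > 0
    if not sd_ok.any():
        raise ValueError("all SNPs constant; PCA undefined")
    if standardize:
        p = np.clip(col_mean / 2.0, 1e-9, 1 - 1e-9)
        scale = np.sqrt(2 * p * (1 - p))
        Xc = Xc / scale
    Xc[:, ~sd_ok] = 0.0
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    # sign convention: dominant loading of each component is positive
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    var = S**2
    return PCAResult(
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        explained_variance_ratio=var[:k] / var.sum(),
        sample_ids=list(sub.samples["id"]),
        snp_ids=list(sub.snps["id"]),
    )


def _farthest_points(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point corner picking (start at the point
    farthest from the centroid)."""
    d0 = np.linalg.norm(X - X.mean(axis=0), axis=1)
    idx = [int(np.argmax(d0))]
    while len(idx) < k:
        dmin = np.min(
            np.stack([np.linalg.norm(X - X[i], axis=1) for i in idx]), axis=0
        )
        idx.append(int(np.argmax(dmin)))
    return X[idx]


def _label_by_frequency(copy_counts: Counter, n_classes: int) -> dict:
    """Map internal class index -> letter, A for the most frequent."""
    order = sorted(range(n_classes), key=lambda c: (-copy_counts.get(c, 0), c))
    return {c: "ABC"[rank] for rank, c in enumerate(order)}


def call_karyotypes_from_pca(pca: PCAResult, n_alleles: int = 2, hemizygous=None):
    """Cluster PC scores into karyotype classes and label them by frequency.

    Biallelic loci: 1-D k-means (k=3) on PC1 with deterministic
    min/median/max initialization.  Triallelic loci: k-means (k=6) on
    PC1/PC2 initialized at three farthest-point corners plus their pairwise
    midpoints; corner clusters are the homozygotes.  Hemizygous individuals
    (single chromosome copy) are assigned the corresponding single-letter
    call; one found in a heterozygote cluster is impossible for a true
    hemizygote and becomes a flagged no-call.
    """
    n = pca.scores.shape[0]
    hemi = np.zeros(n, dtype=bool) if hemizygous is None else np.asarray(hemizygous)
    ids = list(pca.sample_ids)

    if n_alleles == 2:
        x = pca.scores[:, 0]
        if np.ptp(x) < 1e-12:
            data = pd.DataFrame(
                {"id": ids, "genotype": ["A" if h else "AA" for h in hemi],
                 "cluster": 0, "no_call": False, "hemizygous": hemi}
            )
            return KaryotypeCalls(data, ("A",), {"monomorphic": True})
        init = np.array([[x.min()], [np.median(x)], [x.max()]])
        km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300).fit(x[:, None])
        order = np.argsort(km.cluster_centers_.ravel())
        # internal classes 0/1: the two extreme clusters; middle = heterozygote
        cluster_of = km.labels_
        geno_classes = {order[0]: (0, 0), order[1]: (0, 1), order[2]: (1, 1)}
        pair = [geno_classes[c] for c in cluster_of]
        if min(np.bincount(cluster_of, minlength=3)) == 0:
            data = pd.DataFrame(
                {"id": ids, "genotype": NO_CALL, "cluster": -1,
                 "no_call": True, "hemizygous": hemi}
            )
            return KaryotypeCalls(data, ("A", "B"), {"unresolvable": True})
        n_classes = 2
    elif n_alleles == 3:
        X2 = pca.scores[:, :2]
        corners = _farthest_points(X2, 3)
        mids = [(corners[a] + corners[b]) / 2 for a, b in ((0, 1), (0, 2), (1, 2))]
        init = np.vstack([corners, mids])
        km = KMeans(n_clusters=6, init=init, n_init=1, max_iter=300).fit(X2)
        homo = {0: (0, 0), 1: (1, 1), 2: (2, 2), 3: (0, 1), 4: (0, 2), 5: (1, 2)}
        pair = [homo[c] for c in km.labels_]
        cluster_of = km.labels_
        n_classes = 3
    else:
        raise ValueError("n_alleles must be 2 or 3")

    copy_counts: Counter = Counter()
    for i, (c1, c2) in enumerate(pair):
        if hemi[i]:
            if c1 == c2:
                copy_counts[c1] += 1
        else:
            copy_counts[c1] += 1
            copy_counts[c2] += 1
    letter = _label_by_frequency(copy_counts, n_classes)

    genos, nocall = [], []
    for i, (c1, c2) in enumerate(pair):
        if hemi[i]:
            if c1 != c2:  # heterozygote cluster: impossible for one copy
                genos.append(NO_CALL)
                nocall.append(True)
            else:
                genos.append(letter[c1])
                nocall.append(False)
        else:
            genos.append("".join(sorted((letter[c1], letter[c2]))))
            nocall.append(False)
    data = pd.DataFrame(
        {"id": ids, "genotype": genos, "cluster": cluster_of,
         "no_call": nocall, "hemizygous": hemi}
    )
    labels = tuple("ABC"[: n_classes])
    return KaryotypeCalls(data, labels, {})


def cluster_heterozygosity(gm, block_snp_indices, calls: KaryotypeCalls,
                           n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Mean SNP heterozygosity within the block per karyotype cluster.

    Per diploid individual, the fraction of heterozygous (dosage 1) calls
    across the block SNPs; averaged within each genotype group with a
    bootstrap-over-individuals 95% CI.  Hemizygous individuals are excluded
    (heterozygosity is undefined on one chromosome copy).  Empty groups give
    missing rows.
    """
    idx = np.asarray(block_snp_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("block contains no SNPs")
    het = (gm.dosages[:, idx] == 1).astype(float)
    het[np.isnan(gm.dosages[:, idx])] = np.nan
    with np.errstate(invalid="ignore"):
        per_ind = np.nanmean(het, axis=1)
    ok = ~calls.data["no_call"].to_numpy() & ~calls.data["hemizygous"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for geno in sorted(calls.data.loc[ok, "genotype"].unique()):
        vals = per_ind[ok & (calls.data["genotype"] == geno).to_numpy()]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows.append((geno, np.nan, np.nan, np.nan, 0))
            continue
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((geno, float(vals.mean()), float(lo), float(hi), vals.size))
    return pd.DataFrame(rows, columns=["genotype", "heterozygosity", "ci_low", "ci_high", "n"])


def test_higher_pc_normality(pca: PCAResult, component_index: int = 1):
    """Normality test of a higher PC's scores (D'Agostino-Pearson).

    Gaussian scores on PC2 indicate no additional substructure beyond the
    inversion; rejection flags a possible further rearrangement.
    """
    x = pca.scores[:, component_index]
    if x.size < 8:
        raise ValueError("need >= 8 individuals")
    if np.ptp(x) < 1e-12:
        raise ValueError("constant scores: normality test undefined")
    res = stats.normaltest(x)
    return float(res.statistic), float(res.pvalue)


def select_tag_snps(gm, pca: PCAResult, block, r2_min: float = 0.9,
                    n_per_breakpoint: int = 2, use_pc2: bool = False,
                    calls: KaryotypeCalls | None = None) -> TagPanel:
    """Pick tag SNPs in high LD with the inversion's PC eigenvector.

    Candidates are block SNPs whose dosage r2 with the PC1 scores (or PC2
    when ``use_pc2``) exceeds ``r2_min``; the panel takes up to
    ``n_per_breakpoint`` candidates from each end of the block, which
    maximizes the physical span and places tags in both breakpoint regions
    when possible.  The dosage -> genotype vote map is learned from the PCA
    calls (modal called genotype per observed dosage value).
    """
    sub, X, hemi = _pca_input(gm)
    idx = np.asarray(block.snp_indices if hasattr(block, "snp_indices") else block, dtype=int)
    r2_1 = np.array([composite_ld_r2(X[:, j], pca.scores[:, 0]) for j in idx])
    r2_2 = (
        np.array([composite_ld_r2(X[:, j], pca.scores[:, 1]) for j in idx])
        if use_pc2
        else np.full(idx.size, np.nan)
    )
    best = np.nanmax(np.vstack([r2_1, np.nan_to_num(r2_2, nan=-1.0)]), axis=0)
    keep = best > r2_min
    cand = idx[keep]
    if cand.size == 0:
        return TagPanel(
            pd.DataFrame(columns=["id", "pos", "r2_pc1", "r2_pc2"]),
            {},
            allele_labels=calls.allele_labels if calls else ("A", "B"),
        )
    pos = sub.snps["pos"].to_numpy()[cand]
    order = np.argsort(pos)
    cand = cand[order]
    chosen = list(
        dict.fromkeys(list(cand[:n_per_breakpoint]) + list(cand[-n_per_breakpoint:]))
    )
    tags = pd.DataFrame(
        {
            "id": sub.snps["id"].to_numpy()[chosen],
            "pos": sub.snps["pos"].to_numpy()[chosen],
            "r2_pc1": [r2_1[list(idx).index(j)] for j in chosen],
            "r2_pc2": [r2_2[list(idx).index(j)] for j in chosen],
        }
    )
    vote_map: dict = {}
    if calls is not None:
        geno = calls.data["genotype"].to_numpy()
        usable = ~calls.data["no_call"].to_numpy() & ~hemi
        for j in chosen:
            snp_id = sub.snps["id"].iloc[j]
            for v in (0.0, 1.0, 2.0):
                m = usable & (X[:, j] == v)
                if m.any():
                    vote_map[(snp_id, v)] = Counter(geno[m]).most_common(1)[0][0]
    return TagPanel(tags, vote_map,
                    allele_labels=calls.allele_labels if calls else ("A", "B"))


def _hemi_vote(label: str):
    """Collapse a diploid vote to a single-copy call; het labels conflict."""
    if len(label) == 2 and label[0] == label[1]:
        return label[0]
    return None


def call_from_tags(gm, panel: TagPanel, rule: str = "majority") -> KaryotypeCalls:
    """Call karyotypes from tag-SNP genotypes alone.

    ``majority``: the plurality of tag votes decides; missing tags are
    allowed; exact ties give a no-call.  ``unanimity``: all tags must be
    present and agree, otherwise no-call.
    """
    if rule not in ("majority", "unanimity"):
        raise ValueError("rule must be 'majority' or 'unanimity'")
    if len(panel) == 0:
        raise ValueError("empty tag panel")
    sub, X, hemi = _pca_input(gm)
    col_of = {sid: j for j, sid in enumerate(sub.snps["id"])}
    tag_cols = [col_of[t] for t in panel.tags["id"]]
    rows = []
    for i, sid in enumerate(sub.samples["id"]):
        votes = []
        n_missing = 0
        for t, j in zip(panel.tags["id"], tag_cols):
            v = X[i, j]
            if np.isnan(v):
                n_missing += 1
                continue
            label = panel.vote_map.get((t, float(v)))
            if label is None:
                n_missing += 1
                continue
            if hemi[i]:
                label = _hemi_vote(label)
                if label is None:
                    n_missing += 1
                    continue
            votes.append(label)
        call, no_call = NO_CALL, True
        if rule == "majority" and votes:
            top = Counter(votes).most_common()
            if len(top) == 1 or top[0][1] > top[1][1]:
                call, no_call = top[0][0], False
        elif rule == "unanimity" and n_missing == 0 and votes and len(set(votes)) == 1:
            call, no_call = votes[0], False
        rows.append((sid, call, -1, no_call, bool(hemi[i])))
    data = pd.DataFrame(rows, columns=["id", "genotype", "cluster", "no_call", "hemizygous"])
    return KaryotypeCalls(data, panel.allele_labels, {"rule": rule})
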