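"""Additive/dominance association models, meta-analysis, permutation tests.

Inversion genotypes enter models through two simultaneous predictors: an
additive code X_add (1 = homozygous major arrangement, 0 = heterokaryotype,
-1 = homozygous minor) and a dominance code X_dom (1 = heterokaryotype,
0 = either homozygote).  Under Hardy-Weinberg-balanced genotypes the two are
near-orthogonal, so both gene actions are estimable in one fit.  Models are
fixed-effect throughout: pedigree-relatedness and permanent-environment
random effects are deliberately out of scope (synthetic individuals are
unrelated, so the estimands are unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class GenotypeCoding:
    """Additive/dominance regression codes for biallelic inversion genotypes."""

    x_add: np.ndarray  # 1 / 0 / -1, NaN for no-call or out-of-contrast
    x_dom: np.ndarray  # 1 heterokaryotype, 0 homokaryotype; NaN hemizygous/missing
    het: np.ndarray  # heterokaryotype indicator for parental models
    ids: list | None = None
    major: str = "A"
    minor: str = "B"


@dataclass
class AssocResult:
    beta_add: float
    se_add: float
    p_add: float
    beta_dom: float
    se_dom: float
    p_dom: float
    n: int
    labels: dict = field(default_factory=dict)


@dataclass
class MetaSummary:
    pooled: float
    se: float
    p_value: float
    cochran_q: float
    q_df: int
    heterogeneity_p: float
    components: np.ndarray
    component_ses: np.ndarray


@dataclass
class FreqDepPredictor:
    """Per-individual sum of aviary-specific frequencies of its two alleles."""

    predictor: pd.Series  # indexed like the input individuals
    aviary_freqs: pd.DataFrame  # aviary x allele frequency table
    focal_sex: str | None = None
    n_missing_aviaries: int = 0


@dataclass
class PermutationSummary:
    null_add: np.ndarray
    null_dom: np.ndarray
    null_abs_add_mean: float
    null_abs_add_se: float
    null_abs_dom_mean: float
    null_abs_dom_se: float
    p_add: float | None = None
    p_dom: float | None = None
    degenerate: bool = False


def code_additive_dominance(calls, alleles: tuple | None = None) -> GenotypeCoding:
    """Code karyotype labels as additive and dominance predictors.

    ``alleles`` restricts a multi-allelic locus to one allele pair (defaults
    to the two most frequent alleles).  The major allele of the pair is coded
    +1.  Hemizygous single-letter calls get an additive code (+1 major, -1
    minor) but an undefined dominance code, so they drop out of dominance
    fits.
    """
    from invkaryo.popgen import allele_frequencies

    if hasattr(calls, "genotypes"):
        series = calls.genotypes
    else:
        series = pd.Series(list(calls))
    labels = [g if isinstance(g, str) and g != "NN" else None for g in series]
    freqs = allele_frequencies([g for g in labels if g]).frequencies
    if alleles is None:
        ranked = sorted(freqs, key=lambda a: (-freqs[a], a))
        if len(ranked) < 2:
            raise ValueError("locus is monomorphic; additive coding undefined")
        alleles = tuple(ranked[:2])
    a, b = alleles
    major, minor = (a, b) if freqs.get(a, 0) >= freqs.get(b, 0) else (b, a)
    x_add = np.full(len(labels), np.nan)
    x_dom = np.full(len(labels), np.nan)
    het = np.full(len(labels), np.nan)
    for i, g in enumerate(labels):
        if g is None:
            continue
        if len(g) == 1:  # hemizygous
            if g == major:
                x_add[i] = 1.0
            elif g == minor:
                x_add[i] = -1.0
            continue
        if set(g) - {major, minor}:
            continue  # carries an allele outside the contrast
        if g[0] != g[1]:
            x_add[i], x_dom[i], het[i] = 0.0, 1.0, 1.0
        elif g[0] == major:
            x_add[i], x_dom[i], het[i] = 1.0, 0.0, 0.0
        else:
            x_add[i], x_dom[i], het[i] = -1.0, 0.0, 0.0
    ids = list(series.index) if hasattr(series, "index") else None
    return GenotypeCoding(x_add, x_dom, het, ids, major, minor)


def _design(columns: dict, min_n: int = 10):
    X = pd.DataFrame(columns)
    keep = ~X.isna().any(axis=1)
    X = X[keep]
    if len(X) < min_n:
        raise ValueError(f"fewer than {min_n} complete cases")
    mat = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(mat.to_numpy())
    if rank < mat.shape[1]:
        # name the columns involved in the deficiency
        bad = []
        base = mat.to_numpy()
        for j, name in enumerate(mat.columns):
            others = np.delete(base, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return mat, keep.to_numpy()


def fit_phenotype_model(trait, coding: GenotypeCoding, covariates=None) -> AssocResult:
    """OLS of a (Z-transformed) trait on X_add + X_dom (+ covariates).

    Returns both partial slopes with standard errors and P values.
    """
    y = np.asarray(trait, dtype=float)
    cols = {"x_add": coding.x_add, "x_dom": coding.x_dom}
    if covariates is not None:
        for name, v in pd.DataFrame(covariates).items():
            cols[str(name)] = np.asarray(v, dtype=float)
    cols["_y"] = y
    X = pd.DataFrame(cols)
    keep = ~X.isna().any(axis=1)
    yk = y[keep.to_numpy()]
    mat, _ = _design({k: v[keep.to_numpy()] for k, v in cols.items() if k != "_y"})
    fit = sm.OLS(yk, mat).fit()
    return AssocResult(
        beta_add=float(fit.params["x_add"]),
        se_add=float(fit.bse["x_add"]),
        p_add=float(fit.pvalues["x_add"]),
        beta_dom=float(fit.params["x_dom"]),
        se_dom=float(fit.bse["x_dom"]),
        p_dom=float(fit.pvalues["x_dom"]),
        n=int(fit.nobs),
    )


def fit_embryo_model(egg_records: pd.DataFrame, covariates=None) -> pd.DataFrame:
    """Logistic regression of embryo death on parental heterokaryotypy.

    ``egg_records`` needs ``died`` (0/1, infertile eggs already excluded) and
    the 0/1 predictors ``sire_het`` and ``dam_het``.  Returns one row per
    parent with the odds ratio, Wald 95% CI, and P; complete separation is
    flagged (``separation``) with unbounded CIs reported as such.
    """
    died = egg_records["died"].to_numpy(dtype=float)
    if died.sum() == 0 or died.sum() == len(died):
        raise ValueError("need at least one death and one survival")
    cols = {
        "sire_het": egg_records["sire_het"].to_numpy(dtype=float),
        "dam_het": egg_records["dam_het"].to_numpy(dtype=float),
    }
    if covariates is not None:
        for name, v in pd.DataFrame(covariates).items():
            cols[str(name)] = np.asarray(v, dtype=float)
    mat, keep = _design(cols, min_n=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(died[keep], mat, family=sm.families.Binomial()).fit()
    rows = []
    for name in ("sire_het", "dam_het"):
        beta, se = float(fit.params[name]), float(fit.bse[name])
        sep = not np.isfinite(se) or se > 10
        lo, hi = beta - 1.96 * se, beta + 1.96 * se
        rows.append(
            {
                "parent": name.replace("_het", ""),
                "log_or": beta,
                "se": se,
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(lo)) if not sep else np.nan,
                "ci_high": float(np.exp(hi)) if not sep else np.nan,
                "p_value": float(fit.pvalues[name]),
                "separation": bool(sep),
            }
        )
    return pd.DataFrame(rows)


def sqrt_z_transform(values, by=None) -> np.ndarray:
    """Square-root then Z-transform (in that order), optionally within groups."""
    x = np.sqrt(np.asarray(values, dtype=float))
    if by is None:
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("zero variance after square-root transform")
        return (x - np.nanmean(x)) / sd
    s = pd.Series(x)
    out = s.groupby(pd.Series(list(by))).transform(
        lambda v: (v - v.mean()) / v.std(ddof=1)
    )
    if out.isna().any() and not s.isna().any():
        raise ValueError("zero variance after square-root transform in a group")
    return out.to_numpy()


def fit_fitness_model(fitness, coding: GenotypeCoding, covariates=None,
                      population=None) -> AssocResult:
    """Association of a count-like fitness component with inversion genotype.

    The response is square-root transformed then Z-transformed (within
    population when given) before the additive+dominance OLS fit.
    """
    if np.nanmin(np.asarray(fitness, dtype=float)) < 0:
        raise ValueError("fitness counts must be >= 0")
    y = sqrt_z_transform(fitness, by=population)
    return fit_phenotype_model(y, coding, covariates)


def meta_fixed_effect(estimates, ses) -> MetaSummary:
    """Inverse-variance fixed-effect meta-analysis with Cochran's Q.

    pooled = sum(w_i b_i) / sum(w_i), w_i = 1/se_i^2; SE = sum(w_i)^(-1/2);
    Q = sum(w_i (b_i - pooled)^2) on k-1 df.
    """
    b = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("need >= 2 component estimates")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - pooled) ** 2))
    q_df = b.size - 1
    z = pooled / se
    return MetaSummary(
        pooled=pooled,
        se=se,
        p_value=float(2 * stats.norm.sf(abs(z))),
        cochran_q=q,
        q_df=q_df,
        heterogeneity_p=float(stats.chi2.sf(q, q_df)),
        components=b,
        component_ses=s,
    )


def weighted_mean_effect(estimates, ses):
    """Inverse-variance weighted mean effect with a two-sided Z-test P.

    Identical to the pooled value of :func:`meta_fixed_effect`.
    """
    m = meta_fixed_effect(estimates, ses)
    return m.pooled, m.p_value


def _stratum_permutation(groups: np.ndarray, rng) -> np.ndarray:
    """Index permutation that shuffles only within each group."""
    order = np.arange(groups.size)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        order[idx] = idx[rng.permutation(idx.size)]
    return order


def _permute_within(groups: np.ndarray, values: np.ndarray, rng) -> np.ndarray:
    return values[_stratum_permutation(groups, rng)]


def _fit_add_dom(y: np.ndarray, x_add: np.ndarray, x_dom: np.ndarray,
                 covariates=None) -> AssocResult:
    """Lean OLS of y on [1, x_add, x_dom, covariates] (complete cases)."""
    cols = [x_add, x_dom]
    names = ["x_add", "x_dom"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cols.extend(np.asarray(cov[c], dtype=float) for c in cov.columns)
        names.extend(str(c) for c in cov.columns)
    X = np.column_stack([np.ones_like(y)] + cols)
    keep = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 complete cases")
    fit = sm.OLS(y[keep], X[keep]).fit()
    ia, id_ = 1, 2
    return AssocResult(
        beta_add=float(fit.params[ia]), se_add=float(fit.bse[ia]),
        p_add=float(fit.pvalues[ia]),
        beta_dom=float(fit.params[id_]), se_dom=float(fit.bse[id_]),
        p_dom=float(fit.pvalues[id_]), n=int(fit.nobs),
    )


def permutation_null(trait, genotypes, sexes, n_perm: int = 100, seed: int = 0,
                     covariates=None, observed: AssocResult | None = None) -> PermutationSummary:
    """Null distribution of additive/dominance effects by permutation.

    Genotype labels are permuted within each sex stratum (preserving the
    per-stratum genotype multiset), the model is refit per permutation, and
    |effect| is summarized as mean +/- SE.  When ``observed`` is given, the
    empirical two-sided P is (r + 1)/(n_perm + 1) with r the number of null
    |effects| at least as large as the observed one.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    geno = np.asarray(list(genotypes), dtype=object)
    sexes = np.asarray(list(sexes))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    # Permuting genotype labels within sex and re-coding is identical to
    # permuting the per-individual codes (the coding map depends only on the
    # stratum-preserved genotype multiset), so codes are computed once.
    base = code_additive_dominance(geno)
    y = np.asarray(trait, dtype=float)
    null_a, null_d = np.empty(n_perm), np.empty(n_perm)
    for r in range(n_perm):
        order = _stratum_permutation(sexes, rng)
        res = _fit_add_dom(y, base.x_add[order], base.x_dom[order], covariates)
        null_a[r], null_d[r] = res.beta_add, res.beta_dom
    degenerate = np.ptp(null_a) < 1e-12 and np.ptp(null_d) < 1e-12
    if degenerate:
        warnings.warn("all permutation effects identical (constant genotype column?)")
    summary = PermutationSummary(
        null_add=null_a,
        null_dom=null_d,
        null_abs_add_mean=float(np.mean(np.abs(null_a))),
        null_abs_add_se=float(np.std(np.abs(null_a), ddof=1) / np.sqrt(n_perm)),
        null_abs_dom_mean=float(np.mean(np.abs(null_d))),
        null_abs_dom_se=float(np.std(np.abs(null_d), ddof=1) / np.sqrt(n_perm)),
        degenerate=degenerate,
    )
    if observed is not None:
        summary.p_add = float(
            (np.sum(np.abs(null_a) >= abs(observed.beta_add)) + 1) / (n_perm + 1)
        )
        summary.p_dom = float(
            (np.sum(np.abs(null_d) >= abs(observed.beta_dom)) + 1) / (n_perm + 1)
        )
    return summary


def power_by_spikein(trait, genotypes, sexes, effect_grid, effect: str = "additive",
                     n_perm_per_cell: int = 10, alpha: float = 0.05,
                     seed: int = 0, covariates=None) -> pd.DataFrame:
    """Power to detect spiked effects of configured sizes.

    Per effect size: permute genotypes within sex, then add/subtract the
    effect from the two homozygote groups (additive) or add it to the
    heterozygotes (dominance), refit, and report the fraction of fits
    significant at ``alpha``.
    """
    if effect not in ("additive", "dominance"):
        raise ValueError("effect must be 'additive' or 'dominance'")
    y0 = np.asarray(trait, dtype=float)
    geno = np.asarray(list(genotypes), dtype=object)
    sexes = np.asarray(list(sexes))
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    base = code_additive_dominance(geno)
    rows = []
    for e in effect_grid:
        hits = 0
        for _ in range(n_perm_per_cell):
            order = _stratum_permutation(sexes, rng)
            x_add, x_dom = base.x_add[order], base.x_dom[order]
            if effect == "additive":
                y = y0 + e * np.where(np.isnan(x_add), 0.0, x_add)
            else:
                y = y0 + e * np.where(np.isnan(x_dom), 0.0, x_dom)
            res = _fit_add_dom(y, x_add, x_dom, covariates)
            p = res.p_add if effect == "additive" else res.p_dom
            hits += p < alpha
        rows.append((float(e), hits / n_perm_per_cell))
    return pd.DataFrame(rows, columns=["effect_size", "power"])


def freq_dep_predictor(karyotypes, aviaries, sexes=None, focal_sex=None) -> FreqDepPredictor:
    """Sum of aviary-specific allele frequencies of an individual's alleles.

    Frequencies are computed per aviary from called birds of ``focal_sex``
    (all birds when ``None``), then every individual in the aviary gets the
    sum of its own two alleles' frequencies (a biallelic heterozygote always
    gets exactly 1).  Aviaries with no called focal-sex bird yield missing
    predictors and are counted in ``n_missing_aviaries``.
    """
    karyo = pd.Series(list(karyotypes))
    aviary = pd.Series(list(aviaries))
    sex = pd.Series(list(sexes)) if sexes is not None else pd.Series(["U"] * len(karyo))
    called = karyo.notna() & (karyo != "NN")
    focal = called if focal_sex is None else called & (sex == focal_sex)
    freq_rows, missing = {}, 0
    for av in aviary.unique():
        members = (aviary == av) & focal
        from collections import Counter

        copies: Counter = Counter()
        for g in karyo[members]:
            copies.update(g)
        total = sum(copies.values())
        if total == 0:
            missing += 1
            warnings.warn(f"aviary {av!r}: no called focal-sex birds; predictor missing")
            freq_rows[av] = {}
        else:
            freq_rows[av] = {a: c / total for a, c in copies.items()}
    pred = np.full(len(karyo), np.nan)
    for i, (g, av) in enumerate(zip(karyo, aviary)):
        if not called.iloc[i] or not freq_rows.get(av):
            continue
        pred[i] = sum(freq_rows[av].get(a, 0.0) for a in g)
    table = pd.DataFrame(freq_rows).T.fillna(0.0)
    table.index.name = "aviary"
    return FreqDepPredictor(
        predictor=pd.Series(pred, index=karyo.index),
        aviary_freqs=table,
        focal_sex=focal_sex,
        n_missing_aviaries=missing,
    )


def fit_freq_dep(fitness, predictor: FreqDepPredictor, covariates=None,
                 sqrt_transform: bool = True, population=None) -> AssocResult:
    """Regression of a fitness component on the frequency-sum predictor.

    A constant predictor (e.g. every aviary fixed for one allele) is a
    degenerate design and raises.
    """
    x = predictor.predictor.to_numpy()
    ok = ~np.isnan(x) & ~np.isnan(np.asarray(fitness, dtype=float))
    if np.ptp(x[ok]) < 1e-12:
        raise ValueError("degenerate predictor: frequency sum is constant")
    y = sqrt_z_transform(fitness, by=population) if sqrt_transform else np.asarray(fitness, float)
    cols = {"freq_sum": x}
    if covariates is not None:
        for name, v in pd.DataFrame(covariates).items():
            cols[str(name)] = np.asarray(v, dtype=float)
    cols_y = pd.DataFrame({**cols, "_y": y})
    keep = ~cols_y.isna().any(axis=1)
    mat, _ = _design({k: np.asarray(v)[keep.to_numpy()] for k, v in cols.items()})
    fit = sm.OLS(y[keep.to_numpy()], mat).fit()
    return AssocResult(
        beta_add=float(fit.params["freq_sum"]),
        se_add=float(fit.bse["freq_sum"]),
        p_add=float(fit.pvalues["freq_sum"]),
        beta_dom=np.nan,
        se_dom=np.nan,
        p_dom=np.nan,
        n=int(fit.nobs),
        labels={"predictor": "freq_sum"},
    )
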