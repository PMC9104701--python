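"""Per-gene age, sex, and age-by-sex effect models.

Transcripts: negative-binomial GLM of counts on sex + generation + age
(continuous, in years, so the slope is a log2 fold change per year), with a
per-gene profile-MLE dispersion shared between the null and full fits and a
likelihood-ratio chi-square test for the dropped term. Proteins: ordinary
least squares on log2 abundance with an F-test. Both report BH-adjusted
q-values and standardized effects (slope / SE).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)


def filter_transcripts(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with at least one read in at least half of the samples."""
    n = counts.shape[1]
    need = int(np.ceil(n / 2))
    keep = (counts >= 1).sum(axis=1) >= need
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean reference.

    The reference uses genes with all-positive counts; if none exist, falls
    back to total-count factors normalized to geometric mean 1.
    """
    mat = counts.to_numpy(float)
    allpos = (mat > 0).all(axis=1)
    if allpos.any():
        logs = np.log(mat[allpos])
        ref = logs.mean(axis=1)  # log geometric mean per gene
        sf = np.exp(np.median(logs - ref[:, None], axis=0))
    else:
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Depth-normalized log2 expression: log2(count / size_factor + 1)."""
    sf = size_factors(counts)
    norm = np.log2(counts.to_numpy(float) / sf.to_numpy()[None, :] + 1.0)
    return pd.DataFrame(norm, index=counts.index, columns=counts.columns), sf


def _design(samples: pd.DataFrame, test: str) -> tuple[np.ndarray, np.ndarray, int]:
    """(full design, null design, df of the test) for the requested term."""
    male = (samples["sex"] == "M").to_numpy(float)
    gen = pd.get_dummies(samples["generation"], drop_first=True).to_numpy(float)
    age = samples["age_years"].to_numpy(float)
    ones = np.ones(len(samples))
    base = np.column_stack([ones, male, gen])
    if test == "age":
        full = np.column_stack([base, age])
        null = base
    elif test == "sex":
        full = np.column_stack([ones, gen, age, male])
        null = np.column_stack([ones, gen, age])
    elif test == "age_by_sex":
        full = np.column_stack([base, age, age * male])
        null = np.column_stack([base, age])
    else:
        raise ValueError(f"unknown test {test!r}")
    return full, null, full.shape[1] - null.shape[1]


def _nb_llf(y, X, offset, alpha):
    """Fitted NB GLM log-likelihood and params at fixed dispersion alpha."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    model = sm.GLM(y, X, family=fam, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    return res.llf, res


def fit_transcript_age(counts: pd.DataFrame, samples: pd.DataFrame,
                       test: str = "age", fdr: float = 0.01,
                       sf: pd.Series = None) -> pd.DataFrame:
    """NB GLM likelihood-ratio tests per gene; slopes as log2 FC per year.

    The dispersion is profiled out per gene under the full model (MLE over
    log alpha) and held fixed for the null fit so the LRT compares nested
    models at a common dispersion. Non-converging genes fall back to a
    Poisson GLM and are flagged. Size factors default to median-of-ratios on
    ``counts``; pass ``sf`` when fitting a subset of a larger matrix.
    """
    X_full, X_null, df_test = _design(samples, test)
    if sf is None:
        sf = size_factors(counts)
    offset = np.log(sf.reindex(counts.columns).to_numpy())
    rows = []
    for gene, y in counts.iterrows():
        y = y.to_numpy(float)
        fallback = False
        try:
            def neg_profile(log_a):
                llf, _ = _nb_llf(y, X_full, offset, np.exp(log_a))
                return -llf
            opt = optimize.minimize_scalar(neg_profile, bounds=(np.log(1e-8), np.log(10.0)),
                                           method="bounded", options={"xatol": 1e-3})
            alpha = float(np.exp(opt.x))
            llf_full, res_full = _nb_llf(y, X_full, offset, alpha)
            llf_null, _ = _nb_llf(y, X_null, offset, alpha)
        except Exception:
            fallback = True
            alpha = 0.0
            fam = sm.families.Poisson()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res_full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
                res_null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
            llf_full, llf_null = res_full.llf, res_null.llf
        deviance = max(2.0 * (llf_full - llf_null), 0.0)
        p = float(stats.chi2.sf(deviance, df_test))
        beta = res_full.params[-1]  # tested column is last in every design
        se = res_full.bse[-1]
        rows.append((gene, beta / LN2, se / LN2, deviance, p, alpha, fallback))
    out = pd.DataFrame(rows, columns=["gene_id", "effect", "se", "stat", "p",
                                      "dispersion", "poisson_fallback"])
    out["level"] = "transcript"
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["standardized"] = np.where(out["se"] > 0, out["effect"] / out["se"], np.nan)
    out["significant"] = out["q"] < fdr
    return out


def fit_protein_age(proteins: pd.DataFrame, samples: pd.DataFrame,
                    test: str = "age", fdr: float = 0.01) -> pd.DataFrame:
    """OLS age-effect models on log2 protein abundance with F-tests.

    Missing samples are dropped per protein; proteins with fewer complete
    observations than parameters + 2 yield missing results.
    """
    X_full, X_null, df_test = _design(samples, test)
    rows = []
    for prot, row in proteins.iterrows():
        y = row.to_numpy(float)
        obs = ~np.isnan(y)
        n = int(obs.sum())
        if n < X_full.shape[1] + 2:
            rows.append((prot, np.nan, np.nan, np.nan, np.nan))
            continue
        Xf, Xn, yy = X_full[obs], X_null[obs], y[obs]
        beta, _, _, _ = np.linalg.lstsq(Xf, yy, rcond=None)
        rss1 = float(((yy - Xf @ beta) ** 2).sum())
        beta0, _, _, _ = np.linalg.lstsq(Xn, yy, rcond=None)
        rss0 = float(((yy - Xn @ beta0) ** 2).sum())
        dof = n - Xf.shape[1]
        F = ((rss0 - rss1) / df_test) / (rss1 / dof) if dof > 0 and rss1 > 0 else np.nan
        p = float(stats.f.sf(F, df_test, dof)) if np.isfinite(F) else np.nan
        sigma2 = rss1 / dof
        XtX_inv = np.linalg.pinv(Xf.T @ Xf)
        se = float(np.sqrt(sigma2 * XtX_inv[-1, -1]))
        rows.append((prot, float(beta[-1]), se, float(F), p))
    out = pd.DataFrame(rows, columns=["gene_id", "effect", "se", "stat", "p"])
    out["level"] = "protein"
    pvec = out["p"].to_numpy()
    q = np.full_like(pvec, np.nan)
    ok = ~np.isnan(pvec)
    if ok.any():
        q[ok] = bh_fdr(pvec[ok])
    out["q"] = q
    out["standardized"] = np.where(out["se"] > 0, out["effect"] / out["se"], np.nan)
    out["significant"] = out["q"] < fdr
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def concordance_by_age(transcripts: pd.DataFrame, proteins: pd.DataFrame,
                       samples: pd.DataFrame, min_pairs: int = 4) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-age-group Pearson r between transcript and protein.

    Uses pairwise-complete samples; groups with fewer than ``min_pairs``
    complete pairs yield a missing r. Returns (long table, per-group medians).
    """
    shared_genes = transcripts.index.intersection(proteins.index)
    shared_samples = [s for s in transcripts.columns if s in set(proteins.columns)]
    meta = samples.set_index("sample_id").loc[shared_samples]
    rows = []
    for gene in shared_genes:
        t = transcripts.loc[gene, shared_samples].to_numpy(float)
        pr = proteins.loc[gene, shared_samples].to_numpy(float)
        for age, gsel in meta.groupby("age_months").groups.items():
            sel = meta.index.isin(gsel)
            x, y = t[sel], pr[sel]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_pairs or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append((gene, age, r))
    table = pd.DataFrame(rows, columns=["gene_id", "age_months", "r"])
    medians = table.groupby("age_months")["r"].median()
    return table, medians
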