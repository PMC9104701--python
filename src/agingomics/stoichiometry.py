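"""Age-related decay of protein-complex co-abundance (stoichiometry).

For every within-complex pair of subunits, Pearson correlation of abundance
across mice is computed separately per age group; regressing each pair's
correlation on age (years) gives a slope in correlation units per year. A
complex-level mixed model with per-pair random intercepts and slopes,

    r_ijk = mu + u[ij] + (beta_age + v[ij]) * x_k + e_ijk,

pools pairs into one overall decay estimate. Significance comes from
permuting the sample-to-age assignment: pair-level empirical p-values pool
the permuted slopes across pairs of the same complex (BH-adjusted across all
pairs); complex-level p-values use each complex's own permuted slopes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .config import subseed
from .age_effects import bh_fdr

log = logging.getLogger(__name__)

AGE_X = np.array([0.5, 1.0, 1.5])


def nan_pearson(X: np.ndarray, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson correlation matrix of the rows of X.

    Matches pandas' pairwise-complete behavior but runs on matrix products,
    which keeps the permutation loops fast. Returns (r, n_complete); entries
    with fewer than ``min_n`` complete pairs (or zero variance) are NaN.
    """
    M = (~np.isnan(X)).astype(float)
    Z = np.where(np.isnan(X), 0.0, X)
    n = M @ M.T
    sx = Z @ M.T
    sy = sx.T
    sxx = (Z * Z) @ M.T
    syy = sxx.T
    sxy = Z @ Z.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx**2
        vy = n * syy - sy**2
        r = cov / np.sqrt(vx * vy)
    r[(n < min_n) | ~np.isfinite(r)] = np.nan
    return r, n.astype(int)


def _complex_members(catalog: pd.DataFrame, matrix: pd.DataFrame,
                     min_members: int = 4) -> dict:
    """complex_id -> list of member feature ids observed in the matrix."""
    out = {}
    for cid, sub in catalog.groupby("complex_id", sort=False):
        members = [g for g in sub["gene_id"] if g in matrix.index]
        if len(members) < min_members:
            log.info("complex %s skipped: %d observed members (<%d)",
                     cid, len(members), min_members)
            continue
        out[cid] = members
    return out


def _group_masks(samples: pd.DataFrame, columns, stratify_sex: bool = False) -> dict:
    meta = samples.set_index("sample_id").loc[list(columns)]
    keys = ["age_months", "sex"] if stratify_sex else ["age_months"]
    return {key: meta.index.isin(idx)
            for key, idx in meta.groupby(keys).groups.items()}


def pairwise_age_correlations(matrix: pd.DataFrame, catalog: pd.DataFrame,
                              samples: pd.DataFrame, stratify_sex: bool = False,
                              min_complete: int = 10) -> pd.DataFrame:
    """Per-pair Pearson r within each age group (optionally by sex).

    Pairs with fewer than ``min_complete`` pairwise-complete samples in any
    group are excluded. Returns a wide table with one r column per age group.
    """
    members = _complex_members(catalog, matrix)
    masks = _group_masks(samples, matrix.columns, stratify_sex)
    rows = []
    for cid, genes in members.items():
        X = matrix.loc[genes].to_numpy(float)
        per_group = {}
        for key, sel in masks.items():
            r, n = nan_pearson(X[:, np.asarray(sel)], min_n=min_complete)
            per_group[key] = (r, n)
        iu = np.triu_indices(len(genes), k=1)
        for a, b in zip(*iu):
            rec = {"complex_id": cid, "gene_i": genes[a], "gene_j": genes[b]}
            ok = True
            for key, (r, n) in per_group.items():
                label = key if not isinstance(key, tuple) else "_".join(map(str, key))
                rec[f"r_{label}"] = r[a, b]
                rec[f"n_{label}"] = n[a, b]
                if n[a, b] < min_complete or np.isnan(r[a, b]):
                    ok = False
            if ok:
                rows.append(rec)
    return pd.DataFrame(rows)


def pair_slopes(trajectories: pd.DataFrame,
                ages_months=(6, 12, 18)) -> pd.DataFrame:
    """OLS slope of pair correlation on age in years (x = age_months / 12)."""
    out = trajectories.copy()
    cols = [f"r_{a}" for a in ages_months]
    x = np.array(ages_months) / 12.0
    R = out[cols].to_numpy(float)
    ok = (~np.isnan(R)).sum(axis=1) >= 2
    slopes = np.full(len(out), np.nan)
    # closed-form least squares per row, tolerating a missing group
    for i in np.flatnonzero(ok):
        m = ~np.isnan(R[i])
        xm = x[m] - x[m].mean()
        slopes[i] = float(np.sum(xm * (R[i, m] - R[i, m].mean())) / np.sum(xm**2))
    out["slope"] = slopes
    return out


def complex_joint_model(trajectories: pd.DataFrame, complex_id: str,
                        ages_months=(6, 12, 18)) -> dict:
    """Overall complex decay: mixed model with per-pair random intercept/slope.

    Random intercept u[ij] ~ N(0, tau^2) and independent random slope
    v[ij] ~ N(0, tau_age^2), REML via statsmodels MixedLM. Boundary or
    non-converging fits fall back to the mean of per-pair OLS slopes with its
    empirical standard error. With every pair observed at all three ages the
    fixed slope equals that mean exactly; the mixed model contributes the SE
    and variance components.
    """
    sub = trajectories[trajectories["complex_id"] == complex_id]
    if len(sub) == 0:
        raise ValueError(f"no pair trajectories for complex {complex_id!r}")
    cols = [f"r_{a}" for a in ages_months]
    x = np.array(ages_months) / 12.0
    long = []
    for idx, row in sub.iterrows():
        for xk, c in zip(x, cols):
            if not np.isnan(row[c]):
                long.append((f"{row['gene_i']}|{row['gene_j']}", xk, row[c]))
    df = pd.DataFrame(long, columns=["pair", "x", "r"])
    slopes = pair_slopes(sub, ages_months)["slope"].to_numpy()
    fallback = {
        "complex_id": complex_id,
        "beta_age": float(np.nanmean(slopes)),
        "se": float(np.nanstd(slopes, ddof=1) / np.sqrt(np.sum(~np.isnan(slopes))))
        if np.sum(~np.isnan(slopes)) > 1 else np.nan,
        "tau2": np.nan, "tau2_age": np.nan, "sigma2": np.nan,
        "n_members": len(set(sub["gene_i"]) | set(sub["gene_j"])),
        "n_pairs": len(sub),
        "method": "pair_slope_mean",
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("r ~ x", df, groups=df["pair"], re_formula="1",
                             vc_formula={"xs": "0 + x"})
            fit = md.fit(reml=True)
        if not np.isfinite(fit.bse["x"]):
            return fallback
        return {
            "complex_id": complex_id,
            "beta_age": float(fit.params["x"]),
            "se": float(fit.bse["x"]),
            "tau2": float(fit.cov_re.iloc[0, 0]),
            "tau2_age": float(fit.vcomp[0]) if len(fit.vcomp) else np.nan,
            "sigma2": float(fit.scale),
            "n_members": fallback["n_members"],
            "n_pairs": len(sub),
            "method": "mixed_model",
        }
    except Exception:
        return fallback


def _complex_stat(slopes: np.ndarray) -> float:
    """Complex-level decay statistic: mean of per-pair slopes.

    Equals the mixed-model fixed slope whenever the pair design is balanced
    (every pair observed at every age), which makes the permutation null
    directly comparable to the observed mixed-model estimate.
    """
    return float(np.nanmean(slopes))


def _pair_slopes_fast(X: np.ndarray, group_sel: list, min_complete: int) -> np.ndarray:
    """Upper-triangle pair slopes for one complex under one age assignment."""
    k = X.shape[0]
    iu = np.triu_indices(k, 1)
    R = np.empty((3, len(iu[0])))
    valid = np.ones(len(iu[0]), dtype=bool)
    for gi, sel in enumerate(group_sel):
        r, n = nan_pearson(X[:, sel], min_n=min_complete)
        R[gi] = r[iu]
        valid &= n[iu] >= min_complete
    R[:, ~valid] = np.nan
    xc = AGE_X - AGE_X.mean()
    with np.errstate(invalid="ignore"):
        slopes = (xc[:, None] * (R - np.nanmean(R, axis=0))).sum(axis=0) / np.sum(xc**2)
    slopes[np.isnan(R).any(axis=0)] = np.nan
    return slopes


def permutation_significance(matrix: pd.DataFrame, catalog: pd.DataFrame,
                             samples: pd.DataFrame, B: int = 1000, seed: int = 0,
                             min_complete: int = 10,
                             fdr_pairs: float = 0.1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation p-values for pair slopes and complex-level decay.

    Shuffles the sample-to-age assignment B times and recomputes all pair
    slopes. Pair p-values pool the permuted null across pairs of the same
    complex and are BH-adjusted across all pairs; complex p-values compare
    the observed mean pair slope with its own permuted distribution. Both are
    two-sided on |slope| and deterministic given the seed.
    """
    if B < 20:
        raise ValueError("B < 20 gives too coarse a p-value resolution")
    rng = subseed(seed, "stoich_perm")
    members = _complex_members(catalog, matrix)
    cols = list(matrix.columns)
    meta = samples.set_index("sample_id").loc[cols]
    ages = meta["age_months"].to_numpy()
    group_sel = [np.flatnonzero(ages == a) for a in (6, 12, 18)]

    pair_rows, cx_rows = [], []
    for cid, genes in members.items():
        X = matrix.loc[genes].to_numpy(float)
        obs_slopes = _pair_slopes_fast(X, group_sel, min_complete)
        obs_beta = _complex_stat(obs_slopes)
        perm_abs = np.empty((B, len(obs_slopes)))
        perm_beta = np.empty(B)
        for b in range(B):
            pi = rng.permutation(len(cols))
            psel = [pi[s] for s in group_sel]
            s = _pair_slopes_fast(X, psel, min_complete)
            perm_abs[b] = np.abs(s)
            perm_beta[b] = _complex_stat(s)
        pooled = perm_abs[:, ~np.isnan(obs_slopes)].ravel()
        pooled = pooled[~np.isnan(pooled)]
        iu = np.triu_indices(len(genes), 1)
        for j, (a, b2) in enumerate(zip(*iu)):
            sl = obs_slopes[j]
            if np.isnan(sl):
                continue
            p = (1.0 + np.sum(pooled >= abs(sl))) / (len(pooled) + 1.0)
            pair_rows.append((cid, genes[a], genes[b2], sl, min(p, 1.0)))
        ok = ~np.isnan(perm_beta)
        p_cx = (1.0 + np.sum(np.abs(perm_beta[ok]) >= abs(obs_beta))) / (ok.sum() + 1.0)
        cx_rows.append((cid, obs_beta, len(genes), len(obs_slopes), min(p_cx, 1.0)))

    pairs = pd.DataFrame(pair_rows, columns=["complex_id", "gene_i", "gene_j",
                                             "slope", "perm_p"])
    if len(pairs):
        pairs["q"] = bh_fdr(pairs["perm_p"].to_numpy())
        pairs["significant"] = pairs["q"] < fdr_pairs
    cxs = pd.DataFrame(cx_rows, columns=["complex_id", "beta_age", "n_members",
                                         "n_pairs", "perm_p"])
    return pairs, cxs


def analyze_stoichiometry(matrix: pd.DataFrame, catalog: pd.DataFrame,
                          samples: pd.DataFrame, B: int = 1000, seed: int = 0,
                          stratify_sex: bool = False, min_complete: int = 10,
                          fdr_pairs: float = 0.1, complex_p: float = 0.05) -> dict:
    """Full stage: trajectories, slopes, joint models, permutation p-values."""
    traj = pairwise_age_correlations(matrix, catalog, samples,
                                     stratify_sex=stratify_sex,
                                     min_complete=min_complete)
    traj = pair_slopes(traj)
    joint = pd.DataFrame([complex_joint_model(traj, cid)
                          for cid in traj["complex_id"].unique()])
    perm_pairs, perm_cx = permutation_significance(
        matrix, catalog, samples, B=B, seed=seed, min_complete=min_complete,
        fdr_pairs=fdr_pairs)
    if len(joint) and len(perm_cx):
        joint = joint.merge(perm_cx[["complex_id", "perm_p"]], on="complex_id", how="left")
        joint["significant"] = joint["perm_p"] < complex_p
    return {"pairs": traj, "complexes": joint,
            "perm_pairs": perm_pairs, "perm_complexes": perm_cx}
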