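"""Peptide-to-protein quantification for TMT-batched proteomics.

Pipeline: drop peptides overlapping founder polymorphisms (their intensity is
zeroed in non-reference samples, which fakes local QTL signal), roll peptides
up to log2 protein abundance with within-batch sample scaling,

    Protein_ij = log2( sum_{k in K_j} Peptide_ik / s_i + 1 ),
    s_i = (sum_L Peptide_il) / max_{q in batch(i)} (sum_L Peptide_ql),

drop proteins missing in more than half the samples, remove the batch effect
as a mixed-model BLUP, and rank-normalize for genetic mapping.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .simulate import GenotypeProbs, nearest_marker_index, N_FOUNDERS

log = logging.getLogger(__name__)


def _sample_columns(peptides: pd.DataFrame) -> list:
    meta = {"peptide_id", "protein_id", "gene_id", "variant_mask"}
    return [c for c in peptides.columns if c not in meta]


def filter_polymorphic_peptides(peptides: pd.DataFrame, genomes: GenotypeProbs,
                                gene_map: pd.DataFrame, samples: pd.DataFrame,
                                r_cut: float = 0.7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop candidate polymorphic peptides whose founder allele effects match
    the reference-sharing pattern with Pearson r >= r_cut (inclusive).

    Candidates are peptides whose variant mask marks at least one founder as
    not sharing the reference allele. For each candidate the 8 founder allele
    effects are estimated by least squares of log2(intensity + 1) on founder
    dosages at the gene's nearest marker, with sex and age as covariates, and
    correlated against the 0/1 reference-sharing indicator. Monomorphic
    peptides are always retained.
    """
    cols = _sample_columns(peptides)
    sample_order = samples["sample_id"].tolist()
    if set(cols) != set(sample_order):
        raise ValueError("peptide table and sample table disagree on samples")
    masks = peptides["variant_mask"].astype(str).str.zfill(N_FOUNDERS)
    candidate = masks.str.contains("0")

    gm = gene_map.set_index("gene_id")
    nearest = pd.Series(
        nearest_marker_index(gm.reset_index(), genomes.markers),
        index=gm.index)
    covar = np.column_stack([
        np.ones(len(samples)),
        (samples["sex"] == "M").to_numpy(float),
        samples["age_years"].to_numpy(),
    ])

    y_all = np.log2(peptides[sample_order].to_numpy(float) + 1.0)
    report_rows = []
    drop = np.zeros(len(peptides), dtype=bool)
    for i in np.flatnonzero(candidate.to_numpy()):
        gene = peptides["gene_id"].iloc[i]
        mk = int(nearest.get(gene, -1)) if gene in nearest.index else -1
        if mk < 0:
            log.warning("peptide %s: gene %s has no mappable marker; retained",
                        peptides['peptide_id'].iloc[i], gene)
            report_rows.append((peptides["peptide_id"].iloc[i], np.nan, False))
            continue
        dos = genomes.probs[mk]  # (N, 8)
        y = y_all[i]
        obs = ~np.isnan(y)
        X = np.column_stack([covar[obs], dos[obs]])
        beta, *_ = np.linalg.lstsq(X, y[obs], rcond=None)
        effects = beta[covar.shape[1]:]
        indicator = np.array([float(c) for c in masks.iloc[i]])
        if np.std(effects) == 0 or np.std(indicator) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(effects, indicator)[0, 1])
        dropped = bool(not np.isnan(r) and r >= r_cut)
        drop[i] = dropped
        report_rows.append((peptides["peptide_id"].iloc[i], r, dropped))

    report = pd.DataFrame(report_rows, columns=["peptide_id", "allele_effect_r", "dropped"])
    retained = peptides.loc[~drop].reset_index(drop=True)
    log.info("polymorphic filter: %d candidates, %d dropped, %d peptides retained",
             int(candidate.sum()), int(drop.sum()), len(retained))
    return retained, report


def sample_scaling(peptides: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Within-batch loading normalization s_i from all observed peptides.

    s_i is the sample's total observed intensity divided by the maximum total
    within its batch, so the most heavily loaded sample of every batch has
    s = 1 exactly.
    """
    cols = samples["sample_id"].tolist()
    totals = peptides[cols].sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total intensity: {bad}")
    batch = samples.set_index("sample_id")["batch"]
    batch_max = totals.groupby(batch).transform("max")
    return totals / batch_max


def rollup_proteins(peptides: pd.DataFrame, samples: pd.DataFrame,
                    scaling: pd.Series = None) -> tuple[pd.DataFrame, pd.Series]:
    """Roll peptides up to log2 protein abundance with sample scaling.

    Missing peptides contribute 0 to the sum; a protein is missing for a
    sample only when every component peptide is missing. Returns
    (proteins x samples abundance matrix, per-sample scaling s).
    """
    cols = samples["sample_id"].tolist()
    if scaling is None:
        scaling = sample_scaling(peptides, samples)
    s = scaling.reindex(cols).to_numpy()
    inten = peptides[cols].to_numpy(float)
    observed = ~np.isnan(inten)
    filled = np.where(observed, inten, 0.0)
    prot_ids = peptides["protein_id"].to_numpy()
    order = pd.unique(prot_ids)
    sums = pd.DataFrame(filled, columns=cols).groupby(prot_ids, sort=False).sum()
    any_obs = pd.DataFrame(observed, columns=cols).groupby(prot_ids, sort=False).any()
    abundance = np.log2(sums.to_numpy() / s[None, :] + 1.0)
    abundance[~any_obs.to_numpy()] = np.nan
    out = pd.DataFrame(abundance, index=sums.index, columns=cols).loc[order]
    return out, pd.Series(s, index=cols, name="scaling")


def filter_missing_proteins(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop proteins missing in strictly more than half the samples."""
    n = matrix.shape[1]
    keep = matrix.isna().sum(axis=1) <= n / 2
    log.info("missingness filter: %d of %d proteins retained", int(keep.sum()), len(keep))
    return matrix.loc[keep]


def remove_batch_effects(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Subtract per-protein batch BLUPs from a mixed model.

    Per protein: abundance ~ age group (categorical) + sex, with a random
    batch intercept fitted by REML; the batch BLUP is subtracted from each
    sample's abundance. Fixed effects are left in place. Proteins observed in
    fewer than 3 samples are returned unchanged.
    """
    if samples["batch"].nunique() < 2:
        raise ValueError("batch correction requires at least 2 batches")
    meta = samples.set_index("sample_id").loc[matrix.columns]
    out = matrix.copy()
    for prot, row in matrix.iterrows():
        obs = row.notna()
        if obs.sum() < 3:
            log.warning("protein %s observed in <3 samples; left uncorrected", prot)
            continue
        df = pd.DataFrame({
            "y": row[obs].to_numpy(),
            "age": pd.Categorical(meta.loc[obs, "age_months"]),
            "sex": meta.loc[obs, "sex"].to_numpy(),
            "batch": meta.loc[obs, "batch"].to_numpy(),
        })
        if df["batch"].nunique() < 2:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("y ~ C(age) + sex", df, groups=df["batch"])
                fit = md.fit(reml=True)
            blup = pd.Series({b: float(re.iloc[0]) for b, re in fit.random_effects.items()})
        except Exception:  # singular fits on degenerate proteins
            log.warning("batch model failed for %s; left uncorrected", prot)
            continue
        adjust = blup.reindex(df["batch"]).to_numpy()
        out.loc[prot, obs] = row[obs].to_numpy() - adjust
    return out


def rank_normal(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature rank-based inverse normal transform.

    Observed values become Phi^{-1}((rank - 0.5) / n_obs) with average ranks
    for ties; missing values stay missing.
    """
    vals = matrix.to_numpy(float)
    out = np.full_like(vals, np.nan)
    for i in range(vals.shape[0]):
        obs = ~np.isnan(vals[i])
        n = int(obs.sum())
        if n == 0:
            continue
        ranks = stats.rankdata(vals[i, obs], method="average")
        out[i, obs] = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantify(peptides: pd.DataFrame, samples: pd.DataFrame,
             genomes: GenotypeProbs = None, gene_map: pd.DataFrame = None,
             r_cut: float = 0.7, batch_correct: bool = True) -> dict:
    """Full proteomics stage; returns dict with matrices and reports.

    The scaling factors are computed from the complete observed peptide set
    before the polymorphic filter (loading normalization precedes peptide
    selection) and are not recomputed afterward.
    """
    scaling = sample_scaling(peptides, samples)
    report = None
    if genomes is not None and gene_map is not None:
        peptides, report = filter_polymorphic_peptides(
            peptides, genomes, gene_map, samples, r_cut=r_cut)
    abundance, s = rollup_proteins(peptides, samples, scaling=scaling)
    abundance = filter_missing_proteins(abundance)
    corrected = remove_batch_effects(abundance, samples) if batch_correct else abundance
    return {
        "abundance": corrected,
        "abundance_uncorrected": abundance,
        "rank_normal": rank_normal(corrected),
        "scaling": s,
        "polymorphic_report": report,
    }
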