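"""Sample-mixup detection by cross-source haplotype concordance.

Compares two founder-haplotype reconstructions of the same mice (e.g.
genotyping-array-based vs expression-based). For each mouse the mean
Euclidean distance between the 8-founder probability rows,

    dbar_i = (1/M) * sum_m ( sum_a (p_mia - q_mia)^2 )^(1/2),

is near 0 when both sources describe the same animal and approaches sqrt(2)
for unrelated genomes. Samples with dbar_i > 0.8 (strict) are flagged; flagged
samples are cross-matched to find mutual best matches, which indicate swapped
IDs rather than contamination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeProbs


def interpolate_probs(probs: GenotypeProbs, target_map: pd.DataFrame) -> GenotypeProbs:
    """Carry probability rows to a target marker map by nearest position.

    For each target marker the row of the nearest source marker on the same
    chromosome is used (ties break toward the lower coordinate), which keeps
    every output row exactly on the probability simplex.
    """
    src = probs.markers
    out_rows = np.empty((len(target_map), probs.n_samples, probs.probs.shape[2]))
    src_chrom = src["chromosome"].to_numpy()
    src_pos = src["position_bp"].to_numpy()
    for c in pd.unique(target_map["chromosome"]):
        tsel = np.flatnonzero(target_map["chromosome"].to_numpy() == c)
        ssel = np.flatnonzero(src_chrom == c)
        if len(ssel) == 0:
            raise ValueError(f"chromosome {c!r} absent from source map")
        spos = src_pos[ssel]
        tpos = target_map["position_bp"].to_numpy()[tsel]
        # first index achieving the min |delta| = lower coordinate on ties
        d = np.abs(tpos[:, None] - spos[None, :])
        nearest = ssel[np.argmin(d, axis=1)]
        out_rows[tsel] = probs.probs[nearest]
    return GenotypeProbs(markers=target_map.copy(), sample_ids=list(probs.sample_ids),
                         probs=out_rows)


def haplotype_distance(p: GenotypeProbs, q: GenotypeProbs) -> pd.Series:
    """Per-sample mean Euclidean distance between founder-probability rows."""
    if list(p.markers["marker_id"]) != list(q.markers["marker_id"]):
        raise ValueError("marker sets differ between the two reconstructions")
    if p.sample_ids != q.sample_ids:
        raise ValueError("sample sets differ between the two reconstructions")
    per_marker = np.sqrt(((p.probs - q.probs) ** 2).sum(axis=2))  # (M, N)
    return pd.Series(per_marker.mean(axis=0), index=p.sample_ids, name="dbar")


def _cross_distance_matrix(expr: GenotypeProbs, array: GenotypeProbs,
                           rows: np.ndarray) -> np.ndarray:
    """dbar between expression rows (subset) and every array sample."""
    e = expr.probs[:, rows, :]  # (M, R, 8)
    a = array.probs  # (M, N, 8)
    d = np.sqrt(((e[:, :, None, :] - a[:, None, :, :]) ** 2).sum(axis=3))  # (M, R, N)
    return d.mean(axis=0)


def flag_mixups(dbar: pd.Series, expr: GenotypeProbs = None,
                array: GenotypeProbs = None, threshold: float = 0.8) -> pd.DataFrame:
    """Flag samples with dbar strictly above the threshold and resolve them.

    When both reconstructions are supplied, each flagged sample's expression
    profile is compared against every array profile; pairs of flagged samples
    that are mutual nearest matches are labeled ``swap_candidate`` and the
    rest ``exclude``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    report = pd.DataFrame({"sample_id": dbar.index, "dbar": dbar.to_numpy()})
    report["flagged"] = report["dbar"] > threshold
    report["best_match"] = report["sample_id"]
    report["resolution"] = "keep"
    flagged = np.flatnonzero(report["flagged"].to_numpy())
    if len(flagged) and expr is not None and array is not None:
        cross = _cross_distance_matrix(expr, array, flagged)
        best = np.argmin(cross, axis=1)
        ids = np.asarray(array.sample_ids)
        report.loc[flagged, "best_match"] = ids[best]
        match_of = dict(zip(report.loc[flagged, "sample_id"], ids[best]))
        for i in flagged:
            sid = report.at[i, "sample_id"]
            other = match_of[sid]
            mutual = match_of.get(other) == sid and other != sid
            report.at[i, "resolution"] = "swap_candidate" if mutual else "exclude"
    elif len(flagged):
        report.loc[flagged, "resolution"] = "exclude"
    return report


def qc_mixups(array: GenotypeProbs, expr: GenotypeProbs,
              threshold: float = 0.8) -> pd.DataFrame:
    """Full QC: interpolate to the array map, compute dbar, flag and resolve."""
    expr_on_array = expr
    if list(expr.markers["marker_id"]) != list(array.markers["marker_id"]):
        expr_on_array = interpolate_probs(expr, array.markers)
    dbar = haplotype_distance(array, expr_on_array)
    return flag_mixups(dbar, expr=expr_on_array, array=array, threshold=threshold)
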