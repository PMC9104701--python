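"""Kinship-aware haplotype-dosage genome scans in a multiparent population.

Additive scans fit, at every marker,

    y = covariates + founder dosages + u + e,   u ~ N(0, tau_K^2 K_LOCO),

with the kinship variance ratio profiled once per (phenotype, chromosome)
under the no-QTL null and held fixed across loci, so the scan reduces to
generalized least squares in a whitened basis and LOD = (n/2) log10(RSS_null
/ RSS_marker) is non-negative by construction. Age-interactive scans add
dosage-by-age columns and test them against the additive model (LOD_int).
Genome-wide significance for the interaction uses residual permutation: the
null mixed model y = covariates + u + e is fitted with all-loci (non-LOCO)
kinship, its fitted values (fixed effects + kinship BLUP) are kept in place,
and the residuals are permuted before rescanning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import subseed
from .simulate import GenotypeProbs


@dataclass
class Kinship:
    """Realized genomic relationship matrices from founder probabilities.

    K[j, k] = (1/M) * sum_m sum_a p_mja * p_mka, either over all markers
    (``overall``) or excluding one chromosome at a time (``loco``).
    """

    overall: np.ndarray
    loco: dict  # chromosome -> N x N matrix
    sample_ids: list


def compute_kinship(genomes: GenotypeProbs, mode: str = "loco") -> Kinship:
    probs = genomes.probs
    chroms = genomes.markers["chromosome"].to_numpy()
    total = np.einsum("mia,mja->ij", probs, probs)
    m_all = probs.shape[0]
    overall = total / m_all
    loco = {}
    if mode == "loco":
        uniq = pd.unique(chroms)
        if len(uniq) < 2:
            raise ValueError("LOCO kinship requires at least 2 chromosomes")
        for c in uniq:
            sel = chroms == c
            part = np.einsum("mia,mja->ij", probs[sel], probs[sel])
            loco[c] = (total - part) / (m_all - sel.sum())
    return Kinship(overall=overall, loco=loco, sample_ids=list(genomes.sample_ids))


@dataclass
class NullFit:
    """Profiled null mixed-model fit and its whitening transform."""

    h2: float
    loglik: float
    U: np.ndarray  # eigenvectors of K
    d: np.ndarray  # eigenvalues of K
    sqrt_w: np.ndarray  # (h*d + (1-h))^{-1/2}
    rss_null: float  # covariate-only RSS in the whitened basis


def _profile_loglik(yt, Xt, d, h):
    n = yt.shape[0]
    v = h * d + (1.0 - h)
    w = 1.0 / v
    sw = np.sqrt(w)
    A = Xt * sw[:, None]
    b = yt * sw
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(((b - A @ beta) ** 2).sum())
    ll = -0.5 * n * np.log(rss / n) - 0.5 * np.sum(np.log(v)) - 0.5 * n * (1 + np.log(2 * np.pi))
    return ll, rss, sw


def fit_null_lmm(y: np.ndarray, covariates: np.ndarray, K: np.ndarray,
                 eig: tuple = None, grid: int = 50) -> NullFit:
    """Profile-ML heritability fit on an eigendecomposed kinship matrix.

    Maximizes the profiled likelihood over h in [0, 0.99) on a grid followed
    by golden-section refinement; ties resolve to the smallest h (so K = I
    returns h = 0). Pass ``eig=(d, U)`` to reuse a cached decomposition.
    """
    X = np.atleast_2d(covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    if eig is None:
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
    else:
        d, U = eig
    yt = U.T @ y
    Xt = U.T @ X
    hs = np.linspace(0.0, 0.99, grid)
    lls = np.array([_profile_loglik(yt, Xt, d, h)[0] for h in hs])
    i = int(np.argmax(lls))  # argmax takes the first (smallest h) on ties
    lo = hs[max(i - 1, 0)]
    hi = hs[min(i + 1, grid - 1)]
    gr = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    for _ in range(40):
        c1 = b - gr * (b - a)
        c2 = a + gr * (b - a)
        if _profile_loglik(yt, Xt, d, c1)[0] >= _profile_loglik(yt, Xt, d, c2)[0]:
            b = c2
        else:
            a = c1
    h = 0.5 * (a + b)
    ll_ref, _, _ = _profile_loglik(yt, Xt, d, h)
    if lls[i] >= ll_ref:  # grid point (incl. h=0) at least as good
        h, ll_ref = hs[i], lls[i]
    ll, rss, sw = _profile_loglik(yt, Xt, d, h)
    return NullFit(h2=float(h), loglik=float(ll), U=U, d=d, sqrt_w=sw, rss_null=rss)


def _eig_cache(kinship: Kinship) -> dict:
    cache = {}
    for c, K in kinship.loco.items():
        d, U = np.linalg.eigh(K)
        cache[c] = (np.clip(d, 0.0, None), U)
    d, U = np.linalg.eigh(kinship.overall)
    cache["__overall__"] = (np.clip(d, 0.0, None), U)
    return cache


class GenomeScanner:
    """Shared precomputation for many scans over one genome and covariate set."""

    def __init__(self, genomes: GenotypeProbs, kinship: Kinship,
                 covariates: np.ndarray, age_years: np.ndarray = None):
        self.genomes = genomes
        self.kinship = kinship
        self.X = np.atleast_2d(covariates)
        self.age = age_years
        self.eig = _eig_cache(kinship)
        self.chroms = genomes.markers["chromosome"].to_numpy()

    def scan(self, y: np.ndarray, interactive: bool = False) -> pd.DataFrame:
        """Genome scan; returns per-marker LOD (and LOD_int when requested)."""
        n = y.shape[0]
        probs = self.genomes.probs
        out_lod = np.zeros(probs.shape[0])
        out_int = np.zeros(probs.shape[0]) if interactive else None
        for c in pd.unique(self.chroms):
            d, U = self.eig[c]
            nf = fit_null_lmm(y, self.X, None, eig=(d, U))
            sw = nf.sqrt_w
            yt = (U.T @ y) * sw
            Xt = (U.T @ self.X) * sw[:, None]
            rss_null = nf.rss_null
            sel = np.flatnonzero(self.chroms == c)
            # whiten all dosage (and interaction) columns for this chromosome at once
            D = probs[sel]  # (mc, n, 8)
            Dt = np.einsum("ij,mja->mia", U.T, D) * sw[None, :, None]
            if interactive:
                DA = D * self.age[None, :, None]
                DAt = np.einsum("ij,mja->mia", U.T, DA) * sw[None, :, None]
            for k, m in enumerate(sel):
                if D[k].std(axis=0).max() == 0:
                    continue
                Xa = np.column_stack([Xt, Dt[k]])
                beta, *_ = np.linalg.lstsq(Xa, yt, rcond=None)
                rss_add = float(((yt - Xa @ beta) ** 2).sum())
                out_lod[m] = max(0.5 * n * np.log10(max(rss_null, 1e-300) / max(rss_add, 1e-300)), 0.0)
                if interactive:
                    Xf = np.column_stack([Xa, DAt[k]])
                    betaf, *_ = np.linalg.lstsq(Xf, yt, rcond=None)
                    rss_full = float(((yt - Xf @ betaf) ** 2).sum())
                    out_int[m] = max(0.5 * n * np.log10(max(rss_add, 1e-300) / max(rss_full, 1e-300)), 0.0)
        res = self.genomes.markers.copy()
        res["lod"] = out_lod
        if interactive:
            res["lod_int"] = out_int
        return res


def scan_additive(y: np.ndarray, genomes: GenotypeProbs, kinship: Kinship,
                  covariates: np.ndarray) -> pd.DataFrame:
    return GenomeScanner(genomes, kinship, covariates).scan(y, interactive=False)


def scan_interactive(y: np.ndarray, genomes: GenotypeProbs, kinship: Kinship,
                     covariates: np.ndarray, age_years: np.ndarray) -> pd.DataFrame:
    return GenomeScanner(genomes, kinship, covariates, age_years).scan(y, interactive=True)


def gls_scan_bruteforce(y: np.ndarray, genomes: GenotypeProbs, kinship: Kinship,
                        covariates: np.ndarray, h2: dict = None) -> pd.DataFrame:
    """Reference additive scan via explicit covariance-matrix GLS.

    Independent oracle for the whitened fast path: builds V = h K + (1-h) I
    per chromosome, Cholesky-whitens the full system, and solves each marker
    model directly. Quadratic in n; for tests on small instances only.
    """
    X = np.atleast_2d(covariates)
    chroms = genomes.markers["chromosome"].to_numpy()
    n = y.shape[0]
    out = np.zeros(genomes.probs.shape[0])
    for c in pd.unique(chroms):
        K = kinship.loco[c]
        d, U = np.linalg.eigh(K)
        nf = fit_null_lmm(y, X, None, eig=(np.clip(d, 0, None), U))
        h = h2[c] if h2 is not None else nf.h2
        V = h * K + (1 - h) * np.eye(n)
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, y)
        Xw = np.linalg.solve(L, X)
        b0, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss0 = float(((yw - Xw @ b0) ** 2).sum())
        for m in np.flatnonzero(chroms == c):
            Dm = np.linalg.solve(L, genomes.probs[m])
            Xa = np.column_stack([Xw, Dm])
            b1, *_ = np.linalg.lstsq(Xa, yw, rcond=None)
            rss1 = float(((yw - Xa @ b1) ** 2).sum())
            out[m] = 0.5 * n * np.log10(rss0 / rss1)
    res = genomes.markers.copy()
    res["lod"] = out
    return res


def residual_permutation_null(y: np.ndarray, genomes: GenotypeProbs,
                              kinship: Kinship, covariates: np.ndarray,
                              age_years: np.ndarray, B: int, seed: int,
                              scanner: GenomeScanner = None) -> np.ndarray:
    """Max interactive LODs over B residual-permutation replicates.

    Fits y = covariates + u + e with the all-loci kinship, keeps the fitted
    fixed effects plus the kinship BLUP in place, permutes the residual
    vector, and rescans genome-wide. Returns the B genome-wide maxima.
    """
    if scanner is None:
        scanner = GenomeScanner(genomes, kinship, covariates, age_years)
    d, U = scanner.eig["__overall__"]
    nf = fit_null_lmm(y, scanner.X, None, eig=(d, U))
    h = nf.h2
    yt = U.T @ y
    Xt = U.T @ scanner.X
    w = 1.0 / (h * d + (1 - h))
    A = Xt * np.sqrt(w)[:, None]
    beta, *_ = np.linalg.lstsq(A, yt * np.sqrt(w), rcond=None)
    fixed = scanner.X @ beta
    resid_marg = y - fixed
    # kinship BLUP: E[u | y] = h K V^{-1} (y - X beta) in the eigenbasis
    shrink = h * d * w
    blup = U @ (shrink * (U.T @ resid_marg))
    fitted = fixed + blup
    e = y - fitted
    rng = subseed(seed, "residual_perm")
    maxima = np.empty(B)
    for b in range(B):
        ystar = fitted + e[rng.permutation(e.shape[0])]
        res = scanner.scan(ystar, interactive=True)
        maxima[b] = res["lod_int"].max()
    return maxima


def residual_permutation_threshold(y, genomes, kinship, covariates, age_years,
                                   B: int = 1000, quantile: float = 0.95,
                                   seed: int = 0, scanner=None):
    """Genome-wide LOD_int threshold from the residual-permutation null."""
    import logging
    if B < 100:
        logging.getLogger(__name__).warning(
            "B=%d permutations is low for a reported threshold", B)
    maxima = residual_permutation_null(y, genomes, kinship, covariates,
                                       age_years, B, seed, scanner=scanner)
    return float(np.quantile(maxima, quantile)), maxima


def pooled_permutation_threshold(phenotypes: pd.DataFrame, genomes, kinship,
                                 covariates, age_years, B: int = 1000,
                                 quantile: float = 0.95, seed: int = 0) -> tuple:
    """One shared threshold: B permutation maxima spread across phenotypes.

    Distributes the B replicates round-robin over the phenotype rows (the
    permutation null is pooled, as when a single study-wide threshold is
    reported) and returns (threshold, all maxima).
    """
    scanner = GenomeScanner(genomes, kinship, covariates, age_years)
    ids = list(phenotypes.index)
    per = np.full(len(ids), B // len(ids))
    per[: B % len(ids)] += 1
    maxima = []
    for k, pid in enumerate(ids):
        if per[k] == 0:
            continue
        y = phenotypes.loc[pid].to_numpy(float)
        m = residual_permutation_null(y, genomes, kinship, covariates, age_years,
                                      int(per[k]), seed + k, scanner=scanner)
        maxima.append(m)
    maxima = np.concatenate(maxima)
    return float(np.quantile(maxima, quantile)), maxima


def call_age_qtl_peaks(scans: dict, threshold: float, suggestive: float,
                       gene_positions: pd.DataFrame,
                       local_window: float = 1e7) -> pd.DataFrame:
    """Per-phenotype, per-chromosome interaction peaks above the cutoffs.

    ``scans`` maps phenotype id -> scan table with lod_int. A peak is the
    max-LOD_int marker of a chromosome if it exceeds the suggestive level;
    peaks above ``threshold`` are significant. Peaks on the phenotype's own
    chromosome within ``local_window`` bp are local, the rest distal.
    """
    gp = gene_positions.set_index("gene_id")
    rows = []
    for pid, tab in scans.items():
        for c, sub in tab.groupby("chromosome", sort=False):
            i = sub["lod_int"].idxmax()
            lod = float(sub.loc[i, "lod_int"])
            if lod <= suggestive:
                continue
            pos = int(sub.loc[i, "position_bp"])
            if pid in gp.index:
                gchrom = gp.loc[pid, "chromosome"]
                gpos = int(gp.loc[pid, "position_bp"])
                local = (gchrom == c) and abs(pos - gpos) <= local_window
            else:
                gchrom, gpos, local = None, None, False
            rows.append((pid, sub.loc[i, "marker_id"], c, pos, lod,
                         lod > threshold, "local" if local else "distal",
                         gchrom, gpos))
    return pd.DataFrame(rows, columns=["phenotype_id", "marker_id", "chromosome",
                                       "position_bp", "lod_int", "significant",
                                       "class", "gene_chromosome", "gene_position_bp"])


def find_hotspots(peaks: pd.DataFrame, window_bp: float = 4e6,
                  step_bp: float = 1e6, min_count: int = 30) -> pd.DataFrame:
    """Sliding-window distal-QTL density; windows with count > min_count merge.

    Windows are half-open [start, start + window_bp) stepped by ``step_bp``;
    overlapping seed windows on a chromosome merge into one hotspot whose
    members are all phenotypes with peaks in the merged span.
    """
    distal = peaks[peaks["class"] == "distal"]
    rows = []
    for c, sub in distal.groupby("chromosome", sort=False):
        pos = np.sort(sub["position_bp"].to_numpy())
        if len(pos) == 0:
            continue
        starts = np.arange(0, pos.max() + step_bp, step_bp)
        seeds = []
        for s in starts:
            cnt = int(np.sum((pos >= s) & (pos < s + window_bp)))
            if cnt > min_count:
                seeds.append((s, s + window_bp))
        merged = []
        for s, e in seeds:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            inside = sub[(sub["position_bp"] >= s) & (sub["position_bp"] < e)]
            rows.append((c, int(s), int(e), len(inside),
                         ",".join(sorted(inside["phenotype_id"]))))
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "qtl_count", "members"])


def refine_hotspot_members(members: list, matrix: pd.DataFrame,
                           min_mean_r: float = 0.3) -> list:
    """Keep members whose |mean correlation| with the others is >= min_mean_r.

    Single non-iterated pass, inclusive at the boundary; members absent from
    the matrix are dropped.
    """
    present = [m for m in members if m in matrix.index]
    if len(present) < 3:
        return present
    X = matrix.loc[present].to_numpy(float)
    from .stoichiometry import nan_pearson
    r, _ = nan_pearson(X)
    np.fill_diagonal(r, np.nan)
    mean_r = np.nanmean(r, axis=1)
    return [m for m, mr in zip(present, mean_r) if abs(mr) >= min_mean_r]
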