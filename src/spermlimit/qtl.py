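"""Single-marker regression QTL scans with permutation thresholds.

At each marker m the LOD score under a normal phenotype model is

    LOD(m) = (n / 2) * log10(RSS_null / RSS_full)

from ordinary least squares, where for a plain scan the null model is the
intercept alone and the full model adds the 0/1 marker genotype; with an
additive covariate (e.g. the focal nurf-1-like marker) the null is
intercept + covariate and the full model adds the marker; with an
interactive covariate the full model adds the marker and the marker x
covariate product. Genome-wide significance is calibrated by permuting the
phenotype vector across strains (optionally stratified within covariate
genotype classes) and taking an upper quantile of the per-permutation
maximum LOD. Scans report marker positions only (pure marker regression,
no interval mapping).

The panel is fully inbred, so genotypes are coded 0/1 with no dominance
term. All scans are evaluated with closed-form projections so that
thousands of permutations cost a handful of matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import RILPanel

__all__ = [
    "LOD_CAP",
    "ScanResult",
    "PermutationThreshold",
    "marker_regression_scan",
    "permutation_threshold",
    "bayes_credible_interval",
    "scan_fitted_parameters",
]

logger = logging.getLogger(__name__)

#: LOD reported for an exact fit (RSS_full == 0), kept finite for thresholds
LOD_CAP = 50.0
_MIN_STRAINS = 10


def _residualize(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of the columns of X after OLS projection onto span(Z)."""
    q, _ = np.linalg.qr(Z)
    return X - q @ (q.T @ X)


def _lod_from_rss(n: int, rss0: np.ndarray, rss1: np.ndarray):
    """(n/2) log10(rss0/rss1), with exact fits capped and flagged."""
    rss0 = np.asarray(rss0, dtype=float)
    rss1 = np.asarray(rss1, dtype=float)
    tiny = np.finfo(float).tiny
    perfect = rss1 <= 1e-12 * np.maximum(rss0, tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = 0.5 * n * np.log10(np.maximum(rss0, tiny) / np.maximum(rss1, tiny))
    lod = np.where(perfect, LOD_CAP, lod)
    lod = np.clip(lod, 0.0, LOD_CAP)
    return lod, perfect


def _scan_lods(
    G: np.ndarray,
    Y: np.ndarray,
    covariate: np.ndarray | None,
    interactive: bool,
):
    """LOD matrices for markers x phenotype-columns.

    Returns (lod, perfect_flags, monomorphic) where lod has shape (m, p).
    For covariate scans the null model is intercept + covariate for both the
    additive and the interactive LOD (the interactive LOD therefore measures
    marker main effect + marker x covariate jointly, as in covariate scans
    of RIL phenotypes).
    """
    n, m = G.shape
    Y = Y if Y.ndim == 2 else Y[:, None]
    if covariate is None:
        Z = np.ones((n, 1))
    else:
        Z = np.column_stack([np.ones(n), covariate])
    Gt = _residualize(G, Z)
    Yt = _residualize(Y, Z)
    rss0 = np.sum(Yt * Yt, axis=0)  # (p,)
    # a phenotype fully explained by the null (e.g. constant) carries no
    # marker information: RSS_null is pure projection round-off there
    null_degenerate = rss0 <= 1e-20 * np.maximum(np.sum(Y * Y, axis=0), 1e-300)

    gg = np.sum(Gt * Gt, axis=0)  # (m,)
    mono = gg <= 1e-12 * n
    gg_safe = np.where(mono, 1.0, gg)
    gy = Gt.T @ Yt  # (m, p)

    if not interactive:
        explained = gy**2 / gg_safe[:, None]
    else:
        if covariate is None:
            raise ValueError("interactive scan requires a covariate")
        H = G * covariate[:, None]
        Ht = _residualize(H, Z)
        hh = np.sum(Ht * Ht, axis=0)
        gh = np.sum(Gt * Ht, axis=0)
        hy = Ht.T @ Yt
        det = gg * hh - gh**2
        degenerate = det <= 1e-10 * np.maximum(gg * hh, 1e-300)
        det_safe = np.where(degenerate, 1.0, det)
        expl2 = (
            hh[:, None] * gy**2
            - 2.0 * gh[:, None] * gy * hy
            + gg[:, None] * hy**2
        ) / det_safe[:, None]
        # interaction column collinear with the marker: fall back to the
        # marker-only explained sum of squares
        expl1 = gy**2 / gg_safe[:, None]
        explained = np.where(degenerate[:, None], expl1, expl2)
    explained = np.where(mono[:, None], 0.0, explained)
    explained = np.minimum(explained, rss0[None, :])
    lod, perfect = _lod_from_rss(n, rss0[None, :], rss0[None, :] - explained)
    lod = np.where(mono[:, None] | null_degenerate[None, :], 0.0, lod)
    return lod, perfect & ~mono[:, None] & ~null_degenerate[None, :], mono


@dataclass
class PermutationThreshold:
    scan_type: str
    alpha: float
    n_permutations: int
    seed: int
    threshold: float
    maxima: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "scan_type": self.scan_type,
            "alpha": self.alpha,
            "n_perm": self.n_permutations,
            "seed": self.seed,
            "threshold": self.threshold,
        }


@dataclass
class ScanResult:
    """Per-marker LOD curves plus any attached permutation thresholds."""

    frame: pd.DataFrame
    n: int
    covariate_marker: str | None = None
    primary_column: str = "lod_single"
    thresholds: dict[str, PermutationThreshold] = field(default_factory=dict)

    def peak(self, column: str | None = None, chromosome: str | None = None):
        """Row of the maximum LOD (leftmost marker on ties)."""
        col = column or self.primary_column
        f = self.frame
        if chromosome is not None:
            f = f[f["chrom"] == chromosome]
        best = f[col].to_numpy()
        return f.iloc[int(np.argmax(best))]

    def significant_markers(self, column: str | None = None) -> pd.DataFrame:
        col = column or self.primary_column
        thr = self.thresholds[col].threshold
        return self.frame[self.frame[col] >= thr]


def _aligned_phenotype(panel: RILPanel, phenotype) -> tuple[np.ndarray, np.ndarray]:
    """Phenotype values aligned to panel strains; returns (values, keep_mask)."""
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(panel.strains).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
        if y.shape[0] != panel.n_strains:
            raise ValueError("phenotype length does not match panel strains")
    keep = np.isfinite(y)
    return y, keep


def marker_regression_scan(
    panel: RILPanel,
    phenotype,
    covariate_marker: str | None = None,
    interactive: bool = False,
) -> ScanResult:
    """One-dimensional marker-regression scan of a per-strain phenotype.

    Always reports `lod_single`; when `covariate_marker` is given, also
    `lod_addcov` and (with `interactive=True`) `lod_intcov` and
    `lod_int_only` = lod_intcov - lod_addcov, the pure-interaction signal.
    Strains with missing phenotype are dropped listwise.
    """
    y, keep = _aligned_phenotype(panel, phenotype)
    if keep.sum() < _MIN_STRAINS:
        raise ValueError(
            f"need phenotype for >= {_MIN_STRAINS} strains, have {int(keep.sum())}"
        )
    G = panel.genotypes.to_numpy(dtype=float)[keep]
    yv = y[keep][:, None]
    n = int(keep.sum())

    out = panel.gmap.table[["marker", "chrom", "cM"]].copy().reset_index(drop=True)
    flags = np.array([""] * len(out), dtype=object)

    lod_s, perf_s, mono = _scan_lods(G, yv, None, False)
    out["lod_single"] = lod_s[:, 0]
    flags[mono] = "monomorphic"
    flags[perf_s[:, 0]] = "perfect_fit"
    primary = "lod_single"

    cov = None
    if covariate_marker is not None:
        panel.gmap.require(covariate_marker)
        cov = panel.genotypes[covariate_marker].to_numpy(dtype=float)[keep]
        lod_a, perf_a, _ = _scan_lods(G, yv, cov, False)
        out["lod_addcov"] = lod_a[:, 0]
        flags[perf_a[:, 0]] = "perfect_fit"
        primary = "lod_addcov"
        if interactive:
            lod_i, perf_i, _ = _scan_lods(G, yv, cov, True)
            out["lod_intcov"] = lod_i[:, 0]
            out["lod_int_only"] = np.maximum(lod_i[:, 0] - lod_a[:, 0], 0.0)
            flags[perf_i[:, 0]] = "perfect_fit"
            primary = "lod_intcov"
    out["flags"] = flags
    return ScanResult(
        frame=out, n=n, covariate_marker=covariate_marker, primary_column=primary
    )


def _permuted_indices(
    rng: np.random.Generator,
    n: int,
    n_perm: int,
    strata: np.ndarray | None,
) -> np.ndarray:
    idx = np.empty((n_perm, n), dtype=int)
    base = np.arange(n)
    if strata is None:
        for p in range(n_perm):
            idx[p] = rng.permutation(n)
        return idx
    groups = [np.nonzero(strata == v)[0] for v in np.unique(strata)]
    for p in range(n_perm):
        row = base.copy()
        for g in groups:
            row[g] = g[rng.permutation(len(g))]
        idx[p] = row
    return idx


def permutation_threshold(
    panel: RILPanel,
    phenotype,
    covariate_marker: str | None = None,
    interactive: bool = False,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stratified: bool = True,
) -> PermutationThreshold:
    """Genome-wide LOD threshold from phenotype permutations.

    Records the maximum LOD over all markers for each permuted phenotype and
    returns the empirical (1 - alpha) quantile (upper order statistic, so the
    test is conservative at finite n_perm). With a covariate in the model the
    shuffles are stratified within covariate genotype classes by default,
    preserving the covariate-phenotype association under the null of no
    marker effect.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if alpha <= 0.05 and n_perm < 100:
        raise ValueError("need n_perm >= 100 for alpha <= 0.05")
    y, keep = _aligned_phenotype(panel, phenotype)
    G = panel.genotypes.to_numpy(dtype=float)[keep]
    yv = y[keep]
    n = yv.size

    cov = None
    strata = None
    if covariate_marker is not None:
        panel.gmap.require(covariate_marker)
        cov = panel.genotypes[covariate_marker].to_numpy(dtype=float)[keep]
        if stratified:
            strata = cov
        scan_type = "interactive_covariate" if interactive else "additive_covariate"
    else:
        scan_type = "single"

    rng = np.random.default_rng(seed)
    idx = _permuted_indices(rng, n, n_perm, strata)
    Y = yv[idx].T  # (n, n_perm)
    lod, _, _ = _scan_lods(G, Y, cov, interactive)
    maxima = lod.max(axis=0)
    k = max(int(np.ceil((1.0 - alpha) * n_perm)), 1)
    threshold = float(np.sort(maxima)[k - 1])
    return PermutationThreshold(
        scan_type=scan_type,
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
        threshold=threshold,
        maxima=maxima,
    )


def bayes_credible_interval(
    scan: ScanResult,
    chromosome: str,
    mass: float = 0.95,
    column: str | None = None,
) -> tuple[float, float]:
    """Approximate Bayes credible interval for a QTL peak on one chromosome.

    Normalizes 10^LOD over the chromosome's markers as a posterior and grows
    the smallest contiguous marker interval containing the peak until it
    holds >= `mass` of that posterior. A flat profile (including all-zero
    LOD) yields the whole chromosome.
    """
    col = column or scan.primary_column
    f = scan.frame[scan.frame["chrom"] == chromosome]
    if len(f) == 0:
        raise ValueError(f"chromosome {chromosome!r} not in scan")
    lod = f[col].to_numpy(dtype=float)
    pos = f["cM"].to_numpy(dtype=float)
    if not np.any(np.isfinite(lod)):
        raise ValueError("no finite LOD on chromosome")
    if lod.max() - lod.min() < 1e-12:
        logger.warning(
            "flat LOD profile on %s: credible interval is the whole chromosome",
            chromosome,
        )
        return float(pos[0]), float(pos[-1])
    w = np.power(10.0, lod - lod.max())
    post = w / w.sum()
    peak = int(np.argmax(lod))  # argmax returns the leftmost maximum
    lo = hi = peak
    total = post[peak]
    while total < mass and (lo > 0 or hi < len(post) - 1):
        left = post[lo - 1] if lo > 0 else -np.inf
        right = post[hi + 1] if hi < len(post) - 1 else -np.inf
        if left >= right:
            lo -= 1
            total += post[lo]
        else:
            hi += 1
            total += post[hi]
    return float(pos[lo]), float(pos[hi])


def scan_fitted_parameters(
    panel: RILPanel,
    panel_fit,
    covariate_marker: str | None = None,
) -> tuple[ScanResult, ScanResult]:
    """Scans of the fitted k_o and S_0 vectors (all covariate modes).

    Strains whose fits did not converge are excluded (logged)."""
    frame = panel_fit.to_frame() if hasattr(panel_fit, "to_frame") else panel_fit
    usable = frame[frame["converged"].astype(bool)]
    dropped = len(frame) - len(usable)
    if dropped:
        logger.info("excluding %d unconverged strains from parameter scans", dropped)
    ko = usable["k_o"].reindex(panel.strains)
    s0 = usable["s_0"].reindex(panel.strains)
    kwargs = dict(covariate_marker=covariate_marker, interactive=covariate_marker is not None)
    return (
        marker_regression_scan(panel, ko, **kwargs),
        marker_regression_scan(panel, s0, **kwargs),
    )
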