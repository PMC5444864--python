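"""Genotype-partition summaries, drop-one ANOVA and the sign-epistasis zone.

The quantitative-genetic layer asks, for each modifier QTL and assay time
point, whether the modifier has an effect on the egg-laying rate, whether
that effect interacts non-linearly with the focal (nurf-1-like) locus, and
in which direction. All significant QTLs are fitted together per time point
with their main effects and their interactions with the focal locus
(y = Q1 + ... + Qfocal + ... + Q1*Qfocal + ...); a QTL's F statistic comes
from dropping its main and interaction terms at once, and the
Benjamini-Hochberg procedure controls the false discovery rate across the
QTL x timepoint family.

Direction-of-effect epistasis nomenclature: a modifier whose effect points
the same way in both focal backgrounds (different magnitudes) shows
*positive* epistasis; opposite directions show *negative* epistasis. The
feedback model predicts a transient window of negative epistasis — the
*sign epistasis zone* — between the times at which the modifier's
rate-difference contrast crosses zero in each of the two focal backgrounds,
a direct consequence of the faster class exhausting its sperm earlier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .model import EggLayingParams, egg_rate
from .panel import RILPanel

__all__ = [
    "SignEpistasisZone",
    "InteractionCall",
    "RankDeficiencyError",
    "benjamini_hochberg",
    "partition_by_genotype",
    "drop_one_anova",
    "classify_interaction",
    "sign_epistasis_zone",
]


class RankDeficiencyError(ValueError):
    """The ANOVA design matrix is rank deficient."""


def benjamini_hochberg(pvalues, alpha: float = 0.05):
    """BH step-up FDR control; returns (reject mask, adjusted q-values)."""
    p = np.asarray(pvalues, dtype=float)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, q


def partition_by_genotype(
    panel: RILPanel,
    phenotypes: pd.DataFrame,
    loci: Sequence[str],
) -> pd.DataFrame:
    """Class mean and SEM of a per-timepoint phenotype at 1 or 2 loci.

    `phenotypes` is strains x timepoints. Classes are the 2 (one locus) or
    4 (two loci) genotype combinations; SEM is reported only for classes
    with n >= 2, and empty classes appear with n = 0 and no mean.
    """
    if not 1 <= len(loci) <= 2:
        raise ValueError("partition on 1 or 2 loci")
    for m in loci:
        panel.gmap.require(m)
    geno = panel.genotypes.loc[:, list(loci)]
    y = phenotypes.reindex(panel.strains)

    from itertools import product

    rows = []
    for combo in product((0, 1), repeat=len(loci)):
        mask = np.ones(panel.n_strains, dtype=bool)
        for m, g in zip(loci, combo):
            mask &= geno[m].to_numpy() == g
        for tp in y.columns:
            vals = y.loc[mask, tp].dropna().to_numpy()
            n = vals.size
            rows.append(
                {
                    "timepoint": tp,
                    **{f"g_{m}": g for m, g in zip(loci, combo)},
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _design(geno: pd.DataFrame, qtl_markers: list[str], focal: str):
    """Full-model design matrix: intercept, main effects, modifier x focal
    interactions. Returns (X, column labels, column groups per QTL)."""
    n = len(geno)
    cols = [np.ones(n)]
    labels = ["intercept"]
    for m in qtl_markers:
        cols.append(geno[m].to_numpy(dtype=float))
        labels.append(f"main:{m}")
    gf = geno[focal].to_numpy(dtype=float)
    for m in qtl_markers:
        if m == focal:
            continue
        cols.append(geno[m].to_numpy(dtype=float) * gf)
        labels.append(f"int:{m}x{focal}")
    X = np.column_stack(cols)
    groups = {}
    for m in qtl_markers:
        if m == focal:
            grp = [labels.index(f"main:{m}")] + [
                i for i, l in enumerate(labels) if l.startswith("int:")
            ]
        else:
            grp = [labels.index(f"main:{m}"), labels.index(f"int:{m}x{focal}")]
        groups[m] = grp
    return X, labels, groups


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def drop_one_anova(
    panel: RILPanel,
    phenotypes: pd.DataFrame,
    qtl_markers: Sequence[str],
    focal_marker: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Drop-one ANOVA of all QTLs against per-timepoint phenotypes.

    For every QTL and timepoint: F from dropping the QTL's main effect and
    its interaction(s) with the focal locus out of the full model; a
    separate interaction-only F (modifiers only); BH-adjusted q-values, each
    family spanning all QTL x timepoint tests of its kind; variance
    explained as drop-one sum of squares over total (type-III style); the
    direction of the modifier effect within each focal background; and the
    epistasis classification.
    """
    qtl_markers = list(dict.fromkeys(qtl_markers))
    if focal_marker not in qtl_markers:
        raise ValueError("focal_marker must be among qtl_markers")
    for m in qtl_markers:
        panel.gmap.require(m)
    geno = panel.genotypes
    y_all = phenotypes.reindex(panel.strains)
    X, labels, groups = _design(geno, qtl_markers, focal_marker)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via QR pivots
        _, R = np.linalg.qr(X)
        bad = [labels[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise RankDeficiencyError(f"design matrix rank deficient; check terms {bad}")

    gf = geno[focal_marker].to_numpy()
    rows = []
    for tp in y_all.columns:
        y = y_all[tp].to_numpy(dtype=float)
        keep = np.isfinite(y)
        Xk, yk = X[keep], y[keep]
        n, p = Xk.shape
        dof = n - p
        if dof < 1:
            raise ValueError(f"timepoint {tp}: not enough strains for the model")
        rss_full = _rss(Xk, yk)
        ss_total = float(np.sum((yk - yk.mean()) ** 2))
        for m in qtl_markers:
            drop = groups[m]
            Xd = np.delete(Xk, drop, axis=1)
            rss_d = _rss(Xd, yk)
            df1 = len(drop)
            F = ((rss_d - rss_full) / df1) / (rss_full / dof)
            pval = float(f_dist.sf(F, df1, dof))
            row = {
                "qtl": m,
                "timepoint": tp,
                "is_focal": m == focal_marker,
                "f_drop": float(F),
                "df1": df1,
                "df2": dof,
                "p_drop": pval,
                "variance_explained": float(
                    min(max((rss_d - rss_full) / ss_total, 0.0), 1.0)
                ),
            }
            if m != focal_marker:
                int_idx = labels.index(f"int:{m}x{focal_marker}")
                Xi = np.delete(Xk, [int_idx], axis=1)
                rss_i = _rss(Xi, yk)
                Fi = (rss_i - rss_full) / (rss_full / dof)
                row["f_int"] = float(Fi)
                row["p_int"] = float(f_dist.sf(Fi, 1, dof))
                g = geno[m].to_numpy()[keep]
                gfk = gf[keep]
                eff = {}
                for bg in (0, 1):
                    sel = gfk == bg
                    hi = y[keep][sel & (g == 1)]
                    lo = y[keep][sel & (g == 0)]
                    eff[bg] = (
                        float(hi.mean() - lo.mean())
                        if hi.size and lo.size
                        else np.nan
                    )
                row["effect_in_A"] = eff[0]
                row["effect_in_B"] = eff[1]
            else:
                row.update(
                    f_int=np.nan, p_int=np.nan, effect_in_A=np.nan, effect_in_B=np.nan
                )
            rows.append(row)

    out = pd.DataFrame(rows)
    out["q_drop"] = np.nan
    out["q_int"] = np.nan
    _, out.loc[:, "q_drop"] = benjamini_hochberg(out["p_drop"], alpha)
    mod = ~out["is_focal"]
    if mod.any():
        _, qi = benjamini_hochberg(out.loc[mod, "p_int"], alpha)
        out.loc[mod, "q_int"] = qi
    # spec-facing alias: the adjusted q of the QTL-effect test
    out["q"] = out["q_drop"]

    labels_out = []
    flags = []
    for _, r in out.iterrows():
        if r["is_focal"]:
            labels_out.append("focal")
            flags.append("")
            continue
        call = classify_interaction(
            r["effect_in_A"],
            r["effect_in_B"],
            effect_significant=bool(r["q_drop"] < alpha),
            interaction_significant=bool(r["q_int"] < alpha),
        )
        labels_out.append(call.label)
        flags.append("boundary" if call.boundary else "")
    out["classification"] = labels_out
    out["flags"] = flags
    return out


class InteractionCall(NamedTuple):
    label: str
    boundary: bool = False


def classify_interaction(
    effect_in_background_a: float,
    effect_in_background_b: float,
    *,
    interaction_significant: bool,
    effect_significant: bool = True,
) -> InteractionCall:
    """Direction-of-effect epistasis classification.

    No significant QTL effect -> "not significant"; significant effect
    without a significant interaction -> "additive"; significant interaction
    with same-sign effects in the two focal backgrounds -> "positive
    epistasis"; opposite signs -> "negative epistasis". An exactly zero
    effect alongside a significant interaction is classified by the nonzero
    effect's direction (same-sign rule) and flagged as a boundary case.
    """
    a, b = float(effect_in_background_a), float(effect_in_background_b)
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("both effects must be finite")
    if not effect_significant:
        return InteractionCall("not significant")
    if not interaction_significant:
        return InteractionCall("additive")
    if a == 0.0 or b == 0.0:
        return InteractionCall("positive epistasis", boundary=True)
    if np.sign(a) == np.sign(b):
        return InteractionCall("positive epistasis")
    return InteractionCall("negative epistasis")


@dataclass(frozen=True)
class SignEpistasisZone:
    """Time window in which the modifier's effect direction depends on the
    focal genotype. Empty iff t_open == t_close."""

    t_open: float
    t_close: float
    class_params: dict
    flag: str = ""

    @property
    def empty(self) -> bool:
        return not (self.t_close > self.t_open)

    @property
    def width(self) -> float:
        return max(self.t_close - self.t_open, 0.0)

    def midpoint(self) -> float:
        return 0.5 * (self.t_open + self.t_close)


def _contrast_crossing(
    p_with: EggLayingParams,
    p_without: EggLayingParams,
    horizon: float,
    xtol: float,
) -> float | None:
    """First zero of egg_rate(with) - egg_rate(without) on (0, horizon]."""
    grid = np.linspace(0.0, horizon, 2001)[1:]
    d = np.asarray(egg_rate(p_with, grid)) - np.asarray(egg_rate(p_without, grid))
    sign = np.sign(d)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        return None

    def fn(t):
        return float(egg_rate(p_with, float(t)) - egg_rate(p_without, float(t)))

    i = idx[0]
    return float(brentq(fn, grid[i], grid[i + 1], xtol=xtol))


def sign_epistasis_zone(
    baseline_k_o: float,
    focal_effect: float,
    modifier_effect: float,
    s_0: float,
    k_f: float = 2.6e-4,
    xtol: float = 1e-6,
) -> SignEpistasisZone:
    """Model-derived sign-epistasis window for two loci acting additively
    on the oocyte generation rate.

    The four genotype classes have k_o = baseline, baseline + modifier,
    baseline + focal, baseline + focal + modifier. Within each focal
    background the modifier's rate contrast changes sign exactly once as
    the faster class runs out of sperm; the zone is the interval between
    those two crossing times, inside which the modifier points in opposite
    directions in the two backgrounds.
    """
    kos = {
        "base": baseline_k_o,
        "mod": baseline_k_o + modifier_effect,
        "focal": baseline_k_o + focal_effect,
        "focal+mod": baseline_k_o + focal_effect + modifier_effect,
    }
    if any(v <= 0 for v in kos.values()):
        raise ValueError(f"all genotype-class k_o values must be positive: {kos}")
    params = {
        k: EggLayingParams(k_o=v, k_f=k_f, s_0=s_0) for k, v in kos.items()
    }
    if modifier_effect == 0.0:
        return SignEpistasisZone(0.0, 0.0, params, flag="zero modifier effect")

    horizon = 10.0 * s_0 / min(kos.values())
    t0 = _contrast_crossing(params["mod"], params["base"], horizon, xtol)
    t1 = _contrast_crossing(params["focal+mod"], params["focal"], horizon, xtol)
    if t0 is None or t1 is None:
        return SignEpistasisZone(0.0, 0.0, params, flag="no crossing within horizon")
    lo, hi = sorted((t0, t1))
    return SignEpistasisZone(lo, hi, params)
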