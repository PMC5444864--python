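"""End-to-end validation measurements on synthetic study-scale data.

Each function runs one self-contained computation — closed form vs numeric
integration, estimator recovery, permutation-threshold calibration,
parameter-resolved mapping power, ANOVA cross-checks, the model's
sign-switch and mating predictions — and returns the measured quantities.
The acceptance script and the acceptance test suite both call these, so the
reported numbers are always recomputed from scratch.

Problem sizes default to the study design (94 strains, 192 markers, five
6-hour windows of six animals) with permutation counts and replicate grids
sized for a single CPU.
"""

from __future__ import annotations

import numpy as np
import numpy.linalg as la
import pandas as pd

from .epistasis import benjamini_hochberg, drop_one_anova, sign_epistasis_zone
from .fitting import AssayObservation, StrainPhenotype, fit_panel, fit_strain
from .model import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    EggLayingParams,
    analytic_trajectory,
    effect_size,
    effect_size_crossings,
    egg_rate,
    simulate_numeric,
    simulate_with_mating,
    window_eggs,
)
from .panel import (
    DEFAULT_WINDOWS,
    GeneticMap,
    PanelConfig,
    QTLSpec,
    generate_ril_genotypes,
    generate_study_like_dataset,
)
from .io import phenotypes_to_strains
from .qtl import marker_regression_scan, permutation_threshold

__all__ = [
    "standard_grid",
    "analytic_numeric_agreement",
    "noiseless_recovery",
    "noisy_recovery",
    "effect_size_sign_switch",
    "sign_zone_reproduction",
    "permutation_fpr",
    "parameter_scan_power",
    "anova_bh_agreement",
    "mating_rescue",
]


def standard_grid() -> list[EggLayingParams]:
    """The 100-point physiological grid: k_o in [1,10], k_f in [1e-4,1e-3]
    (log-spaced), S_0 in [100,500]."""
    return [
        EggLayingParams(k_o=ko, k_f=kf, s_0=s0)
        for ko in np.linspace(1.0, 10.0, 5)
        for kf in np.geomspace(1e-4, 1e-3, 5)
        for s0 in np.linspace(100.0, 500.0, 4)
    ]


def analytic_numeric_agreement(n_times: int = 25) -> dict:
    """Closed form vs adaptive Runge-Kutta over the grid and t in [0,120] h.

    Returns the maximum relative discrepancy of (S, O, E) where sperm remain
    above 1e-9 S_0 (relative with an absolute floor of one cell/egg), and the
    worst conservation violation as a multiple of the integration tolerance.
    """
    times = np.linspace(0.0, 120.0, n_times)[1:]
    worst = 0.0
    worst_cons = 0.0
    grid = standard_grid()
    for p in grid:
        a = analytic_trajectory(p, times)
        n = simulate_numeric(p, times)
        mask = n.S > 1e-9 * p.s_0
        for x, y in ((a.S, n.S), (a.O, n.O), (a.E, n.E)):
            rel = np.abs(x - y) / np.maximum(np.abs(y), 1.0)
            if mask.any():
                worst = max(worst, float(rel[mask].max()))
        tol = 10.0 * (DEFAULT_RTOL * p.s_0 + DEFAULT_ATOL)
        for traj in (a, n):
            c1 = np.abs(traj.E + traj.S - p.s_0).max()
            c2 = np.abs(traj.O + traj.E - p.k_o * traj.times).max()
            worst_cons = max(worst_cons, float(max(c1, c2) / tol))
    return {
        "max_rel_discrepancy": worst,
        "max_conservation_violation_vs_budget": worst_cons,
        "n_parameter_sets": len(grid),
    }


def _noiseless_phenotype(p: EggLayingParams, n_animals: int = 6) -> StrainPhenotype:
    return StrainPhenotype(
        "s",
        [
            AssayObservation(a, b, n_animals, n_animals * window_eggs(p, a, b))
            for a, b in DEFAULT_WINDOWS
        ],
    )


def noiseless_recovery() -> dict:
    """Exact-recovery identity: fit model-generated five-window data for
    every grid parameter set; report the worst relative error."""
    worst = 0.0
    grid = standard_grid()
    for p in grid:
        r = fit_strain(_noiseless_phenotype(p), k_f=p.k_f)
        worst = max(
            worst,
            abs(r.k_o - p.k_o) / p.k_o,
            abs(r.s_0 - p.s_0) / p.s_0,
        )
    return {"max_rel_error": float(worst), "n_parameter_sets": len(grid)}


def noisy_recovery(seed: int, n_strains: int = 100, n_replicates: int = 10) -> dict:
    """Median absolute relative error of (k_o, S_0) under the assay design:
    six animals, five 6-h windows, Poisson counts, 10 replicates."""
    p = EggLayingParams(k_o=5.0, k_f=2.6e-4, s_0=263.0)
    rng = np.random.default_rng(seed)
    errs_ko, errs_s0 = [], []
    for _ in range(n_strains):
        obs = [
            AssayObservation(a, b, 6, int(rng.poisson(6 * window_eggs(p, a, b))))
            for a, b in DEFAULT_WINDOWS
            for _ in range(n_replicates)
        ]
        r = fit_strain(StrainPhenotype("s", obs))
        errs_ko.append(abs(r.k_o - p.k_o) / p.k_o)
        errs_s0.append(abs(r.s_0 - p.s_0) / p.s_0)
    return {
        "median_rel_error_ko": float(np.median(errs_ko)),
        "median_rel_error_s0": float(np.median(errs_s0)),
        "n_strains": n_strains,
    }


def effect_size_sign_switch() -> dict:
    """Pairs differing only in k_o: the effect-size curve crosses zero
    exactly once, positive before (for the larger k_o) and negative after."""
    pairs = [
        (7.0, 5.0, 2.6e-4, 263.0),
        (10.0, 9.0, 1e-4, 400.0),
        (2.0, 1.0, 1e-3, 150.0),
        (6.0, 3.0, 5e-4, 300.0),
    ]
    n_ok = 0
    crossing_ref = np.nan
    for ko_a, ko_b, kf, s0 in pairs:
        a = EggLayingParams(k_o=ko_a, k_f=kf, s_0=s0)
        b = EggLayingParams(k_o=ko_b, k_f=kf, s_0=s0)
        crossings = effect_size_crossings(a, b)
        if len(crossings) != 1:
            continue
        t_x = crossings[0]
        early = effect_size(a, b, [0.5 * t_x])[0]
        late = effect_size(a, b, [1.5 * t_x])[0]
        if early > 0 > late:
            n_ok += 1
        if (ko_a, ko_b) == (7.0, 5.0):
            crossing_ref = t_x
    return {
        "n_pairs": len(pairs),
        "n_single_crossing_correct_signs": n_ok,
        "crossing_time_ko7_vs_ko5_h": float(crossing_ref),
    }


def sign_zone_reproduction(baselines=(6.0, 8.0, 10.0, 12.0)) -> dict:
    """Sign-epistasis zone with the study's effect sizes (focal +5.2,
    modifier -1.0 on k_o): nonempty for every baseline, contrasts of
    opposite sign strictly inside and the same sign outside."""
    n_ok = 0
    widths = []
    for base in baselines:
        z = sign_epistasis_zone(base, 5.2, -1.0, 263.0, 2.6e-4)
        if z.empty:
            continue
        pm = z.class_params

        def contrasts(t):
            d0 = egg_rate(pm["mod"], t) - egg_rate(pm["base"], t)
            d1 = egg_rate(pm["focal+mod"], t) - egg_rate(pm["focal"], t)
            return d0, d1

        ins = contrasts(z.midpoint())
        before = contrasts(0.5 * z.t_open)
        after = contrasts(z.t_close + 0.5 * z.width)
        if (
            np.sign(ins[0]) != np.sign(ins[1])
            and np.sign(before[0]) == np.sign(before[1])
            and np.sign(after[0]) == np.sign(after[1])
        ):
            n_ok += 1
            widths.append(z.width)
    return {
        "n_baselines": len(baselines),
        "n_zones_valid": n_ok,
        "zone_width_h_at_baseline_6": float(widths[0]) if widths else np.nan,
    }


def permutation_fpr(
    seed: int, n_panels: int = 200, n_perm: int = 200, alpha: float = 0.05
) -> dict:
    """Genome-wide false-positive rate of the permutation threshold on null
    panels (94 strains x 192 markers, phenotype pure noise).

    Permutation count reduced from the study's 1000 to `n_perm` per panel to
    keep the replicate count at 200 panels on one CPU.
    """
    gmap = GeneticMap.uniform()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_panels):
        panel = generate_ril_genotypes(94, gmap, seed=rng)
        y = rng.normal(size=94)
        thr = permutation_threshold(
            panel, y, n_perm=n_perm, alpha=alpha, seed=int(rng.integers(2**31))
        )
        scan = marker_regression_scan(panel, y)
        hits += int(scan.frame["lod_single"].max() >= thr.threshold)
    return {"false_positive_rate": hits / n_panels, "n_panels": n_panels}


def _detect(panel, values, n_perm, seed):
    scan = marker_regression_scan(panel, values)
    thr = permutation_threshold(panel, values, n_perm=n_perm, alpha=0.05, seed=seed)
    peak = scan.peak("lod_single")
    return bool(scan.frame["lod_single"].max() >= thr.threshold), str(peak["chrom"])


def parameter_scan_power(
    seed: int, n_seeds: int = 50, n_perm: int = 200
) -> dict:
    """Fig 6-style parameter-resolved mapping on planted single-QTL panels.

    A k_o-only QTL (effect +1.0 on baseline 6.0) must light up the k_o scan
    and leave the S_0 scan at its false-positive rate, and conversely for an
    S_0-only QTL (effect +40 on 263). Panels: 94 strains, one replicate per
    window, Poisson noise, per-strain fits with shared fixed k_f.
    """
    base = EggLayingParams(k_o=6.0, k_f=2.6e-4, s_0=263.0)
    ko_qtl = QTLSpec(marker="cII_m16", parameter="k_o", effect=1.0)
    s0_qtl = QTLSpec(marker="cV_m16", parameter="s_0", effect=40.0)
    counts = {
        "ko_detected": 0,
        "ko_peak_on_II": 0,
        "s0_leak": 0,
        "s0_detected": 0,
        "s0_peak_on_V": 0,
        "ko_leak": 0,
    }
    for i in range(n_seeds):
        for qtl, tags in ((ko_qtl, ("ko", "s0_leak", "II", "k_o", "s_0")),
                          (s0_qtl, ("s0", "ko_leak", "V", "s_0", "k_o"))):
            name, leak_key, chrom, target, other = tags
            cfg = PanelConfig(baseline=base, qtls=(qtl,))
            ds = generate_study_like_dataset(cfg, seed=seed + 7919 * i + (0 if name == "ko" else 1))
            fit = fit_panel(phenotypes_to_strains(ds.panel.phenotypes))
            frame = fit.to_frame()
            sig_t, chrom_t = _detect(
                ds.panel, frame[target], n_perm, seed + 2 * i
            )
            sig_o, _ = _detect(ds.panel, frame[other], n_perm, seed + 2 * i + 1)
            counts[f"{name}_detected"] += int(sig_t)
            counts[f"{name}_peak_on_{chrom}"] += int(sig_t and chrom_t == chrom)
            counts[leak_key] += int(sig_o)
    return {
        "power_ko_scan": counts["ko_peak_on_II"] / n_seeds,
        "false_positive_rate_s0_scan": counts["s0_leak"] / n_seeds,
        "power_s0_scan": counts["s0_peak_on_V"] / n_seeds,
        "false_positive_rate_ko_scan": counts["ko_leak"] / n_seeds,
        "n_seeds": n_seeds,
    }


def anova_bh_agreement(seed: int, n_fixtures: int = 25, n_bh: int = 300) -> dict:
    """Drop-one F against brute-force nested regression on random 12-strain
    fixtures, and BH rejections against literal enumeration of the step-up
    rule on random p-vectors of length <= 12."""
    rng = np.random.default_rng(seed)
    gmap = GeneticMap.uniform(n_chromosomes=2, markers_per_chromosome=3, spacing_cm=10.0)
    markers = gmap.markers[:3]
    worst_f = 0.0
    for _ in range(n_fixtures):
        panel = generate_ril_genotypes(12, gmap, seed=rng)
        # regenerate until the three tested loci are polymorphic and the
        # design has full rank
        g = panel.genotypes[markers].to_numpy(float)
        if (g.std(axis=0) == 0).any():
            continue
        y = rng.normal(size=12)
        try:
            tab = drop_one_anova(
                panel,
                pd.DataFrame({"t": y}, index=panel.strains),
                markers,
                focal_marker=markers[0],
            )
        except ValueError:
            continue
        one = np.ones(12)
        gf = g[:, 0]
        X = np.column_stack([one, g, g[:, 1] * gf, g[:, 2] * gf])

        def rss(Xm):
            beta = la.lstsq(Xm, y, rcond=None)[0]
            return float(np.sum((y - Xm @ beta) ** 2))

        rss_full = rss(X)
        dof = 12 - X.shape[1]
        for idx, m in enumerate(markers):
            if m == markers[0]:
                drop = [1, 4, 5]
            else:
                drop = [1 + idx, 3 + idx]
            Xd = np.delete(X, drop, axis=1)
            F = ((rss(Xd) - rss_full) / len(drop)) / (rss_full / dof)
            got = float(tab[tab["qtl"] == m]["f_drop"].iloc[0])
            worst_f = max(worst_f, abs(got - F) / max(abs(F), 1e-300))

    mismatches = 0
    for _ in range(n_bh):
        m = int(rng.integers(1, 13))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        reject, _ = benjamini_hochberg(p, alpha=0.05)
        order = np.argsort(p, kind="stable")
        kmax = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= 0.05 * k / m:
                kmax = k
        expect = np.zeros(m, dtype=bool)
        expect[order[:kmax]] = True
        mismatches += int(not np.array_equal(reject, expect))
    return {
        "max_rel_f_discrepancy": worst_f,
        "n_fixtures": n_fixtures,
        "bh_mismatches": mismatches,
        "n_bh_vectors": n_bh,
    }


def mating_rescue() -> dict:
    """Sperm top-up prediction: +1000 sperm at 24 h strictly raises the egg
    rate at 48 h and every later window start, for all grid parameter sets."""
    times = np.array([48.0, 60.0, 66.0, 84.0, 90.0])
    grid = standard_grid()
    n_ok = 0
    min_margin = np.inf
    for p in grid:
        m = simulate_with_mating(p, 24.0, 1000.0, times)
        u = simulate_numeric(p, times)
        rate_m = p.k_f * m.O * m.S
        rate_u = p.k_f * u.O * u.S
        margin = float((rate_m - rate_u).min())
        min_margin = min(min_margin, margin)
        n_ok += int(np.all(rate_m > rate_u))
    return {
        "n_parameter_sets": len(grid),
        "n_strictly_rescued": n_ok,
        "min_rate_gain": min_margin,
    }
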