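"""Synthetic biparental recombinant-inbred-line (RIL) panels.

Emulates a 94-strain RIL panel from a two-parent cross (N2-like "A" x
LSJ2-like "B") genotyped at 192 markers over the six *C. elegans*
chromosomes, with quantitative trait loci acting additively on the
egg-laying model parameters k_o and/or S_0, and egg-count assays observed
with Poisson counting noise. Every downstream stage (fitting, QTL scans,
epistasis ANOVA) is exercised against these panels, for which the planted
truth is known.

Genotypes are drawn from the closed-form RIL-by-selfing process: along a
chromosome the inbred genotype is a two-state Markov chain whose switch
probability between adjacent markers is R = 2r / (1 + 2r), where r is the
per-meiosis Haldane recombination fraction r = (1 - exp(-2d)) / 2 for map
distance d Morgans. A brute-force multi-generation selfing simulator is
included as an independent check of that closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import EggLayingParams, _soe
from .fitting import DEFAULT_KF

__all__ = [
    "GeneticMap",
    "RILPanel",
    "QTLSpec",
    "PanelConfig",
    "StudyDataset",
    "ConfigurationError",
    "DEFAULT_WINDOWS",
    "DEFAULT_BASELINE",
    "DEFAULT_QTLS",
    "CHROMOSOME_NAMES",
    "haldane_r",
    "ril_switch_probability",
    "generate_ril_genotypes",
    "simulate_ril_by_selfing",
    "plant_qtl_effects",
    "simulate_assays",
    "generate_study_like_dataset",
]

CHROMOSOME_NAMES = ("I", "II", "III", "IV", "V", "X")

#: five ~6-hour assay windows spanning the reproductive lifespan (hours post-L4)
DEFAULT_WINDOWS = ((18.0, 24.0), (30.0, 36.0), (42.0, 48.0), (60.0, 66.0), (84.0, 90.0))

#: all-A (N2-like) genotype class; B alleles add the QTL effects below
DEFAULT_BASELINE = EggLayingParams(k_o=11.2, k_f=DEFAULT_KF, s_0=263.0)


class ConfigurationError(ValueError):
    """A planted QTL architecture is inconsistent with the panel or model."""


def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_switch_probability(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Probability that a selfed RIL changes parental phase between two
    markers d_cm apart: R = 2r / (1 + 2r) with Haldane r."""
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with chromosome assignment and cM position."""

    table: pd.DataFrame  # columns: marker, chrom, cM

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if len(t) == 0:
            raise ValueError("empty genetic map")
        if t["marker"].duplicated().any():
            raise ValueError("duplicate marker names")
        for _, grp in t.groupby("chrom", sort=False):
            if np.any(np.diff(grp["cM"].to_numpy()) < 0):
                raise ValueError("cM positions must be non-decreasing per chromosome")

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 6,
        markers_per_chromosome: int = 32,
        spacing_cm: float = 5.0,
    ) -> "GeneticMap":
        """Evenly spaced markers; default 6 x 32 = 192 markers at 5 cM."""
        rows = []
        for c in range(n_chromosomes):
            name = (
                CHROMOSOME_NAMES[c]
                if c < len(CHROMOSOME_NAMES)
                else f"chr{c + 1}"
            )
            for i in range(markers_per_chromosome):
                rows.append(
                    {
                        "marker": f"c{name}_m{i:02d}",
                        "chrom": name,
                        "cM": i * spacing_cm,
                    }
                )
        return cls(pd.DataFrame(rows))

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def require(self, marker: str) -> None:
        if marker not in set(self.table["marker"]):
            raise KeyError(f"marker {marker!r} not in genetic map")


@dataclass
class RILPanel:
    """Genotype matrix (strains x markers, 0 = A allele, 1 = B allele),
    genetic map, and optionally phenotypes and the simulated truth table."""

    genotypes: pd.DataFrame
    gmap: GeneticMap
    phenotypes: pd.DataFrame | None = None
    true_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = self.genotypes
        if list(g.columns) != self.gmap.markers:
            raise ValueError("genotype columns must match the map's marker order")
        vals = g.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                "genotypes must be coded 0 (A) / 1 (B): fully inbred lines, "
                "no heterozygotes"
            )

    @property
    def strains(self) -> list[str]:
        return self.genotypes.index.tolist()

    @property
    def n_strains(self) -> int:
        return len(self.genotypes)


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: additive allelic effect (B minus A) on a model parameter,
    with an optional product-interaction partner."""

    marker: str
    parameter: str  # "k_o" or "s_0"
    effect: float
    partner: str | None = None
    interaction_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter not in ("k_o", "s_0"):
            raise ValueError("QTL parameter must be 'k_o' or 's_0'")
        if not np.isfinite(self.effect) or not np.isfinite(self.interaction_effect):
            raise ValueError("QTL effects must be finite")


#: default architecture: a large-effect focal locus (nurf-1-like) lowering the
#: oocyte rate, a small k_o modifier, and a sperm-count locus on V
DEFAULT_QTLS = (
    QTLSpec(marker="cII_m16", parameter="k_o", effect=-5.2),
    QTLSpec(marker="cX_m16", parameter="k_o", effect=-1.0),
    QTLSpec(marker="cV_m28", parameter="s_0", effect=40.0),
)


def generate_ril_genotypes(
    n_strains: int,
    gmap: GeneticMap | None = None,
    seed: int | np.random.Generator = 0,
) -> RILPanel:
    """Draw inbred-line genotypes from the closed-form RIL-by-selfing chain."""
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    gmap = gmap or GeneticMap.uniform()
    rng = np.random.default_rng(seed)
    cols: list[np.ndarray] = []
    for _, grp in gmap.table.groupby("chrom", sort=False):
        pos = grp["cM"].to_numpy()
        g = rng.integers(0, 2, size=n_strains)
        cols.append(g.copy())
        for d in np.diff(pos):
            flip = rng.random(n_strains) < ril_switch_probability(d)
            g = np.where(flip, 1 - g, g)
            cols.append(g.copy())
    geno = pd.DataFrame(
        np.column_stack(cols).astype(np.int8),
        index=[f"RIL{i + 1:03d}" for i in range(n_strains)],
        columns=gmap.markers,
    )
    return RILPanel(genotypes=geno, gmap=gmap)


def simulate_ril_by_selfing(
    n_strains: int,
    gmap: GeneticMap | None = None,
    seed: int | np.random.Generator = 0,
    max_generations: int = 200,
) -> RILPanel:
    """Brute-force RIL construction: F1 heterozygote selfed until every locus
    is homozygous, with per-meiosis crossovers at Haldane frequencies.

    Slower than :func:`generate_ril_genotypes`; kept as the mechanistic
    reference the closed-form chain is validated against.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    gmap = gmap or GeneticMap.uniform()
    rng = np.random.default_rng(seed)

    chrom_blocks: list[np.ndarray] = []
    for _, grp in gmap.table.groupby("chrom", sort=False):
        m = len(grp)
        r = haldane_r(np.diff(grp["cM"].to_numpy()))
        # maternal/paternal haplotypes per line, F1: one A gamete, one B gamete
        mat = np.zeros((n_strains, m), dtype=np.int8)
        pat = np.ones((n_strains, m), dtype=np.int8)

        def gamete(mat, pat, active):
            n = active.sum()
            strand = rng.integers(0, 2, size=n)
            out = np.empty((n, m), dtype=np.int8)
            hap = np.where(strand[:, None] == 0, mat[active], pat[active])
            other = np.where(strand[:, None] == 0, pat[active], mat[active])
            cross = rng.random((n, max(m - 1, 0))) < r
            phase = np.zeros(n, dtype=bool)
            out[:, 0] = hap[:, 0]
            for j in range(1, m):
                phase ^= cross[:, j - 1]
                out[:, j] = np.where(phase, other[:, j], hap[:, j])
            return out

        active = np.ones(n_strains, dtype=bool)
        for _ in range(max_generations):
            active = (mat != pat).any(axis=1)
            if not active.any():
                break
            g1 = gamete(mat, pat, active)
            g2 = gamete(mat, pat, active)
            mat[active] = g1
            pat[active] = g2
        else:
            raise RuntimeError("selfing did not reach fixation; raise max_generations")
        chrom_blocks.append(mat)

    geno = pd.DataFrame(
        np.concatenate(chrom_blocks, axis=1),
        index=[f"RIL{i + 1:03d}" for i in range(n_strains)],
        columns=gmap.markers,
    )
    return RILPanel(genotypes=geno, gmap=gmap)


def plant_qtl_effects(
    panel: RILPanel,
    baseline: EggLayingParams,
    qtls: Sequence[QTLSpec],
) -> pd.DataFrame:
    """Per-strain parameter table: baseline plus the additive (and optional
    product-interaction) allelic effects implied by each strain's genotype.

    Raises ConfigurationError if any strain's k_o or S_0 is driven <= 0.
    """
    k_o = np.full(panel.n_strains, baseline.k_o)
    s_0 = np.full(panel.n_strains, baseline.s_0)
    target = {"k_o": k_o, "s_0": s_0}
    for q in qtls:
        panel.gmap.require(q.marker)
        g = panel.genotypes[q.marker].to_numpy().astype(float)
        contrib = q.effect * g
        if q.partner is not None:
            panel.gmap.require(q.partner)
            contrib = contrib + (
                q.interaction_effect
                * g
                * panel.genotypes[q.partner].to_numpy().astype(float)
            )
        target[q.parameter] += contrib
    bad = np.nonzero((k_o <= 0) | (s_0 <= 0))[0]
    if bad.size:
        names = [panel.strains[i] for i in bad]
        raise ConfigurationError(
            f"planted QTL effects drive parameters non-positive for strains {names}"
        )
    return pd.DataFrame(
        {"k_o": k_o, "k_f": baseline.k_f, "s_0": s_0},
        index=pd.Index(panel.strains, name="strain"),
    )


def simulate_assays(
    param_table: pd.DataFrame,
    windows: Sequence[tuple[float, float]] = DEFAULT_WINDOWS,
    n_animals: int = 6,
    n_replicates: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Poisson egg-count assays for every strain/window/replicate.

    eggs ~ Poisson(n_animals * (E(end) - E(start))) per replicate, the small-
    integer counting noise appropriate for six animals observed for six hours.
    """
    win = np.asarray(windows, dtype=float)
    if win.ndim != 2 or win.shape[1] != 2 or np.any(win[:, 1] <= win[:, 0]):
        raise ValueError("windows must be (start, end) pairs with end > start")
    if n_animals < 1 or n_replicates < 1:
        raise ValueError("n_animals and n_replicates must be >= 1")
    starts, ends = win[:, 0], win[:, 1]
    order = np.argsort(starts)
    if np.any(ends[order][:-1] > starts[order][1:]):
        warnings.warn("assay windows overlap", stacklevel=2)

    rng = np.random.default_rng(seed)
    ts = np.unique(win)
    rows = []
    for strain, row in param_table.iterrows():
        p = EggLayingParams(k_o=row["k_o"], k_f=row["k_f"], s_0=row["s_0"])
        _, _, E = _soe(p, ts)
        e_at = dict(zip(ts, E))
        for (t0, t1) in win:
            lam = n_animals * max(e_at[t1] - e_at[t0], 0.0)
            draws = rng.poisson(lam, size=n_replicates)
            for rep, eggs in enumerate(draws):
                rows.append(
                    {
                        "strain": strain,
                        "window_start": t0,
                        "window_end": t1,
                        "n_animals": n_animals,
                        "eggs": int(eggs),
                        "replicate_id": f"r{rep + 1}",
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PanelConfig:
    """Study-scale defaults: 94 RILs, 192 markers on 6 chromosomes, five
    6-hour windows of 6 animals each, one replicate per window."""

    n_strains: int = 94
    n_chromosomes: int = 6
    markers_per_chromosome: int = 32
    spacing_cm: float = 5.0
    baseline: EggLayingParams = DEFAULT_BASELINE
    qtls: tuple[QTLSpec, ...] = DEFAULT_QTLS
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    n_animals: int = 6
    n_replicates: int = 1

    def make_map(self) -> GeneticMap:
        return GeneticMap.uniform(
            self.n_chromosomes, self.markers_per_chromosome, self.spacing_cm
        )


@dataclass
class StudyDataset:
    """A complete simulated study: panel with phenotypes plus planted truth."""

    panel: RILPanel
    config: PanelConfig
    seed: int
    truth: dict = field(default_factory=dict)


def generate_study_like_dataset(
    config: PanelConfig | None = None, seed: int = 0
) -> StudyDataset:
    """One call producing genotypes, true parameters, Poisson phenotypes and a
    manifest of the planted truths; genotype and assay noise use independent
    substreams derived from `seed`."""
    config = config or PanelConfig()
    gmap = config.make_map()
    ss = np.random.SeedSequence(seed)
    geno_rng, assay_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    panel = generate_ril_genotypes(config.n_strains, gmap, seed=geno_rng)
    params = plant_qtl_effects(panel, config.baseline, config.qtls)
    phen = simulate_assays(
        params,
        windows=config.windows,
        n_animals=config.n_animals,
        n_replicates=config.n_replicates,
        seed=assay_rng,
    )
    panel.phenotypes = phen
    panel.true_params = params
    truth = {
        "seed": seed,
        "baseline": {
            "k_o": config.baseline.k_o,
            "k_f": config.baseline.k_f,
            "s_0": config.baseline.s_0,
        },
        "qtls": [
            {
                "marker": q.marker,
                "parameter": q.parameter,
                "effect": q.effect,
                "partner": q.partner,
                "interaction_effect": q.interaction_effect,
            }
            for q in config.qtls
        ],
        "windows": [list(w) for w in config.windows],
        "n_animals": config.n_animals,
        "n_replicates": config.n_replicates,
    }
    return StudyDataset(panel=panel, config=config, seed=seed, truth=truth)
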