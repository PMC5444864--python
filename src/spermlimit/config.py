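"""Run configuration for the simulate -> fit -> scan -> epistasis pipeline.

A single YAML file (plus an optional seed override) drives every stage;
each stochastic stage draws its generator from an independent substream of
the top-level seed, so a run is reproducible end to end and stages can be
re-run in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fitting import DEFAULT_KF
from .model import EggLayingParams
from .panel import (
    DEFAULT_BASELINE,
    DEFAULT_QTLS,
    DEFAULT_WINDOWS,
    PanelConfig,
    QTLSpec,
)

__all__ = ["RunConfig", "ScanConfig", "FitConfig", "stage_rng"]

_STAGES = {"genotypes": 0, "assays": 1, "permutations": 2, "extra": 3}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


def stage_seed(seed: int, stage: str) -> int:
    """31-bit integer seed derived for a named stage (for APIs taking ints)."""
    ss = np.random.SeedSequence([int(seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FitConfig:
    k_f: float = DEFAULT_KF
    share_kf: bool = False
    n_starts: int = 5


@dataclass
class ScanConfig:
    covariate_marker: str | None = "cII_m16"
    n_perm: int = 1000
    alpha: float = 0.05
    stratified: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    panel: PanelConfig = field(default_factory=PanelConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "panel": {
                "n_strains": self.panel.n_strains,
                "n_chromosomes": self.panel.n_chromosomes,
                "markers_per_chromosome": self.panel.markers_per_chromosome,
                "spacing_cm": self.panel.spacing_cm,
                "baseline": {
                    "k_o": self.panel.baseline.k_o,
                    "k_f": self.panel.baseline.k_f,
                    "s_0": self.panel.baseline.s_0,
                },
                "qtls": [
                    {
                        "marker": q.marker,
                        "parameter": q.parameter,
                        "effect": q.effect,
                        "partner": q.partner,
                        "interaction_effect": q.interaction_effect,
                    }
                    for q in self.panel.qtls
                ],
                "windows": [list(w) for w in self.panel.windows],
                "n_animals": self.panel.n_animals,
                "n_replicates": self.panel.n_replicates,
            },
            "fit": asdict(self.fit),
            "scan": asdict(self.scan),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        p = d.get("panel", {})
        b = p.get("baseline", {})
        baseline = EggLayingParams(
            k_o=float(b.get("k_o", DEFAULT_BASELINE.k_o)),
            k_f=float(b.get("k_f", DEFAULT_BASELINE.k_f)),
            s_0=float(b.get("s_0", DEFAULT_BASELINE.s_0)),
        )
        qtls = tuple(
            QTLSpec(
                marker=q["marker"],
                parameter=q["parameter"],
                effect=float(q["effect"]),
                partner=q.get("partner"),
                interaction_effect=float(q.get("interaction_effect", 0.0)),
            )
            for q in p.get("qtls", [asdict_q(q) for q in DEFAULT_QTLS])
        )
        panel = PanelConfig(
            n_strains=int(p.get("n_strains", 94)),
            n_chromosomes=int(p.get("n_chromosomes", 6)),
            markers_per_chromosome=int(p.get("markers_per_chromosome", 32)),
            spacing_cm=float(p.get("spacing_cm", 5.0)),
            baseline=baseline,
            qtls=qtls,
            windows=tuple(
                tuple(map(float, w)) for w in p.get("windows", DEFAULT_WINDOWS)
            ),
            n_animals=int(p.get("n_animals", 6)),
            n_replicates=int(p.get("n_replicates", 1)),
        )
        f = d.get("fit", {})
        s = d.get("scan", {})
        return cls(
            seed=int(d.get("seed", 0)),
            out_dir=str(d.get("out_dir", "results/run")),
            panel=panel,
            fit=FitConfig(
                k_f=float(f.get("k_f", DEFAULT_KF)),
                share_kf=bool(f.get("share_kf", False)),
                n_starts=int(f.get("n_starts", 5)),
            ),
            scan=ScanConfig(
                covariate_marker=s.get("covariate_marker", "cII_m16"),
                n_perm=int(s.get("n_perm", 1000)),
                alpha=float(s.get("alpha", 0.05)),
                stratified=bool(s.get("stratified", True)),
            ),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def asdict_q(q: QTLSpec) -> dict:
    return {
        "marker": q.marker,
        "parameter": q.parameter,
        "effect": q.effect,
        "partner": q.partner,
        "interaction_effect": q.interaction_effect,
    }
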