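"""CSV / JSON serialization for every pipeline stage.

All tabular interchange is plain RFC-4180 CSV with a header row; genotypes
are written with the parental allele codes A (N2-like) / B (LSJ2-like) and
read back to the 0/1 coding used for regression. Each stage can record its
outputs in a manifest (file, rows, sha256) for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .fitting import AssayObservation, StrainPhenotype
from .panel import GeneticMap, RILPanel

__all__ = [
    "write_map_csv",
    "read_map_csv",
    "write_genotypes_csv",
    "read_genotypes_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "phenotypes_to_strains",
    "write_params_csv",
    "read_params_csv",
    "write_json",
    "read_json",
    "file_digest",
    "manifest_entry",
]

_ALLELES = {0: "A", 1: "B"}
_CODES = {"A": 0, "B": 1}


def write_map_csv(gmap: GeneticMap, path) -> None:
    gmap.table[["marker", "chrom", "cM"]].to_csv(path, index=False)


def read_map_csv(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path))


def write_genotypes_csv(panel: RILPanel, path) -> None:
    g = panel.genotypes.apply(lambda col: col.map(_ALLELES))
    g.index.name = "strain"
    g.to_csv(path)


def read_genotypes_csv(path, gmap: GeneticMap) -> RILPanel:
    g = pd.read_csv(path, index_col="strain")
    bad = set(g.to_numpy().ravel()) - set(_CODES)
    if bad:
        raise ValueError(f"genotype file contains non-A/B codes: {sorted(bad)}")
    g = g.apply(lambda col: col.map(_CODES)).astype("int8")
    return RILPanel(genotypes=g[gmap.markers], gmap=gmap)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    cols = ["strain", "window_start", "window_end", "n_animals", "eggs", "replicate_id"]
    phenotypes[cols].to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed phenotype CSV {path}: {exc}") from exc
    required = {"strain", "window_start", "window_end", "n_animals", "eggs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV missing columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"phenotype CSV {path} is empty")
    if "replicate_id" not in df.columns:
        df["replicate_id"] = ""
    return df


def phenotypes_to_strains(df: pd.DataFrame) -> list[StrainPhenotype]:
    out = []
    for strain, grp in df.groupby("strain", sort=False):
        obs = [
            AssayObservation(
                window_start=float(r.window_start),
                window_end=float(r.window_end),
                n_animals=int(r.n_animals),
                eggs=float(r.eggs),
                replicate_id=str(r.replicate_id),
            )
            for r in grp.itertuples()
        ]
        out.append(StrainPhenotype(strain=str(strain), observations=obs))
    return out


def write_params_csv(panel_fit, path) -> None:
    frame = panel_fit.to_frame() if hasattr(panel_fit, "to_frame") else panel_fit
    frame.to_csv(path)


def read_params_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="strain")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def manifest_entry(path) -> dict:
    p = Path(path)
    text = p.read_text()
    rows = max(text.count("\n") - 1, 0) if p.suffix == ".csv" else None
    return {"file": p.name, "rows": rows, "sha256": file_digest(p)}
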