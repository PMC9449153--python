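"""Plain-text readers and writers for pipeline artifacts.

Formats (all uncompressed text):

* pedigree CSV: id,sire,dam[,sex,generation] with 0 = unknown parent;
* genotype TSV: first column ``animal``, then one dosage column per marker
  (header row of marker names), with a sidecar marker table
  marker/chromosome/position;
* phenotype CSV: long format, one row per hen x age x trait;
* symmetric matrices in coordinate format (i, j, value) for inspection;
* a JSON run manifest (config, seed, package version, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .relationships import GenotypeMatrix, Pedigree

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_matrix_coo",
    "write_manifest",
]

PHENO_COLUMNS = ["hen", "tom", "age_weeks", "hatch_week", "egg_hatch_week", "trait", "value"]


def write_pedigree(ped: Pedigree, path) -> None:
    def id_or_zero(pos: np.ndarray) -> np.ndarray:
        out = np.zeros(ped.n, dtype=np.int64)
        known = pos >= 0
        out[known] = ped.ids[pos[known]]
        return out

    df = pd.DataFrame(
        {"id": ped.ids, "sire": id_or_zero(ped.sire), "dam": id_or_zero(ped.dam)}
    )
    if ped.sex is not None:
        df["sex"] = ped.sex
    if ped.generation is not None:
        df["generation"] = ped.generation
    df.to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path))


def write_genotypes(geno: GenotypeMatrix, path, marker_path) -> None:
    df = pd.DataFrame(
        geno.dosages, columns=geno.marker_meta["marker"], index=geno.animal_ids
    )
    df.index.name = "animal"
    df.to_csv(path, sep="\t")
    geno.marker_meta.to_csv(marker_path, sep="\t", index=False)


def read_genotypes(path, marker_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="animal")
    meta = pd.read_csv(marker_path, sep="\t", dtype={"chromosome": str})
    if list(df.columns) != list(meta["marker"]):
        raise ValueError("marker table does not match genotype columns")
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=np.int8),
        animal_ids=df.index.to_numpy(dtype=np.int64),
        marker_meta=meta,
    )


def write_phenotypes(data: pd.DataFrame, path) -> None:
    data[PHENO_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    return df


def write_matrix_coo(mat, path, ids=None) -> None:
    """Symmetric matrix (sparse or dense) as 'i j value' rows (upper triangle)."""
    coo = sparse.coo_matrix(mat)
    keep = coo.row <= coo.col
    rows, cols, vals = coo.row[keep], coo.col[keep], coo.data[keep]
    if ids is not None:
        ids = np.asarray(ids)
        rows, cols = ids[rows], ids[cols]
    pd.DataFrame({"i": rows, "j": cols, "value": vals}).to_csv(path, sep="\t", index=False)


def write_manifest(config: dict, path, seed: int | None = None) -> dict:
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
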