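"""Readers and writers for the plain-text formats the tool consumes.

Pedigrees and phenotypes are CSV, genotypes are TSV (or the PLINK ``.raw``
dialect), matrices are TSV with id row/column labels, nested reports are
JSON.  ``"0"`` denotes an unknown parent and ``NA`` a missing dosage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix, Pedigree, RelationshipMatrix
from .mixed_model import EvaluationResult, VarianceComponents

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_matrix",
    "write_matrix",
    "write_evaluation",
    "read_ebv_pairs",
    "RunConfig",
]

PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: malformed header, missing column(s) {missing}; found {list(df.columns)}"
        )


def read_pedigree(path: str | Path) -> tuple[Pedigree, pd.DataFrame]:
    """Pedigree CSV with header ``id,sire,dam`` ('0' = unknown parent)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["id", "sire", "dam"], path)
    ped = Pedigree.from_records(df[["id", "sire", "dam"]].itertuples(index=False))
    return ped, df


def write_pedigree(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype CSV: ``id,y`` plus factor/covariate columns."""
    df = pd.read_csv(path)
    _require_columns(df, ["id", "y"], path)
    df["id"] = df["id"].astype(str)
    return df


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV (id + locus columns, 'NA' missing) or PLINK .raw dialect.

    A ``.raw`` file is recognized by its ``FID IID ...`` header; only IID
    and the SNP dosage columns are used.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
    if header[:2] == ["FID", "IID"]:
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        loci = [c for c in df.columns if c not in PLINK_RAW_META]
        ids = df["IID"].astype(str).tolist()
        dosages = df[loci].to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        if df.columns[0] != "id":
            raise ValueError(
                f"{path}: malformed genotype header; expected first column 'id' "
                f"or a PLINK .raw 'FID IID ...' header, found {df.columns[0]!r}"
            )
        loci = list(df.columns[1:])
        ids = df["id"].astype(str).tolist()
        dosages = df[loci].to_numpy(dtype=float)
    return GenotypeMatrix(ids, loci, dosages)


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.locus_ids)
    df.insert(0, "id", genotypes.ids)
    with np.errstate(invalid="ignore"):
        df[genotypes.locus_ids] = df[genotypes.locus_ids].astype("Int64").astype(object)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_matrix(K: RelationshipMatrix, path: str | Path) -> None:
    """Matrix TSV with id row/column labels."""
    pd.DataFrame(K.matrix, index=K.ids, columns=K.ids).to_csv(
        path, sep="\t", index_label="id"
    )


def read_matrix(path: str | Path, source: str = "pedigree") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelationshipMatrix(df.index.astype(str).tolist(), df.to_numpy(), source)


def write_evaluation(result: EvaluationResult, outdir: str | Path) -> None:
    """Serialize solutions, PEV/PEC blocks and metadata to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pev = np.diag(result.C_uu) if result.C_uu is not None else np.full(len(result.ids), np.nan)
    pd.DataFrame({"id": result.ids, "ebv": result.u_hat.to_numpy(), "pev": pev}).to_csv(
        outdir / "solutions.tsv", sep="\t", index=False
    )
    result.beta_hat.rename_axis("effect").to_frame("estimate").to_csv(
        outdir / "fixed_effects.tsv", sep="\t"
    )
    if result.C_uu is not None:
        pd.DataFrame(result.C_uu, index=result.ids, columns=result.ids).to_csv(
            outdir / "C_uu.tsv", sep="\t", index_label="id"
        )
        pd.DataFrame(
            result.C_bb, index=result.beta_hat.index, columns=result.beta_hat.index
        ).to_csv(outdir / "C_bb.tsv", sep="\t", index_label="effect")
    meta = {
        "model": result.model,
        "data": result.data_tag,
        "sigma2_u": result.vc.sigma2_u,
        "sigma2_e": result.vc.sigma2_e,
        "sigma2_u_inf": result.vc.sigma2_u_inf,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_ebv_pairs(path: str | Path) -> pd.DataFrame:
    """EBV-pair TSV: ``id, ebv_partial, ebv_whole[, subset]`` (subset r|v)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["id", "ebv_partial", "ebv_whole"], path)
    df["id"] = df["id"].astype(str)
    return df


@dataclass
class RunConfig:
    """Resolved run configuration; written next to every output."""

    pedigree: str | None = None
    phenotypes: str | None = None
    genotypes: str | None = None
    factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    sigma2_u: float | None = None
    sigma2_e: float | None = None
    sigma2_u_inf: float | None = None
    partition: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("pedigree", "phenotypes", "genotypes"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path}: {key} file not found: {p}")
        return cfg

    def variance_components(self) -> VarianceComponents:
        if self.sigma2_u is None or self.sigma2_e is None:
            raise ValueError("config must set sigma2_u and sigma2_e")
        return VarianceComponents(self.sigma2_u, self.sigma2_e, self.sigma2_u_inf)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
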