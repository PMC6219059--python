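"""Simulation of pedigrees, breeding values, genotypes and phenotypes.

The simulator provides the ground truth (TBV) against which every LR
statistic is validated.  It implements an infinitesimal additive model on a
discrete-generation pedigree: founder TBV are N(0, sigma2_u) and offspring
TBV are the parent average plus a Mendelian-sampling deviation with
variance ``0.5 (1 - (F_s + F_d)/2) sigma2_u``, so that Var(u) = A sigma2_u
exactly.  Phenotypes are ``y = contemporary-group effect + u + e``.
Optional truncation selection (on phenotype, TBV or EBV) builds up the
Bulmer effect; the realized per-generation genetic variance is recorded so
an equilibrium variance can be read off.  Genotypes, when requested, are
gene-dropped at unlinked biallelic loci.

All outputs are reproducible from ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinship import GenotypeMatrix, Pedigree, RelationshipMatrix
from .mixed_model import FixedDesign, VarianceComponents, solve_mme

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_pedigree",
    "simulate_tbv",
    "simulate_phenotypes",
    "apply_truncation_selection",
    "gene_drop",
    "simulate_population",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated population.

    Defaults give the unselected two-generation design used throughout:
    20 sires x 100 dams with 5 offspring per dam (500 phenotyped offspring),
    h^2 = 0.4 on a unit phenotypic scale, and 10 contemporary groups per
    generation with effect SD 0.5.
    """

    n_sires: int = 20
    n_dams: int = 100
    offspring_per_dam: int = 5
    n_generations: int = 2
    sigma2_u: float = 0.4
    sigma2_e: float = 0.6
    n_groups: int = 10
    group_sd: float = 0.5
    n_loci: int = 0
    founder_freq: float = 0.5
    selection: str = "none"  # none | phenotype | tbv | ebv
    proportion: float = 1.0  # selected fraction when selection != none
    phenotyped: str = "last"  # last | nonfounders | all
    theta_p: float = 1.0  # dispersion scalars for scaling experiments
    theta_w: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.proportion <= 1:
            raise ValueError("selected proportion must be in (0, 1]")
        if self.sigma2_u <= 0 or self.sigma2_e < 0:
            raise ValueError("variances must be positive")
        if self.selection not in ("none", "phenotype", "tbv", "ebv"):
            raise ValueError(f"unknown selection rule {self.selection!r}")

    @property
    def vc(self) -> VarianceComponents:
        return VarianceComponents(self.sigma2_u, self.sigma2_e)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated population."""

    config: SimulationConfig
    pedigree: Pedigree
    table: pd.DataFrame  # id, sire, dam, generation, sex
    u: pd.Series  # TBV by id
    beta: pd.Series  # true contemporary-group effects
    phenotypes: pd.DataFrame  # id, y, cg
    nrm: RelationshipMatrix
    genotypes: GenotypeMatrix | None = None
    realized_var: list[float] = field(default_factory=list)  # per generation
    selection_history: list[dict] = field(default_factory=list)

    @property
    def generation(self) -> pd.Series:
        return self.table.set_index("id")["generation"]


def apply_truncation_selection(
    ids: Sequence[str],
    criterion: np.ndarray,
    proportion: float,
    n_select: int | None = None,
) -> list[str]:
    """Ids of the top fraction (or top ``n_select``) by criterion value."""
    ids = list(ids)
    n = n_select if n_select is not None else int(np.floor(len(ids) * proportion))
    if n < 2:
        raise ValueError("selected proportion yields fewer than 2 parents")
    order = np.argsort(np.asarray(criterion, dtype=float))[::-1]
    return [ids[i] for i in order[:n]]


def _mate(
    sires: list[str], dams: list[str], offspring_per_dam: int, start: int, gen: int,
    rng: np.random.Generator,
) -> list[tuple[str, str, str, int, str]]:
    """Each dam mated to one sire (cyclic over a shuffled dam list)."""
    dams = list(dams)
    rng.shuffle(dams)
    rows = []
    nid = start
    for j, dam in enumerate(dams):
        sire = sires[j % len(sires)]
        for k in range(offspring_per_dam):
            rows.append((str(nid), sire, dam, gen, "M" if (j + k) % 2 == 0 else "F"))
            nid += 1
    return rows


def simulate_pedigree(config: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Random-mating pedigree (no selection) as a table (id, sire, dam, generation, sex)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = _founders(config)
    for g in range(1, config.n_generations):
        prev = [r for r in rows if r[3] == g - 1]
        sires, dams = _choose_parents(prev, config, rng)
        rows += _mate(sires, dams, config.offspring_per_dam, len(rows) + 1, g, rng)
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex"])


def _founders(config: SimulationConfig) -> list[tuple[str, str, str, int, str]]:
    rows = []
    for i in range(config.n_sires):
        rows.append((str(i + 1), "0", "0", 0, "M"))
    for i in range(config.n_dams):
        rows.append((str(config.n_sires + i + 1), "0", "0", 0, "F"))
    return rows


def _choose_parents(prev_rows, config, rng, criterion=None):
    """Next-generation parents: random, or truncation on the criterion.

    The mating structure fixes the parent counts (n_sires, n_dams); under
    selection the realized selected proportion is counts / candidates.
    """
    males = [r[0] for r in prev_rows if r[4] == "M"]
    females = [r[0] for r in prev_rows if r[4] == "F"]
    if len(males) < min(2, config.n_sires) or len(females) < min(2, config.n_dams):
        raise ValueError(
            "infeasible family structure: more parents demanded than available "
            f"({len(males)} males / {len(females)} females)"
        )
    if criterion is not None:
        sires = apply_truncation_selection(
            males, criterion.loc[males].to_numpy(), 1.0,
            n_select=min(config.n_sires, len(males)),
        )
        dams = apply_truncation_selection(
            females, criterion.loc[females].to_numpy(), 1.0,
            n_select=min(config.n_dams, len(females)),
        )
    else:
        sires = list(rng.choice(males, size=min(config.n_sires, len(males)), replace=False))
        dams = list(rng.choice(females, size=min(config.n_dams, len(females)), replace=False))
    return sires, dams


def simulate_tbv(
    table: pd.DataFrame, sigma2_u: float, seed: int = 0
) -> pd.Series:
    """TBV down a pedigree table via the Mendelian-sampling recursion."""
    ped = Pedigree.from_records(table[["id", "sire", "dam"]].itertuples(index=False))
    rng = np.random.default_rng(seed)
    u, _ = _drop_tbv(ped, sigma2_u, rng)
    return pd.Series(u, index=ped.ids, name="u")


def _drop_tbv(
    ped: Pedigree, sigma2_u: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """TBV vector and inbreeding coefficients, maintaining the NRM on the fly."""
    n = len(ped)
    A = np.zeros((n, n))
    u = np.zeros(n)
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[:i, si]
            if di >= 0:
                row += A[:i, di]
            A[:i, i] = A[i, :i] = 0.5 * row
        if si >= 0 and di >= 0:
            Fs, Fd = A[si, si] - 1.0, A[di, di] - 1.0
            ms_var = 0.5 * (1.0 - 0.5 * (Fs + Fd)) * sigma2_u
            u[i] = 0.5 * (u[si] + u[di]) + rng.normal(0.0, np.sqrt(ms_var))
        else:
            u[i] = rng.normal(0.0, np.sqrt(sigma2_u))
    return u, np.diag(A) - 1.0


def simulate_phenotypes(
    ids: Sequence[str],
    u: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
    beta: pd.Series | None = None,
    group_prefix: str = "cg",
) -> tuple[pd.DataFrame, pd.Series]:
    """Phenotypes ``y = beta_cg + u + e`` with balanced random group assignment."""
    ids = list(ids)
    groups = [f"{group_prefix}{j + 1}" for j in range(config.n_groups)]
    if beta is None:
        beta = pd.Series(rng.normal(0.0, config.group_sd, config.n_groups), index=groups)
    assign = np.array([groups[j % config.n_groups] for j in range(len(ids))])
    rng.shuffle(assign)
    e = rng.normal(0.0, np.sqrt(config.sigma2_e), len(ids))
    y = beta.loc[assign].to_numpy() + u.loc[ids].to_numpy() + e
    return pd.DataFrame({"id": ids, "y": y, "cg": assign}), beta


def gene_drop(
    table: pd.DataFrame,
    n_loci: int,
    founder_freqs: float | np.ndarray,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop unlinked biallelic loci down a pedigree table."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    ped = Pedigree.from_records(table[["id", "sire", "dam"]].itertuples(index=False))
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(founder_freqs, dtype=float), (n_loci,))
    n = len(ped)
    hap = np.zeros((n, 2, n_loci), dtype=np.uint8)
    cols = np.arange(n_loci)
    for i in range(n):
        for h, par in enumerate((ped.sire_idx[i], ped.dam_idx[i])):
            if par < 0:
                hap[i, h] = rng.random(n_loci) < p
            else:
                hap[i, h] = hap[par, rng.integers(0, 2, n_loci), cols]
    dosages = hap.sum(axis=1).astype(float)
    loci = [f"snp{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(list(ped.ids), loci, dosages)


def simulate_population(config: SimulationConfig, seed: int | None = None) -> SimulationTruth:
    """Full simulation: pedigree, TBV, phenotypes, optional selection & genotypes.

    With ``selection != "none"`` parents of each generation are chosen by
    truncation on the configured criterion; the per-generation realized
    genetic variance and the selection history are recorded.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    rows = _founders(config)
    u_vals: dict[str, float] = {}
    A: dict | None = None  # incremental NRM bookkeeping below
    # incremental tabular NRM over a growing list of rows
    total = config.n_sires + config.n_dams + (
        (config.n_generations - 1) * config.n_dams * config.offspring_per_dam
    )
    Amat = np.zeros((total, total))
    pos: dict[str, int] = {}
    u_arr = np.zeros(total)

    def _append(idv: str, sire: str, dam: str) -> None:
        i = len(pos)
        si = pos.get(sire, -1)
        di = pos.get(dam, -1)
        Amat[i, i] = 1.0 + (0.5 * Amat[si, di] if si >= 0 and di >= 0 else 0.0)
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += Amat[:i, si]
            if di >= 0:
                row += Amat[:i, di]
            Amat[:i, i] = Amat[i, :i] = 0.5 * row
        if si >= 0 and di >= 0:
            Fs, Fd = Amat[si, si] - 1.0, Amat[di, di] - 1.0
            ms = 0.5 * (1.0 - 0.5 * (Fs + Fd)) * config.sigma2_u
            u_arr[i] = 0.5 * (u_arr[si] + u_arr[di]) + rng.normal(0.0, np.sqrt(ms))
        else:
            u_arr[i] = rng.normal(0.0, np.sqrt(config.sigma2_u))
        pos[idv] = i

    for r in rows:
        _append(r[0], r[1], r[2])

    pheno_frames: list[pd.DataFrame] = []
    betas: list[pd.Series] = []
    realized_var = [float(np.var([u_arr[pos[r[0]]] for r in rows]))]
    history: list[dict] = []

    def _phenotype_generation(gen_rows: list, gen: int) -> None:
        ids = [r[0] for r in gen_rows]
        u_ser = pd.Series([u_arr[pos[i]] for i in ids], index=ids)
        df, beta = simulate_phenotypes(
            ids, u_ser, config, rng, group_prefix=f"g{gen}c"
        )
        pheno_frames.append(df)
        betas.append(beta)

    if config.phenotyped == "all":
        _phenotype_generation(rows, 0)

    for g in range(1, config.n_generations):
        prev = [r for r in rows if r[3] == g - 1]
        criterion = None
        if config.selection != "none" and g > 1:
            prev_ids = [r[0] for r in prev]
            if config.selection == "tbv":
                criterion = pd.Series([u_arr[pos[i]] for i in prev_ids], index=prev_ids)
            elif config.selection == "phenotype":
                ph = pd.concat(pheno_frames).set_index("id")["y"]
                criterion = ph.reindex(prev_ids)
                if criterion.isna().any():
                    raise ValueError("phenotype selection requires phenotyped candidates")
            elif config.selection == "ebv":
                criterion = _ebv_criterion(rows, pheno_frames, config, prev_ids, Amat, pos)
        sires, dams = _choose_parents(prev, config, rng, criterion)
        if criterion is not None:
            history.append({"generation": g, "sires": sires, "dams": dams})
        new = _mate(sires, dams, config.offspring_per_dam, len(rows) + 1, g, rng)
        for r in new:
            _append(r[0], r[1], r[2])
        rows += new
        realized_var.append(float(np.var([u_arr[pos[r[0]]] for r in new])))
        if config.phenotyped == "all" or config.phenotyped == "nonfounders" or (
            config.phenotyped == "last" and g == config.n_generations - 1
        ):
            _phenotype_generation(new, g)

    table = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex"])
    ped = Pedigree.from_records(table[["id", "sire", "dam"]].itertuples(index=False))
    nrm = RelationshipMatrix(list(ped.ids), Amat[: len(rows), : len(rows)], "pedigree")
    phenotypes = (
        pd.concat(pheno_frames, ignore_index=True)
        if pheno_frames
        else pd.DataFrame(columns=["id", "y", "cg"])
    )
    geno = gene_drop(table, config.n_loci, config.founder_freq, seed=seed + 1) if config.n_loci else None
    return SimulationTruth(
        config=config,
        pedigree=ped,
        table=table,
        u=pd.Series(u_arr[: len(rows)], index=list(ped.ids), name="u"),
        beta=pd.concat(betas) if betas else pd.Series(dtype=float),
        phenotypes=phenotypes,
        nrm=nrm,
        genotypes=geno,
        realized_var=realized_var,
        selection_history=history,
    )


def _ebv_criterion(rows, pheno_frames, config, candidate_ids, Amat, pos):
    """PBLUP EBV of candidates from all phenotypes so far (for EBV selection)."""
    if not pheno_frames:
        raise ValueError("EBV selection requires phenotypes")
    ids = [r[0] for r in rows]
    K = RelationshipMatrix(ids, Amat[: len(ids), : len(ids)], "pedigree")
    phen = pd.concat(pheno_frames, ignore_index=True)
    res = solve_mme(phen, FixedDesign(factors=["cg"]), K, config.vc, compute_cov=False)
    return res.u_hat.loc[candidate_ids]
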