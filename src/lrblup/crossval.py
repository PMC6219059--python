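"""Partial/whole partitions, replicate LR runs, and model comparison.

One replicate masks records (random fraction or generation cutoff), solves
the animal model on the partial and the whole data, and computes the 16
statistics used to profile an evaluation: the REML heritability of the
partial data, the slopes, correlations and EBV changes on the full cohort
and within the reference ('r', records kept) and validation ('v', records
masked) subsets, and the predictivities of precorrected phenotypes.
Validation individuals carry no record in the partial data, so their
partial EBV come only from relatives (parent average under a pedigree
matrix, genomic relationships under a GRM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .lr_stats import EbvPair, compute_lr_statistics, mu_wp, predictivity, rho_w_p
from .mixed_model import (
    EvaluationResult,
    FixedDesign,
    VarianceComponents,
    em_reml,
    precorrect,
    solve_mme,
)

__all__ = [
    "PartitionSpec",
    "ReplicateSummary",
    "make_partition",
    "run_lr_replicate",
    "run_crossval",
    "summarize_replicates",
    "compare_models",
    "compare_models_protocol",
    "STATISTIC_NAMES",
]

logger = logging.getLogger(__name__)

#: the 16 replicate statistics, in reporting order
STATISTIC_NAMES = [
    "h2",
    "b_wp", "b_wp_r", "b_wp_v",
    "b_pw", "b_pw_r", "b_pw_v",
    "rho_wp", "rho_wp_r", "rho_wp_v",
    "r_yr_ur", "r_yv_uv",
    "d_wp_r", "d_wp_v",
    "Vd_wp_r", "Vd_wp_v",
]


@dataclass(frozen=True)
class PartitionSpec:
    """How to carve partial datasets out of the whole one."""

    scheme: str = "random_mask"  # random_mask | cutoff
    fraction: float = 0.5  # fraction of records masked (floor rule)
    cutoff_generation: int | None = None
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("random_mask", "cutoff"):
            raise ValueError(f"unknown partition scheme {self.scheme!r}")
        if self.scheme == "random_mask" and not 0 <= self.fraction < 1:
            raise ValueError("mask fraction must be in [0, 1)")
        if self.scheme == "cutoff" and self.cutoff_generation is None:
            raise ValueError("cutoff scheme needs cutoff_generation")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")


def make_partition(
    phenotypes: pd.DataFrame,
    spec: PartitionSpec,
    replicate_index: int = 0,
    generation: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Partial phenotype table and the validation individual ids.

    Masking acts on records; the validation set is the individuals with at
    least one masked record.  Deterministic given ``(spec.seed,
    replicate_index)``; the number of masked records is
    ``floor(fraction * n)``.
    """
    if spec.scheme == "random_mask":
        rng = np.random.default_rng([spec.seed, replicate_index])
        n_mask = int(np.floor(spec.fraction * len(phenotypes)))
        masked = rng.choice(len(phenotypes), size=n_mask, replace=False)
        mask = np.zeros(len(phenotypes), dtype=bool)
        mask[masked] = True
    else:
        if generation is None:
            raise ValueError("cutoff partition needs a generation mapping per id")
        gen = generation.loc[phenotypes["id"].astype(str)].to_numpy()
        mask = gen >= spec.cutoff_generation
    partial = phenotypes.loc[~mask].reset_index(drop=True)
    validation = sorted(
        set(phenotypes.loc[mask, "id"].astype(str)) - set(partial["id"].astype(str))
    )
    return partial, validation


def run_lr_replicate(
    whole: pd.DataFrame,
    design: FixedDesign,
    spec: PartitionSpec,
    replicate_index: int,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    generation: pd.Series | None = None,
    estimate_h2: bool = True,
    whole_result: EvaluationResult | None = None,
) -> dict[str, float]:
    """The 16 statistics for one partition replicate (one relationship source).

    LR statistics use the fixed (whole-data) variance components in `vc`;
    ``h2`` is re-estimated by EM-REML on the partial data.  Pass a
    pre-computed `whole_result` to reuse the whole-data solve across
    replicates.
    """
    partial, validation = make_partition(whole, spec, replicate_index, generation)
    if partial.empty:
        raise ValueError("empty partial dataset")
    res_w = whole_result if whole_result is not None else solve_mme(
        whole, design, K, vc, compute_cov=False, data_tag="whole"
    )
    res_p = solve_mme(partial, design, K, vc, compute_cov=False, data_tag="partial")

    phen_ids = list(dict.fromkeys(whole["id"].astype(str)))
    pair = EbvPair.from_results(res_p, res_w, focal=phen_ids, validation=validation)

    out: dict[str, float] = {"replicate": replicate_index, "n_validation": len(validation)}
    if estimate_h2:
        try:
            out["h2"] = em_reml(partial, design, K, start=vc).h2
        except Exception as e:  # non-fatal per replicate
            logger.warning("replicate %d: EM-REML failed (%s)", replicate_index, e)
            out["h2"] = np.nan
    else:
        out["h2"] = np.nan

    for tag, suffix in (("all", ""), ("r", "_r"), ("v", "_v")):
        sub = pair.subset(tag)
        keys = [f"{s}{suffix}" for s in ("mu_wp", "b_wp", "b_pw", "rho_wp")]
        if tag in ("r", "v"):
            keys += [f"d_wp{suffix}", f"Vd_wp{suffix}"]
        try:
            s = compute_lr_statistics(sub)
        except (ValueError, ZeroDivisionError):  # empty or degenerate subset
            out.update(dict.fromkeys(keys, np.nan))
            continue
        out[f"mu_wp{suffix}"] = s.mu_wp
        out[f"b_wp{suffix}"] = s.b_wp
        out[f"b_pw{suffix}"] = s.b_pw
        out[f"rho_wp{suffix}"] = s.rho_wp
        if tag in ("r", "v"):
            out[f"d_wp{suffix}"] = s.d_wp
            out[f"Vd_wp{suffix}"] = s.Vd_wp

    # predictivities: partial EBV vs whole-data-precorrected phenotypes
    y_star = precorrect(whole, res_w)
    per_id = (
        pd.DataFrame({"id": whole["id"].astype(str), "y_star": y_star})
        .groupby("id", sort=False)["y_star"]
        .mean()
    )
    for tag, name in (("r", "r_yr_ur"), ("v", "r_yv_uv")):
        sub = pair.subset(tag)
        try:
            out[name] = predictivity(per_id.loc[sub.ids].to_numpy(), sub.u_hat_p)
        except (ValueError, ZeroDivisionError):
            out[name] = np.nan
    return out


def run_crossval(
    whole: pd.DataFrame,
    design: FixedDesign,
    spec: PartitionSpec,
    sources: dict[str, RelationshipMatrix],
    vc: VarianceComponents,
    generation: pd.Series | None = None,
    estimate_h2: bool = True,
) -> pd.DataFrame:
    """Replicate table: one row per (replicate, relationship source).

    Replicate-level failures are logged and skipped, not fatal.
    """
    rows = []
    for name, K in sources.items():
        res_w = solve_mme(whole, design, K, vc, compute_cov=False, data_tag="whole")
        for r in range(spec.n_replicates):
            try:
                rec = run_lr_replicate(
                    whole, design, spec, r, K, vc, generation,
                    estimate_h2=estimate_h2, whole_result=res_w,
                )
            except Exception as e:
                logger.warning("replicate %d (%s) skipped: %s", r, name, e)
                continue
            rec["source"] = name
            rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class ReplicateSummary:
    """Per-statistic mean/SD/min/max and the correlation matrix across replicates."""

    summary: pd.DataFrame  # statistics x (mean, sd, min, max)
    correlations: pd.DataFrame  # statistics x statistics

    def __post_init__(self) -> None:
        s = self.summary
        eps = 1e-12 * (1.0 + s["mean"].abs())
        bad = s.index[(s["min"] > s["mean"] + eps) | (s["mean"] > s["max"] + eps)]
        if len(bad):
            raise AssertionError(f"inconsistent summary rows: {list(bad)}")


def summarize_replicates(
    records: pd.DataFrame, statistics: Sequence[str] = STATISTIC_NAMES
) -> ReplicateSummary:
    """Table-style summary over replicates (mean, SD, min, max; correlations).

    Correlations with a constant statistic are reported as missing.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 replicates to summarize")
    cols = [c for c in statistics if c in records.columns]
    sub = records[cols]
    summary = pd.DataFrame(
        {
            "mean": sub.mean(),
            "sd": sub.std(ddof=1),
            "min": sub.min(),
            "max": sub.max(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = sub.corr()
    np.fill_diagonal(corr.values, 1.0)
    return ReplicateSummary(summary, corr)


def compare_models(
    ebv_a: np.ndarray | pd.Series, ebv_g: np.ndarray | pd.Series
) -> float:
    """``rho_AG = corr(u_hat_A, u_hat_G)`` over a focal set.

    Interpreting marker data as extra information, this correlation
    estimates ``acc_A / acc_G``: the lower it is, the larger the genomic
    gain in accuracy.
    """
    a = np.asarray(ebv_a, dtype=float)
    g = np.asarray(ebv_g, dtype=float)
    pair = EbvPair([str(i) for i in range(a.size)], a, g)
    return rho_w_p(pair)


def compare_models_protocol(
    whole: pd.DataFrame,
    design: FixedDesign,
    spec: PartitionSpec,
    K_pedigree: RelationshipMatrix,
    K_genomic: RelationshipMatrix,
    vc: VarianceComponents,
    replicate_index: int = 0,
    generation: pd.Series | None = None,
) -> dict[str, float]:
    """Paired PBLUP-vs-GBLUP partial/whole comparison on one partition.

    Runs the whole and partial evaluations under both relationship
    matrices, reports (mu_wp, b_wp, rho_wp) per model on the validation
    cohort plus the cross-model correlations on partial and on whole data.
    """
    partial, validation = make_partition(whole, spec, replicate_index, generation)
    if len(validation) < 2:
        raise ValueError("validation cohort too small")
    out: dict[str, float] = {}
    results = {}
    for name, K in (("pblup", K_pedigree), ("gblup", K_genomic)):
        res_w = solve_mme(whole, design, K, vc, compute_cov=False, data_tag="whole")
        res_p = solve_mme(partial, design, K, vc, compute_cov=False, data_tag="partial")
        pair = EbvPair.from_results(res_p, res_w, focal=validation)
        out[f"mu_wp_{name}"] = mu_wp(pair)
        out[f"b_wp_{name}"] = compute_lr_statistics(pair).b_wp
        out[f"rho_wp_{name}"] = rho_w_p(pair)
        results[name] = (res_p, res_w)
    for tag, idx in (("p", 0), ("w", 1)):
        out[f"rho_pblup_gblup_{tag}"] = compare_models(
            results["pblup"][idx].u_hat.loc[validation],
            results["gblup"][idx].u_hat.loc[validation],
        )
    return out
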