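"""Shared fixtures: small pedigrees and the standard simulated population."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lrblup import FixedDesign, Pedigree, SimulationConfig, simulate_population

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def trio():
    """Two unrelated founders and one offspring."""
    return Pedigree.from_records([("s", "0", "0"), ("d", "0", "0"), ("o", "s", "d")])


@pytest.fixture(scope="session")
def fullsib_family():
    """Parents plus ten full sibs."""
    recs = [("s", "0", "0"), ("d", "0", "0")] + [
        (f"o{k}", "s", "d") for k in range(10)
    ]
    return Pedigree.from_records(recs)


@pytest.fixture(scope="session")
def std_truth():
    """The standard unselected two-generation population.

    20 sires x 100 dams x 5 offspring (500 phenotyped), h2 = 0.4, 10
    contemporary groups; the design shared by the replicated experiments.
    """
    return simulate_population(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def cg_design():
    return FixedDesign(factors=["cg"])


def tbv_redrawer(truth):
    """Fast TBV re-sampler for a fixed pedigree (same law as the simulator)."""
    ped = truth.pedigree
    s, d = ped.sire_idx, ped.dam_idx
    F = np.diag(truth.nrm.matrix) - 1.0
    s2u = truth.config.sigma2_u
    sd = np.where(
        (s >= 0) & (d >= 0),
        np.sqrt(0.5 * (1.0 - 0.5 * (F[np.maximum(s, 0)] + F[np.maximum(d, 0)])) * s2u),
        np.sqrt(s2u),
    )

    def draw(rng):
        u = np.zeros(len(ped.ids))
        noise = rng.normal(0.0, sd)
        for i in range(len(u)):
            u[i] = (0.5 * (u[s[i]] + u[d[i]]) if s[i] >= 0 else 0.0) + noise[i]
        return u

    return draw


def redraw_phenotypes(truth, rng, u=None):
    """New phenotype table for the fixed design (same CG assignment and effects)."""
    if u is None:
        u = tbv_redrawer(truth)(rng)
    idx = {i: k for k, i in enumerate(truth.pedigree.ids)}
    rec_ix = np.array([idx[i] for i in truth.phenotypes["id"]])
    y = (
        truth.beta.loc[truth.phenotypes["cg"]].to_numpy()
        + u[rec_ix]
        + rng.normal(0.0, np.sqrt(truth.config.sigma2_e), len(rec_ix))
    )
    return (
        pd.DataFrame(
            {"id": truth.phenotypes["id"], "y": y, "cg": truth.phenotypes["cg"]}
        ),
        u,
    )
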