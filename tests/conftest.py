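"""Shared fixtures: small generated cohorts and an in-memory analysis runner."""

from pathlib import Path

import pandas as pd
import pytest

import comet_bioage as cb

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_config():
    return cb.SyntheticConfig(n_cu=60, n_mci=50, n_dementia=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cb.generate_cohort(small_config)


@pytest.fixture(scope="session")
def combat_fixture():
    data = pd.read_csv(DATA_DIR / "combat_fixture_data.csv", index_col=0)
    cov = pd.read_csv(DATA_DIR / "combat_fixture_covariates.csv", index_col=0)
    expected = pd.read_csv(DATA_DIR / "combat_fixture_expected.csv", index_col=0)
    return data, cov, expected


def covariate_table(participants: pd.DataFrame) -> pd.DataFrame:
    part = participants.set_index("id")
    return pd.DataFrame({
        "age": part["age_at_mri"],
        "sex": (part["sex"] == "female").astype(float),
        "icv": part["icv"],
    })


def analyze_cohort(cfg: cb.SyntheticConfig, with_clocks: bool = True) -> dict:
    """Run the full analysis in memory; returns every intermediate table."""
    participants, roi, amyloid, truth = cb.generate_cohort(cfg)
    labels = cb.build_cohort_table(participants, amyloid)
    part = participants.set_index("id")
    cov = covariate_table(participants)
    cu = labels.index[labels["cohort"] == "CU"]
    combat = cb.fit_combat(roi.loc[cu], cov.loc[cu, ["age", "sex"]],
                           part.loc[cu, "scanner_field"])
    harmonized = cb.apply_combat(combat, roi, cov[["age", "sex"]], part["scanner_field"])
    models = cb.fit_comet_models(harmonized.loc[cu], cov)
    comet = cb.compute_comet(harmonized, cov, models)
    out = {"participants": participants, "roi": roi, "amyloid": amyloid,
           "truth": truth, "labels": labels, "covariates": cov, "cu_ids": cu,
           "combat": combat, "harmonized": harmonized, "comet_models": models,
           "comet": comet}
    if with_clocks:
        betas, clocks = cb.generate_clock_data(participants, truth, cfg)
        matrix = cb.select_replicate(betas, cfg.seed + 1)
        out["betas"] = betas
        out["clocks"] = clocks
        out["bag"] = cb.compute_bag_table(matrix, clocks, part["age_at_mri"])
    return out


def comet_bag_r(seed: int, rho: float) -> float:
    """Estimated symptomatic CoMeT-BAG Pearson r at one generator seed."""
    cfg = cb.SyntheticConfig(coupling_rho=rho, seed=seed)
    res = analyze_cohort(cfg)
    sym = res["labels"].index[res["labels"]["cohort"] == "symptomatic"]
    return cb.pearson(res["bag"].loc[sym, "bag"], res["comet"].loc[sym, "comet"]).r
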