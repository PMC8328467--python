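import numpy as np
import pandas as pd
import pytest

from reefchrono.binning import ReefZone, TimeBin
from reefchrono.glmm import GLMMDesign, _design_from_table
from reefchrono.records import filter_full_complement, harmonize_records
from reefchrono.synthetic import default_caribbean_scenario, generate_dataset
from reefchrono.taxa import ALL_SPECIES


def make_design(
    seed: int,
    n_countries: int = 3,
    n_per_bin: int = 15,
    bins=(TimeBin.PLEISTOCENE, TimeBin.B1960_1969),
    beta0: float = 0.5,
    bin_effects=(-1.0,),
    sigma_u: float = 1.0,
    trials: int = 1,
) -> tuple[GLMMDesign, np.ndarray]:
    """Small single-species random-intercept dataset with known truth."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_u, n_countries)
    rows = []
    k = 0
    for bi, tb in enumerate(bins):
        eff = 0.0 if bi == 0 else bin_effects[bi - 1]
        for i in range(n_per_bin):
            c = i % n_countries
            eta = beta0 + eff + u[c]
            y = rng.binomial(trials, 1.0 / (1.0 + np.exp(-eta)))
            rows.append((f"s{k}", f"C{c}", tb, "SP", int(y), trials))
            k += 1
    table = pd.DataFrame(
        rows, columns=["survey_id", "country", "bin", "species", "successes", "trials"]
    )
    return _design_from_table(table), u


@pytest.fixture(scope="session")
def small_scenario_data():
    """One small default-style scenario realization, harmonized (crest)."""
    cfg = default_caribbean_scenario(seed=42)
    cfg.n_countries = 8
    cfg.sites_per_country_per_bin = {
        tb: (6 if tb <= TimeBin.B1970_1979 else 12) for tb in TimeBin
    }
    records, truth = generate_dataset(cfg)
    matrices, log = harmonize_records(records)
    crest = {tb: m for (z, tb), m in matrices.items() if z is ReefZone.CREST}
    return {"config": cfg, "records": records, "truth": truth, "matrices": crest, "log": log}


@pytest.fixture(scope="session")
def full_complement_matrices(small_scenario_data):
    return {
        tb: filter_full_complement(m, list(ALL_SPECIES))
        for tb, m in small_scenario_data["matrices"].items()
    }
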