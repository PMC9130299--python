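"""Shared fixtures: hand-built toy cohorts and a reusable set of reduced-size
synthetic pipeline replicates (generated once per session)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gliosurv.cohort import Cohort
from gliosurv.genomics import NestedLassoConfig, select_lambda_nested
from gliosurv.integration import run_layered_models
from gliosurv.signature import apply_signature, train_signature
from gliosurv.simulate import SyntheticConfig, generate_replication_split
from gliosurv.stratify import assign_risk_groups, logrank_test


def make_cohort(
    os_months,
    mgmt=None,
    gender=None,
    eor=None,
    age=None,
    n_features=4,
    seed=0,
    role="discovery",
) -> Cohort:
    """Small hand-controllable cohort; unspecified covariates are filled
    deterministically."""
    n = len(os_months)
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"p{i:04d}" for i in range(n)], name="patient_id")
    clinical = pd.DataFrame(
        {
            "age": age if age is not None else np.linspace(40, 80, n),
            "gender": gender if gender is not None
            else np.where(np.arange(n) % 2 == 0, "female", "male"),
            "eor": eor if eor is not None
            else np.where(np.arange(n) % 2 == 0, "gross_or_near_total",
                          "partial_or_biopsy"),
            "mgmt": mgmt if mgmt is not None
            else np.where(np.arange(n) % 3 == 0, "methylated", "unmethylated"),
        },
        index=ids,
    )
    half = n_features // 2
    cols = [f"conv_{i:02d}" for i in range(half)] + [
        f"deep_{i:02d}" for i in range(n_features - half)
    ]
    features = pd.DataFrame(
        rng.standard_normal((n, n_features)), index=ids, columns=cols
    )
    mutations = pd.DataFrame(
        rng.integers(0, 2, size=(n, 3)), index=ids,
        columns=["EGFR", "RB1", "NOTCH2"],
    )
    survival = pd.DataFrame(
        {"os_months": np.asarray(os_months, dtype=float), "event_observed": True},
        index=ids,
    )
    return Cohort(clinical=clinical, features=features, mutations=mutations,
                  survival=survival, role=role)


#: Reduced-size study conditions with independent hazard signal in the
#: clinical, latent-radiomic, and genomic layers.
REPLICATE_CONFIG = dict(
    n_discovery=200,
    n_replication=112,
    n_conventional_features=24,
    n_deep_features=40,
    beta_latent=(1.0, -0.8, 0.6, 0.0, 0.0),
)


def run_reduced_pipeline(seed: int) -> dict:
    """One reduced-size end-to-end replicate; returns summary quantities."""
    cfg = SyntheticConfig(seed=seed, **REPLICATE_CONFIG)
    disc, rep, truth = generate_replication_split(cfg)
    model = train_signature(disc, c_grid=[1.0], seed=seed)
    spi = apply_signature(model, rep)
    sel = select_lambda_nested(
        rep.mutations,
        rep.os_months.to_numpy(),
        NestedLassoConfig(n_outer_reps=5, inner_reps=5, n_lambdas=50, seed=seed),
    )
    results, table = run_layered_models(
        rep, spi, sel.selected_genes, n_boot=100, seed=seed
    )
    times = rep.os_months.to_numpy()
    groups6 = assign_risk_groups(results[-1].linear_predictor)
    lr6 = logrank_test(times, groups6)
    val_auc = {
        name: float(np.nanmean([d["validation_auc"]
                                for d in clf.fold_diagnostics]))
        for name, clf in (("high_risk", model.high_risk),
                          ("low_risk", model.low_risk))
    }
    return {
        "seed": seed,
        "table": table,
        "results": results,
        "logrank_p_model6": lr6.p_value,
        "mean_val_auc": val_auc,
        "spi": spi,
        "replication": rep,
        "truth": truth,
        "selected_genes": sel.selected_genes,
    }


@pytest.fixture(scope="session")
def pipeline_replicates() -> list[dict]:
    """Ten independent reduced-size end-to-end replicates."""
    return [run_reduced_pipeline(seed) for seed in range(10)]
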