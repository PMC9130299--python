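"""End-to-end orchestration: simulate → signature → genes → integrate → stratify.

One seed drives every stochastic stage through deterministically derived
per-stage streams, so a rerun with the same configuration reproduces all
numeric outputs bit-identically. Each run writes a manifest with the
configuration hash, per-stage seeds, and SHA-256 checksums of every output
file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, summarize_cohort, write_cohort
from .genomics import NestedLassoConfig, select_lambda_nested
from .integration import forest_table, run_layered_models
from .signature import (
    RiskLabelConfig,
    SignatureModel,
    apply_signature,
    train_signature,
)
from .simulate import SyntheticConfig, generate_replication_split
from .stratify import assign_risk_groups, group_km_curves, logrank_test

__all__ = ["RunConfig", "run_full_pipeline", "stage_seed"]

log = logging.getLogger("gliosurv")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    labels: RiskLabelConfig = field(default_factory=RiskLabelConfig)
    lasso: NestedLassoConfig = field(default_factory=NestedLassoConfig)
    c_grid: tuple[float, ...] = (0.01, 1.0, 100.0)
    rfe_step: float = 0.1
    min_features: int = 8
    n_boot: int = 1000
    tau_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed rules every stage
        self.synthetic = dataclasses.replace(
            self.synthetic, seed=stage_seed(self.seed, "simulate")
        )
        self.lasso = dataclasses.replace(
            self.lasso, seed=stage_seed(self.seed, "select-genes")
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        if "labels" in kwargs:
            kwargs["labels"] = RiskLabelConfig(**kwargs["labels"])
        if "lasso" in kwargs:
            kwargs["lasso"] = NestedLassoConfig(**kwargs["lasso"])
        if "c_grid" in kwargs:
            kwargs["c_grid"] = tuple(kwargs["c_grid"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["causal_genes"] = dict(self.synthetic.causal_genes)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_pipeline(config: RunConfig, outdir: str) -> dict:
    """Run every stage into ``outdir``; returns the manifest dict.

    Any stage failure is re-raised annotated with the stage name.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    outputs: dict[str, str] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as exc:  # annotate and abort
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {
                "seconds": round(dt, 3),
                "seed": stage_seed(config.seed, name),
            }
            log.info("stage %s: done in %.2fs", name, dt)

        return wrap

    holder: dict = {}

    @stage("simulate")
    def _simulate():
        disc, rep, truth = generate_replication_split(config.synthetic)
        holder["disc"], holder["rep"] = disc, rep
        for role, cohort in (("discovery", disc), ("replication", rep)):
            paths = write_cohort(cohort, os.path.join(outdir, role))
            outputs.update({f"{role}/{k}": v for k, v in paths.items()})
        truth_path = os.path.join(outdir, "ground_truth.json")
        with open(truth_path, "w") as fh:
            json.dump(
                {
                    "coefficients": truth.coefficients,
                    "baseline_scale": truth.baseline_scale,
                    "weibull_shape": truth.weibull_shape,
                    "linear_predictor": truth.linear_predictor.tolist(),
                },
                fh,
                indent=2,
            )
        outputs["ground_truth"] = truth_path
        summary = summarize_cohort(rep)
        spath = os.path.join(outdir, "replication_summary.csv")
        summary.to_csv(spath, index=False)
        outputs["replication_summary"] = spath

    @stage("train-signature")
    def _train():
        model = train_signature(
            holder["disc"],
            labels=config.labels,
            c_grid=config.c_grid,
            seed=stage_seed(config.seed, "train-signature"),
            rfe_step=config.rfe_step,
            min_features=config.min_features,
        )
        holder["model"] = model
        path = os.path.join(outdir, "signature_model.json")
        with open(path, "w") as fh:
            fh.write(model.to_json())
        outputs["signature_model"] = path

    @stage("apply-signature")
    def _apply():
        spi = apply_signature(holder["model"], holder["rep"])
        holder["spi"] = spi
        path = os.path.join(outdir, "spi.csv")
        spi.rename_axis("patient_id").to_csv(path)
        outputs["spi"] = path

    @stage("select-genes")
    def _genes():
        rep = holder["rep"]
        lasso = dataclasses.replace(
            config.lasso,
            outer_train_n=config.lasso.outer_train_n,
            outer_test_n=rep.n_patients - config.lasso.outer_train_n,
        )
        sel = select_lambda_nested(rep.mutations, rep.os_months.to_numpy(), lasso)
        holder["genes"] = sel.selected_genes
        path = os.path.join(outdir, "gene_selection.json")
        with open(path, "w") as fh:
            json.dump(
                {
                    "lambda_final": sel.lambda_final,
                    "selected_genes": sel.selected_genes,
                    "coefficients": sel.coefficients.to_dict(),
                    "outer_results": sel.outer_results.to_dict("records"),
                },
                fh,
                indent=2,
            )
        outputs["gene_selection"] = path

    @stage("integrate")
    def _integrate():
        results, table = run_layered_models(
            holder["rep"],
            holder["spi"],
            holder["genes"],
            n_boot=config.n_boot,
            tau_quantile=config.tau_quantile,
            seed=stage_seed(config.seed, "integrate"),
        )
        holder["results"] = results
        cpath = os.path.join(outdir, "model_comparison.csv")
        table.to_csv(cpath, index=False)
        fpath = os.path.join(outdir, "forest.csv")
        forest_table(results).to_csv(fpath, index=False)
        outputs["model_comparison"] = cpath
        outputs["forest"] = fpath

    @stage("stratify")
    def _stratify():
        times = holder["rep"].os_months.to_numpy()
        rows = []
        for r in holder["results"]:
            groups = assign_risk_groups(r.linear_predictor)
            lr = logrank_test(times, groups)
            rows.append(
                {
                    "model": r.spec.model_id,
                    "statistic": lr.statistic,
                    "df": lr.df,
                    "p_value": lr.p_value,
                }
            )
            if r.spec.model_id == 6:
                gpath = os.path.join(outdir, "risk_groups_model6.csv")
                groups.labels.rename_axis("patient_id").to_csv(gpath)
                kpath = os.path.join(outdir, "km_curves_model6.csv")
                group_km_curves(times, groups).to_csv(kpath, index=False)
                outputs["risk_groups_model6"] = gpath
                outputs["km_curves_model6"] = kpath
        lpath = os.path.join(outdir, "logrank.csv")
        pd.DataFrame(rows).to_csv(lpath, index=False)
        outputs["logrank"] = lpath

    manifest["checksums"] = {k: _sha256(v) for k, v in sorted(outputs.items())}
    mpath = os.path.join(outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
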