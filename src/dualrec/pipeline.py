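"""Configuration-driven orchestration of the full analysis.

A run executes: design resolution -> data simulation or ingestion ->
maximum-likelihood and/or hierarchical fitting -> posterior-predictive
checks -> posterior contrasts -> Bayes-factor tests, writing every
intermediate artifact plus a manifest with seeds and content hashes. All
randomness flows from a single root seed, split per stage, so re-running a
config reproduces every deterministic artifact byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignSpec, build_design, probe_cell_totals
from .hierarchical import fit_latent_trait, group_contrast_draws, posterior_predictive_check
from .ml import fit_dataset
from .model import build_dual_recollection_model
from .simulate import ResponseDataset, default_population, make_experiment_dataset
from .stats import contrast_decision, run_bf_tests

__all__ = ["RunConfig", "load_config", "validate_inputs", "run_pipeline"]

log = logging.getLogger("dualrec.pipeline")


@dataclass
class RunConfig:
    design: str  # preset name or path to a design JSON
    seed: int
    outdir: str
    data: str | None = None  # counts CSV; simulated when absent
    n_participants: int = 32
    population_sd: float = 0.5
    fitter: str = "both"  # ml | hierarchical | both
    mcmc: dict = field(default_factory=lambda: {"chains": 2, "warmup": 500, "draws": 500})
    contrasts: list[dict] = field(default_factory=list)
    tests: list[dict] = field(default_factory=list)

    def validate(self) -> list[str]:
        errors = []
        if self.seed is None:
            errors.append("seed is mandatory")
        if self.fitter not in {"ml", "hierarchical", "both"}:
            errors.append(f"fitter must be ml|hierarchical|both, got {self.fitter!r}")
        if self.data is not None and not Path(self.data).exists():
            errors.append(f"data file not found: {self.data}")
        if self.design.endswith(".json") and not Path(self.design).exists():
            errors.append(f"design file not found: {self.design}")
        for key in ("chains", "warmup", "draws"):
            if key not in self.mcmc:
                errors.append(f"mcmc option {key!r} missing")
        return errors


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _resolve_design(spec: str) -> DesignSpec:
    if spec.endswith(".json"):
        return DesignSpec.from_json(Path(spec).read_text())
    return build_design(spec)


def validate_inputs(path: str | Path, design: DesignSpec) -> tuple[ResponseDataset | None, list[dict]]:
    """Schema and consistency validation of a counts CSV against a design.

    Returns the dataset (or None) plus a machine-readable error list; rows
    are never silently dropped.
    """
    errors: list[dict] = []
    path = Path(path)
    if not path.exists():
        return None, [{"rule": "file-exists", "detail": str(path)}]
    counts = pd.read_csv(path)
    required = ["participant", "probe", "item_class", "n_yes", "n_total"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        return None, [{"rule": "columns", "detail": f"missing columns: {missing}"}]
    bad = counts[(counts.n_yes < 0) | (counts.n_yes > counts.n_total)]
    for idx in bad.index:
        errors.append({"rule": "count-range", "row": int(idx), "detail": "n_yes outside [0, n_total]"})

    expected = {
        (r.probe, r.item_class): int(r.n_total) for r in probe_cell_totals(design).itertuples()
    }
    for pid, grp in counts.groupby("participant"):
        cells = grp.groupby(["probe", "item_class"])["n_total"].sum().to_dict()
        for cell, n_exp in expected.items():
            if cell not in cells:
                errors.append(
                    {"rule": "completeness", "participant": str(pid), "cell": f"{cell[0]}|{cell[1]}",
                     "detail": "cell missing"}
                )
            elif int(cells[cell]) != n_exp:
                errors.append(
                    {"rule": "allocation", "participant": str(pid), "cell": f"{cell[0]}|{cell[1]}",
                     "detail": f"n_total {cells[cell]} != design allocation {n_exp}"}
                )
    if errors:
        return None, errors
    dataset = ResponseDataset(counts=counts, design=design)
    return dataset, []


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ["simulate", "ml", "hierarchical", "ppc", "bf"],
            np.random.SeedSequence(config.seed).spawn(5),
        )
    }
    artifacts: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "config": {k: getattr(config, k) for k in RunConfig.__dataclass_fields__},
        "stage_seeds": stage_seeds,
        "artifacts": artifacts,
    }

    try:
        design = _resolve_design(config.design)
        log.info("stage=design id=%s condition=%s", design.experiment_id, design.condition)
        model = build_dual_recollection_model(design)
        (outdir / "model.json").write_text(model.to_json(indent=1))
        (outdir / "model.eqn").write_text(model.to_eqn())
        artifacts["model.json"] = _sha256(outdir / "model.json")
        artifacts["model.eqn"] = _sha256(outdir / "model.eqn")

        if config.data is not None:
            dataset, verrors = validate_inputs(config.data, design)
            if verrors:
                raise ValueError(f"input validation failed: {verrors}")
            log.info("stage=ingest path=%s participants=%d", config.data, dataset.n_participants)
        else:
            if config.design.endswith(".json"):
                raise ValueError("simulation requires a named design preset; supply `data` for custom designs")
            pop = default_population(
                config.design, config.n_participants, sd=config.population_sd, model=model
            )
            dataset = make_experiment_dataset(
                config.design, pop=pop, seed=stage_seeds["simulate"], model=model
            )
            log.info("stage=simulate participants=%d seed=%d",
                     dataset.n_participants, stage_seeds["simulate"])
        dataset.write(outdir / "dataset.csv")
        artifacts["dataset.csv"] = _sha256(outdir / "dataset.csv")

        ml_estimates = None
        if config.fitter in ("ml", "both"):
            ml_estimates = fit_dataset(dataset, model, seed=stage_seeds["ml"])
            ml_estimates.to_csv(outdir / "ml_estimates.csv", index=False)
            artifacts["ml_estimates.csv"] = _sha256(outdir / "ml_estimates.csv")
            log.info("stage=ml participants=%d converged=%d",
                     len(ml_estimates), int(ml_estimates["converged"].sum()))

        posterior = None
        if config.fitter in ("hierarchical", "both"):
            posterior = fit_latent_trait(
                dataset,
                model,
                seed=stage_seeds["hierarchical"],
                n_chains=int(config.mcmc["chains"]),
                n_warmup=int(config.mcmc["warmup"]),
                n_draws=int(config.mcmc["draws"]),
            )
            posterior.summary_frame().to_csv(outdir / "posterior_summary.csv", index=False)
            posterior.draws_frame().to_csv(outdir / "posterior_draws.csv", index=False)
            artifacts["posterior_summary.csv"] = _sha256(outdir / "posterior_summary.csv")
            artifacts["posterior_draws.csv"] = _sha256(outdir / "posterior_draws.csv")
            log.info("stage=hierarchical converged=%s flags=%s", posterior.converged, posterior.flags)

            ppc = posterior_predictive_check(posterior, dataset, seed=stage_seeds["ppc"])
            (outdir / "ppc.json").write_text(json.dumps(ppc, indent=1))
            artifacts["ppc.json"] = _sha256(outdir / "ppc.json")
            log.info("stage=ppc T1_p=%.3f T2_p=%.3f", ppc["T1_p"], ppc["T2_p"])

            if config.contrasts:
                results = []
                for c in config.contrasts:
                    draws = group_contrast_draws(posterior, c["parameter_a"], c["parameter_b"])
                    decision = contrast_decision(draws)
                    results.append(
                        {
                            "name": c.get("name", f"{c['parameter_a']}-{c['parameter_b']}"),
                            "mean_diff": decision.mean_diff,
                            "bci_95": list(decision.bci_95),
                            "substantial": decision.substantial,
                        }
                    )
                (outdir / "contrasts.json").write_text(json.dumps(results, indent=1))
                artifacts["contrasts.json"] = _sha256(outdir / "contrasts.json")
                log.info("stage=contrast n=%d", len(results))

        if config.tests and ml_estimates is not None:
            report = run_bf_tests(ml_estimates, config.tests)
            report.to_csv(outdir / "bf_report.csv", index=False)
            report.to_json(outdir / "bf_report.json", orient="records", indent=1)
            artifacts["bf_report.csv"] = _sha256(outdir / "bf_report.csv")
            log.info("stage=bf n=%d", len(report))

        _write_markdown_report(outdir, design, posterior)
        if (outdir / "report.md").exists():
            artifacts["report.md"] = _sha256(outdir / "report.md")

        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        log.info("stage=done artifacts=%d", len(artifacts))
        return manifest
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_markdown_report(outdir: Path, design: DesignSpec, posterior) -> None:
    lines = [
        f"# Run report: {design.experiment_id} ({design.condition})",
        "",
        f"Targets: {design.n_targets}; distractors: {design.n_distractors}; "
        f"probes: {', '.join(design.probe_types)}",
        "",
    ]
    if posterior is not None:
        lines += ["## Group-level estimates (SD) [95% BCI]", ""]
        lines += ["| parameter | estimate (SD) [95% BCI] |", "|---|---|"]
        for p in posterior.parameter_names:
            lo, hi = posterior.bci_95[p]
            lines.append(
                f"| {p} | {posterior.group_means[p]:.3f} ({posterior.group_sds[p]:.3f}) "
                f"[{lo:.3f}, {hi:.3f}] |"
            )
        lines += ["", f"Converged: {posterior.converged}; flags: {list(posterior.flags)}"]
        if posterior.ppc:
            lines.append(f"PPC: T1 p = {posterior.ppc['T1_p']:.3f}, T2 p = {posterior.ppc['T2_p']:.3f}")
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
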