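"""End-to-end reproducible runs from a declarative configuration.

A run is: obtain data (a named synthetic scenario or a CSV) -> global
preparation -> fixed subsample splits -> the variant x criterion experiment
-> CSV artifacts under a fixed output tree:

    output_dir/
      config.yaml      resolved configuration
      manifest.json    config hash, expanded seeds, library versions
      data/            dataset CSV + preprocessing report
      metrics/         per-replicate and aggregated performance tables
      importance/      top-5 stability tables per variant
      figures/         optional BIC-curve / metric-bar plots
      logs/run.log     per-replicate chosen penalty, support size, failures

Two runs with identical configuration produce bit-identical CSVs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .data import ClusteredDataset, GAUSSIAN, BINOMIAL
from .evaluation import ExperimentResult, make_subsamples, run_experiment
from .preprocess import prepare_global
from .synthetic import ScenarioConfig
from .tuning import CRITERIA, CV_1SE, HOSPS_RANDOM, VARIANTS

SCENARIOS = {
    "los": synthetic.los_scenario,
    "mortality": synthetic.mortality_scenario,
    "confounded": synthetic.confounded_scenario,
    "recovery": synthetic.recovery_scenario,
}


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    input: str = "los"                       # scenario name or CSV path
    outcome_family: str = GAUSSIAN           # used when input is a CSV
    variants: tuple[str, ...] = ("no_hosps", "hosps_fixed", "hosps_random")
    criteria: tuple[str, ...] = ("cv_min", "cv_1se", "aic", "bic")
    estimator: str = "classic"
    alpha: float = 1.0
    R: int = 20
    seed: int = 0                            # expands into the three sub-seeds
    split_seed: int | None = None
    cv_seed: int | None = None
    data_seed: int | None = None
    output_dir: str = "clusterlasso_run"
    population_subsample_fraction: float | None = None
    between_effect: float | None = None      # confounded scenario only
    allow_1se_mixed: bool = False
    make_figures: bool = False

    def validate(self) -> None:
        if not self.variants:
            raise RunConfigError("variants: must not be empty")
        if not self.criteria:
            raise RunConfigError("criteria: must not be empty")
        for v in self.variants:
            if v not in VARIANTS:
                raise RunConfigError(f"variants: unknown variant {v!r}")
        for c in self.criteria:
            if c not in CRITERIA:
                raise RunConfigError(f"criteria: unknown criterion {c!r}")
        if self.estimator not in ("classic", "post"):
            raise RunConfigError(f"estimator: unknown value {self.estimator!r}")
        if not (0 < self.alpha <= 1):
            raise RunConfigError("alpha: must be in (0, 1]")
        if self.R < 1:
            raise RunConfigError("R: need at least one replicate")
        if self.outcome_family not in (GAUSSIAN, BINOMIAL):
            raise RunConfigError(
                f"outcome_family: unknown family {self.outcome_family!r}"
            )
        frac = self.population_subsample_fraction
        if frac is not None and not (0 < frac <= 1):
            raise RunConfigError(
                "population_subsample_fraction: must be in (0, 1]"
            )
        only_mixed = set(self.variants) == {HOSPS_RANDOM}
        if (
            only_mixed
            and set(self.criteria) == {CV_1SE}
            and not self.allow_1se_mixed
        ):
            raise RunConfigError(
                "criteria: cv_1se is not offered for hosps_random "
                "(set allow_1se_mixed to override)"
            )

    def expanded_seeds(self) -> tuple[int, int, int]:
        """(split_seed, cv_seed, data_seed), derived from the top-level seed
        where not given explicitly."""
        derived = [
            int(s % (2**31))
            for s in np.random.SeedSequence(self.seed).generate_state(3)
        ]
        return (
            self.split_seed if self.split_seed is not None else derived[0],
            self.cv_seed if self.cv_seed is not None else derived[1],
            self.data_seed if self.data_seed is not None else derived[2],
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["variants"] = list(self.variants)
        d["criteria"] = list(self.criteria)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("variants", "criteria"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_input(config: RunConfig) -> tuple[ClusteredDataset, ScenarioConfig | None]:
    """Resolve the input field into a dataset."""
    _, _, data_seed = config.expanded_seeds()
    if config.input in SCENARIOS:
        scen = SCENARIOS[config.input](seed=data_seed)
        if config.input == "confounded":
            be = 1.0 if config.between_effect is None else config.between_effect
            data = synthetic.generate_confounded_scenario(scen, be)
        else:
            data = synthetic.generate(scen)
        return data, scen
    path = Path(config.input)
    if not path.exists():
        raise RunConfigError(
            f"input: {config.input!r} is neither a known scenario "
            f"({sorted(SCENARIOS)}) nor an existing file"
        )
    return ClusteredDataset.from_csv(path, family=config.outcome_family), None


def run(config: RunConfig) -> ExperimentResult:
    """Execute the configured experiment and write the artifact tree."""
    config.validate()
    split_seed, cv_seed, data_seed = config.expanded_seeds()
    out = Path(config.output_dir)
    for sub in ("data", "metrics", "importance", "figures", "logs"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    data, scen = load_input(config)

    if config.population_subsample_fraction is not None:
        rng = np.random.default_rng(data_seed + 1)
        m = int(round(config.population_subsample_fraction * data.n))
        rows = np.sort(rng.choice(data.n, size=m, replace=False))
        data = data.subset_rows(rows)

    data.to_csv(out / "data" / "dataset.csv")
    if scen is not None:
        scen.to_yaml(out / "data" / "scenario.yaml")

    prepared, report = prepare_global(data)
    report.to_json(out / "data" / "preprocess_report.json")

    splits = make_subsamples(prepared, R=config.R, seed=split_seed)
    result = run_experiment(
        prepared,
        variants=list(config.variants),
        criteria=list(config.criteria),
        splits=splits,
        alpha=config.alpha,
        estimator=config.estimator,
        cv_seed=cv_seed,
        allow_1se_mixed=config.allow_1se_mixed,
    )

    # artifacts
    config.to_yaml(out / "config.yaml")
    result.metrics.to_csv(out / "metrics" / "metrics.csv", index=False)
    result.aggregate.to_csv(out / "metrics" / "aggregate.csv", index=False)
    for variant, table in result.importance.items():
        df = table.table.copy()
        df["formatted"] = table.formatted()
        df.to_csv(out / "importance" / f"importance_{variant}.csv")

    import importlib.metadata as md

    manifest = {
        "config_hash": config.content_hash(),
        "seeds": {
            "seed": config.seed,
            "split_seed": split_seed,
            "cv_seed": cv_seed,
            "data_seed": data_seed,
        },
        "n_rows": int(data.n),
        "n_predictors_prepared": int(prepared.p),
        "split_checksums": result.split_checksums,
        "versions": {
            pkg: md.version(pkg) for pkg in ("numpy", "scipy", "pandas")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    with open(out / "logs" / "run.log", "w") as fh:
        fh.write(f"run completed in {time.time() - t0:.1f}s\n")
        pivot = result.metrics[
            result.metrics.metric.isin(["chosen_lambda", "n_selected"])
        ]
        for _, row in pivot.iterrows():
            fh.write(
                f"replicate={row.replicate} variant={row.variant} "
                f"criterion={row.criterion} {row.metric}={row.value:.6g}\n"
            )
        for msg in result.failures:
            fh.write(f"FAILED: {msg}\n")

    if config.make_figures:
        _write_figures(result, out / "figures", data.family)
    return result


def _write_figures(result: ExperimentResult, figdir: Path, family: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    headline = "rmse" if family == GAUSSIAN else "auc"
    agg = result.aggregate
    sub = agg[agg.metric == headline]
    if len(sub):
        fig, ax = plt.subplots(figsize=(8, 4))
        labels = [f"{v}\n{c}" for v, c in zip(sub.variant, sub.criterion)]
        ax.bar(labels, sub["mean"], yerr=sub["sd"], capsize=3)
        ax.set_ylabel(headline.upper())
        ax.set_title(f"{headline.upper()} by variant and criterion (mean, SD bars)")
        fig.tight_layout()
        fig.savefig(figdir / f"{headline}_by_variant.png", dpi=120)
        plt.close(fig)
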