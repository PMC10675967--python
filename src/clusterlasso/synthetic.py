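"""Synthetic clustered hospital data.

Inpatient administrative records of the kind this pipeline targets are
access-restricted, so it is exercised on generated data that reproduce
their statistical structure: unequal hospital sizes, ~30
Elixhauser-style binary comorbidity indicators, a "planned admission"
indicator whose prevalence is structurally confounded with the hospital
(a share of hospitals admit no elective patients at all, another share only
elective patients), a per-hospital random intercept on the link scale, and
either a positively skewed positive continuous outcome (length of stay,
log-normal around the linear predictor) or a rare binary outcome
(in-hospital mortality, 3-7% prevalence).

The predictor layout is fixed: column 0 is ``planned_admission``, columns
1..K are ``comorb_01`` .. ``comorb_K``. ``beta_true`` is aligned with that
layout (entry 0 = planned admission).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .data import ClusteredDataset, GAUSSIAN, BINOMIAL

GAUSSIAN_LOG = "gaussian-log"
OUTCOME_FAMILIES = (GAUSSIAN_LOG, BINOMIAL)


class ConfigError(ValueError):
    """A scenario configuration field violates its invariants."""


def _logistic(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class ScenarioConfig:
    """Generative quantities for one synthetic hospital scenario.

    Attributes
    ----------
    n_hospitals : int
        Number of clusters (>= 2).
    hospital_size_range : tuple of int
        (min, max) patients per hospital; sizes drawn uniformly.
    n_comorbidity_vars : int
        Number of binary comorbidity indicators.
    comorbidity_prevalence_range : tuple of float
        Per-variable prevalence drawn uniformly in this range.
    beta_true : sequence of float
        Fixed effects on the link scale, length ``1 + n_comorbidity_vars``
        (planned admission first).
    tau : float
        SD of the hospital random intercept on the link scale.
    confound_fractions : tuple of float
        (share of hospitals with 0% planned admissions, share with 100%).
        Remaining hospitals get a prevalence drawn Uniform(0.1, 0.9) so the
        indicator has both within- and between-hospital variance.
    outcome_family : {"gaussian-log", "binomial"}
        gaussian-log emits raw positive y with log(y) linear in eta;
        binomial emits Bernoulli(logistic(eta)).
    base_rate : float
        Intercept on the link scale (for binomial, logit of the baseline
        event probability).
    noise_sd : float
        Residual SD on the log scale (gaussian-log only).
    seed : int
        RNG seed; generation is bit-reproducible given the config.
    """

    n_hospitals: int = 50
    hospital_size_range: tuple[int, int] = (20, 60)
    n_comorbidity_vars: int = 30
    comorbidity_prevalence_range: tuple[float, float] = (0.05, 0.30)
    beta_true: tuple[float, ...] = ()
    tau: float = 0.25
    confound_fractions: tuple[float, float] = (0.15, 0.22)
    outcome_family: str = GAUSSIAN_LOG
    base_rate: float = 2.0
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.beta_true:
            self.beta_true = tuple(0.0 for _ in range(1 + self.n_comorbidity_vars))
        self.beta_true = tuple(float(b) for b in self.beta_true)

    def validate(self) -> None:
        if self.outcome_family not in OUTCOME_FAMILIES:
            raise ConfigError(f"outcome_family: unknown value {self.outcome_family!r}")
        if self.n_hospitals < 2:
            raise ConfigError("n_hospitals: need at least 2 hospitals")
        lo, hi = self.hospital_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("hospital_size_range: need 1 <= min <= max")
        if self.n_comorbidity_vars < 0:
            raise ConfigError("n_comorbidity_vars: must be nonnegative")
        plo, phi = self.comorbidity_prevalence_range
        if not (0.0 < plo <= phi < 1.0):
            raise ConfigError(
                "comorbidity_prevalence_range: need 0 < low <= high < 1"
            )
        if len(self.beta_true) != 1 + self.n_comorbidity_vars:
            raise ConfigError(
                f"beta_true: expected length {1 + self.n_comorbidity_vars} "
                f"(planned admission + comorbidities), got {len(self.beta_true)}"
            )
        f0, f1 = self.confound_fractions
        if f0 < 0 or f1 < 0 or f0 + f1 > 1:
            raise ConfigError(
                "confound_fractions: entries must be nonnegative and sum <= 1"
            )
        if self.tau < 0:
            raise ConfigError("tau: must be nonnegative")
        if self.outcome_family == GAUSSIAN_LOG and self.noise_sd <= 0:
            raise ConfigError("noise_sd: must be positive for gaussian-log")

    @property
    def var_names(self) -> list[str]:
        width = max(2, len(str(self.n_comorbidity_vars)))
        return ["planned_admission"] + [
            f"comorb_{j + 1:0{width}d}" for j in range(self.n_comorbidity_vars)
        ]

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hospital_size_range"] = list(self.hospital_size_range)
        d["comorbidity_prevalence_range"] = list(self.comorbidity_prevalence_range)
        d["beta_true"] = list(self.beta_true)
        d["confound_fractions"] = list(self.confound_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in (
            "hospital_size_range",
            "comorbidity_prevalence_range",
            "beta_true",
            "confound_fractions",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _generate(config: ScenarioConfig, between_effect: float | None) -> ClusteredDataset:
    """Shared generator.

    ``between_effect is None`` is the plain scenario. Otherwise the planned
    admission variable's effect is carried entirely by the hospital
    intercept: its within-hospital coefficient is forced to 0 and each
    hospital's intercept is shifted by ``between_effect`` times the
    hospital's planned-admission prevalence parameter.
    """
    config.validate()
    H = config.n_hospitals
    K = config.n_comorbidity_vars
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(H + 1)
    g = np.random.default_rng(children[0])  # global stream
    hosp_rngs = [np.random.default_rng(c) for c in children[1:]]

    lo, hi = config.hospital_size_range
    sizes = g.integers(lo, hi + 1, size=H)
    plo, phi = config.comorbidity_prevalence_range
    comorb_prev = g.uniform(plo, phi, size=K)

    # planned-admission structural categories: round(f*H) all-zero hospitals,
    # round(f*H) all-one hospitals, chosen at random
    f0, f1 = config.confound_fractions
    n0 = int(round(f0 * H))
    n1 = min(int(round(f1 * H)), H - n0)
    perm = g.permutation(H)
    category = np.full(H, "mid", dtype=object)
    category[perm[:n0]] = "zero"
    category[perm[n0 : n0 + n1]] = "one"

    beta = np.asarray(config.beta_true, dtype=float)
    if between_effect is not None:
        beta = beta.copy()
        beta[0] = 0.0  # planned admission acts only through the intercept

    X_parts, y_parts, labels = [], [], []
    width = max(3, len(str(H)))
    for h in range(H):
        rng = hosp_rngs[h]
        n_h = int(sizes[h])
        b_h = config.tau * rng.standard_normal()
        u = rng.uniform(0.1, 0.9)
        if category[h] == "zero":
            p_h = 0.0
        elif category[h] == "one":
            p_h = 1.0
        else:
            p_h = u
        planned = (rng.uniform(size=n_h) < p_h).astype(float)
        comorb = (rng.uniform(size=(n_h, K)) < comorb_prev).astype(float)
        X_h = np.column_stack([planned, comorb]) if K else planned[:, None]
        eta = config.base_rate + X_h @ beta + b_h
        if between_effect is not None:
            eta = eta + between_effect * p_h
        if config.outcome_family == GAUSSIAN_LOG:
            y_h = np.exp(eta + config.noise_sd * rng.standard_normal(n_h))
        else:
            y_h = (rng.uniform(size=n_h) < _logistic(eta)).astype(float)
        X_parts.append(X_h)
        y_parts.append(y_h)
        labels.append(np.repeat(f"H{h + 1:0{width}d}", n_h))

    family = GAUSSIAN if config.outcome_family == GAUSSIAN_LOG else BINOMIAL
    return ClusteredDataset(
        X=np.vstack(X_parts),
        y=np.concatenate(y_parts),
        cluster=np.concatenate(labels),
        var_names=config.var_names,
        family=family,
    )


def generate(config: ScenarioConfig) -> ClusteredDataset:
    """Draw one clustered dataset from the scenario; deterministic given seed."""
    return _generate(config, between_effect=None)


def generate_confounded_scenario(
    config: ScenarioConfig, between_effect: float
) -> ClusteredDataset:
    """Scenario where planned admission is a purely between-hospital signal.

    The variable's within-hospital coefficient is zero; hospitals that admit
    many elective patients systematically shift the outcome through their
    intercept. A cluster-ignoring model attributes that shift to the
    indicator itself, a random-intercept model absorbs it — the construction
    used to study importance demotion under random effects.
    """
    return _generate(config, between_effect=float(between_effect))


# ---------------------------------------------------------------------------
# Preset scenarios. These are the study conditions used by the test suite,
# the acceptance script and the CLI demo; parameters are chosen to mirror
# the structure of the motivating administrative data (rare mortality,
# log-normal stay, hospital-level ICC a visible but minority share).
# ---------------------------------------------------------------------------

def _beta_with_signals(n_vars: int, signals: dict[int, float]) -> tuple[float, ...]:
    beta = [0.0] * n_vars
    for j, v in signals.items():
        beta[j] = v
    return tuple(beta)


def los_scenario(seed: int = 0, tau: float = 0.25) -> ScenarioConfig:
    """Length-of-stay scenario: log-normal outcome, 5 real comorbidity
    signals plus a modest planned-admission effect."""
    return ScenarioConfig(
        n_hospitals=50,
        hospital_size_range=(20, 60),
        n_comorbidity_vars=30,
        beta_true=_beta_with_signals(
            31, {0: 0.15, 1: 0.40, 2: -0.40, 3: 0.30, 4: -0.30, 5: 0.25}
        ),
        tau=tau,
        outcome_family=GAUSSIAN_LOG,
        base_rate=2.0,
        noise_sd=0.6,
        seed=seed,
    )


def mortality_scenario(seed: int = 0, tau: float = 0.30) -> ScenarioConfig:
    """Rare binary outcome (~5% baseline), a few moderate log-odds effects."""
    base = float(np.log(0.05 / 0.95))
    return ScenarioConfig(
        n_hospitals=50,
        hospital_size_range=(30, 80),
        n_comorbidity_vars=30,
        beta_true=_beta_with_signals(31, {0: 0.2, 1: 0.5, 2: 0.4, 3: -0.4}),
        tau=tau,
        outcome_family=BINOMIAL,
        base_rate=base,
        noise_sd=0.6,
        seed=seed,
    )


def confounded_scenario(seed: int = 0) -> ScenarioConfig:
    """Config for :func:`generate_confounded_scenario` (pair with
    ``between_effect=1.0``): small tau, strong structural planned-admission
    signal, five real comorbidity effects that fill the top-5 ranking once
    the structural signal is absorbed by the hospital intercepts."""
    return ScenarioConfig(
        n_hospitals=60,
        hospital_size_range=(15, 45),
        n_comorbidity_vars=30,
        beta_true=_beta_with_signals(
            31, {1: 0.50, 2: -0.50, 3: 0.40, 4: -0.40, 5: 0.35}
        ),
        tau=0.15,
        confound_fractions=(0.15, 0.22),
        outcome_family=GAUSSIAN_LOG,
        base_rate=2.0,
        noise_sd=0.5,
        seed=seed,
    )


def recovery_scenario(seed: int = 0) -> ScenarioConfig:
    """Support/variance recovery scenario: 60 hospitals of 30-100 patients,
    30 predictors with 5 true nonzero effects, tau=0.3, residual SD 0.5."""
    return ScenarioConfig(
        n_hospitals=60,
        hospital_size_range=(30, 100),
        n_comorbidity_vars=29,
        beta_true=_beta_with_signals(
            30, {0: 0.30, 1: 0.40, 2: -0.40, 3: 0.30, 4: -0.25}
        ),
        tau=0.30,
        outcome_family=GAUSSIAN_LOG,
        base_rate=2.0,
        noise_sd=0.5,
        seed=seed,
    )
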