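"""Synthetic covariance matrices and Monte-Carlo experiments.

Generates data from fusion-true models (the items really do fuse into a
zero-residual scale that alone transmits their effects) and from
deliberately misspecified variants that operationalize the misfit mechanisms
the diagnostics are meant to detect:

* ``bypass`` — one item's true score directly affects a downstream variable;
* ``extra_cause`` — the scale receives an additional cause, either an
  unmodeled ("latent") input, equivalent to a genuine scale residual
  variance, or a named modeled variable;
* ``weighted`` — the world fuses the items with one item's weight scaled,
  while the fitted scale keeps equal weights.

The default topology is a scaled-down mirror of a realistic scale-validation
layout: 3 items, 2 downstream variables, 2 controls, 5% measurement-error
fractions throughout — the same structural features (items -> scale ->
interrelated downstream, controls covarying with the item true scores) at a
fraction of the cost.  Misspecification magnitudes are standardized
(effect = magnitude x sd(source)/sd(target) ... expressed so power is
comparable across loci); sampling draws raw multivariate-normal data and
computes the usual unbiased sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import fit, implied_covariance
from .model import (
    FusionModelSpec,
    MatrixModel,
    PathSpec,
    build_baseline,
    candidate_set,
    declare_model,
)
from .moments import SampleMoments

__all__ = [
    "ScenarioSpec",
    "RecoveryReport",
    "mini_config",
    "mini3_config",
    "mini_scenario",
    "true_sigma",
    "true_model",
    "sample_cov",
    "recovery_experiment",
]

SCENARIO_KINDS = ("fusion_true", "bypass", "extra_cause", "weighted")


@dataclass
class ScenarioSpec:
    """A data-generating scenario: spec + true values + optional perturbation."""

    kind: str
    spec: FusionModelSpec
    values: dict[str, float]
    n_obs: int = 1000
    seed: int = 0
    # perturbation (ignored for fusion_true)
    locus: PathSpec | None = None
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind != "fusion_true":
            if self.kind == "extra_cause" and self.locus is None:
                # unmodeled cause: equivalent to genuine scale residual variance
                s = self.spec.scale.name
                self.locus = PathSpec(s, s, klass="scale_residual")
            if self.locus is None:
                raise ValueError(f"scenario kind {self.kind!r} needs a perturbation locus")
            keys = {c.locus_key() for c in candidate_set(self.spec)}
            if self.locus.locus_key() not in keys:
                raise ValueError(
                    f"perturbation locus {self.locus.locus_key()} is not in the "
                    "diagnostics candidate set"
                )


def mini3_config() -> dict:
    """Mini variant for the extra-cause scenario: three downstream channels
    and *no* free downstream interconnections.

    An unmodeled cause of the scale leaves the item moments and item-by-
    downstream moments untouched; its entire signature is excess covariation
    among the scale's downstream variables.  A free downstream->downstream
    path absorbs exactly that excess, so the residual diagnostic needs
    several unsaturated downstream channels to have power.
    """
    cfg = mini_config()
    cfg["variables"].append({"name": "d3", "role": "downstream", "error_fraction": 0.05})
    cfg["paths"] = [p for p in cfg["paths"] if (p["source"], p["target"]) != ("d1", "d2")]
    cfg["paths"].append({"source": "S", "target": "d3"})
    return cfg


def mini3_true_values() -> dict[str, float]:
    vals = mini_true_values()
    del vals["d1->d2"]
    vals["S->d3"] = 0.35
    vals["var(d3(LV))"] = 0.6
    return vals


def mini_config() -> dict:
    """Declarative config for the mini test topology (3 items, 2 downstream,
    2 controls; 5% error fractions; equal-weight average scale)."""
    return {
        "scale": {"name": "S", "items": ["i1", "i2", "i3"]},
        "variables": [
            {"name": "i1", "role": "scale_item", "error_fraction": 0.05},
            {"name": "i2", "role": "scale_item", "error_fraction": 0.05},
            {"name": "i3", "role": "scale_item", "error_fraction": 0.05},
            {"name": "d1", "role": "downstream", "error_fraction": 0.05},
            {"name": "d2", "role": "downstream", "error_fraction": 0.05},
            {"name": "c1", "role": "control", "error_fraction": 0.05},
            {"name": "c2", "role": "control", "error_fraction": 0.05},
        ],
        "paths": [
            {"source": "S", "target": "d1"},
            {"source": "S", "target": "d2"},
            {"source": "d1", "target": "d2"},
            {"source": "c1", "target": "d1"},
            {"source": "c2", "target": "d2"},
        ],
    }


def mini_true_values() -> dict[str, float]:
    """True parameters of the mini topology: moderate scale effects, modest
    inter-item covariances, weak control effects — a plausible field setting."""
    vals = {
        "S->d1": 0.4,
        "S->d2": 0.3,
        "d1->d2": 0.25,
        "c1->d1": 0.2,
        "c2->d2": 0.2,
        "var(d1(LV))": 0.6,
        "var(d2(LV))": 0.6,
    }
    for it in ("i1", "i2", "i3"):
        vals[f"var({it}(TS))"] = 1.0
    for c in ("c1", "c2"):
        vals[f"var({c}(LV))"] = 1.0
    for a, b in (("i1", "i2"), ("i1", "i3"), ("i2", "i3")):
        vals[f"cov({a}(TS),{b}(TS))"] = 0.3
    vals["cov(c1(LV),c2(LV))"] = 0.2
    for it in ("i1", "i2", "i3"):
        for c in ("c1", "c2"):
            vals[f"cov({it}(TS),{c}(LV))"] = 0.15
    return vals


def mini_scenario(
    kind: str = "fusion_true",
    n_obs: int = 1000,
    seed: int = 0,
    magnitude: float | None = None,
    locus: PathSpec | None = None,
) -> ScenarioSpec:
    """Ready-made scenario on the mini topology.

    Default perturbations: ``bypass`` adds a true i1 -> d2 effect of
    standardized magnitude 0.2; ``weighted`` doubles i1's true fusing weight
    (magnitude = multiplier); ``extra_cause`` adds an unmodeled cause
    contributing variance equal to the scale's baseline variance
    (magnitude 1.0) and runs on the three-downstream variant
    (:func:`mini3_config`) where such a cause is identifiable.
    """
    values = mini_true_values()
    if kind == "extra_cause":
        spec = declare_model(mini3_config())
        values = mini3_true_values()
    else:
        spec = declare_model(mini_config())
    if magnitude is None:
        magnitude = {"bypass": 0.2, "weighted": 2.0, "extra_cause": 1.0}.get(kind, 0.0)
    if locus is None and kind == "bypass":
        locus = PathSpec("i1", "d2", klass="item_bypass")
    if locus is None and kind == "weighted":
        locus = PathSpec("i1", "S", klass="item_weight")
    return ScenarioSpec(
        kind=kind,
        spec=spec,
        values=values,
        n_obs=n_obs,
        seed=seed,
        locus=locus,
        magnitude=magnitude,
    )


# -- forward construction ----------------------------------------------------


def _dummy_moments(spec: FusionModelSpec) -> SampleMoments:
    names = [v.name for v in spec.variables]
    return SampleMoments(names, np.eye(len(names)), max(10 * len(names), 100))


def _assemble(scenario: ScenarioSpec, perturb: bool) -> tuple[MatrixModel, np.ndarray]:
    """Build the true-model matrices and the exactly-implied covariance.

    Proxy error variances are solved so each observed variable carries
    exactly its declared error fraction: e = f/(1-f) x systematic variance.
    """
    spec = scenario.spec
    model = build_baseline(spec, _dummy_moments(spec))
    theta = np.empty(model.n_free)
    for k, f in enumerate(model.free):
        if f.name not in scenario.values:
            raise KeyError(f"no true value provided for parameter {f.name!r}")
        theta[k] = scenario.values[f.name]
    # write true values into the fixed matrices so the model carries them
    model.beta_fixed = model.beta(theta)
    model.psi_fixed = model.psi(theta)
    model.free = []

    # item proxy errors from true-score variances
    for it in spec.items:
        f = spec.variable(it).error_fraction
        i = model.index[it]
        ts = model.index[f"{it}(TS)"]
        model.psi_fixed[i, i] = f / (1.0 - f) * model.psi_fixed[ts, ts] if f < 1 else 0.0
    # control proxy errors from construct variances
    for c in spec.controls:
        f = spec.variable(c).error_fraction
        i = model.index[c]
        lv = model.index[f"{c}(LV)"]
        model.psi_fixed[i, i] = f / (1.0 - f) * model.psi_fixed[lv, lv] if f < 1 else 0.0

    if perturb and scenario.kind != "fusion_true":
        locus = scenario.locus
        mat, i, j = model.path_locus(locus)
        if scenario.kind == "weighted":
            model.beta_fixed[i, j] *= scenario.magnitude
        elif locus.klass == "scale_residual":
            base_var = _latent_variance(model, model.index[spec.scale.name])
            model.psi_fixed[i, i] = scenario.magnitude * base_var
        else:
            sd_src = np.sqrt(_latent_variance(model, j))
            sd_tgt = np.sqrt(_latent_variance(model, i))
            model.beta_fixed[i, j] = scenario.magnitude * sd_tgt / sd_src

    # downstream proxy errors from (possibly perturbed) construct variances
    for d in spec.downstream:
        f = spec.variable(d).error_fraction
        i = model.index[d]
        lv = model.index[f"{d}(LV)"]
        v = _latent_variance(model, lv)
        model.psi_fixed[i, i] = f / (1.0 - f) * v if f < 1 else 0.0

    sigma = implied_covariance(np.empty(0), model)
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        raise ValueError(
            f"scenario implies a non-positive-definite covariance (min eig {eig.min():.3g})"
        )
    return model, sigma


def _latent_variance(model: MatrixModel, idx: int) -> float:
    m = model.beta_fixed.shape[0]
    a = np.linalg.inv(np.eye(m) - model.beta_fixed)
    return float((a @ model.psi_fixed @ a.T)[idx, idx])


def true_model(scenario: ScenarioSpec) -> MatrixModel:
    """Fully-fixed true model (including any perturbation)."""
    return _assemble(scenario, perturb=True)[0]


def true_sigma(scenario: ScenarioSpec) -> np.ndarray:
    """Exactly-implied covariance matrix of the scenario's true model."""
    return _assemble(scenario, perturb=True)[1]


def sample_cov(sigma_true: np.ndarray, n_obs: int, seed: int,
               labels: list[str] | None = None) -> SampleMoments:
    """Sample covariance of ``n_obs`` multivariate-normal draws (ddof 1)."""
    sigma_true = np.asarray(sigma_true, dtype=float)
    p = sigma_true.shape[0]
    if n_obs <= p:
        raise ValueError(f"n_obs={n_obs} must exceed p={p}")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma_true)
    x = rng.standard_normal((n_obs, p)) @ chol.T
    s = np.cov(x, rowvar=False, ddof=1)
    labels = labels or [f"v{i}" for i in range(p)]
    return SampleMoments(list(labels), s, n_obs)


# -- Monte-Carlo experiments -------------------------------------------------


@dataclass
class RecoveryReport:
    """Per-parameter recovery and detection rates across replications."""

    scenario: ScenarioSpec
    params: pd.DataFrame  # true, mean, bias, rmse, mc_se per free parameter
    rejection_rate: float
    mi_detection_rate: float | None
    n_converged: int
    reps: int
    alpha: float
    failures: list[int] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"scenario {self.scenario.kind} (N={self.scenario.n_obs}, "
            f"reps={self.reps}, alpha={self.alpha})",
            f"  converged: {self.n_converged}/{self.reps}",
            f"  baseline rejection rate: {self.rejection_rate:.3f}",
        ]
        if self.mi_detection_rate is not None:
            lines.append(f"  MI detection rate: {self.mi_detection_rate:.3f}")
        lines.append(f"  max |bias| / MC-SE: {self.max_bias_z():.2f}")
        return "\n".join(lines)

    def max_bias_z(self, klass: str | None = None) -> float:
        sub = self.params
        if klass is not None:
            sub = sub[sub["class"] == klass]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (sub["bias"].abs() / sub["mc_se"]).to_numpy()
        return float(np.nanmax(z)) if len(z) else np.nan


def recovery_experiment(
    scenario: ScenarioSpec,
    reps: int = 200,
    alpha: float = 0.05,
    compute_mi: bool | None = None,
) -> RecoveryReport:
    """Fit the *baseline* model to ``reps`` replicates drawn from the scenario.

    Reports per-parameter bias/RMSE against the scenario's true values, the
    baseline chi-square rejection rate at ``alpha``, and (for misspecified
    scenarios) how often the true perturbation locus attains the maximum
    modification index among the scale-confronting candidates.
    Non-convergent replicates are logged and excluded, never fatal.
    Deterministic given (scenario.seed, reps).
    """
    from .diagnostics import modification_indices

    spec = scenario.spec
    sigma = true_sigma(scenario)
    labels = [v.name for v in spec.variables]
    if compute_mi is None:
        compute_mi = scenario.kind != "fusion_true"
    candidates = candidate_set(spec) if compute_mi else []
    target_key = scenario.locus.locus_key() if scenario.locus is not None else None

    rng = np.random.default_rng(scenario.seed)
    seeds = rng.integers(0, 2**31 - 1, size=reps)
    estimates: list[np.ndarray] = []
    rejections = 0
    detections = 0
    failures: list[int] = []
    param_meta = None
    for r in range(reps):
        moments = sample_cov(sigma, scenario.n_obs, int(seeds[r]), labels=labels)
        model = build_baseline(spec, moments)
        if param_meta is None:
            param_meta = [(f.name, f.klass) for f in model.free]
        try:
            res = fit(model, moments)
        except Exception:
            failures.append(r)
            continue
        if not res.converged:
            failures.append(r)
            continue
        estimates.append(res.theta_hat)
        if res.df > 0 and res.p_value < alpha:
            rejections += 1
        if compute_mi:
            mis = [m for m in modification_indices(res, candidates) if np.isfinite(m.mi)]
            if mis and mis[0].locus.locus_key() == target_key:
                detections += 1

    n_ok = len(estimates)
    est = np.array(estimates) if n_ok else np.zeros((0, len(param_meta or [])))
    true_vals = np.array([scenario.values.get(nm, np.nan) for nm, _ in (param_meta or [])])
    mean = est.mean(axis=0) if n_ok else np.full_like(true_vals, np.nan)
    bias = mean - true_vals
    rmse = np.sqrt(((est - true_vals) ** 2).mean(axis=0)) if n_ok else bias
    mc_se = est.std(axis=0, ddof=1) / np.sqrt(n_ok) if n_ok > 1 else np.full_like(bias, np.nan)
    params = pd.DataFrame(
        {
            "parameter": [nm for nm, _ in (param_meta or [])],
            "class": [kl for _, kl in (param_meta or [])],
            "true": true_vals,
            "mean": mean,
            "bias": bias,
            "rmse": rmse,
            "mc_se": mc_se,
        }
    )
    return RecoveryReport(
        scenario=scenario,
        params=params,
        rejection_rate=rejections / n_ok if n_ok else np.nan,
        mi_detection_rate=(detections / n_ok if n_ok else np.nan) if compute_mi else None,
        n_converged=n_ok,
        reps=reps,
        alpha=alpha,
        failures=failures,
    )
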