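"""Declarative fusion-validity model specification and its matrix translation.

A fusion-validity model embeds a researcher-constructed scale among its own
items and theorized downstream/control variables.  The scale is a latent
variable *caused* by the observed items through fixed weights (1/k for an
average scale) and carries no residual: its producing equation is exactly the
arithmetic the researcher used to compute scale scores.  Every observed
variable is modeled as a perfectly-measured latent (loading 1.0, zero
indicator error), which moves all fixed measurement-error variances into the
latent residual covariance matrix Psi.  Each scale item additionally receives
a true-score latent connected to the observed item by a fixed unit effect, so
that item measurement error flows into the scale exactly as it does when real
error-containing item scores are averaged.

The public surface is :func:`declare_model` (validate a declarative config),
:func:`build_baseline` (translate to matrices against a sample covariance),
:func:`add_amendment` / :func:`drop_amendment`, :func:`degrees_of_freedom`
and :func:`candidate_set` (the scale-confronting loci that diagnostics may
query or free).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from fractions import Fraction

import networkx as nx
import numpy as np

from .moments import SampleMoments

__all__ = [
    "VariableDecl",
    "ScaleDefinition",
    "PathSpec",
    "FusionModelSpec",
    "FreeParameter",
    "MatrixModel",
    "declare_model",
    "fixed_error_variance",
    "build_baseline",
    "degrees_of_freedom",
    "add_amendment",
    "drop_amendment",
    "candidate_set",
]

ROLES = ("scale_item", "downstream", "control")
PATH_CLASSES = (
    "scale_effect",
    "downstream_effect",
    "control_effect",
    "item_weight",
    "item_bypass",
    "cause_of_scale",
    "scale_residual",
)


class ModelSpecError(ValueError):
    """Raised when a declarative model description is internally inconsistent."""


@dataclass(frozen=True)
class VariableDecl:
    """An observed variable: its role and fixed measurement-error fraction.

    ``error_fraction`` is the proportion of the *observed sample variance*
    fixed as measurement-error variance before estimation (e.g. 0.05 for a
    5-point Likert item granted 5% error variance).
    """

    name: str
    role: str
    error_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ModelSpecError(f"unknown role {self.role!r} for variable {self.name!r}")
        if not 0.0 <= self.error_fraction <= 1.0:
            raise ModelSpecError(
                f"error_fraction for {self.name!r} must be in [0, 1], got {self.error_fraction}"
            )


@dataclass
class ScaleDefinition:
    """How the scale's values are produced from its items.

    For an average scale every weight is exactly 1/k (kept as an exact
    rational internally; reports round to 3 decimals).  ``residual_variance``
    is fixed at zero unless the researcher knowingly models an incomplete
    scale.  ``from_true_scores`` selects the measurement-error-free variant
    in which the fixed weights emanate from the item true scores instead of
    the observed (error-containing) items.
    """

    name: str
    items: list[str]
    weights: list[float] | None = None
    residual_variance: float = 0.0
    from_true_scores: bool = False

    def __post_init__(self) -> None:
        if not self.items:
            raise ModelSpecError("a scale needs at least one item")
        if self.weights is None:
            k = len(self.items)
            self.weights = [float(Fraction(1, k)) for _ in self.items]
        if len(self.weights) != len(self.items):
            raise ModelSpecError(
                f"scale {self.name!r}: {len(self.weights)} weights for {len(self.items)} items"
            )
        if self.residual_variance < 0:
            raise ModelSpecError("scale residual_variance must be nonnegative")

    @classmethod
    def average(cls, name: str, items: list[str]) -> "ScaleDefinition":
        return cls(name=name, items=list(items))


@dataclass(frozen=True)
class PathSpec:
    """One directed effect: free, fixed at a value, or equality-constrained.

    ``equal`` names an equality group: all paths sharing the label are
    estimated as a single parameter (the identification device for a
    reciprocal pair without instruments).
    """

    source: str
    target: str
    fixed: float | None = None
    equal: str | None = None
    klass: str | None = None

    @property
    def is_free(self) -> bool:
        return self.fixed is None

    def locus_key(self) -> tuple[str, str]:
        return (self.source, self.target)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "free" if self.is_free else f"fixed={self.fixed}"
        return f"{self.source} -> {self.target} [{self.klass}, {status}]"


@dataclass
class FusionModelSpec:
    """Validated declarative description of a fusion-validity model."""

    variables: list[VariableDecl]
    scale: ScaleDefinition
    paths: list[PathSpec]
    exogenous_covariances: str = "default"
    disturbance_covariances: list[tuple[str, str]] = field(default_factory=list)

    # -- convenience views -------------------------------------------------
    @property
    def items(self) -> list[str]:
        return list(self.scale.items)

    def names(self, role: str) -> list[str]:
        return [v.name for v in self.variables if v.role == role]

    @property
    def downstream(self) -> list[str]:
        return self.names("downstream")

    @property
    def controls(self) -> list[str]:
        return self.names("control")

    def variable(self, name: str) -> VariableDecl:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def role_of(self, name: str) -> str:
        if name == self.scale.name:
            return "scale"
        return self.variable(name).role

    def describe(self) -> str:
        """Human-readable listing of the declared structure and free paths."""
        lines = [
            f"Scale {self.scale.name}: "
            + " + ".join(
                f"{w:.3f}*{it}" for w, it in zip(self.scale.weights, self.scale.items)
            ),
            f"  residual variance fixed at {self.scale.residual_variance}",
            f"Items ({len(self.items)}): {', '.join(self.items)}",
            f"Downstream ({len(self.downstream)}): {', '.join(self.downstream)}",
            f"Controls ({len(self.controls)}): {', '.join(self.controls)}",
            "Paths:",
        ]
        lines += [f"  {p}" for p in self.paths]
        return "\n".join(lines)

    # -- validation --------------------------------------------------------
    def validate(self, baseline: bool = True) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ModelSpecError("variable names are not unique")
        if self.scale.name in names:
            raise ModelSpecError(
                f"scale name {self.scale.name!r} collides with an observed variable"
            )
        for it in self.scale.items:
            if it not in names:
                raise ModelSpecError(f"scale item {it!r} is not a declared variable")
            if self.variable(it).role != "scale_item":
                raise ModelSpecError(f"scale item {it!r} must have role 'scale_item'")
        extra_items = set(self.names("scale_item")) - set(self.scale.items)
        if extra_items:
            raise ModelSpecError(f"scale_item variables not used by the scale: {extra_items}")
        if not self.downstream:
            raise ModelSpecError(
                "no downstream variables declared: the scale's effects would be "
                "inestimable (downstream variables make estimation possible)"
            )
        known = set(names) | {self.scale.name}
        for p in self.paths:
            if p.source not in known or p.target not in known:
                raise ModelSpecError(f"path {p} references an undeclared variable")
        for p in self.paths:
            if p.klass not in PATH_CLASSES:
                raise ModelSpecError(f"path {p} has unresolved class {p.klass!r}")
            if baseline and p.klass in ("item_bypass", "cause_of_scale"):
                raise ModelSpecError(
                    f"baseline models exclude {p.klass} paths; found {p}"
                )
            if baseline and p.klass == "item_weight" and p.is_free:
                raise ModelSpecError(f"item weights are fixed in a baseline model: {p}")
        for a, b in self.disturbance_covariances:
            if self.role_of(a) != "downstream" or self.role_of(b) != "downstream":
                raise ModelSpecError(
                    f"disturbance covariance ({a},{b}) must join two downstream variables"
                )

    def to_config(self) -> dict:
        """Serialize back to the declarative config dialect (round-trips)."""
        cfg: dict = {
            "scale": {
                "name": self.scale.name,
                "items": list(self.scale.items),
                "weights": [float(w) for w in self.scale.weights],
                "residual_variance": float(self.scale.residual_variance),
                "from_true_scores": bool(self.scale.from_true_scores),
            },
            "variables": [
                {"name": v.name, "role": v.role, "error_fraction": float(v.error_fraction)}
                for v in self.variables
            ],
            "paths": [],
            "exogenous_covariances": self.exogenous_covariances,
        }
        for p in self.paths:
            d: dict = {"source": p.source, "target": p.target}
            if p.fixed is not None:
                d["fixed"] = float(p.fixed)
            if p.equal is not None:
                d["equal"] = p.equal
            if p.klass is not None:
                d["klass"] = p.klass
            cfg["paths"].append(d)
        if self.disturbance_covariances:
            cfg["disturbance_covariances"] = [list(t) for t in self.disturbance_covariances]
        return cfg


def _infer_klass(spec: FusionModelSpec, p: PathSpec) -> str:
    """Classify a path from the roles of its endpoints."""
    if p.klass is not None:
        return p.klass
    src = spec.role_of(p.source)
    tgt = spec.role_of(p.target)
    if tgt == "scale":
        return "item_weight" if src == "scale_item" else "cause_of_scale"
    if tgt != "downstream":
        raise ModelSpecError(
            f"path target {p.target!r} has role {tgt!r}; only downstream variables "
            "and the scale receive effects"
        )
    if src == "scale":
        return "scale_effect"
    if src == "downstream":
        return "downstream_effect"
    if src == "control":
        return "control_effect"
    # scale_item -> downstream: bypasses originate in the item true score
    return "item_bypass"


def declare_model(config: dict) -> FusionModelSpec:
    """Build and validate a :class:`FusionModelSpec` from a declarative config.

    The config is a plain mapping (typically parsed from YAML by
    :mod:`fusionval.io`) with keys ``scale``, ``variables``, ``paths`` and
    optionally ``exogenous_covariances``/``disturbance_covariances``/
    ``baseline``.  ``scale.weights`` may be the string ``"average"`` (or be
    omitted) for equal 1/k weights.
    """
    sc = dict(config["scale"])
    weights = sc.get("weights", "average")
    if isinstance(weights, str):
        if weights != "average":
            raise ModelSpecError(f"unknown weights rule {weights!r}")
        weights = None
    scale = ScaleDefinition(
        name=sc["name"],
        items=list(sc["items"]),
        weights=None if weights is None else [float(w) for w in weights],
        residual_variance=float(sc.get("residual_variance", 0.0)),
        from_true_scores=bool(sc.get("from_true_scores", False)),
    )
    raw_vars = config["variables"]
    if isinstance(raw_vars, dict):
        raw_vars = [{"name": k, **v} for k, v in raw_vars.items()]
    variables = [
        VariableDecl(v["name"], v["role"], float(v.get("error_fraction", 0.0)))
        for v in raw_vars
    ]
    paths = [
        PathSpec(
            source=p["source"],
            target=p["target"],
            fixed=None if p.get("fixed") is None else float(p["fixed"]),
            equal=p.get("equal"),
            klass=p.get("klass"),
        )
        for p in config.get("paths", [])
    ]
    spec = FusionModelSpec(
        variables=variables,
        scale=scale,
        paths=paths,
        exogenous_covariances=config.get("exogenous_covariances", "default"),
        disturbance_covariances=[
            tuple(t) for t in config.get("disturbance_covariances", [])
        ],
    )
    known = {v.name for v in variables} | {scale.name}
    for p in spec.paths:
        if p.source not in known or p.target not in known:
            raise ModelSpecError(f"path {p.source} -> {p.target} references an undeclared variable")
    spec.paths = [replace(p, klass=_infer_klass(spec, p)) for p in spec.paths]
    seen = set()
    for p in spec.paths:
        if p.locus_key() in seen:
            raise ModelSpecError(f"duplicate path {p.source} -> {p.target}")
        seen.add(p.locus_key())
    spec.validate(baseline=bool(config.get("baseline", True)))
    return spec


def fixed_error_variance(fraction: float, sample_variance: float) -> float:
    """Fixed measurement-error variance: ``fraction`` of the sample variance."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"error fraction must be in [0, 1], got {fraction}")
    if sample_variance < 0:
        raise ValueError(f"sample variance must be nonnegative, got {sample_variance}")
    return fraction * sample_variance


# ---------------------------------------------------------------------------
# Matrix translation
# ---------------------------------------------------------------------------

Locus = tuple[str, int, int]  # ("B" | "Psi", row, col)


@dataclass(frozen=True)
class FreeParameter:
    """One free parameter and the matrix loci it occupies.

    Multiple loci occur for equality-constrained paths; symmetric Psi
    off-diagonals are stored once as (i, j) with i >= j and mirrored when the
    matrix is assembled.
    """

    name: str
    loci: tuple[Locus, ...]
    start: float
    klass: str


@dataclass
class MatrixModel:
    """All-latent coefficient matrices with their free/fixed pattern.

    ``lambda_matrix`` (p x m) carries the fixed unit loadings of the observed
    proxies, ``beta_fixed``/``psi_fixed`` the fixed parts of the latent
    effect and residual-covariance matrices, ``theta_matrix`` (p x p) the
    indicator error variances (all zero by convention), and ``free`` the
    ordered free parameters.
    """

    spec: FusionModelSpec
    obs_names: list[str]
    latent_names: list[str]
    lambda_matrix: np.ndarray
    beta_fixed: np.ndarray
    psi_fixed: np.ndarray
    theta_matrix: np.ndarray
    free: list[FreeParameter]
    index: dict[str, int]
    redefined: bool = False
    warnings: list[str] = field(default_factory=list)

    # -- basic queries -----------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.obs_names)

    @property
    def m(self) -> int:
        return len(self.latent_names)

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def free_index(self) -> list[tuple[str, tuple[Locus, ...]]]:
        return [(f.name, f.loci) for f in self.free]

    @property
    def scale_name(self) -> str:
        return self.spec.scale.name

    @property
    def report_scale_name(self) -> str:
        return ("New-" + self.scale_name) if self.redefined else self.scale_name

    def latent_of(self, name: str, bypass_source: bool = False) -> int:
        """Map a declared name to the latent index acting in structural paths.

        Downstream/control names map to their construct latents; the scale to
        itself; a scale item maps to its true-score latent when
        ``bypass_source`` (bypass effects emanate from true scores), else to
        the observed-item proxy latent.
        """
        if name == self.scale_name:
            return self.index[name]
        role = self.spec.role_of(name)
        if role == "scale_item":
            return self.index[_ts(name) if bypass_source else name]
        return self.index[_lv(name)]

    def start_vector(self) -> np.ndarray:
        return np.array([f.start for f in self.free])

    def beta(self, theta: np.ndarray) -> np.ndarray:
        b = self.beta_fixed.copy()
        for val, f in zip(theta, self.free):
            for mat, i, j in f.loci:
                if mat == "B":
                    b[i, j] = val
        return b

    def psi(self, theta: np.ndarray) -> np.ndarray:
        ps = self.psi_fixed.copy()
        for val, f in zip(theta, self.free):
            for mat, i, j in f.loci:
                if mat == "Psi":
                    ps[i, j] = val
                    ps[j, i] = val
        return ps

    def free_locus_keys(self) -> set[Locus]:
        return {loc for f in self.free for loc in f.loci}

    def param(self, name: str) -> FreeParameter:
        for f in self.free:
            if f.name == name:
                return f
        raise KeyError(name)

    def structural_graph(self, theta: np.ndarray | None = None) -> nx.DiGraph:
        """Directed graph of all (fixed + free) latent-level effects."""
        b = self.beta(theta) if theta is not None else self.beta(self.start_vector())
        g = nx.DiGraph()
        g.add_nodes_from(self.latent_names)
        rows, cols = np.nonzero(self.beta_fixed)
        for i, j in zip(rows, cols):
            g.add_edge(self.latent_names[j], self.latent_names[i])
        for f in self.free:
            for mat, i, j in f.loci:
                if mat == "B":
                    g.add_edge(self.latent_names[j], self.latent_names[i])
        del b
        return g

    def path_locus(self, path: PathSpec) -> Locus:
        """Matrix locus of a structural path (or the scale residual)."""
        if path.klass == "scale_residual":
            s = self.index[self.scale_name]
            return ("Psi", s, s)
        src_is_bypass = path.klass == "item_bypass"
        j = self.latent_of(path.source, bypass_source=src_is_bypass)
        if path.klass == "item_weight":
            # weight loci sit where the scale's producing equation puts them
            j = self.index[
                _ts(path.source) if self.spec.scale.from_true_scores else path.source
            ]
        i = self.latent_of(path.target)
        return ("B", i, j)


def _ts(item: str) -> str:
    return f"{item}(TS)"


def _lv(name: str) -> str:
    return f"{name}(LV)"


def _path_param_name(path: PathSpec) -> str:
    if path.klass == "scale_residual":
        return f"resid({path.source})"
    src = f"{path.source}(TS)" if path.klass == "item_bypass" else path.source
    return f"{src}->{path.target}"


def build_baseline(spec: FusionModelSpec, moments: SampleMoments) -> MatrixModel:
    """Translate a declarative spec into the all-latent matrix model.

    Fixed entries: unit true-score->item and construct->proxy effects, the
    scale's item weights, and every measurement-error variance computed as
    ``error_fraction x observed sample variance``.  Free entries: all
    declared structural paths, the exogenous covariance blocks (item true
    scores, controls, and their cross block under the default pattern) and
    the downstream disturbance variances.  Start values follow the
    indicatorless-latent recipe: exogenous moments start at the corresponding
    observed moments (minus fixed error on the diagonal) and free effects at
    a small nonzero value.
    """
    spec.validate(baseline=False)
    obs = [v.name for v in spec.variables]
    missing = [x for x in obs if x not in moments.labels]
    if missing:
        raise ModelSpecError(f"variables absent from the covariance matrix: {missing}")
    mom = moments.reorder(obs)

    items = spec.items
    downstream = spec.downstream
    controls = spec.controls
    latents = (
        list(obs)
        + [_ts(it) for it in items]
        + [_lv(x) for x in downstream + controls]
        + [spec.scale.name]
    )
    index = {name: k for k, name in enumerate(latents)}
    p, m = len(obs), len(latents)

    lam = np.zeros((p, m))
    for i, name in enumerate(obs):
        lam[i, index[name]] = 1.0
    beta = np.zeros((m, m))
    psi = np.zeros((m, m))
    theta = np.zeros((p, p))

    s_index = index[spec.scale.name]
    psi[s_index, s_index] = spec.scale.residual_variance

    # fixed measurement structure + error variances (as Psi of the proxies)
    for v in spec.variables:
        err = fixed_error_variance(v.error_fraction, mom.variance(v.name))
        i = index[v.name]
        psi[i, i] = err
        if v.role == "scale_item":
            beta[i, index[_ts(v.name)]] = 1.0
        else:
            beta[i, index[_lv(v.name)]] = 1.0

    # the scale's producing equation: fixed weights from the (observed) items
    for it, w in zip(items, spec.scale.weights):
        src = _ts(it) if spec.scale.from_true_scores else it
        beta[s_index, index[src]] = float(w)

    free: list[FreeParameter] = []

    # structural paths
    equal_groups: dict[str, list[Locus]] = {}
    equal_meta: dict[str, tuple[str, str]] = {}
    mm_stub = MatrixModel(spec, obs, latents, lam, beta, psi, theta, [], index)
    for path in spec.paths:
        locus = mm_stub.path_locus(path)
        if path.fixed is not None:
            mat, i, j = locus
            if mat == "B":
                beta[i, j] = path.fixed
            else:
                psi[i, j] = psi[j, i] = path.fixed
            continue
        if path.equal is not None:
            equal_groups.setdefault(path.equal, []).append(locus)
            equal_meta.setdefault(path.equal, (path.klass, _path_param_name(path)))
            continue
        free.append(
            FreeParameter(_path_param_name(path), (locus,), 0.05, path.klass)
        )
    for label, loci in equal_groups.items():
        klass, name0 = equal_meta[label]
        free.append(FreeParameter(f"equal:{label}", tuple(loci), 0.05, klass))

    # exogenous covariance blocks
    def exo_var(name: str, latent: str, fraction: float) -> FreeParameter:
        i = index[latent]
        start = (1.0 - fraction) * mom.variance(name)
        return FreeParameter(f"var({latent})", (("Psi", i, i),), start, "exog_var")

    def exo_cov(na: str, la: str, nb: str, lb: str) -> FreeParameter:
        i, j = index[la], index[lb]
        if i < j:
            i, j = j, i
        start = float(mom.s_matrix[obs.index(na), obs.index(nb)])
        return FreeParameter(f"cov({la},{lb})", (("Psi", i, j),), start, "exog_cov")

    if spec.exogenous_covariances not in ("default", "none"):
        raise ModelSpecError(
            f"unknown exogenous covariance pattern {spec.exogenous_covariances!r}"
        )
    exo = [(it, _ts(it), spec.variable(it).error_fraction) for it in items]
    exo += [(c, _lv(c), spec.variable(c).error_fraction) for c in controls]
    for name, latent, frac in exo:
        free.append(exo_var(name, latent, frac))
    if spec.exogenous_covariances == "default":
        for a in range(len(exo)):
            for b in range(a + 1, len(exo)):
                na, la, _ = exo[a]
                nb, lb, _ = exo[b]
                free.append(exo_cov(na, la, nb, lb))

    # downstream disturbances
    for d in downstream:
        i = index[_lv(d)]
        frac = spec.variable(d).error_fraction
        start = (1.0 - frac) * mom.variance(d)
        free.append(FreeParameter(f"var({_lv(d)})", (("Psi", i, i),), start, "disturbance"))
    for a, b in spec.disturbance_covariances:
        i, j = index[_lv(a)], index[_lv(b)]
        if i < j:
            i, j = j, i
        free.append(
            FreeParameter(f"cov({_lv(a)},{_lv(b)})", (("Psi", i, j),), 0.0, "disturbance_cov")
        )

    model = MatrixModel(
        spec=spec,
        obs_names=obs,
        latent_names=latents,
        lambda_matrix=lam,
        beta_fixed=beta,
        psi_fixed=psi,
        theta_matrix=theta,
        free=free,
        index=index,
        redefined=any(p.klass == "cause_of_scale" for p in spec.paths),
    )
    if not mom.is_positive_definite:
        model.warnings.append("input covariance matrix is not positive definite")
    # sanity: (I - B) invertible at start values
    b0 = model.beta(model.start_vector())
    if abs(np.linalg.det(np.eye(m) - b0)) < 1e-12:
        raise ModelSpecError("(I - B) is singular at the start values")
    return model


def degrees_of_freedom(model: MatrixModel, p: int | None = None) -> int:
    """Model degrees of freedom: distinct sample moments minus free parameters."""
    p = model.p if p is None else p
    df = p * (p + 1) // 2 - model.n_free
    if df < 0:
        raise ValueError(
            f"negative degrees of freedom ({df}): the model is over-parameterized"
        )
    return df


def add_amendment(model: MatrixModel, path: PathSpec) -> MatrixModel:
    """Return a new model with ``path`` freed (or its fixed value changed).

    The input model is left untouched.  Freeing a locus reduces df by one.
    If the new edge closes a directed cycle the amendment is flagged in
    ``warnings`` together with the loop members (identification-sensitive
    loci).  Freeing a cause-of-scale path marks the scale as redefined, which
    renames it in all reports.
    """
    if path.klass is None:
        path = replace(path, klass=_infer_klass(model.spec, path))
    new = copy.deepcopy(model)
    locus = new.path_locus(path)
    if locus in new.free_locus_keys():
        raise ModelSpecError(f"locus of {path} is already free")
    if path.fixed is not None:
        mat, i, j = locus
        target = new.beta_fixed if mat == "B" else new.psi_fixed
        target[i, j] = path.fixed
        if mat == "Psi":
            target[j, i] = path.fixed
        return new

    mat, i, j = locus
    current = new.beta_fixed[i, j] if mat == "B" else new.psi_fixed[i, j]
    start = current if path.klass in ("item_weight", "scale_residual") else 0.0
    if mat == "B":
        new.beta_fixed[i, j] = 0.0
    name = _path_param_name(path)
    new.free = list(new.free) + [FreeParameter(name, (locus,), start, path.klass)]

    if path.klass == "cause_of_scale":
        new.redefined = True
        new.warnings.append(
            f"scale redefined: {new.scale_name} now also receives {path.source}; "
            f"reported as New-{new.scale_name}"
        )
    if mat == "B":
        # the new edge src -> tgt closes a cycle iff tgt already reached src
        g_before = model.structural_graph()
        src_latent = new.latent_names[j]
        tgt_latent = new.latent_names[i]
        if src_latent in g_before and nx.has_path(g_before, tgt_latent, src_latent):
            members = nx.shortest_path(g_before, tgt_latent, src_latent)
            edges = list(zip(members[:-1], members[1:])) + [(src_latent, tgt_latent)]
            new.warnings.append(
                f"amendment {path.source}->{path.target} closes a causal loop: "
                + " -> ".join(members + [tgt_latent])
                + "; identification-sensitive loci: "
                + ", ".join(f"{u}->{v}" for u, v in edges)
            )
    # reciprocal-pair warning: both directions free without an equality tie
    if mat == "B":
        rev = ("B", j, i)
        if rev in new.free_locus_keys() and not any(
            len(f.loci) > 1 and locus in f.loci for f in new.free
        ):
            new.warnings.append(
                f"both directions of {path.source}<->{path.target} are free; without an "
                "instrument or equality constraint this pair may be underidentified"
            )
    return new


def drop_amendment(model: MatrixModel, path: PathSpec) -> MatrixModel:
    """Inverse of :func:`add_amendment` for a freed path: re-fix it at its
    original baseline value (zero for paths, the weight for item weights)."""
    if path.klass is None:
        path = replace(path, klass=_infer_klass(model.spec, path))
    new = copy.deepcopy(model)
    locus = new.path_locus(path)
    keep = [f for f in new.free if locus not in f.loci]
    if len(keep) == len(new.free):
        raise ModelSpecError(f"locus of {path} is not free")
    new.free = keep
    mat, i, j = locus
    if path.klass == "item_weight":
        w = model.spec.scale.weights[model.spec.scale.items.index(path.source)]
        new.beta_fixed[i, j] = float(w)
    elif path.klass == "scale_residual":
        new.psi_fixed[i, j] = model.spec.scale.residual_variance
    elif mat == "B":
        new.beta_fixed[i, j] = 0.0
    if path.klass == "cause_of_scale":
        new.redefined = any(f.klass == "cause_of_scale" for f in new.free)
    new.warnings = [w for w in model.warnings]
    return new


def candidate_set(spec: FusionModelSpec) -> list[PathSpec]:
    """Scale-confronting loci a diagnostics pass may query.

    Enumerates every item-bypass locus (k items x m downstream), every
    cause-of-scale locus (controls and downstream variables into the scale),
    the scale's residual-variance locus, and the k item-weight loci —
    excluding loci already present in the spec.  Deterministic lexicographic
    order by (source, target).
    """
    present = {p.locus_key() for p in spec.paths}
    out: list[PathSpec] = []
    for it in spec.items:
        for d in spec.downstream:
            if (it, d) not in present:
                out.append(PathSpec(it, d, klass="item_bypass"))
    for src in spec.controls + spec.downstream:
        if (src, spec.scale.name) not in present:
            out.append(PathSpec(src, spec.scale.name, klass="cause_of_scale"))
    for it in spec.items:
        if (it, spec.scale.name) not in present:
            out.append(PathSpec(it, spec.scale.name, klass="item_weight"))
    if spec.scale.residual_variance == 0.0:
        out.append(PathSpec(spec.scale.name, spec.scale.name, klass="scale_residual"))
    return sorted(out, key=lambda p: (p.source, p.target, p.klass))
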