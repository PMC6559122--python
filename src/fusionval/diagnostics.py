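"""Scale-confronting diagnostics: modification indices, expected parameter
change, standardized residuals, and the baseline-to-amended search.

The modification index for a fixed locus is a univariate score
(Lagrange-multiplier) statistic computed from the gradient and the *full*
extended expected-information matrix at the restricted optimum — not the
diagonal approximation — so that the index approximates the chi-square drop
an actual refit with that locus freed would deliver.  The expected parameter
change (EPC) is the predicted value the parameter would take if freed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .estimate import FitResult, _grad_and_info, fit
from .model import (
    FreeParameter,
    MatrixModel,
    ModelSpecError,
    PathSpec,
    add_amendment,
    candidate_set,
    _path_param_name,
)
from .moments import SampleMoments

__all__ = [
    "ModificationIndex",
    "AmendmentTrace",
    "AmendmentPolicy",
    "modification_indices",
    "standardized_residuals",
    "scale_residual_diagnostic",
    "weight_diagnostics",
    "amend_search",
]


@dataclass(frozen=True)
class ModificationIndex:
    """Score-test estimate of the chi-square drop from freeing one locus."""

    locus: PathSpec
    mi: float
    epc: float
    note: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.locus.source}->{self.locus.target}: MI={self.mi:.2f} EPC={self.epc:.3f}"


def _candidate_parameter(model: MatrixModel, path: PathSpec) -> FreeParameter:
    locus = model.path_locus(path)
    return FreeParameter(_path_param_name(path), (locus,), 0.0, path.klass or "candidate")


def modification_indices(
    fit_result: FitResult, candidates: list[PathSpec]
) -> list[ModificationIndex]:
    """Univariate score statistics and EPCs for currently-fixed loci.

    Candidates whose locus is already free are excluded with a notice;
    candidates whose score variance is (numerically) zero are unidentifiable
    when freed singly and are likewise excluded.  Sorted descending by MI,
    ties broken lexicographically by (source, target).
    """
    model = fit_result.model
    theta = fit_result.theta_hat
    s = fit_result.moments.s_matrix
    mult = fit_result.moments.n_obs - (1 if fit_result.chi2_multiplier == "n-1" else 0)

    free_keys = model.free_locus_keys()
    kept: list[PathSpec] = []
    notes: list[ModificationIndex] = []
    for c in candidates:
        if model.path_locus(c) in free_keys:
            notes.append(
                ModificationIndex(c, np.nan, np.nan, "excluded: locus already free")
            )
        else:
            kept.append(c)
    if not kept:
        return notes

    ext = list(model.free) + [_candidate_parameter(model, c) for c in kept]
    grad, info = _grad_and_info(model, theta, s, params=ext)
    q = model.n_free
    e_ff = info[:q, :q]
    out: list[ModificationIndex] = []
    scale_e = float(np.mean(np.diag(e_ff))) or 1.0
    try:
        e_ff_inv = np.linalg.inv(e_ff + 1e-12 * scale_e * np.eye(q))
    except np.linalg.LinAlgError:
        e_ff_inv = np.linalg.pinv(e_ff)
    for k, c in enumerate(kept):
        g_c = grad[q + k]
        e_cc = info[q + k, q + k]
        e_cf = info[q + k, :q]
        schur = float(e_cc - e_cf @ e_ff_inv @ e_cf)
        if schur <= 1e-10 * max(e_cc, 1.0):
            out.append(
                ModificationIndex(
                    c, np.nan, np.nan, "excluded: parameter unidentified when freed"
                )
            )
            continue
        mi = 0.5 * mult * g_c**2 / schur
        epc = -g_c / schur
        out.append(ModificationIndex(c, float(mi), float(epc)))
    scored = [m for m in out if np.isfinite(m.mi)]
    excluded = [m for m in out if not np.isfinite(m.mi)]
    scored.sort(key=lambda m: (-m.mi, m.locus.source, m.locus.target))
    return scored + excluded + notes


def standardized_residuals(fit_result: FitResult, moments: SampleMoments) -> np.ndarray:
    """Residual covariances (s_ij - sigma_ij) over their asymptotic errors.

    The variance of a residual moment is the sampling variance of s_ij minus
    the variance absorbed by the fitted moment (delta method through the
    free parameters); entries where that difference is numerically zero or
    negative (e.g. exactly-reproduced moments) are reported as zero when the
    raw residual is itself negligible.
    """
    model = fit_result.model
    mom = moments.reorder(model.obs_names)
    s = mom.s_matrix
    sigma = fit_result.implied_sigma
    n = mom.n_obs
    resid = s - sigma

    from .estimate import _dsigma_stack

    dsig = _dsigma_stack(model, fit_result.theta_hat, model.free)
    _, info = _grad_and_info(model, fit_result.theta_hat, s)
    scale_e = float(np.mean(np.diag(info))) or 1.0
    try:
        acov = (2.0 / (n - 1)) * np.linalg.inv(info + 1e-12 * scale_e * np.eye(len(info)))
    except np.linalg.LinAlgError:
        acov = (2.0 / (n - 1)) * np.linalg.pinv(info)
    # var(sigma_hat_ij) = sum_kl dSig_k[i,j] acov_kl dSig_l[i,j]
    var_fitted = np.einsum("kij,kl,lij->ij", dsig, acov, dsig)
    var_s = (np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / (n - 1)
    var_resid = var_s - var_fitted
    denom = np.sqrt(np.clip(var_resid, 0.0, None))
    tiny = denom <= np.sqrt(var_s) * 1e-6
    out = np.zeros_like(resid)
    ok = ~tiny
    out[ok] = resid[ok] / denom[ok]
    # a moment fitted essentially perfectly has a ~0/0 ratio; report 0 unless
    # the raw residual is non-negligible, then fall back to the sampling SD
    big = tiny & (np.abs(resid) > 1e-8 * np.sqrt(np.outer(np.diag(s), np.diag(s))))
    out[big] = resid[big] / np.sqrt(var_s[big])
    return out


def scale_residual_diagnostic(fit_result: FitResult) -> ModificationIndex:
    """MI/EPC for freeing the scale's fixed-zero residual variance.

    A substantial index suggests some unmodeled variable may be fusing with
    the modeled scale items (or that the downstream variables share other
    unmodeled common causes).
    """
    model = fit_result.model
    scale = model.spec.scale.name
    path = PathSpec(scale, scale, klass="scale_residual")
    if model.path_locus(path) in model.free_locus_keys():
        raise ModelSpecError("the scale residual variance is already free")
    res = modification_indices(fit_result, [path])
    m = res[0]
    return ModificationIndex(
        m.locus,
        m.mi,
        m.epc,
        "a substantial index here suggests an unidentified variable may be "
        "fusing with the modeled scale items",
    )


def weight_diagnostics(fit_result: FitResult) -> list[ModificationIndex]:
    """MI/EPC for each fixed item-weight locus of the scale.

    Large indices recommend a (re)weighted scale.  With a single item the
    weight is unidentifiable (collinear with the scale's effects) and is
    excluded by the score-variance check.
    """
    spec = fit_result.model.spec
    paths = [
        PathSpec(it, spec.scale.name, klass="item_weight") for it in spec.scale.items
    ]
    return modification_indices(fit_result, paths)


@dataclass
class AmendmentPolicy:
    """Policy knobs for the sequential amendment search."""

    alpha: float = 0.05
    mi_threshold: float = 3.84
    max_additions: int = 6
    allow_loops: bool = False
    sign_filter: str | None = None  # None or "positive" / "negative" on EPC
    interactive: object | None = None  # callable(ModificationIndex) -> bool


@dataclass
class AmendmentStep:
    locus: PathSpec
    mi: float
    epc: float
    chi2_before: float
    chi2_after: float
    df_before: int
    df_after: int
    realized: float
    flags: list[str] = field(default_factory=list)


@dataclass
class AmendmentTrace:
    steps: list[AmendmentStep]
    final: FitResult
    status: str  # "baseline_ok" | "resolved" | "unresolved" | "max_additions"

    def summary(self) -> str:
        lines = [f"amendment search: {self.status}"]
        for s in self.steps:
            lines.append(
                f"  + {s.locus.source}->{s.locus.target} "
                f"(MI {s.mi:.1f}, EPC {s.epc:.3f}, realized {s.realized:.3f}): "
                f"chi2 {s.chi2_before:.1f}/df {s.df_before} -> "
                f"{s.chi2_after:.1f}/df {s.df_after}"
                + ("  [" + "; ".join(s.flags) + "]" if s.flags else "")
            )
        lines.append(
            f"  final: chi2 {self.final.chi_square:.1f}, df {self.final.df}, "
            f"p {self.final.p_value:.3f}"
        )
        return "\n".join(lines)


def _would_close_loop(model: MatrixModel, path: PathSpec) -> bool:
    locus = model.path_locus(path)
    if locus[0] != "B":
        return False
    g = model.structural_graph()
    src = path.source if path.klass != "item_bypass" else f"{path.source}(TS)"
    tgt = path.target
    # edge source -> target closes a loop iff target already reaches source
    tgt_l = model.latent_names[locus[1]]
    src_l = model.latent_names[locus[2]]
    return nx.has_path(g, tgt_l, src_l)


def amend_search(
    baseline_fit: FitResult,
    candidates: list[PathSpec] | None = None,
    policy: AmendmentPolicy | None = None,
) -> AmendmentTrace:
    """Greedy sequential freeing of the top admissible modification index.

    Starting from a (typically failing) baseline fit, repeatedly frees the
    scale-confronting candidate with the largest MI above the threshold,
    refits, and stops when the fit p-value reaches ``policy.alpha``, the
    candidate ledger is exhausted, or ``max_additions`` is reached.
    Loop-closing candidates are skipped unless ``allow_loops`` (when enabled,
    stability of the reduced form is checked after each refit).  EPC signs
    are only *flagged* — a program cannot vet theoretical palatability; use
    ``policy.interactive`` (a callable receiving the ModificationIndex and
    returning accept/reject) to keep the human in the loop.
    """
    policy = policy or AmendmentPolicy()
    if candidates is None:
        candidates = candidate_set(baseline_fit.model.spec)
    remaining = list(candidates)
    steps: list[AmendmentStep] = []
    current = baseline_fit

    if current.p_value >= policy.alpha:
        return AmendmentTrace(steps, current, "baseline_ok")

    while len(steps) < policy.max_additions:
        if current.p_value >= policy.alpha:
            return AmendmentTrace(steps, current, "resolved")
        mis = modification_indices(current, remaining)
        admissible = []
        for m in mis:
            if not np.isfinite(m.mi) or m.mi < policy.mi_threshold:
                continue
            if policy.sign_filter == "positive" and m.epc <= 0:
                continue
            if policy.sign_filter == "negative" and m.epc >= 0:
                continue
            if not policy.allow_loops and _would_close_loop(current.model, m.locus):
                continue
            if policy.interactive is not None and not policy.interactive(m):
                continue
            admissible.append(m)
        if not admissible:
            return AmendmentTrace(steps, current, "unresolved")
        top = admissible[0]
        flags = []
        amended = add_amendment(current.model, top.locus)
        flags += [w for w in amended.warnings if w not in current.model.warnings]
        if top.epc < 0:
            flags.append("negative EPC: counteracts the item's effect via the scale")
        new_fit = fit(amended, current.moments, chi2_multiplier=current.chi2_multiplier)
        if policy.allow_loops:
            b_hat = amended.beta(new_fit.theta_hat)
            rho = float(np.max(np.abs(np.linalg.eigvals(b_hat))))
            if rho >= 1.0:
                flags.append(f"unstable reduced form: spectral radius of B = {rho:.3f}")
        realized = new_fit.theta_hat[-1]
        steps.append(
            AmendmentStep(
                locus=top.locus,
                mi=top.mi,
                epc=top.epc,
                chi2_before=current.chi_square,
                chi2_after=new_fit.chi_square,
                df_before=current.df,
                df_after=new_fit.df,
                realized=float(realized),
                flags=flags,
            )
        )
        remaining = [c for c in remaining if c.locus_key() != top.locus.locus_key()]
        current = new_fit

    status = "resolved" if current.p_value >= policy.alpha else "max_additions"
    return AmendmentTrace(steps, current, status)
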