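"""Direct / indirect / total effect decomposition for items, scale, and
downstream variables.

Every item of an average scale transmits the same indirect effect to a given
downstream variable: the product of the fixed unit true-score-to-item effect,
the fixed weight 1/k, and the scale's estimated direct effect on that
variable.  A freed bypass path adds a direct effect; the item's total effect
is direct plus indirect.  The indirect-via-scale product deliberately uses
the scale's *direct* coefficient on the target (the quantity the fixed-weight
arithmetic composes with); loop-consistent totals over the whole latent
system are available separately via :func:`total_effects` and diverge from
the simple product when the scale sits in a causal loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimate import FitResult

__all__ = [
    "EffectDecomposition",
    "item_indirect_via_scale",
    "decomposition_table",
    "total_effects",
    "total_effects_from_beta",
    "classify_total",
]


@dataclass(frozen=True)
class EffectDecomposition:
    """Per (item, downstream target) effect decomposition row."""

    item: str
    target: str
    indirect_via_scale: float
    direct: float
    total: float
    baseline_indirect: float | None = None
    tag: str = ""


class UnstableLoopError(RuntimeError):
    pass


def _scale_effect(fit: FitResult, target: str) -> float:
    spec = fit.model.spec
    if target not in spec.downstream:
        raise ValueError(f"{target!r} is not a downstream variable of the scale")
    if not any(
        p.klass == "scale_effect" and p.target == target for p in spec.paths
    ):
        raise ValueError(f"no scale effect on {target!r} is present in the model")
    return fit.coefficient(spec.scale.name, target)


def item_indirect_via_scale(fit: FitResult, item: str, target: str) -> float:
    """Indirect effect of an item on a downstream variable through the scale:
    (1.0 true-score-to-item) x (fixed weight w_i) x (scale -> target)."""
    spec = fit.model.spec
    if item not in spec.scale.items:
        raise ValueError(f"{item!r} is not an item of scale {spec.scale.name!r}")
    w = float(spec.scale.weights[spec.scale.items.index(item)])
    return 1.0 * w * _scale_effect(fit, target)


def classify_total(indirect: float, direct: float, tol: float = 0.5) -> str:
    """Tag a bypass row: supplementing / nullifying / reversing.

    Same-signed direct and indirect effects supplement one another; an
    opposing direct effect nullifies the indirect when the net total is small
    (within ``tol`` of the indirect's magnitude) and reverses it otherwise.
    """
    total = direct + indirect
    if direct == 0.0 or np.sign(direct) == np.sign(indirect):
        return "supplementing"
    if abs(total) <= tol * abs(indirect):
        return "nullifying"
    if np.sign(total) != np.sign(indirect):
        return "reversing"
    return "counteracting"


def decomposition_table(
    baseline_fit: FitResult | None, amended_fit: FitResult
) -> list[EffectDecomposition]:
    """One row per freed item-bypass locus in the amended model.

    Reports the item's indirect effect via the scale in the baseline model
    (if a baseline fit is supplied), the amended indirect and direct effects,
    and the total (direct + indirect, exactly), tagged by
    :func:`classify_total`.
    """
    spec = amended_fit.model.spec
    rows: list[EffectDecomposition] = []
    for f in amended_fit.model.free:
        if f.klass != "item_bypass":
            continue
        # parameter names are "item(TS)->target"
        src, target = f.name.split("->")
        item = src.removesuffix("(TS)")
        indirect = item_indirect_via_scale(amended_fit, item, target)
        direct = amended_fit.estimate(f.name)
        base = (
            item_indirect_via_scale(baseline_fit, item, target)
            if baseline_fit is not None
            else None
        )
        rows.append(
            EffectDecomposition(
                item=item,
                target=target,
                indirect_via_scale=indirect,
                direct=direct,
                total=direct + indirect,
                baseline_indirect=base,
                tag=classify_total(indirect, direct),
            )
        )
    return rows


def total_effects_from_beta(beta: np.ndarray) -> np.ndarray:
    """Total-effect matrix (I - B)^-1 - I for a direct-effect matrix B.

    Equals the sum of the powers B + B^2 + ... (effects along paths of every
    length), which converges iff the spectral radius of B is below one.
    """
    beta = np.asarray(beta, dtype=float)
    rho = float(np.max(np.abs(np.linalg.eigvals(beta)))) if beta.size else 0.0
    if rho >= 1.0:
        raise UnstableLoopError(
            f"spectral radius of B is {rho:.3f} >= 1; total effects do not converge"
        )
    m = beta.shape[0]
    return np.linalg.inv(np.eye(m) - beta) - np.eye(m)


def total_effects(fit: FitResult) -> np.ndarray:
    """Latent total-effect matrix (I - B-hat)^-1 - I at the estimates.

    Valid (convergent) only when the loop system is stable; an unstable loop
    raises with the loop listed.
    """
    model = fit.model
    b = model.beta(fit.theta_hat)
    try:
        return total_effects_from_beta(b)
    except UnstableLoopError as exc:
        from .estimate import _loop_report

        raise UnstableLoopError(f"{exc} Loop(s): {_loop_report(model, b)}") from None
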