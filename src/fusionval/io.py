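"""Readers, writers and report rendering.

Covariance dialects:

* ``full_csv`` — a square CSV with a header row of labels and the label as
  the first column of each row; the sample size travels in a leading
  ``# n_obs: <N>`` comment line (or is passed explicitly).
* ``lower_triangular`` — the whitespace dialect used by classic SEM
  programs' CM input: a line ``n_obs <N>``, a line ``labels <name> ...``,
  then one whitespace-separated row per variable with i entries in row i.

Model and scenario configs are YAML documents in the dialect accepted by
:func:`fusionval.model.declare_model`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import AmendmentTrace
from .effects import EffectDecomposition
from .estimate import FitResult
from .model import FusionModelSpec, declare_model
from .moments import SampleMoments

__all__ = [
    "read_covariance",
    "write_covariance",
    "read_model_config",
    "write_model_config",
    "fit_table",
    "estimates_table",
    "decomposition_frame",
    "render_report",
]


def read_covariance(
    path: str | Path, dialect: str = "auto", n_obs: int | None = None
) -> SampleMoments:
    """Read a labeled covariance matrix (full CSV or lower-triangular)."""
    text = Path(path).read_text()
    if dialect == "auto":
        first = text.lstrip().splitlines()[0]
        dialect = (
            "lower_triangular"
            if first.split() and first.split()[0] in ("n_obs", "labels")
            else "full_csv"
        )
    if dialect == "full_csv":
        return _read_full_csv(text, n_obs)
    if dialect == "lower_triangular":
        return _read_lower_triangular(text, n_obs)
    raise ValueError(f"unknown covariance dialect {dialect!r}")


def _read_full_csv(text: str, n_obs: int | None) -> SampleMoments:
    lines = text.splitlines()
    body = []
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if payload.lower().startswith("n_obs"):
                n_obs = int(payload.split(":")[-1].split()[-1])
            continue
        if stripped:
            body.append(ln)
    if n_obs is None:
        raise ValueError("sample size missing: add a '# n_obs: N' line or pass n_obs")
    frame = pd.read_csv(_io.StringIO("\n".join(body)), index_col=0)
    labels = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != labels:
        raise ValueError("row labels do not match column labels")
    return SampleMoments(labels, frame.to_numpy(dtype=float), n_obs)


def _read_lower_triangular(text: str, n_obs: int | None) -> SampleMoments:
    labels: list[str] | None = None
    rows: list[list[float]] = []
    for ln in text.splitlines():
        tok = ln.split()
        if not tok or tok[0].startswith("#"):
            continue
        if tok[0].lower() == "n_obs":
            n_obs = int(tok[1])
        elif tok[0].lower() == "labels":
            labels = tok[1:]
        else:
            rows.append([float(t) for t in tok])
    if labels is None:
        raise ValueError("missing 'labels' line")
    if n_obs is None:
        raise ValueError("missing 'n_obs' line (or pass n_obs explicitly)")
    p = len(labels)
    if len(rows) != p:
        raise ValueError(f"expected {p} triangle rows, found {len(rows)}")
    for i, r in enumerate(rows):
        if len(r) != i + 1:
            raise ValueError(
                f"triangle row {i + 1} ({labels[i]}) has {len(r)} entries, expected {i + 1}"
            )
    s = np.zeros((p, p))
    for i, r in enumerate(rows):
        s[i, : i + 1] = r
    s = s + np.tril(s, -1).T
    return SampleMoments(labels, s, n_obs)


def write_covariance(
    moments: SampleMoments, path: str | Path, dialect: str = "full_csv"
) -> None:
    path = Path(path)
    if dialect == "full_csv":
        buf = [f"# n_obs: {moments.n_obs}"]
        frame = moments.to_frame()
        buf.append(frame.to_csv(float_format="%.10g").rstrip("\n"))
        path.write_text("\n".join(buf) + "\n")
    elif dialect == "lower_triangular":
        lines = [f"n_obs {moments.n_obs}", "labels " + " ".join(moments.labels)]
        for i in range(moments.p):
            lines.append(
                " ".join(f"{moments.s_matrix[i, j]:.10g}" for j in range(i + 1))
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown covariance dialect {dialect!r}")


def read_model_config(path: str | Path) -> FusionModelSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return declare_model(cfg)


def write_model_config(spec: FusionModelSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_config(), fh, sort_keys=False)


# -- report rendering --------------------------------------------------------


def fit_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Model-test table: chi-square (1 decimal), df, p (3 decimals)."""
    rows = [
        {
            "model": name,
            "chi_square": round(r.chi_square, 1),
            "df": r.df,
            "P": round(r.p_value, 3),
        }
        for name, r in fits.items()
    ]
    return pd.DataFrame(rows)


def _pretty_latent(fit: FitResult, name: str) -> str:
    if name == fit.model.scale_name:
        return fit.model.report_scale_name
    return name.removesuffix("(LV)")


def estimates_table(fit: FitResult) -> pd.DataFrame:
    """Estimates matrix: one row per endogenous variable, one column per
    predictor, a star where the coefficient exceeds two standard errors,
    and an R-squared column.  Numbers shown to 3 decimals."""
    spec = fit.model.spec
    endo = spec.downstream + [spec.scale.name]
    frame = pd.DataFrame("", index=[_pretty_latent(fit, e) for e in endo], columns=[])
    for f, est, se, sig in zip(
        fit.model.free, fit.theta_hat, fit.std_errors, fit.significant
    ):
        if f.klass not in (
            "scale_effect",
            "downstream_effect",
            "control_effect",
            "item_bypass",
            "cause_of_scale",
            "item_weight",
        ):
            continue
        for mat, i, j in f.loci:
            tgt = _pretty_latent(fit, fit.model.latent_names[i])
            src = _pretty_latent(fit, fit.model.latent_names[j])
            src = src.removesuffix("(LV)")
            if src.endswith("(TS)"):
                src = "TS " + src.removesuffix("(TS)")
            if src not in frame.columns:
                frame[src] = ""
            frame.loc[tgt, src] = f"{est:.3f}" + ("*" if sig else "")
    r2 = fit.r_squared()
    frame["R2"] = [
        f"{r2.get(e if e == spec.scale.name else e + '(LV)', np.nan):.2f}" for e in endo
    ]
    return frame


def decomposition_frame(rows: list[EffectDecomposition]) -> pd.DataFrame:
    out = []
    for r in rows:
        d = {
            "effect": f"From {r.item} to {r.target}",
            "indirect_via_scale": round(r.indirect_via_scale, 3),
            "direct": round(r.direct, 3),
            "total": round(r.total, 3),
            "tag": r.tag,
        }
        if r.baseline_indirect is not None:
            d = {
                "effect": d["effect"],
                "baseline_indirect": round(r.baseline_indirect, 3),
                **{k: v for k, v in d.items() if k != "effect"},
            }
        out.append(d)
    return pd.DataFrame(out)


def render_report(
    fits: dict[str, FitResult],
    decomposition: list[EffectDecomposition] | None = None,
    trace: AmendmentTrace | None = None,
) -> str:
    """Plain-text report: fit tests, estimates, decomposition, warnings."""
    parts = ["== Model tests ==", fit_table(fits).to_string(index=False)]
    for name, r in fits.items():
        parts += [f"\n== Estimates: {name} ==", estimates_table(r).to_string()]
        if r.warnings:
            parts += ["warnings:"] + [f"  - {w}" for w in r.warnings]
    if decomposition:
        parts += [
            "\n== Effects bypassing the scale ==",
            decomposition_frame(decomposition).to_string(index=False),
        ]
    if trace is not None:
        parts += ["\n== Amendment trace ==", trace.summary()]
    return "\n".join(parts)
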