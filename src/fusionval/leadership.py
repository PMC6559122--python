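"""Worked example: the 6-item Leadership scale of the Alberta Context Tool.

Care aides rate their unit leader on six 5-point items (Feedback, Success,
Calmly, Listens, Mentors, Resolves); the published scale is their average,
so each fixed fusing weight is exactly 1/6.  The scale is embedded among
seven interrelated downstream work-attitude variables and six exogenous
controls.  Items and attitudinal downstream indicators carry 5% fixed
measurement-error variance; controls carry Sex 1%, Age 5%, English 5%,
For-profit 0%, Enough-staff 5%, Aggressive-behaviours 5%.

Structure notes (baseline, both provinces):

* three reciprocal pairs among the downstream variables: Supportive<->Control
  (both directions free — each has excluded predictors acting as
  instruments), Taken<->Talk and LikeHere<->Burnout (each estimated under an
  equality constraint, the identification device for a reciprocal pair
  without instruments);
* the Manitoba variant instead fixes the Control -> Supportive direction at
  -0.150, gaining one degree of freedom (68 vs 67).

The Alberta amendments free four item bypass effects (Feedback->Supportive,
Success->Taken, Calmly->Extra, Mentors->LikeHere) and two causes of the
scale (Staff->Leadership and the loop-closing Extra->Leadership), df 67->61.
Manitoba's amendments are Calmly->Taken and Staff->Leadership, df 68->66.

``synthetic_alberta_moments`` returns a SYNTHETIC covariance matrix: the
original raw covariance data are not distributed with this package, so the
matrix is generated from the amended-model coefficient point values above
combined with invented (but realistic) exogenous moments.  It reproduces the
model *structure* exactly and is suitable for exercising the df bookkeeping,
diagnostics and effect decomposition — not for reproducing published
chi-square values.
"""

from __future__ import annotations

from .model import FusionModelSpec, PathSpec, declare_model
from .moments import SampleMoments

__all__ = [
    "ITEMS",
    "DOWNSTREAM",
    "CONTROLS",
    "alberta_config",
    "alberta_spec",
    "manitoba_spec",
    "alberta_amendments",
    "manitoba_amendments",
    "alberta_amended_coefficients",
    "synthetic_alberta_moments",
]

ITEMS = ["Feedback", "Success", "Calmly", "Listens", "Mentors", "Resolves"]
DOWNSTREAM = ["Supportive", "Control", "Taken", "Talk", "Extra", "LikeHere", "Burnout"]
CONTROLS = ["Sex", "Age", "English", "Profit", "Staff", "Aggressive"]

_CONTROL_ERROR = {
    "Sex": 0.01,
    "Age": 0.05,
    "English": 0.05,
    "Profit": 0.0,
    "Staff": 0.05,
    "Aggressive": 0.05,
}

# baseline structural paths: (source, target, equality-group or None)
_BASELINE_PATHS: list[tuple[str, str, str | None]] = [
    # Supportive
    ("Control", "Supportive", None),
    ("Taken", "Supportive", None),
    ("Talk", "Supportive", None),
    ("Leadership", "Supportive", None),
    ("English", "Supportive", None),
    # Control
    ("Supportive", "Control", None),
    ("Talk", "Control", None),
    ("Leadership", "Control", None),
    # Taken / Talk reciprocal pair (equality-constrained)
    ("Talk", "Taken", "taken_talk"),
    ("Taken", "Talk", "taken_talk"),
    ("Leadership", "Taken", None),
    ("English", "Taken", None),
    ("Leadership", "Talk", None),
    ("English", "Talk", None),
    # Extra
    ("Leadership", "Extra", None),
    ("English", "Extra", None),
    ("Profit", "Extra", None),
    ("Staff", "Extra", None),
    # LikeHere
    ("Supportive", "LikeHere", None),
    ("Control", "LikeHere", None),
    ("Taken", "LikeHere", None),
    ("Talk", "LikeHere", None),
    ("Extra", "LikeHere", None),
    ("Burnout", "LikeHere", "likehere_burnout"),
    ("Leadership", "LikeHere", None),
    ("Age", "LikeHere", None),
    ("English", "LikeHere", None),
    ("Profit", "LikeHere", None),
    ("Staff", "LikeHere", None),
    ("Aggressive", "LikeHere", None),
    # Burnout
    ("Supportive", "Burnout", None),
    ("Control", "Burnout", None),
    ("Taken", "Burnout", None),
    ("Talk", "Burnout", None),
    ("Extra", "Burnout", None),
    ("LikeHere", "Burnout", "likehere_burnout"),
    ("Leadership", "Burnout", None),
    ("Profit", "Burnout", None),
    ("Staff", "Burnout", None),
    ("Aggressive", "Burnout", None),
]


def alberta_config(province: str = "alberta") -> dict:
    """Declarative config of the baseline Leadership model."""
    variables = (
        [{"name": it, "role": "scale_item", "error_fraction": 0.05} for it in ITEMS]
        + [{"name": d, "role": "downstream", "error_fraction": 0.05} for d in DOWNSTREAM]
        + [
            {"name": c, "role": "control", "error_fraction": _CONTROL_ERROR[c]}
            for c in CONTROLS
        ]
    )
    paths = []
    for src, tgt, eq in _BASELINE_PATHS:
        d: dict = {"source": src, "target": tgt}
        if eq:
            d["equal"] = eq
        if province == "manitoba" and (src, tgt) == ("Control", "Supportive"):
            d = {"source": src, "target": tgt, "fixed": -0.150}
        paths.append(d)
    return {
        "scale": {"name": "Leadership", "items": list(ITEMS)},
        "variables": variables,
        "paths": paths,
    }


def alberta_spec() -> FusionModelSpec:
    return declare_model(alberta_config("alberta"))


def manitoba_spec() -> FusionModelSpec:
    """Same structure with Control -> Supportive fixed at -0.150 (the fixed
    direction of the otherwise-underidentified reciprocal pair)."""
    return declare_model(alberta_config("manitoba"))


def alberta_amendments() -> list[PathSpec]:
    """The six amendment loci of the amended Alberta model: four item
    bypasses plus two causes of the scale (one closes a loop via Extra)."""
    return [
        PathSpec("Feedback", "Supportive", klass="item_bypass"),
        PathSpec("Success", "Taken", klass="item_bypass"),
        PathSpec("Calmly", "Extra", klass="item_bypass"),
        PathSpec("Mentors", "LikeHere", klass="item_bypass"),
        PathSpec("Staff", "Leadership", klass="cause_of_scale"),
        PathSpec("Extra", "Leadership", klass="cause_of_scale"),
    ]


def manitoba_amendments() -> list[PathSpec]:
    return [
        PathSpec("Calmly", "Taken", klass="item_bypass"),
        PathSpec("Staff", "Leadership", klass="cause_of_scale"),
    ]


def alberta_amended_coefficients() -> dict[tuple[str, str], float]:
    """Point values of the amended Alberta structural coefficients
    ((source, target) -> unstandardized estimate)."""
    return {
        ("Control", "Supportive"): -0.388,
        ("Taken", "Supportive"): 0.224,
        ("Talk", "Supportive"): 0.148,
        ("Leadership", "Supportive"): 0.473,
        ("English", "Supportive"): 0.236,
        ("Supportive", "Control"): 0.556,
        ("Talk", "Control"): 0.090,
        ("Leadership", "Control"): 0.103,
        ("Talk", "Taken"): 0.167,
        ("Taken", "Talk"): 0.167,
        ("Leadership", "Taken"): 0.455,
        ("English", "Taken"): 0.216,
        ("Leadership", "Talk"): 0.191,
        ("English", "Talk"): -0.145,
        ("Leadership", "Extra"): 0.412,
        ("English", "Extra"): 0.321,
        ("Profit", "Extra"): 0.207,
        ("Staff", "Extra"): 0.242,
        ("Supportive", "LikeHere"): 0.115,
        ("Control", "LikeHere"): 0.120,
        ("Taken", "LikeHere"): 0.141,
        ("Talk", "LikeHere"): 0.032,
        ("Extra", "LikeHere"): 0.083,
        ("Burnout", "LikeHere"): -0.062,
        ("Leadership", "LikeHere"): 0.123,
        ("Age", "LikeHere"): 0.026,
        ("English", "LikeHere"): 0.041,
        ("Profit", "LikeHere"): -0.047,
        ("Staff", "LikeHere"): 0.027,
        ("Aggressive", "LikeHere"): 0.001,
        ("Supportive", "Burnout"): -0.152,
        ("Control", "Burnout"): 0.049,
        ("Taken", "Burnout"): -0.079,
        ("Talk", "Burnout"): -0.086,
        ("Extra", "Burnout"): -0.165,
        ("LikeHere", "Burnout"): -0.062,
        ("Leadership", "Burnout"): -0.098,
        ("Profit", "Burnout"): 0.137,
        ("Staff", "Burnout"): -0.367,
        ("Aggressive", "Burnout"): -0.194,
        # amendments
        ("Feedback", "Supportive"): -0.102,
        ("Success", "Taken"): -0.084,
        ("Calmly", "Extra"): -0.206,
        ("Mentors", "LikeHere"): 0.082,
        ("Staff", "Leadership"): 0.173,
        ("Extra", "Leadership"): 0.099,
    }


def synthetic_alberta_moments(n_obs: int = 700) -> SampleMoments:
    """SYNTHETIC covariance matrix with the amended-Alberta structure.

    Structural coefficients take the point values of
    :func:`alberta_amended_coefficients`; exogenous moments are invented:
    item true scores with unit variance and 0.5 covariances (leadership
    items intercorrelate strongly), unit-variance controls covarying at 0.1
    with each other and with the item true scores, downstream disturbance
    variances of 0.6.  Error fractions are honoured exactly, so fitting the
    amended model to this matrix yields F = 0 at the generating values.
    """
    from .synthetic import ScenarioSpec, true_sigma
    from .model import add_amendment, build_baseline
    from .estimate import implied_covariance

    coefs = alberta_amended_coefficients()

    # assemble an amended *spec* whose extra paths are fixed at the point
    # values, then reuse the forward generator machinery
    cfg = alberta_config("alberta")
    cfg["baseline"] = False
    for p in alberta_amendments():
        cfg["paths"].append(
            {"source": p.source, "target": p.target, "klass": p.klass,
             "fixed": coefs[(p.source, p.target)]}
        )
    spec = declare_model(cfg)

    values: dict[str, float] = {}
    for (src, tgt), v in coefs.items():
        if (src, tgt) in {(p.source, p.target) for p in alberta_amendments()}:
            continue
        values[f"{src}->{tgt}"] = v
    values["equal:taken_talk"] = 0.167
    values["equal:likehere_burnout"] = -0.062
    del values["Talk->Taken"], values["Taken->Talk"]
    del values["Burnout->LikeHere"], values["LikeHere->Burnout"]
    for it in ITEMS:
        values[f"var({it}(TS))"] = 1.0
    for c in CONTROLS:
        values[f"var({c}(LV))"] = 1.0
    exo = [f"{it}(TS)" for it in ITEMS] + [f"{c}(LV)" for c in CONTROLS]
    for a in range(len(exo)):
        for b in range(a + 1, len(exo)):
            both_items = a < len(ITEMS) and b < len(ITEMS)
            values[f"cov({exo[a]},{exo[b]})"] = 0.5 if both_items else 0.1
    for d in DOWNSTREAM:
        values[f"var({d}(LV))"] = 0.6

    scenario = ScenarioSpec(kind="fusion_true", spec=spec, values=values, n_obs=n_obs)
    sigma = true_sigma(scenario)
    return SampleMoments([v.name for v in spec.variables], sigma, n_obs)
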