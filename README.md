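# fusionval

Fusion-validity assessment of researcher-constructed scales via causal
structural equation modeling.

## The problem

A scale score (a sum, average, or weighted combination of items) is produced
by the researcher, so its proximal causes are *known exactly* — which makes
the scores collinear with the items and prevents using both as data in one
model. Fusion validity circumvents this by modeling the scale as a latent
variable caused by its observed items through **fixed** weights (1/k for an
average of k items) and **no residual**, then embedding that segment among
theory-specified downstream and control variables. If the items really do
fuse into a unidimensional entity that alone transmits their effects, the
*baseline* model — scale → downstream effects only, no item-to-downstream
paths, no extra causes of the scale — should fit. Misfit concentrated in
scale-confronting parameters (item effects *bypassing* the scale, additional
causes of the scale, the scale's fixed-zero residual variance, or the fixed
item weights) is evidence against the scale as constructed.

The package is for psychometricians and applied researchers (e.g. health
services research teams validating instruments such as the Alberta Context
Tool's Leadership scale) who want this assessment as a reproducible
computation rather than an interactive LISREL session.

## Model

All observed variables enter as perfectly measured latents (Λ = I, Θ_ε = 0);
fixed measurement-error variances (a declared fraction of each observed
sample variance) live in Ψ. Each scale item additionally gets a true-score
latent connected by a fixed unit effect, so item error flows into the scale
exactly as averaging error-containing items does. With latent effects B and
latent residual covariance Ψ, the implied covariance is

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ_ε

and θ̂ minimizes the normal-theory discrepancy

    F(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p ,

giving χ² = (N−1)·F_min with df = p(p+1)/2 minus the number of free
parameters. Diagnostics are univariate score (Lagrange-multiplier) tests —
modification indices with expected parameter change — computed from the full
extended information matrix, restricted to the scale-confronting candidate
ledger. Effect decomposition follows the fixed arithmetic: an item's
indirect effect on a downstream variable is 1.0 × w_i × (scale→target), its
total effect is direct + indirect, and loop-consistent totals are
(I − B̂)⁻¹ − I.

## Worked example

The packaged Leadership layout (6 items, 7 downstream variables, 6 controls;
19 observed variables) ships with a *synthetic* covariance matrix generated
from the amended-model point values, so the full workflow runs end to end:

```python
import fusionval as fv
from fusionval import leadership as ld

mom = ld.synthetic_alberta_moments(n_obs=2000)
base = fv.fit(fv.build_baseline(ld.alberta_spec(), mom), mom)
print(base.chi_square, base.df)            # 143.7 67  -> baseline fails

amended = base.model
for p in ld.alberta_amendments():          # 4 bypasses + 2 causes of scale
    amended = fv.add_amendment(amended, p)
amf = fv.fit(amended, mom)
print(round(amf.chi_square, 1), amf.df)    # 0.0 61   -> amended fits exactly

print(round(fv.item_indirect_via_scale(amf, "Feedback", "Supportive"), 3))
# 0.079  = 1.0 x (1/6) x 0.473, identical for all six items
rows = fv.decomposition_table(base, amf)
```

The decomposition table prints (values the code actually produced):

```
                     effect  baseline_indirect  indirect_via_scale  direct  total           tag
From Feedback to Supportive              0.066               0.079  -0.102 -0.023    nullifying
      From Success to Taken              0.066               0.076  -0.084 -0.008    nullifying
       From Calmly to Extra              0.036               0.069  -0.206 -0.137     reversing
   From Mentors to LikeHere              0.034               0.020   0.082  0.102 supplementing
```

A negative direct effect that nullifies (Feedback→Supportive) or reverses
(Calmly→Extra) the item's small positive effect through the scale is exactly
the evidence that questions the scale's encapsulation of that item. The two
cause-of-scale amendments (Staff→Leadership, and the loop-closing
Extra→Leadership) redefine the scale, which all reports rename
`New-Leadership`.

The same workflow is available from a shell:

```
fusionval fit   --model model.yaml --cov data.cov
fusionval mi    --model model.yaml --cov data.cov
fusionval amend --model model.yaml --cov data.cov --alpha 0.05 --allow-loops
fusionval simulate --kind bypass --reps 200 --seed 1
```

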