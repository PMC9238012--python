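"""Precorrected phenotypes from the full pedigree animal model.

Before any scenario filtering, the full multi-trait model with fixed
batch effects, non-genetic litter effects, additive animal effects
(pedigree relationships, unknown-parent groups) is fitted once, and
every record is replaced by

    y_c = y - (fixed solutions) - (non-genetic random solutions)
        = u_hat + e_hat,

so the later mean-only evaluations see records carrying only genetic
and residual variation.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import StudyDataset, TraitCovariances
from .mme import EvaluationResult, ModelSpec, assemble_mme, build_relationship, solve_mme


def precorrect_phenotypes(
    data: StudyDataset,
    covs: TraitCovariances,
    fixed_effects: list = ("batch",),
    random_effects: list = ("litter",),
    use_groups: bool = True,
    multi_trait: bool = True,
) -> tuple[pd.DataFrame, EvaluationResult]:
    """Fit the full model and return (precorrected table, fit).

    The returned table keeps the layout of ``data.phenotypes`` with the
    ``value`` column replaced by y_c and an audit column ``subtracted``
    holding the removed non-genetic total.  ``multi_trait=False`` fits
    trait by trait, which drops genetic-correlation information but
    scales to large programs.
    """
    rel, n_groups = build_relationship(data, "PBLUP", use_groups=use_groups)
    phen = data.phenotypes
    results = []
    if multi_trait:
        spec = ModelSpec(
            covariances=covs,
            relationship=rel,
            fixed_effects=list(fixed_effects),
            random_effects=list(random_effects),
            n_groups=n_groups,
        )
        fit = solve_mme(assemble_mme(phen, spec))
        subtracted = fit.fitted_nongenetic(phen)
    else:
        fit = None
        subtracted = pd.Series(0.0, index=phen.index)
        for trait in covs.traits:
            sub = phen[phen["trait"] == trait]
            spec = ModelSpec(
                covariances=covs.subset([trait]),
                relationship=rel,
                fixed_effects=list(fixed_effects),
                random_effects=list(random_effects),
                n_groups=n_groups,
            )
            res = solve_mme(assemble_mme(sub, spec))
            subtracted.loc[sub.index] = res.fitted_nongenetic(sub)
            results.append(res)
            fit = res  # last fit returned for inspection
    out = phen.copy()
    out["subtracted"] = pd.Series(subtracted).to_numpy()
    out["value"] = out["value"] - out["subtracted"]
    return out, fit
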