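"""Cross-mean prediction and leave-one-out cross-validation schemes.

A cross's mean performance is predicted as ``m + D_u + T_v + (DxT)_uv``
from a fit on training data that excludes the cross: BLUPs of unobserved
parents and crosses are obtained by carrying their levels (and genomic
covariances) through the mixed-model equations, so genomic variants borrow
information from relatives while the pedigree-only variant shrinks
unobserved levels to zero.

Four leave-one-out schemes mimic the practical prediction targets:

* ``2x-4x`` — the cross is new, but both parents are observed in other
  crosses;
* ``0-4x``  — the diploid parent is entirely unobserved (all its crosses
  are discarded with the fold), the tetraploid parent is observed;
* ``2x-0``  — the reverse;
* ``0-0``   — neither parent is observed anywhere in training; only genomic
  variants can predict here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crosses import estimate_values
from .kinship import KinshipSet
from .lmm import ConvergenceError, ModelFit
from .models import ModelBundle, build_model
from .tables import StudyTables

SCENARIOS = ("2x-4x", "0-4x", "2x-0", "0-0")
_SCENARIO_ALIASES = {
    "2x4x": "2x-4x", "0x4x": "0-4x", "2x0": "2x-0", "0x0": "0-0",
    "2x-4x": "2x-4x", "0-4x": "0-4x", "2x-0": "2x-0", "0-0": "0-0",
}


class UnsupportedScenarioError(ValueError):
    pass


def predict_cross_means(
    fit: ModelFit,
    bundle: ModelBundle,
    targets: list[tuple[str, str]],
) -> pd.Series:
    """Predicted mean performance of target crosses from a fitted model.

    The prediction is ``m + D_u + T_v + (DxT)_uv`` (the dominance part
    includes its expectation ``-F_uv b``); the within-cross hybrid effect
    has mean zero and does not contribute.
    """
    beta = fit.fixed_effects
    obs = bundle.obs
    blocks = sorted(obs["block_id"].unique())
    cycles = sorted(obs["cycle"].unique())
    m_hat = (beta["intercept"]
             + sum(beta.get(f"block[{b}]", 0.0) for b in blocks) / len(blocks)
             + sum(beta.get(f"cycle[{c}]", 0.0) for c in cycles) / len(cycles))
    coef_F = beta.get("F", 0.0)
    gca2, gca4 = fit.blups["gca2"], fit.blups["gca4"]
    out = {}
    for u, v in targets:
        if u not in gca2.index or v not in gca4.index:
            raise KeyError(
                f"cross ({u}, {v}): parent missing from the model levels; "
                "pedigree-only predictions require parents present in the "
                "pedigree, genomic predictions require genotyped parents"
            )
        pred = m_hat + gca2[u] + gca4[v]
        for part in ("sca", "sca_dom", "sca_epi"):
            if part in fit.blups and (u, v) in fit.blups[part].index:
                pred += fit.blups[part][(u, v)]
        if bundle.F_of_cross:
            pred += coef_F * bundle.F_of_cross.get((u, v), 0.0)
        out[(u, v)] = float(pred)
    return pd.Series(out)


def scenario_folds(
    crosses: pd.DataFrame, scenario: str
) -> list[dict]:
    """Eligible folds of a scenario over a design's cross list.

    ``crosses`` must carry columns ``parent2x_id``, ``parent4x_id``.  Each
    fold holds the target cross, the full exclusion set, and the reason a
    cross is skipped when ineligible.
    """
    scenario = _SCENARIO_ALIASES.get(scenario)
    if scenario is None:
        raise ValueError(f"unknown scenario; use one of {SCENARIOS}")
    pairs = list(zip(crosses["parent2x_id"], crosses["parent4x_id"]))
    folds = []
    for u, v in pairs:
        others = [c for c in pairs if c != (u, v)]
        u_elsewhere = any(c[0] == u for c in others)
        v_elsewhere = any(c[1] == v for c in others)
        if scenario == "2x-4x":
            excluded = [(u, v)]
            ok = u_elsewhere and v_elsewhere
            reason = None if ok else "a parent appears in no other cross"
        elif scenario == "0-4x":
            excluded = [c for c in pairs if c[0] == u]
            ok = any(c[1] == v for c in pairs if c not in excluded)
            reason = None if ok else "4x parent absent from remaining crosses"
        elif scenario == "2x-0":
            excluded = [c for c in pairs if c[1] == v]
            ok = any(c[0] == u for c in pairs if c not in excluded)
            reason = None if ok else "2x parent absent from remaining crosses"
        else:  # 0-0
            excluded = [c for c in pairs if c[0] == u or c[1] == v]
            ok = len(excluded) < len(pairs)
            reason = None if ok else "no training crosses would remain"
        folds.append({
            "target": (u, v), "excluded": excluded, "eligible": ok,
            "reason": reason, "scenario": scenario,
        })
    return folds


@dataclass
class PredictionReport:
    scenario: str
    variant: str
    trait: str
    folds: pd.DataFrame           # target, predicted, observed, n_progeny, ...
    predictive_ability: float
    skipped: pd.DataFrame

    def __repr__(self) -> str:  # compact: the folds table dominates otherwise
        return (f"PredictionReport(scenario={self.scenario!r}, "
                f"variant={self.variant!r}, trait={self.trait!r}, "
                f"n_folds={len(self.folds)}, r={self.predictive_ability:.3f})")


def _training_checksum(bundle: ModelBundle) -> str:
    ids = ",".join(sorted(
        f"{p}|{c}" for p, c in zip(bundle.obs["plant_id"], bundle.obs["cycle"])
    ))
    return hashlib.sha1(ids.encode()).hexdigest()


def loo_cross_validation(
    tables: StudyTables,
    trait: str,
    variant: str = "PHENO",
    scenario: str = "2x-4x",
    kinships: KinshipSet | None = None,
    refit: bool = True,
    observed_values=None,
    min_folds: int = 3,
    **fit_kwargs,
) -> PredictionReport:
    """Leave-one-out cross-validation of cross-mean prediction.

    ``refit=True`` re-estimates every variance parameter within each fold;
    ``refit=False`` reuses the full-data REML estimates and only re-solves
    the mixed-model equations on the fold's training records (fast mode).
    Observed cross means are averages of the full-data clonal values
    (BLUE+BLUP composites from the pedigree-only model) over each cross's
    progeny.  Folds where REML fails fall back to EM-only estimation; a
    persistently failing fold is dropped with a logged reason.
    """
    scenario = _SCENARIO_ALIASES.get(scenario, scenario)
    if variant == "PHENO" and scenario == "0-0":
        raise UnsupportedScenarioError(
            "pedigree-only prediction is undefined when neither parent is "
            "observed in training (scenario 0-0)"
        )
    crosses = tables.crosses
    folds = scenario_folds(crosses, scenario)

    # observed cross means from the full-data pedigree-only fit
    if observed_values is None:
        base_bundle = build_model("PHENO", tables, trait)
        base_fit = base_bundle.fit(**fit_kwargs)
        observed_values = estimate_values(base_fit, base_bundle)
    breed = observed_values.breed()
    observed = breed.groupby(["parent2x_id", "parent4x_id"])["yhat"].mean()
    progeny = breed.groupby(["parent2x_id", "parent4x_id"]).size()

    full_fit = None
    if not refit:
        full_bundle = build_model(variant, tables, trait, kinships)
        full_fit = full_bundle.fit(**fit_kwargs)

    rows, skipped = [], []
    for fold in folds:
        u, v = fold["target"]
        if not fold["eligible"]:
            skipped.append((u, v, fold["reason"]))
            continue
        if (u, v) not in observed.index:
            skipped.append((u, v, "no progeny with an observed mean"))
            continue
        bundle = build_model(variant, tables, trait, kinships,
                             exclude_crosses=fold["excluded"])
        try:
            if refit:
                try:
                    fit = bundle.fit(**fit_kwargs)
                except ConvergenceError:
                    fit = bundle.fit(method="em", **fit_kwargs)
            else:
                fit = bundle.model.solve(full_fit.variances, full_fit.R)
        except Exception as exc:  # persistent failure: drop the fold
            skipped.append((u, v, f"fit failed: {exc}"))
            continue
        pred = predict_cross_means(fit, bundle, [(u, v)])[(u, v)]
        rows.append((u, v, pred, float(observed[(u, v)]),
                     int(progeny[(u, v)]), len(fold["excluded"]),
                     _training_checksum(bundle)))

    folds_df = pd.DataFrame(rows, columns=[
        "parent2x_id", "parent4x_id", "predicted", "observed", "n_progeny",
        "n_excluded_crosses", "training_checksum",
    ])
    if len(folds_df) >= min_folds and folds_df["predicted"].std() > 0:
        r = float(stats.pearsonr(folds_df["predicted"],
                                 folds_df["observed"])[0])
    else:
        r = float("nan")
    return PredictionReport(
        scenario=scenario, variant=variant, trait=trait, folds=folds_df,
        predictive_ability=r,
        skipped=pd.DataFrame(skipped, columns=["parent2x_id", "parent4x_id",
                                               "reason"]),
    )
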