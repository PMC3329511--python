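"""The four-step exploratory analysis and the final grade-shift model.

Step 1 compares adult brain mass and adult female body mass as predictors
of time to weaning (post conception and postnatal) with Model II fits and
a partial correlation.  Step 2 tests for a grade shift between limb
biomechanics categories.  Step 3 stratifies by dietary profile, tests
whether omnivores and herbivores differ (controlling brain mass and limb)
and, if not, pools them against carnivores.  Step 4 fits the full
three-predictor ANCOVA, partitions variance sequentially, leave-one-out
predicts the human time to weaning against the natural-fertility-society
reference mean, and places that reference against the 90% prediction bands
of carnivore-only and non-carnivore-only fits at the human brain mass.

Each step consumes only the trait table (steps are independently
callable) and returns a JSON-serializable :class:`StepReport`.  All
computation is deterministic: running the pipeline twice on the same
inputs yields byte-identical reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .regression_core import (
    PredictionResult,
    RegressionFit,
    RmaFit,
    VariancePartition,
    format_p,
    loo_species_prediction,
    ols_ancova,
    partial_correlation,
    predict_with_interval,
    rma_fit,
    sequential_partition,
)
from .trait_data import TraitTable

FULL_MODEL = dict(response="log_wean_pc", continuous=("log_brain",),
                  dummies=("lb_code", "dp_code"))
DEFAULT_ENTRY_ORDER = ("log_brain", "lb_code", "dp_code")


@dataclass
class StepReport:
    step: str
    fits: dict = field(default_factory=dict)
    partition: VariancePartition | None = None
    prediction: PredictionResult | None = None
    narrative: str = ""
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, (RegressionFit, VariancePartition, PredictionResult)):
                return obj.to_dict()
            if isinstance(obj, RmaFit):
                return {
                    "slope": obj.slope, "intercept": obj.intercept, "r": obj.r,
                    "r_squared": obj.r_squared, "n": obj.n, "p_value": obj.p_value,
                }
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj
        return {
            "step": self.step,
            "fits": convert(self.fits),
            "partition": convert(self.partition) if self.partition else None,
            "prediction": convert(self.prediction) if self.prediction else None,
            "narrative": self.narrative,
            "extras": convert(self.extras),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


# ----------------------------------------------------------------------

def step1_compare_predictors(table: TraitTable) -> StepReport:
    """Brain mass vs body mass as predictors of time to weaning (Model II fits)."""
    if table.n < 10:
        raise ValidationError("predictor comparison needs at least 10 species")
    fits = {
        "wean_pc_vs_brain": rma_fit(table.column("log_brain"), table.column("log_wean_pc")),
        "wean_pc_vs_body": rma_fit(table.column("log_body"), table.column("log_wean_pc")),
        "wean_pn_vs_brain": rma_fit(table.column("log_brain"), table.column("log_wean_pn")),
        "wean_pn_vs_body": rma_fit(table.column("log_body"), table.column("log_wean_pn")),
    }
    r_partial, p_partial = partial_correlation(
        table.column("log_brain"), table.column("log_wean_pc"), table.column("log_body")
    )
    winner = ("brain_mass" if fits["wean_pc_vs_brain"].r_squared
              >= fits["wean_pc_vs_body"].r_squared else "body_mass")
    narrative = (
        f"Brain mass R2={fits['wean_pc_vs_brain'].r_squared:.2f} vs body mass "
        f"R2={fits['wean_pc_vs_body'].r_squared:.2f} for weaning post conception; "
        f"winner by R2: {winner}. Raw brain-weaning r={fits['wean_pc_vs_brain'].r:.2f}, "
        f"partial r={r_partial:.2f} controlling body mass (p={format_p(p_partial)}). "
        f"Post-conception R2 ({fits['wean_pc_vs_brain'].r_squared:.2f}) vs postnatal "
        f"({fits['wean_pn_vs_brain'].r_squared:.2f}) for brain mass."
    )
    return StepReport(
        step="step1_compare_predictors",
        fits=fits,
        narrative=narrative,
        extras={
            "winner": winner,
            "partial_r_brain_weaning_controlling_body": r_partial,
            "partial_p": p_partial,
        },
    )


def step2_grade_shift(table: TraitTable) -> StepReport:
    """ANCOVA test of the limb-biomechanics grade shift in time to weaning."""
    lb = table.column("lb_code")
    if len(np.unique(lb)) < 2:
        raise ValidationError("both limb categories must be represented")
    fit = ols_ancova(table, "log_wean_pc", ["log_brain"], ["lb_code"])
    shift = fit.coefficients["lb_code"]
    narrative = (
        f"Grade shift between limb-biomechanics categories: {shift:+.3f} log10 days "
        f"(non-plantigrade relative to plantigrade), "
        f"F={fit.term_f['lb_code']:.2f}, p={format_p(fit.term_f_p_values['lb_code'])}; "
        f"model R2={fit.r_squared:.2f}. "
        + ("Plantigrade species wean later." if shift < 0
           else "Non-plantigrade species wean later.")
    )
    return StepReport(
        step="step2_grade_shift",
        fits={"ancova_brain_limb": fit},
        narrative=narrative,
        extras={
            "grade_shift_log10_days": shift,
            "grade_shift_se": fit.coefficient_se["lb_code"],
            "grade_shift_f": fit.term_f["lb_code"],
            "grade_shift_p": fit.term_f_p_values["lb_code"],
        },
    )


def step3_diet_effect(table: TraitTable, alpha: float = 0.05) -> StepReport:
    """Dietary-profile effect: per-diet Model II fits, omnivore-vs-herbivore test,
    pooling into a non-carnivore group when they do not differ."""
    df = table.to_frame()
    diets = set(df["diet"])
    if diets != {"carnivore", "omnivore", "herbivore"}:
        raise ValidationError("all three diet categories must be represented")
    per_diet = {}
    for diet in ("carnivore", "omnivore", "herbivore"):
        sub = df[df["diet"] == diet]
        per_diet[f"rma_{diet}"] = rma_fit(sub["log_brain"], sub["log_wean_pc"])

    # omnivore vs herbivore, controlling brain mass and limb biomechanics
    noncarn = df[df["diet"] != "carnivore"].copy()
    noncarn["is_herbivore"] = (noncarn["diet"] == "herbivore").astype(int)
    oh_fit = ols_ancova(noncarn, "log_wean_pc", ["log_brain"],
                        ["lb_code", "is_herbivore"])
    oh_p = oh_fit.coefficient_p_values["is_herbivore"]
    pooled = oh_p >= alpha

    fits = dict(per_diet)
    fits["omnivore_vs_herbivore"] = oh_fit
    extras = {
        "omnivore_herbivore_difference": oh_fit.coefficients["is_herbivore"],
        "omnivore_herbivore_p": oh_p,
        "pooled_non_carnivores": pooled,
        "alpha": alpha,
    }
    if pooled:
        full = ols_ancova(table, "log_wean_pc", ["log_brain"], ["lb_code", "dp_code"])
        fits["pooled_ancova"] = full
        extras["carnivore_offset_log10_days"] = -full.coefficients["dp_code"]
        extras["diet_offset_dp"] = full.coefficients["dp_code"]
        extras["diet_offset_se"] = full.coefficient_se["dp_code"]
        extras["diet_p"] = full.term_f_p_values["dp_code"]
        narrative = (
            f"Omnivores and herbivores do not differ (p={format_p(oh_p)}); pooled as "
            f"non-carnivores. Carnivores wean {full.coefficients['dp_code']:+.3f} log10 "
            f"days earlier than non-carnivores (diet term "
            f"F={full.term_f['dp_code']:.2f}, p={format_p(full.term_f_p_values['dp_code'])})."
        )
    else:
        three = df.copy()
        three["is_omnivore"] = (three["diet"] == "omnivore").astype(int)
        three["is_herbivore"] = (three["diet"] == "herbivore").astype(int)
        unpooled = ols_ancova(three, "log_wean_pc", ["log_brain"],
                              ["lb_code", "is_omnivore", "is_herbivore"])
        fits["three_level_ancova"] = unpooled
        narrative = (
            f"Omnivores and herbivores differ (p={format_p(oh_p)}); dietary profile "
            f"kept at three levels."
        )
    return StepReport(step="step3_diet_effect", fits=fits, narrative=narrative,
                      extras=extras)


def step4_final_model(
    table: TraitTable,
    human: str = "Homo_sapiens",
    reference_mean_days: float = 1129.0,
    level: float = 0.90,
    entry_order: Sequence[str] = DEFAULT_ENTRY_ORDER,
) -> StepReport:
    """Full ANCOVA, variance partition, and the leave-humans-out prediction."""
    df = table.to_frame()
    if human not in set(df["species"]):
        raise ValidationError(f"focal species {human!r} not present in table")
    full = ols_ancova(table, FULL_MODEL["response"], FULL_MODEL["continuous"],
                      FULL_MODEL["dummies"])
    partition = sequential_partition(table, FULL_MODEL["response"], entry_order)

    prediction, loo_fit = loo_species_prediction(
        table, human, level=level,
        response=FULL_MODEL["response"],
        continuous=FULL_MODEL["continuous"],
        dummies=FULL_MODEL["dummies"],
    )
    rel_error = abs(prediction.point_days - reference_mean_days) / reference_mean_days

    # diet-stratified predictions at the human brain mass (human itself left out)
    human_row = df[df["species"] == human].iloc[0]
    rest = df[df["species"] != human]
    bands = {}
    for group, mask in (("carnivore", rest["dp_code"] == 0),
                        ("non_carnivore", rest["dp_code"] == 1)):
        sub = rest[mask]
        fit = ols_ancova(sub, "log_wean_pc", ["log_brain"], [])
        band = predict_with_interval(fit, {"log_brain": float(human_row["log_brain"])},
                                     level=level)
        bands[group] = band
    log_ref = math.log10(reference_mean_days)
    in_carn = bands["carnivore"].interval_low <= log_ref <= bands["carnivore"].interval_high
    in_noncarn = (bands["non_carnivore"].interval_low <= log_ref
                  <= bands["non_carnivore"].interval_high)

    narrative = (
        f"Full model adjR2={full.adj_r_squared:.2f}, F={full.f_statistic:.2f} "
        f"(p={format_p(full.f_p_value)}); sequential increments "
        + " / ".join(f"{v:.1f}%" for v in partition.increments)
        + f" (total {partition.total:.1f}%). Leave-{human}-out prediction: "
        f"{prediction.point_days:.0f} days post conception vs reference "
        f"{reference_mean_days:.0f} (relative error {100 * rel_error:.1f}%). "
        f"Reference mean is {'inside' if in_carn else 'outside'} the carnivore "
        f"{level:.0%} prediction band and {'inside' if in_noncarn else 'outside'} "
        f"the non-carnivore band."
    )
    return StepReport(
        step="step4_final_model",
        fits={"full_ancova": full, "loo_fit": loo_fit,
              "carnivore_band": bands["carnivore"],
              "non_carnivore_band": bands["non_carnivore"]},
        partition=partition,
        prediction=prediction,
        narrative=narrative,
        extras={
            "loo_prediction_days_pc": prediction.point_days,
            "reference_mean_days": reference_mean_days,
            "relative_error": rel_error,
            "reference_in_carnivore_band": bool(in_carn),
            "reference_in_non_carnivore_band": bool(in_noncarn),
            "level": level,
        },
    )


def run_pipeline(
    table: TraitTable,
    human: str = "Homo_sapiens",
    reference_mean_days: float = 1129.0,
    level: float = 0.90,
    alpha: float = 0.05,
    entry_order: Sequence[str] = DEFAULT_ENTRY_ORDER,
) -> list[StepReport]:
    """Run steps 1-4 in sequence; step 4 is skipped (with a stub report)
    if the focal species is absent from the table."""
    reports = [
        step1_compare_predictors(table),
        step2_grade_shift(table),
        step3_diet_effect(table, alpha=alpha),
    ]
    if human in set(table.species):
        reports.append(step4_final_model(table, human=human,
                                         reference_mean_days=reference_mean_days,
                                         level=level, entry_order=entry_order))
    else:
        reports.append(StepReport(
            step="step4_final_model",
            narrative=f"Skipped: focal species {human!r} not in table.",
            extras={"skipped": True},
        ))
    return reports


def replicate_headline_study(
    n_replicates: int = 100,
    seed: int = 0,
    base_config=None,
    with_contrasts: bool = True,
) -> dict[str, np.ndarray]:
    """Monte-Carlo battery: headline statistics over seeded stand-in tables.

    Because the generator stands in for a single observed dataset, headline
    quantities are reported as replicate means with Monte-Carlo error rather
    than from one arbitrary draw.  Each replicate simulates a 67-taxon table
    (human record embedded), runs the final model, the variance partition,
    the predictor correlations, the leave-humans-out prediction and the
    diet-stratified bands, and optionally the brain-weaning contrasts on
    the replicate's own chronogram.  Returns arrays keyed by statistic.
    """
    from dataclasses import replace

    from .phylo_contrasts import contrast_correlation, independent_contrasts, parse_newick
    from .synthetic_data import SimConfig, simulate_dataset

    if base_config is None:
        base_config = SimConfig()
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(seed).spawn(n_replicates)]
    keys = ["adj_r_squared", "r_squared", "f_statistic", "f_brain", "f_limb", "f_diet",
            "eta_brain", "eta_limb", "eta_diet",
            "inc_brain_pct", "inc_limb_pct", "inc_diet_pct", "total_pct",
            "r_brain_weaning", "partial_r", "grade_shift", "diet_offset",
            "loo_pred_days", "loo_rel_error",
            "ref_in_carnivore_band", "ref_in_non_carnivore_band",
            "n_contrasts", "contrast_r"]
    out: dict[str, list[float]] = {k: [] for k in keys}
    for rep_seed in seeds:
        config = replace(base_config, seed=rep_seed, include_human=True)
        table, truth = simulate_dataset(config)
        full = ols_ancova(table, FULL_MODEL["response"], FULL_MODEL["continuous"],
                          FULL_MODEL["dummies"])
        partition = sequential_partition(table, FULL_MODEL["response"], DEFAULT_ENTRY_ORDER)
        raw = rma_fit(table.column("log_brain"), table.column("log_wean_pc"))
        pr, _ = partial_correlation(table.column("log_brain"),
                                    table.column("log_wean_pc"),
                                    table.column("log_body"))
        s4 = step4_final_model(table)
        out["adj_r_squared"].append(full.adj_r_squared)
        out["r_squared"].append(full.r_squared)
        out["f_statistic"].append(full.f_statistic)
        out["f_brain"].append(full.term_f["log_brain"])
        out["f_limb"].append(full.term_f["lb_code"])
        out["f_diet"].append(full.term_f["dp_code"])
        out["eta_brain"].append(full.partial_eta_squared["log_brain"])
        out["eta_limb"].append(full.partial_eta_squared["lb_code"])
        out["eta_diet"].append(full.partial_eta_squared["dp_code"])
        out["inc_brain_pct"].append(partition.increments[0])
        out["inc_limb_pct"].append(partition.increments[1])
        out["inc_diet_pct"].append(partition.increments[2])
        out["total_pct"].append(partition.total)
        out["r_brain_weaning"].append(raw.r)
        out["partial_r"].append(pr)
        out["grade_shift"].append(full.coefficients["lb_code"])
        out["diet_offset"].append(full.coefficients["dp_code"])
        out["loo_pred_days"].append(s4.extras["loo_prediction_days_pc"])
        out["loo_rel_error"].append(s4.extras["relative_error"])
        out["ref_in_carnivore_band"].append(float(s4.extras["reference_in_carnivore_band"]))
        out["ref_in_non_carnivore_band"].append(
            float(s4.extras["reference_in_non_carnivore_band"]))
        if with_contrasts:
            tree = parse_newick(truth.newick)
            cb = independent_contrasts(tree, dict(zip(table.species,
                                                      table.column("log_brain"))))
            cw = independent_contrasts(tree, dict(zip(table.species,
                                                      table.column("log_wean_pc"))))
            r, _, _ = contrast_correlation(cb, cw)
            out["n_contrasts"].append(float(cb.n_contrasts))
            out["contrast_r"].append(r)
    return {k: np.asarray(v) for k, v in out.items() if v}


def walk_wean_ratio(walk_days, wean_days) -> np.ndarray:
    """log10 of the walking-onset / weaning-time ratio.

    Both times must be in the same unit; the ratio (hence its log) is
    invariant to which unit that is.
    """
    walk = np.asarray(walk_days, dtype=float)
    wean = np.asarray(wean_days, dtype=float)
    if np.any(walk <= 0) or np.any(wean <= 0):
        raise ValidationError("times must be strictly positive")
    return np.log10(walk / wean)
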