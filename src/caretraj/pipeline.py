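"""End-to-end orchestration: simulate -> filter -> segment -> code ->
select-K/fit -> impute -> DFA -> report, with every stage a pure function
of (inputs, config, seed) and all artifacts written as CSV/YAML text."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, dfa, groupstats, lca, missing, simulate, trajectories

log = logging.getLogger("caretraj")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "caretraj_run"
    n_children: int = 3000
    seed: int = 0
    intake_start: str = "2004-01-01"
    intake_end: str = "2006-12-31"
    lookback_days: int = 548
    gap_days: int = 180
    min_visits: int = 3
    n_months: int = 48
    k_min: int = 2
    k_max: int = 7
    improvement_threshold: float = 0.02
    n_starts: int = 10
    max_em_iter: int = 250
    polish_iter: int = 50
    n_boot: int = 0          # bootstrap replications; 0 skips the GOF test
    dfa_priors: str = "proportional"
    loo: bool = True

    def __post_init__(self):
        if not (1 <= self.k_min <= self.k_max <= 15):
            raise ValueError("k-range must lie within 1..15")
        for name in ("n_children", "lookback_days", "gap_days", "min_visits",
                     "n_months", "n_starts", "max_em_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a freshly simulated cohort and write artifacts.

    Returns a dict of the in-memory results keyed by stage name.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    results: dict = {}

    log.info("stage simulate: n=%d seed=%d", config.n_children, config.seed)
    gen = simulate.default_config(
        n_children=config.n_children, seed=config.seed,
        intake_start=config.intake_start, intake_end=config.intake_end)
    cohort_sim = simulate.sample_cohort(gen)
    cohort_sim.covariates = simulate.inject_missingness(
        cohort_sim.covariates, gen)
    cohort_sim.write(out)
    results["cohort"] = cohort_sim

    log.info("stage filter")
    filt = cohort.apply_filters(
        cohort_sim.children, cohort_sim.visits,
        (config.intake_start, config.intake_end),
        lookback_days=config.lookback_days, min_visits=config.min_visits,
        gap_days=config.gap_days, n_months=config.n_months)
    filt.attrition_frame().to_csv(out / "attrition.csv", index=False)
    for rule, n in filt.attrition:
        log.info("  %-28s removed %d", rule, n)
    results["filter"] = filt

    log.info("stage segment/code")
    summaries = trajectories.summarize_cohort(
        filt.visits, filt.index_dates, min_visits=config.min_visits,
        gap_days=config.gap_days)
    summaries.to_csv(out / "service_use.csv")
    X = trajectories.trajectory_matrix(filt.visits, filt.index_dates,
                                       n_months=config.n_months)
    X.to_csv(out / "trajectory_matrix.csv")
    results["summaries"], results["trajectories"] = summaries, X

    log.info("stage lca: K=%d..%d", config.k_min, config.k_max)
    em_kwargs = dict(n_starts=config.n_starts,
                     max_em_iter=config.max_em_iter,
                     polish_iter=config.polish_iter)
    if config.k_min == config.k_max:
        fit = lca.em_fit(X.to_numpy(), config.k_min, seed=config.seed,
                         **em_kwargs)
        trace = None
        chosen_k = config.k_min
    else:
        trace = lca.select_num_classes(
            X.to_numpy(), range(config.k_min, config.k_max + 1),
            threshold=config.improvement_threshold, seed=config.seed,
            **em_kwargs)
        chosen_k = trace.chosen_k
        fit = trace.fits[chosen_k]
        pd.DataFrame(trace.table).to_csv(out / "selection_trace.csv",
                                         index=False)
    log.info("  chosen K=%d entropy=%.3f", chosen_k, fit.entropy)
    _write_model(fit, out / "lca_model.yaml", config.seed)
    if config.n_boot > 0:
        results["gof_p"] = lca.bootstrap_gof(fit, X.to_numpy(),
                                             n_boot=config.n_boot,
                                             seed=config.seed)
    assign = pd.Series(lca.modal_assignment(fit.posteriors),
                       index=X.index, name="class_index")
    results["lca"], results["selection"], results["assignments"] = \
        fit, trace, assign

    if fit.model.K == 5:
        names = groupstats.assign_pattern_names(summaries, assign)
    else:
        # substantive names are defined for the five-pattern solution only
        names = {k: f"Class {k + 1}" for k in range(fit.model.K)}
    patterns = assign.map(names).rename("pattern")
    pd.DataFrame({"class_index": assign, "pattern": patterns}) \
        .to_csv(out / "assignments.csv")
    results["pattern_names"] = names

    log.info("stage impute")
    cov = cohort_sim.covariates.set_index("child_id").loc[assign.index]
    scale_matrix = cov[list(simulate.SCALES)].to_numpy(float)
    try:
        results["mcar"] = missing.little_mcar_test(scale_matrix)
        log.info("  Little's MCAR chi2=%.2f df=%d p=%.3g",
                 results["mcar"].chi2, results["mcar"].df,
                 results["mcar"].p)
    except missing.McarUndefinedError:
        results["mcar"] = None
        log.info("  MCAR test undefined (single missingness pattern)")
    imputed = cov.copy()
    imputed[list(simulate.SCALES)] = missing.em_impute(scale_matrix)
    imputed.to_csv(out / "covariates_imputed.csv")
    results["imputed"] = imputed

    log.info("stage dfa")
    Xp = np.column_stack([
        (imputed["sex"] == "M").astype(float),
        imputed["age_at_index"].to_numpy(float),
        imputed[list(simulate.SCALES)].to_numpy(float)])
    dfa_report = dfa.report(Xp, patterns.to_numpy(),
                            priors=config.dfa_priors, loo=config.loo)
    results["dfa"] = dfa_report
    model = dfa.fit(Xp, patterns.to_numpy(), priors=config.dfa_priors)
    pred_names = ["sex_male", "age"] + list(simulate.SCALES)
    coef = pd.DataFrame(model.standardized_coefficients, index=pred_names,
                        columns=[f"f{i+1}_std" for i in range(model.s)])
    for i in range(model.s):
        coef[f"f{i+1}_structure"] = model.structure_coefficients[:, i]
    coef.to_csv(out / "dfa_coefficients.csv")
    pd.DataFrame(model.centroids, index=model.classes,
                 columns=[f"f{i+1}" for i in range(model.s)]) \
        .to_csv(out / "dfa_centroids.csv")
    pd.DataFrame(dfa_report.wilks).to_csv(out / "dfa_wilks.csv", index=False)
    log.info("  resubstitution %.1f%%, LOO %.1f%%",
             dfa_report.resubstitution_accuracy, dfa_report.loo_accuracy)

    log.info("stage report")
    table1 = groupstats.pattern_summary(summaries, patterns,
                                        cohort_sim.covariates)
    table1.to_csv(out / "pattern_summary.csv")
    cutoffs = groupstats.clinical_cutoffs(imputed)
    table3 = imputed.join(cutoffs).join(patterns) \
        .groupby("pattern")[list(simulate.SCALES)].agg(["mean", "std"])
    table3.to_csv(out / "clinical_summary.csv")
    results["table1"], results["table3"], results["cutoffs"] = \
        table1, table3, cutoffs
    return results


def _write_model(fit: "lca.LCAFit", path, seed: int) -> None:
    payload = {
        "K": int(fit.model.K),
        "pi": [float(x) for x in fit.model.pi],
        "theta": [[float(x) for x in row] for row in fit.model.theta],
        "loglik": float(fit.loglik),
        "aic": float(fit.aic), "bic": float(fit.bic),
        "caic": float(fit.caic), "entropy": float(fit.entropy),
        "seed": int(seed), "best_start_seed": int(fit.best_start_seed),
        "converged": bool(fit.converged),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
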