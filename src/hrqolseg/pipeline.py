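"""End-to-end analysis pipeline and report assembly.

Ties the stages together in the order the analysis prescribes:
simulate (or load) -> preprocess -> score -> segment -> describe ->
associate -> sensitivity -> discordance, writing a bundle of CSV/JSON
outputs plus a run manifest from which every file is re-derivable
(config + seed).  All numeric outputs are deterministic given the
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    build_design,
    collinearity_check,
    descriptive_table,
    forward_select_aic,
    refit_with_msss,
)
from .preprocess import prepare_cohort
from .scoring import MsssParams, compute_msss
from .segmentation import segment_cohort
from .sensitivity import build_spline_basis, fit_simultaneous_quantiles, select_by_pvalue
from .simulate import GeneratorConfig, default_config, generate_cohort, inject_missingness

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_CANDIDATE_ORDER", "BASE_TERMS"]

log = logging.getLogger("hrqolseg")

BASE_TERMS = ("sex", "phenotype", "srdss_class")

# pre-specified candidate order: symptoms first, then benefits/employment,
# sociodemographics and risk factors, then comorbidities and BMI
DEFAULT_CANDIDATE_ORDER = (
    "symptom_depression",
    "symptom_fatigue",
    "symptom_memory",
    "symptom_pain",
    "symptom_muscle_weakness",
    "symptom_balance",
    "symptom_bladder",
    "symptom_gait",
    "symptom_gastrointestinal",
    "symptom_paresthesia",
    "symptom_spasms",
    "symptom_tremors",
    "symptom_count_class",
    "disability_benefit",
    "employed",
    "swiss_citizen",
    "education",
    "living_situation",
    "marital_status",
    "smoking",
    "dmt_class",
    "first_symptom_visual",
    "first_symptom_paresthesia",
    "first_symptom_gait",
    "first_symptom_spasms",
    "family_ms",
    "comorbidity_mononucleosis",
    "comorbidity_hypertension",
    "comorbidity_cancer",
    "comorbidity_diabetes1",
    "comorbidity_diabetes2",
    "comorbidity_cardiovascular",
    "bmi",
)

INSTRUMENTS = ("eq5d_index", "vas")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int = 20240001
    n: int = 1697
    input_csv: str | None = None  # participant CSV; None -> synthetic cohort
    generator_yaml: str | None = None  # None -> packaged default
    instruments: tuple = INSTRUMENTS
    taus: tuple = (0.25, 0.5, 0.75)
    base_terms: tuple = BASE_TERMS
    candidate_order: tuple = DEFAULT_CANDIDATE_ORDER
    aic_threshold: float = 2.0
    bootstrap_B: int = 100
    alpha: float = 0.05
    outdir: str = "hrqolseg_run"
    run_sensitivity: bool = True
    run_discordance: bool = True

    def validate(self) -> None:
        taus = tuple(self.taus)
        if list(taus) != sorted(taus) or not all(0 < t < 1 for t in taus):
            raise ValueError("taus must be sorted and inside (0, 1)")
        if self.aic_threshold <= 0:
            raise ValueError("AIC threshold must be positive")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(f"input CSV not found: {self.input_csv}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _load_or_generate(config: PipelineConfig, outdir: Path):
    if config.input_csv is not None:
        log.info("loading cohort from %s", config.input_csv)
        return pd.read_csv(config.input_csv), None
    gcfg = (
        GeneratorConfig.from_yaml(config.generator_yaml, seed=config.seed, n=config.n)
        if config.generator_yaml
        else default_config(seed=config.seed, n=config.n)
    )
    log.info("generating synthetic cohort (n=%d, seed=%d)", gcfg.n, gcfg.seed)
    complete, truth = generate_cohort(gcfg)
    observed = inject_missingness(complete, gcfg)
    observed.to_csv(outdir / "cohort.csv", index=False)
    truth.to_json(outdir / "truth.json")
    return observed, truth


def _fit_to_json(fit) -> dict:
    return {
        "categories": fit.categories,
        "n": fit.n,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "params": {c: fit.params[c].to_dict() for c in fit.params.columns},
        "vcov": np.asarray(fit.cov).tolist(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        # outdir is where the bundle lands, not part of the analysis
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "outdir"
        },
        "stages": {},
    }

    # --- simulate / load -------------------------------------------------
    raw, _truth = _load_or_generate(config, outdir)
    manifest["stages"]["input_rows"] = int(len(raw))

    # --- preprocess ------------------------------------------------------
    log.info("preprocessing")
    prepared, counts = prepare_cohort(raw)
    manifest["stages"]["preprocess"] = counts

    # --- score -----------------------------------------------------------
    log.info("scoring MSSS")
    prepared = prepared.copy()
    if "edss" in prepared.columns and prepared["edss"].notna().sum() >= 5:
        prepared["msss"] = compute_msss(
            prepared["edss"].to_numpy(), prepared["years_since_diagnosis"].to_numpy(), MsssParams()
        )
    else:
        prepared["msss"] = np.nan
    manifest["stages"]["msss_observed"] = int(prepared["msss"].notna().sum())

    # --- segment ---------------------------------------------------------
    log.info("segmenting HRQoL")
    for inst in config.instruments:
        if inst not in prepared.columns:
            raise ValueError(f"cohort table lacks instrument column {inst!r}")
    seg = segment_cohort(prepared, instruments=config.instruments, taus=config.taus)
    seg.table.to_csv(outdir / "segmentation.csv", index=False)
    fits_json = {
        inst: [
            {"tau": f.tau, "coef": dict(zip(f.columns, f.coef.tolist())), "loss": f.loss, "n": f.n}
            for f in fl
        ]
        for inst, fl in seg.fits.items()
    }
    (outdir / "quantile_fits.json").write_text(json.dumps(fits_json, indent=1))
    if len(seg.crossing):
        seg.crossing.to_csv(outdir / "quantile_crossing.csv", index=False)
    manifest["stages"]["crossing_rows"] = int(len(seg.crossing))

    labels_by_inst = {}
    for inst in config.instruments:
        sub = seg.table[seg.table["instrument"] == inst].set_index("participant_id")
        labels = sub.loc[prepared["participant_id"], "label"].to_numpy()
        labels_by_inst[inst] = labels
        manifest["stages"][f"groups_{inst}"] = (
            pd.Series(labels).value_counts().to_dict()
        )

    # --- describe + associate per instrument ------------------------------
    describe_vars = [c for c in prepared.columns if c not in ("participant_id", "measurement_date")]
    for inst in config.instruments:
        labels = labels_by_inst[inst]
        log.info("descriptive table (%s)", inst)
        desc = descriptive_table(prepared, labels, describe_vars)
        desc.to_csv(outdir / f"descriptive_{inst}.csv", index=False)

        log.info("multinomial model building (%s)", inst)
        trace, final = forward_select_aic(
            prepared,
            labels,
            config.base_terms,
            config.candidate_order,
            reference="normal",
            threshold=config.aic_threshold,
        )
        final_terms = list(config.base_terms) + trace.retained
        trace.to_frame().to_csv(outdir / f"selection_trace_{inst}.csv", index=False)
        (outdir / f"multinomial_{inst}.json").write_text(json.dumps(_fit_to_json(final), indent=1))
        final.rrr.to_csv(outdir / f"rrr_{inst}.csv", index=False)

        X_final, term_map = build_design(prepared, final_terms)
        vif = collinearity_check(X_final, term_map)
        vif.to_csv(outdir / f"collinearity_{inst}.csv", index=False)

        if prepared["msss"].notna().sum() >= 10 and prepared["msss"].nunique() > 1:
            msss_fit = refit_with_msss(prepared, labels, final_terms, reference="normal")
            msss_fit.rrr.to_csv(outdir / f"rrr_msss_{inst}.csv", index=False)
            manifest["stages"][f"msss_refit_n_{inst}"] = msss_fit.n
        manifest["stages"][f"retained_{inst}"] = trace.retained

        # --- sensitivity: simultaneous quantile regression ----------------
        if config.run_sensitivity:
            log.info("simultaneous quantile regression (%s)", inst)
            age_basis = build_spline_basis(prepared["age_years"], variable="age_years")
            dur_basis = build_spline_basis(
                prepared["years_since_diagnosis"], variable="years_since_diagnosis"
            )
            X_conf, _ = build_design(prepared, list(config.base_terms))
            X_sqr = pd.concat(
                [
                    X_conf[["intercept"]],
                    pd.DataFrame(
                        age_basis.evaluate(prepared["age_years"]),
                        columns=age_basis.column_names(),
                        index=prepared.index,
                    ),
                    pd.DataFrame(
                        dur_basis.evaluate(prepared["years_since_diagnosis"]),
                        columns=dur_basis.column_names(),
                        index=prepared.index,
                    ),
                    X_conf.drop(columns="intercept"),
                ],
                axis=1,
            )
            cand_cols = []
            if trace.retained:
                X_cand, cand_map = build_design(prepared, trace.retained)
                X_cand = X_cand.drop(columns="intercept")
                X_sqr = pd.concat([X_sqr, X_cand], axis=1)
                cand_cols = list(X_cand.columns)
            sqr = fit_simultaneous_quantiles(
                prepared[inst].to_numpy(dtype=float),
                X_sqr,
                taus=config.taus,
                B=config.bootstrap_B,
                seed=config.seed,
            )
            sqr.summary().to_csv(outdir / f"sqr_{inst}.csv", index=False)
            sqr.cross_tau_test().to_csv(outdir / f"sqr_crosstau_{inst}.csv", index=False)
            retained_sqr = select_by_pvalue(sqr, cand_cols, alpha=config.alpha)
            manifest["stages"][f"sqr_retained_{inst}"] = retained_sqr

    # --- discordance -----------------------------------------------------
    if config.run_discordance and {"eq5d_index", "vas"} <= set(config.instruments):
        log.info("discordance analysis")
        sub = seg.table[seg.table["instrument"] == "eq5d_index"].set_index("participant_id")
        disc = sub.loc[prepared["participant_id"], "discordance"].to_numpy()
        manifest["stages"]["discordance"] = pd.Series(disc).value_counts().to_dict()
        desc = descriptive_table(prepared, disc, describe_vars)
        desc.to_csv(outdir / "descriptive_discordance.csv", index=False)
        trace_d, final_d = forward_select_aic(
            prepared,
            disc,
            config.base_terms,
            config.candidate_order,
            reference="within_expectation",
            threshold=config.aic_threshold,
        )
        trace_d.to_frame().to_csv(outdir / "selection_trace_discordance.csv", index=False)
        final_d.rrr.to_csv(outdir / "rrr_discordance.csv", index=False)
        manifest["stages"]["retained_discordance"] = trace_d.retained

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("run complete: %s", outdir)
    return manifest
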