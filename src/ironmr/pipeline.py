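"""End-to-end orchestration of the conservative and liberal MR analyses.

One call runs, per biomarker: instrument selection, strength reporting,
harmonization against the outcome data, the requested estimator battery
(IVW, MR-Egger, weighted median, residual-sum outlier test), and the
leave-one-out and single-SNP diagnostic tables. Output tables and a JSON
run manifest sufficient to reproduce them are written when an output
directory is given.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .diagnostics import leave_one_out, single_snp_results
from .estimators import MRResult, ivw, mr_egger, weighted_median
from .gwas_io import (ALS_CASES, ALS_N, BIOMARKERS, AssociationRecord, GIS_N,
                      SummaryStatError, load_als_fixture, load_iron_table)
from .harmonize import DEFAULT_PALINDROME_WINDOW, harmonize_set
from .instruments import (InstrumentSet, conservative_set, liberal_set,
                          set_strength, strength_stats)
from .power import PowerSpec, detectable_or
from .presso import MIN_INSTRUMENTS as PRESSO_MIN
from .presso import presso_test

logger = logging.getLogger(__name__)

VALID_MODES = ("conservative", "liberal")
VALID_METHODS = ("ivw", "egger", "wm", "presso")


@dataclass(frozen=True)
class AnalysisConfig:
    mode: str = "conservative"
    exposures: tuple[str, ...] = BIOMARKERS
    methods: tuple[str, ...] = ("ivw",)
    effects_model: str = "multiplicative_random"
    presso_nsim: int = 5000
    presso_alpha: float = 0.05
    wm_boot: int = 1000
    seed: int = 0
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW
    exclude_snps: tuple[str, ...] = ()
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; valid: {VALID_MODES}")
        for m in self.methods:
            if m not in VALID_METHODS:
                raise ValueError(f"unknown method {m!r}; valid: {VALID_METHODS}")
        for b in self.exposures:
            if b not in BIOMARKERS:
                raise ValueError(f"unknown biomarker {b!r}; valid: {BIOMARKERS}")
        if self.effects_model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")


def select_instruments(config: AnalysisConfig,
                       table: Mapping[str, Sequence[AssociationRecord]],
                       biomarker: str) -> InstrumentSet:
    if config.mode == "conservative":
        chosen = conservative_set(table, trait=biomarker)
    else:
        chosen = liberal_set(table, biomarker)
    if config.exclude_snps:
        kept = tuple(r for r in chosen.records if r.rsid not in config.exclude_snps)
        chosen = replace(chosen, records=kept)
    return chosen


def run_full_analysis(config: AnalysisConfig,
                      exposure_source: Mapping[str, Sequence[AssociationRecord]] | None = None,
                      outcome_source: Sequence[AssociationRecord] | None = None,
                      ) -> dict[str, pd.DataFrame]:
    """Run the configured analysis; return (and optionally write) tables.

    Returns a dict of DataFrames: ``results`` (pooled estimates),
    ``strength`` (per-SNP R^2/F plus the set-level row), ``harmonization``
    (keep/flip/drop log), ``leave_one_out``, ``single_snp``, ``presso``
    (when requested).
    """
    table = exposure_source if exposure_source is not None else load_iron_table()
    outcomes = outcome_source if outcome_source is not None else load_als_fixture()

    results: list[MRResult] = []
    strength_rows, harm_rows, loo_rows, snp_rows, presso_rows = [], [], [], [], []
    for biomarker in config.exposures:
        instruments = select_instruments(config, table, biomarker)
        if len(instruments) == 0:
            raise SummaryStatError(
                f"no instruments left for {biomarker} after selection")
        for s in strength_stats(instruments.records):
            strength_rows.append({"exposure": biomarker, "rsid": s.rsid,
                                  "r2": s.r2, "f_stat": s.f_stat, "k": s.k})
        sset = set_strength(instruments.records)
        strength_rows.append({"exposure": biomarker, "rsid": "<set>",
                              "r2": sset.r2, "f_stat": sset.f_stat, "k": sset.k})

        harmonized = harmonize_set(instruments, outcomes,
                                   config.palindrome_eaf_window)
        for inst in harmonized.instruments:
            harm_rows.append({"exposure": biomarker, "rsid": inst.rsid,
                              "action": "flip" if inst.flipped else "keep",
                              "reason": "palindromic, EAF-resolved" if inst.palindromic else "alleles aligned"})
        for d in harmonized.dropped:
            harm_rows.append({"exposure": biomarker, "rsid": d.rsid,
                              "action": "drop", "reason": d.reason})
        for rsid in harmonized.missing:
            harm_rows.append({"exposure": biomarker, "rsid": rsid,
                              "action": "missing", "reason": "not found in outcome data"})
        insts = list(harmonized.instruments)

        if "ivw" in config.methods:
            results.append(ivw(insts, config.effects_model).relabel(biomarker, config.mode))
        if "egger" in config.methods and len(insts) >= 3:
            results.append(mr_egger(insts).relabel(biomarker, config.mode))
        if "wm" in config.methods and len(insts) >= 3:
            results.append(weighted_median(insts, n_boot=config.wm_boot,
                                           seed=config.seed).relabel(biomarker, config.mode))
        if "presso" in config.methods and len(insts) >= PRESSO_MIN:
            pres = presso_test(insts, n_sim=config.presso_nsim,
                               significance=config.presso_alpha, seed=config.seed)
            presso_rows.append({"exposure": biomarker, "global_rss": pres.global_rss,
                                "global_p": pres.global_p,
                                "n_outliers": len(pres.outliers),
                                "outliers": ";".join(pres.outliers)})
            if pres.corrected is not None:
                results.append(pres.corrected.relabel(biomarker, config.mode))

        if len(insts) >= 2:
            for row in leave_one_out(insts, config.effects_model):
                r = row.result
                loo_rows.append({"exposure": biomarker, "omitted": row.omitted_rsid,
                                 "nsnp": r.n_snp, "beta": r.beta, "se": r.se,
                                 "or": r.or_value, "ci_low": r.ci_low,
                                 "ci_high": r.ci_high, "pvalue": r.pvalue})
        for inst, r in zip(insts, single_snp_results(insts)):
            snp_rows.append({"exposure": biomarker, "rsid": inst.rsid,
                             "beta": r.beta, "se": r.se, "or": r.or_value,
                             "ci_low": r.ci_low, "ci_high": r.ci_high,
                             "pvalue": r.pvalue})

    tables = {
        "results": _results_frame(results),
        "strength": pd.DataFrame(strength_rows),
        "harmonization": pd.DataFrame(harm_rows),
        "leave_one_out": pd.DataFrame(loo_rows),
        "single_snp": pd.DataFrame(snp_rows),
    }
    if presso_rows:
        tables["presso"] = pd.DataFrame(presso_rows)
    if config.out_dir:
        _write_outputs(config, tables)
    return tables


def _results_frame(results: Sequence[MRResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({"exposure": r.exposure, "mode": r.mode, "method": r.method,
                     "nsnp": r.n_snp, "beta": r.beta, "se": r.se,
                     "or": r.or_value, "ci_low": r.ci_low, "ci_high": r.ci_high,
                     "pvalue": r.pvalue, "q": r.q_stat,
                     "egger_intercept": r.egger_intercept,
                     "egger_intercept_p": r.egger_intercept_p})
    return pd.DataFrame(rows)


def _write_outputs(config: AnalysisConfig, tables: Mapping[str, pd.DataFrame]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {"package": "ironmr", "version": __version__,
                "config": asdict(config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list) + "\n")


def power_table(power_target: float = 0.8, alpha: float = 0.05,
                mode: str = "conservative") -> pd.DataFrame:
    """Detectable OR per biomarker at the target power for the study sizes."""
    table = load_iron_table()
    rows = []
    for biomarker in BIOMARKERS:
        if mode == "conservative":
            instruments = conservative_set(table, trait=biomarker)
        else:
            instruments = liberal_set(table, biomarker)
        r2 = set_strength(instruments.records).r2
        spec = PowerSpec(n=ALS_N, case_fraction=ALS_CASES / ALS_N, r2_sum=r2,
                         alpha=alpha, power=power_target)
        rows.append({"exposure": biomarker, "mode": mode, "n_snp": len(instruments),
                     "r2_sum": r2, "power_target": power_target,
                     "detectable_or": detectable_or(spec),
                     "detectable_or_protective": 1.0 / detectable_or(spec)})
    return pd.DataFrame(rows)
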