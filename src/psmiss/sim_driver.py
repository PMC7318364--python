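"""Monte-Carlo driver: factorial conditions, replication seeding, aggregation.

A *cell* is one condition: exposure scenario (A/G), missingness mechanism
and overall rate, sample size, estimation method and covariate-inclusion
strategy.  Each replication runs the full pipeline — generate a complete
sample, impose missingness, impute, estimate propensity scores, weight,
trim, and regress — and a cell aggregates its replications into bias, SD
of the estimates, mean model-based SE, and RMSE about the true effect.

Seeding uses counter-based streams on (master seed, stream label, rep
index).  The data and mask streams are labelled by the condition only, not
the method, so every method within a condition analyses the identical
complete sample and missingness mask (paired comparison); adding cells
never perturbs existing ones.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import effect_estimation as ee
from . import imputation as imp
from . import missingness as mism
from . import ps_boosting as psb
from . import ps_logistic as psl
from .synthetic_data import GeneratorConfig, generate_complete_sample

__all__ = [
    "CellSpec",
    "CellResult",
    "run_replication",
    "run_cell",
    "run_study",
    "load_config",
    "expand_cells",
    "table_cells",
    "report_table",
    "METHODS",
    "MECHANISMS",
]

logger = logging.getLogger(__name__)

METHODS = (
    "complete", "comGBM", "TMI", "SI_PE", "SI_PE_PU", "MI", "MIMP",
    "GBM_incomplete", "GBM_SI_PE",
)
LOGISTIC_METHODS = ("complete", "TMI", "SI_PE", "SI_PE_PU", "MI", "MIMP")
GBM_METHODS = ("comGBM", "GBM_incomplete", "GBM_SI_PE")
BASELINE_METHODS = ("complete", "comGBM")
MECHANISMS = ("none", "MCAR", "MAR1", "MAR2", "MARSINISTER")

#: Reproduction-run boosting budget; the AASM minimum at n = 500 with
#: shrinkage 0.05 typically falls well inside it.
DEFAULT_BOOST = psb.BoostConfig(shrinkage=0.05, depth=4, max_iterations=2000)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CellSpec:
    """One simulation condition."""

    scenario: str = "A"
    mechanism: str = "MCAR"
    overall_rate: float = 0.25
    n: int = 500
    method: str = "MI"
    strategy: str = "true_confounders"
    replications: int = 1000
    master_seed: int = 0
    true_effect: float = -0.4
    m_imputations: int = 20
    n_cycles: int = 10
    min_pattern_count: int = 100
    mi_model: str = "pmm"
    boost: psb.BoostConfig = field(default=DEFAULT_BOOST)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigError(f"unknown method {self.method!r}")
        if self.mechanism not in MECHANISMS:
            raise ConfigError(f"unknown mechanism {self.mechanism!r}")
        if self.strategy not in psl.STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.mechanism == "none" and self.method not in BASELINE_METHODS:
            raise ConfigError(
                f"mechanism 'none' supports only {BASELINE_METHODS}, got {self.method!r}"
            )
        if self.method in GBM_METHODS and self.strategy != "true_confounders":
            raise ConfigError("GBM methods support only the true_confounders strategy")
        if self.strategy == "correct_G" and (
            self.scenario != "G" or self.method in GBM_METHODS
        ):
            raise ConfigError(
                "the correct_G strategy applies to scenario G with logistic methods"
            )

    def key(self) -> str:
        return (
            f"{self.scenario}|{self.mechanism}|{self.overall_rate}|{self.n}|"
            f"{self.method}|{self.strategy}"
        )


@dataclass
class CellResult:
    """Bias / SD / mean SE / RMSE for one cell."""

    spec: CellSpec
    bias: float
    sd: float
    mean_se: float
    rmse: float
    replications_done: int
    failures: int
    valid: bool

    def to_row(self) -> dict:
        s = self.spec
        return {
            "scenario": s.scenario,
            "mechanism": s.mechanism,
            "rate": s.overall_rate,
            "n": s.n,
            "method": s.method,
            "strategy": s.strategy,
            "bias": self.bias,
            "sd": self.sd,
            "se": self.mean_se,
            "rmse": self.rmse,
            "replications": self.replications_done,
            "failures": self.failures,
            "valid": self.valid,
        }


def _stream(master_seed: int, label: str, rep: int) -> np.random.Generator:
    tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag, rep]))


def _logistic_estimate(Xc, T, Y, strategy, pattern_ids=None):
    D = psl.build_design(Xc, strategy, pattern_ids)
    fit = psl.fit_logistic_ps(D, T, strategy=strategy)
    return ee.estimate_effect(Y, T, fit.ps)


def _gbm_estimate(X4, T, Y, boost_cfg):
    model = psb.boost(X4, T, boost_cfg)
    ps = np.clip(model.ps, psl.PS_CLIP, 1 - psl.PS_CLIP)
    return ee.estimate_effect(Y, T, ps)


def run_replication(spec: CellSpec, rep: int) -> ee.EffectEstimate:
    """One end-to-end pipeline run, deterministic in (master seed, rep)."""
    gen_cfg = GeneratorConfig(n=spec.n, scenario=spec.scenario)
    rng_data = _stream(spec.master_seed, f"data|{spec.scenario}|{spec.n}", rep)
    sample = generate_complete_sample(gen_cfg, rng_data)
    T, Y = sample.T, sample.Y
    conf = mism.CONFOUNDER_COLUMNS

    if spec.method == "complete":
        est = _logistic_estimate(sample.X, T, Y, spec.strategy)
    elif spec.method == "comGBM":
        est = _gbm_estimate(sample.X[:, conf], T, Y, spec.boost)
    else:
        rng_mask = _stream(
            spec.master_seed,
            f"miss|{spec.scenario}|{spec.n}|{spec.mechanism}|{spec.overall_rate}",
            rep,
        )
        incomplete = mism.impose(sample, spec.mechanism, spec.overall_rate, rng_mask)
        rng = _stream(spec.master_seed, f"analysis|{spec.key()}", rep)
        if spec.method == "TMI":
            out = imp.treatment_mean_impute(incomplete)
        elif spec.method == "SI_PE":
            out = imp.regression_impute_pe(incomplete, rng, spec.n_cycles)
        elif spec.method == "SI_PE_PU":
            out = imp.regression_impute_pe_pu(incomplete, rng, spec.n_cycles)
        elif spec.method == "MI":
            out = imp.chained_equations_impute(
                incomplete, spec.m_imputations, spec.n_cycles, rng,
                model=spec.mi_model,
            )
        elif spec.method == "MIMP":
            out = imp.mimp_impute(
                incomplete, spec.m_imputations, spec.min_pattern_count,
                spec.n_cycles, rng, model=spec.mi_model,
            )
        elif spec.method == "GBM_incomplete":
            out = None
            X4 = incomplete.masked_covariates()[:, conf]
            est = _gbm_estimate(X4, T, Y, spec.boost)
        elif spec.method == "GBM_SI_PE":
            out = None
            si = imp.regression_impute_pe(incomplete, rng, spec.n_cycles)
            est = _gbm_estimate(si.completed[0][:, conf], T, Y, spec.boost)
        else:  # pragma: no cover
            raise ConfigError(f"unhandled method {spec.method!r}")
        if out is not None:
            ests, variances = [], []
            for Xc in out.completed:
                e = _logistic_estimate(Xc, T, Y, spec.strategy, out.pattern_ids)
                ests.append(e.estimate)
                variances.append(e.variance)
            est = ee.rubin_combine(ests, variances)
    est.method = spec.method
    est.strategy = spec.strategy
    return est


def run_cell(spec: CellSpec, max_failure_fraction: float = 0.10) -> CellResult:
    """Run all replications of a cell and aggregate.

    Failed replications are logged, excluded from aggregation and counted;
    a cell with more than `max_failure_fraction` failures is flagged
    invalid.
    """
    if spec.replications < 2:
        raise ConfigError("a cell needs at least 2 replications")
    estimates, ses = [], []
    failures = 0
    for rep in range(spec.replications):
        try:
            est = run_replication(spec, rep)
        except Exception:
            failures += 1
            logger.exception("replication %d failed in cell %s", rep, spec.key())
            continue
        estimates.append(est.estimate)
        ses.append(est.se)
    est_arr = np.asarray(estimates)
    r = est_arr.size
    bias = float(est_arr.mean() - spec.true_effect) if r else float("nan")
    sd = float(est_arr.std(ddof=1)) if r > 1 else float("nan")
    rmse = float(np.sqrt(np.mean((est_arr - spec.true_effect) ** 2))) if r else float("nan")
    mean_se = float(np.mean(ses)) if r else float("nan")
    valid = failures <= max_failure_fraction * spec.replications
    return CellResult(
        spec=spec, bias=bias, sd=sd, mean_se=mean_se, rmse=rmse,
        replications_done=r, failures=failures, valid=valid,
    )


_TOP_KEYS = {
    "seed", "replications", "true_effect", "output", "boosting", "imputation",
    "cells",
}
_BOOST_KEYS = {"shrinkage", "depth", "max_iterations", "bag_fraction",
               "min_node", "max_surrogates"}
_IMP_KEYS = {"m", "cycles", "min_pattern_count", "model"}
_CELL_KEYS = {"scenario", "n", "mechanism", "rate", "method", "strategy",
              "replications"}


def load_config(source) -> dict:
    """Parse a YAML config (path or mapping); unknown keys are an error."""
    import yaml

    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    bad = sorted(set(cfg) - _TOP_KEYS)
    if bad:
        raise ConfigError(f"unknown config keys: {bad}")
    for section, allowed in (("boosting", _BOOST_KEYS), ("imputation", _IMP_KEYS)):
        bad = sorted(set(cfg.get(section, {})) - allowed)
        if bad:
            raise ConfigError(f"unknown {section} keys: {bad}")
    for cell in cfg.get("cells", []):
        bad = sorted(set(cell) - _CELL_KEYS)
        if bad:
            raise ConfigError(f"unknown cell keys: {bad}")
    return cfg


def _as_list(v):
    return v if isinstance(v, (list, tuple)) else [v]


def expand_cells(cfg: dict, seed: int | None = None,
                 replications: int | None = None) -> list[CellSpec]:
    """Expand a config's cell entries (lists expand as a product)."""
    seed = cfg.get("seed", 0) if seed is None else seed
    reps = cfg.get("replications", 1000) if replications is None else replications
    bopts = dict(cfg.get("boosting", {}))
    boost = replace(DEFAULT_BOOST, **bopts) if bopts else DEFAULT_BOOST
    iopts = cfg.get("imputation", {})
    specs = []
    for cell in cfg.get("cells", []):
        for scenario in _as_list(cell.get("scenario", "A")):
            for n in _as_list(cell.get("n", 500)):
                for mech in _as_list(cell.get("mechanism", "MCAR")):
                    for rate in _as_list(cell.get("rate", 0.25)):
                        for method in _as_list(cell.get("method", "MI")):
                            for strat in _as_list(cell.get("strategy", "true_confounders")):
                                specs.append(CellSpec(
                                    scenario=scenario, n=n, mechanism=mech,
                                    overall_rate=rate, method=method,
                                    strategy=strat,
                                    replications=cell.get("replications", reps),
                                    master_seed=seed,
                                    true_effect=cfg.get("true_effect", -0.4),
                                    m_imputations=iopts.get("m", 20),
                                    n_cycles=iopts.get("cycles", 10),
                                    min_pattern_count=iopts.get("min_pattern_count", 100),
                                    mi_model=iopts.get("model", "pmm"),
                                    boost=boost,
                                ))
    return specs


def run_study(source, seed: int | None = None, replications: int | None = None,
              jobs: int = 1, output=None) -> pd.DataFrame:
    """Run every cell of a config; returns (and optionally writes) the table."""
    cfg = load_config(source)
    specs = expand_cells(cfg, seed=seed, replications=replications)
    if jobs > 1 and len(specs) > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=jobs)(delayed(run_cell)(s) for s in specs)
    else:
        results = []
        for i, s in enumerate(specs):
            logger.info("cell %d/%d: %s", i + 1, len(specs), s.key())
            results.append(run_cell(s))
    rows = [r.to_row() for r in results]
    columns = ["scenario", "mechanism", "rate", "n", "method", "strategy",
               "bias", "sd", "se", "rmse", "replications", "failures", "valid"]
    df = pd.DataFrame(rows, columns=columns)
    out = output or cfg.get("output")
    if out:
        df.to_csv(out, sep="\t", index=False)
    return df


#: Strategy sets per method in the published result-table layout.
_TABLE_METHOD_ORDER = (
    "complete", "comGBM", "SI_PE_PU", "SI_PE", "TMI", "MI", "MIMP",
    "GBM_incomplete", "GBM_SI_PE",
)
_FOUR_STRATEGIES = ("true_confounders", "leave_x1_out", "add_x5",
                    "leave_x1_out_add_x5")


def table_cells(scenario: str = "A", n: int = 500, rate: float = 0.25) -> list[dict]:
    """Cell entries reproducing one published results table.

    Logistic methods run under all four inclusion strategies; GBM methods
    and the GBM baseline use the true confounders only.  The complete-data
    baselines use mechanism "none".
    """
    cells = [
        {"scenario": scenario, "n": n, "mechanism": "none", "rate": rate,
         "method": "complete", "strategy": list(_FOUR_STRATEGIES)},
        {"scenario": scenario, "n": n, "mechanism": "none", "rate": rate,
         "method": "comGBM", "strategy": "true_confounders"},
    ]
    for mech in ("MCAR", "MAR1", "MAR2", "MARSINISTER"):
        cells.append({"scenario": scenario, "n": n, "mechanism": mech,
                      "rate": rate,
                      "method": ["SI_PE_PU", "SI_PE", "TMI", "MI", "MIMP"],
                      "strategy": list(_FOUR_STRATEGIES)})
        cells.append({"scenario": scenario, "n": n, "mechanism": mech,
                      "rate": rate,
                      "method": ["GBM_incomplete", "GBM_SI_PE"],
                      "strategy": "true_confounders"})
    return cells


def report_table(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a results table into the published layout.

    One row per (mechanism, method), one column block per inclusion
    strategy with bias, SD, SE and RMSE.
    """
    rows = []
    mech_order = {m: i for i, m in enumerate(MECHANISMS)}
    meth_order = {m: i for i, m in enumerate(_TABLE_METHOD_ORDER)}
    grouped = df.groupby(["mechanism", "method"], sort=False)
    for (mech, method), sub in grouped:
        row = {"mechanism": mech, "method": method}
        for _, rec in sub.iterrows():
            tag = rec["strategy"]
            row[f"bias[{tag}]"] = rec["bias"]
            row[f"sd[{tag}]"] = rec["sd"]
            row[f"se[{tag}]"] = rec["se"]
            row[f"rmse[{tag}]"] = rec["rmse"]
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=["mechanism", "method"],
        key=lambda s: s.map(mech_order if s.name == "mechanism" else meth_order),
        kind="stable",
    ).reset_index(drop=True)
    return out
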