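"""End-to-end orchestration: simulate -> analyze -> report, plus the
type-I / power calibration study.

Every entry point takes one top-level seed and derives independent
substreams from it, so a report is reproducible bit-for-bit from the
(config, seed) pair it embeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as tm
from . import trading
from .io import read_experiment_csv, replicates_from_frame
from .replicates import Treatment
from .synthetic import SimulationConfig, generate_experiment, simulate_permeable_pairs
from .trading import Tail

__all__ = [
    "PowerCurve",
    "run_power_study",
    "trading_report",
    "models_report",
    "run_end_to_end",
    "load_config",
]

logger = logging.getLogger("ctenotrade")

#: treatments whose eggs are self-fertilised (no partner sperm in the water)
_SELFED = {Treatment.SOLITARY.value, Treatment.SEALED.value}

DEFAULT_LOW_EGG_THRESHOLD = 25


@dataclass(frozen=True)
class PowerCurve:
    """Rejection rate of the upper-tail trading test as a function of the
    suppression strength gamma."""

    gamma_values: tuple[float, ...]
    rejection_rates: tuple[float, ...]
    alpha: float
    n_replicates: int
    n_experiments: int
    seed: int


def run_power_study(
    gamma_grid: list[float],
    n_replicates: int = 26,
    alpha: float = 0.05,
    n_experiments: int = 2000,
    seed: int = 0,
    config: SimulationConfig | None = None,
    include_drift: bool = False,
) -> PowerCurve:
    """Estimate the upper-tail rejection rate across a gamma grid.

    For each gamma, ``n_experiments`` paired arms of ``n_replicates``
    pairs are simulated and tested against the uniform-split null at
    level ``alpha``.  The rejection rule uses the exact Irwin-Hall
    critical value, which the Monte-Carlo null converges to; gamma = 0
    therefore measures the type-I error and larger gammas the power.

    By default the pairs are simulated under the spawning model alone
    (suppression, size-dependent fecundity), without cross-barrier egg
    drift: drift is a nuisance of the permeable arena that shrinks every
    proportion difference by the factor 1 - 2 * drift_rate and thereby
    makes the uniform-split test strictly conservative.
    ``include_drift=True`` keeps it, to quantify that conservatism.
    """
    if not gamma_grid:
        raise ValueError("gamma_grid must be non-empty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    base = config or SimulationConfig()
    if not include_drift:
        base = dataclasses.replace(base, drift_rate=0.0)
    critical: dict[int, float] = {}

    def crit(n: int) -> float:
        if n not in critical:
            critical[n] = trading.irwin_hall_critical_value(alpha, n, Tail.UPPER)
        return critical[n]

    ss = np.random.SeedSequence(seed)
    rates = []
    for gamma, child in zip(gamma_grid, ss.spawn(len(gamma_grid))):
        rng = np.random.default_rng(child)
        rejections = 0
        for _ in range(n_experiments):
            e1, e2 = simulate_permeable_pairs(n_replicates, base, rng, gamma=gamma)
            totals = e1 + e2
            valid = totals > 0  # double-zero pairs carry no split information
            n_valid = int(valid.sum())
            if n_valid == 0:
                continue
            stat = float(np.abs((e1[valid] - e2[valid]) / totals[valid]).sum())
            if stat > crit(n_valid):
                rejections += 1
        rates.append(rejections / n_experiments)
        logger.info("power study: gamma=%.2f rejection rate=%.4f", gamma, rates[-1])
    return PowerCurve(
        gamma_values=tuple(float(g) for g in gamma_grid),
        rejection_rates=tuple(rates),
        alpha=alpha,
        n_replicates=n_replicates,
        n_experiments=n_experiments,
        seed=seed,
    )


def _result_dict(res: trading.TradingTestResult) -> dict:
    return {
        "observed_total": res.observed.value,
        "n_replicates": res.observed.n_replicates,
        "tail": res.tail.value,
        "exceed_count": res.exceed_count,
        "p_mc": res.p_mc,
        "p_analytic": res.p_analytic,
        "n_sims": res.n_sims,
        "seed": res.seed,
        "tie_correction": res.tie_correction,
        "filters_applied": list(res.filters_applied),
    }


def trading_report(
    frame: pd.DataFrame,
    n_sims: int = 10_000,
    seed: int = 0,
    tie_correction: bool = False,
    sensitivity_threshold: int | None = DEFAULT_LOW_EGG_THRESHOLD,
) -> dict:
    """The gamete-trading analysis of one experiment table.

    Runs the upper-tail test on the permeable arm and the lower-tail
    test on the sealed arm (each against a freshly simulated null with
    the post-filter replicate count), the pooled t-test comparing the
    two arms' per-replicate absolute differences, and — when a
    sensitivity threshold is given — the low-egg-count rerun of both
    the permeable test and the t-test.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    permeable = replicates_from_frame(frame, Treatment.PERMEABLE)
    sealed = replicates_from_frame(frame, Treatment.SEALED)
    logger.info("trading analysis: %d permeable, %d sealed replicates loaded",
                len(permeable), len(sealed))

    perm_res = trading.trading_test(
        permeable, tail=Tail.UPPER, n_sims=n_sims, seed=seeds[0],
        tie_correction=tie_correction,
    )
    seal_res = trading.trading_test(
        sealed, tail=Tail.LOWER, n_sims=n_sims, seed=seeds[1],
        tie_correction=tie_correction,
    )

    def diffs(reps):
        kept = trading.filter_double_zero(reps)
        return [trading.proportion_split(r.eggs_a, r.eggs_b).abs_diff for r in kept]

    t_res = trading.compare_treatment_differences(diffs(permeable), diffs(sealed))
    report = {
        "permeable": _result_dict(perm_res),
        "sealed": _result_dict(seal_res),
        "t_test": dataclasses.asdict(t_res),
    }
    if sensitivity_threshold is not None:
        sens = trading.sensitivity_rerun(
            permeable, threshold=sensitivity_threshold, n_sims=n_sims,
            seed=seeds[2], tail=Tail.UPPER, tie_correction=tie_correction,
        )
        kept_perm = trading.filter_low_total(
            trading.filter_double_zero(permeable), sensitivity_threshold
        )
        sens_t = trading.compare_treatment_differences(
            [trading.proportion_split(r.eggs_a, r.eggs_b).abs_diff for r in kept_perm],
            diffs(sealed),
        )
        report["sensitivity"] = {
            "threshold": sensitivity_threshold,
            "trading_test": _result_dict(sens),
            "t_test": dataclasses.asdict(sens_t),
        }
    return report


def _arena_table(frame: pd.DataFrame, low_egg_threshold: int | None) -> pd.DataFrame:
    """One row per arena: combined eggs, combined developed, viability."""
    agg = (
        frame.groupby(["replicate_id", "treatment"], sort=False)
        .agg(eggs=("eggs", "sum"), developed=("eggs_developed", "sum"),
             block=("block_id", "first"))
        .reset_index()
    )
    n_before = len(agg)
    if low_egg_threshold is not None:
        agg = agg[agg["eggs"] > low_egg_threshold]
        logger.info("models: %d of %d arenas retained after the >%d-egg rule",
                    len(agg), n_before, low_egg_threshold)
    agg = agg.copy()
    agg["viability"] = [
        tm.viability_fraction(int(d), int(e))
        for d, e in zip(agg["developed"], agg["eggs"])
    ]
    return agg


def _fit_dict(fit: tm.LinearModelFit) -> dict:
    return {
        "response": fit.response_name,
        "F": fit.effect_F,
        "df": list(fit.effect_df),
        "p": fit.effect_p,
        "block_p": fit.block_p,
        "degenerate": fit.degenerate,
    }


def _tukey_dict(res: tm.TukeyResult) -> list[dict]:
    return [
        {"group_1": a, "group_2": b, "mean_diff": d, "q": q, "adjusted_p": p}
        for a, b, d, q, p in res.pairs
    ]


def models_report(
    frame: pd.DataFrame,
    low_egg_threshold: int | None = DEFAULT_LOW_EGG_THRESHOLD,
) -> dict:
    """Treatment-level models of egg output and viability.

    The blocked least-squares models cover the three in-block
    treatments (solitary, no-barrier, permeable); the four-treatment
    comparisons including the sealed arm use one-way ANOVA without a
    block term.  Arenas at or below the egg threshold are excluded from
    both responses.
    """
    arenas = _arena_table(frame, low_egg_threshold)
    blocked = arenas[arenas["block"].notna()].rename(columns={"block": "block_id"})
    report: dict = {"n_arenas": len(arenas)}

    for response in ("eggs", "viability"):
        entry: dict = {}
        fit = tm.blocked_least_squares(
            blocked, response=response, treatment="treatment", block="block_id"
        )
        entry["blocked"] = _fit_dict(fit)
        entry["blocked_tukey"] = _tukey_dict(
            tm.tukey_hsd(blocked, response=response, group="treatment", fit=fit)
        )
        fit4 = tm.one_way_anova(arenas, response=response, group="treatment")
        entry["four_treatment_anova"] = _fit_dict(fit4)
        entry["four_treatment_tukey"] = _tukey_dict(
            tm.tukey_hsd(arenas, response=response, group="treatment", fit=fit4)
        )
        entry["group_means"] = (
            arenas.groupby("treatment")[response].mean().to_dict()
        )
        report[response] = entry
    return report


def load_config(path) -> tuple[SimulationConfig, dict]:
    """Read a flat YAML config; keys matching :class:`SimulationConfig`
    fields configure the generator, the rest are analysis options."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a mapping of key: value pairs")
    field_names = {f.name for f in dataclasses.fields(SimulationConfig)}
    sim_kwargs = {k: v for k, v in raw.items() if k in field_names}
    extra = {k: v for k, v in raw.items() if k not in field_names}
    return SimulationConfig(**sim_kwargs), extra


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_end_to_end(
    config: SimulationConfig | str | Path,
    out_dir: str | Path,
    n_sims: int = 10_000,
    tie_correction: bool = False,
    low_egg_threshold: int | None = DEFAULT_LOW_EGG_THRESHOLD,
) -> dict:
    """Simulate one experiment, analyze it, and write all reports.

    Writes ``experiment.csv``, ``analysis.json`` (trading tests) and
    ``models.json`` (treatment models) under ``out_dir``; every report
    embeds the seed and a config hash so it can be regenerated exactly.
    Returns the combined report as a dict.
    """
    if not isinstance(config, SimulationConfig):
        config, extra = load_config(config)
        n_sims = int(extra.get("n_sims", n_sims))
        tie_correction = bool(extra.get("tie_correction", tie_correction))
        if "low_egg_threshold" in extra:
            v = extra["low_egg_threshold"]
            low_egg_threshold = None if v in (None, "none") else int(v)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    experiment = generate_experiment(config)
    csv_path = out / "experiment.csv"
    experiment.to_csv(csv_path)
    logger.info("wrote %s (%d rows)", csv_path, len(experiment.rows))

    frame = read_experiment_csv(csv_path)
    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": dataclasses.asdict(config),
    }
    analysis = {
        "provenance": provenance,
        **trading_report(frame, n_sims=n_sims, seed=config.seed,
                         tie_correction=tie_correction,
                         sensitivity_threshold=low_egg_threshold),
    }
    (out / "analysis.json").write_text(json.dumps(analysis, indent=2) + "\n")

    models = {
        "provenance": provenance,
        **models_report(frame, low_egg_threshold=low_egg_threshold),
    }
    (out / "models.json").write_text(json.dumps(models, indent=2) + "\n")
    return {"analysis": analysis, "models": models, "csv": str(csv_path)}
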