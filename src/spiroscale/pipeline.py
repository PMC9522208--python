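"""End-to-end analysis orchestration.

Order of operations: per-specimen gas-exchange capacities (summed and
doubled over the 8 spiracles), then allometric fits with bootstrap /
Bayesian / optional pGLS uncertainty for every spiracle x metric plus
the two whole-animal totals, then required-dPO2 curves over a mass
grid evaluated from the fitted total-conductance line.

Per-unit failures (an incomplete specimen, a degenerate metric) are
collected and logged with their identifiers; the run continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import units
from .biophysics import (
    ATMOSPHERIC_PO2_KPA,
    DEFAULT_CONSTANTS,
    DEFAULT_SCENARIOS,
    MetabolicScenario,
    PhysicalConstants,
    advective_conductance_from_index,
    diffusive_conductance_from_index,
    exceeds_atmosphere,
    metabolic_o2_demand,
    required_dpo2,
)
from .morphometry import (
    SPIRACLE_LABELS,
    IncompleteSpecimenError,
    Specimen,
    specimen_totals,
    to_morphometrics,
)
from .phylo import PhyloTree, pgls_fit, phylo_covariance
from .scaling import (
    ISOMETRY_REFERENCES,
    ScalingFit,
    bayes_loglog,
    bootstrap_fit,
    isometry_test,
    relative_variability,
)

logger = logging.getLogger(__name__)

PER_SPIRACLE_METRICS = ("depth", "area", "diff_index", "adv_index")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of a full pipeline run (defaults follow the study)."""

    constants: PhysicalConstants = DEFAULT_CONSTANTS
    scenarios: tuple[MetabolicScenario, ...] = DEFAULT_SCENARIOS
    bootstrap_B: int = 10_000
    seed: int = 0
    bayes: bool = True
    bayes_draws: int = 2000
    phylo: bool = False
    pgls_lambda: float = 1.0
    literal_semi_axes: bool = False
    ci_level: float = 0.95
    mass_grid_points: int = 200

    def __post_init__(self):
        if not self.scenarios:
            raise ValueError("scenarios must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "constants" in raw:
            kwargs["constants"] = PhysicalConstants(**raw.pop("constants"))
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(
                MetabolicScenario(**s) for s in raw.pop("scenarios")
            )
        kwargs.update(raw)
        return cls(**kwargs)


def run_capacities(
    specimens: Sequence[Specimen], config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Per-specimen whole-animal conductances and scenario dPO2 values.

    Columns: specimen id/species/mass, total G_diff (nmol s^-1 kPa^-1),
    total G_adv (m^3 s^-1 kPa^-1), and per scenario the required dPO2
    (kPa) plus a flag where it exceeds the 21 kPa atmospheric ceiling.
    Incomplete specimens are reported and skipped.
    """
    rows, errors = [], []
    for s in specimens:
        try:
            totals = specimen_totals(s, literal_semi_axes=config.literal_semi_axes)
        except IncompleteSpecimenError as exc:
            logger.error("skipping specimen %s: %s", s.specimen_id, exc)
            errors.append((s.specimen_id, str(exc)))
            continue
        g_diff = diffusive_conductance_from_index(totals.diff_index, config.constants)
        g_adv = advective_conductance_from_index(
            totals.adv_index * units.M3_PER_CM3_ADVECTIVE, config.constants
        )
        row = {
            "specimen_id": s.specimen_id,
            "species": s.species,
            "mass_g": s.mass,
            "total_area_cm2": totals.area,
            "total_diff_index_cm": totals.diff_index,
            "total_adv_index_cm3": totals.adv_index,
            "g_diff_nmol_s_kpa": g_diff,
            "g_adv_m3_s_kpa": g_adv,
        }
        for scen in config.scenarios:
            d = required_dpo2(s.mass, g_diff, scen, config.constants)
            row[f"dpo2_{scen.name}_kpa"] = d
            row[f"exceeds_atm_{scen.name}"] = bool(exceeds_atmosphere(d))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["errors"] = errors
    return df


def _metric_values(specimens, label, metric, literal_semi_axes):
    """(masses, values) for one spiracle metric, silently dropping
    specimens without that spiracle."""
    masses, vals = [], []
    for s in specimens:
        try:
            m = s.spiracle(label)
        except KeyError:
            continue
        rec = to_morphometrics(m, literal_semi_axes=literal_semi_axes)
        masses.append(s.mass)
        vals.append(getattr(rec, metric))
    return np.array(masses), np.array(vals)


def _total_values(specimens, which, literal_semi_axes):
    masses, vals = [], []
    for s in specimens:
        try:
            t = specimen_totals(s, literal_semi_axes=literal_semi_axes)
        except IncompleteSpecimenError:
            continue
        masses.append(s.mass)
        vals.append(t.diff_index if which == "total_diff" else t.adv_index)
    return np.array(masses), np.array(vals)


def _fit_one(masses, values, metric, label, config, species=None, tree=None, sub_seed=0):
    ref = ISOMETRY_REFERENCES[metric]
    boot = bootstrap_fit(
        masses,
        values,
        B=config.bootstrap_B,
        seed=sub_seed,
        ci_level=config.ci_level,
        metric=metric,
        label=label,
    )
    fit = boot.fit
    ci_lo, ci_hi = boot.ci("slope")
    rv_med, rv_lo, rv_hi = relative_variability(boot)
    row = {
        "spiracle": label,
        "metric": metric,
        "n": fit.n,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "residual_sd": fit.residual_sd,
        "isometry_reference": ref,
        "ci_low": ci_lo,
        "ci_high": ci_hi,
        "p_isometry": isometry_test(boot, ref),
        "relative_variability": relative_variability(fit),
        "rel_var_median": rv_med,
        "rel_var_low": rv_lo,
        "rel_var_high": rv_hi,
    }
    if config.bayes:
        post = bayes_loglog(
            masses, values, draws=config.bayes_draws, seed=sub_seed
        )
        h_lo, h_hi = post.hpd("slope", 0.95)
        row.update(
            bayes_slope_median=post.slope_median,
            bayes_hpd_low=h_lo,
            bayes_hpd_high=h_hi,
            bayes_converged=post.converged,
        )
    if config.phylo and tree is not None and species is not None:
        V = phylo_covariance(tree, species, lam=config.pgls_lambda)
        g = pgls_fit(masses, values, V, metric=metric, label=label)
        row.update(pgls_slope=g.slope, pgls_intercept=g.intercept)
    return row


def run_scaling(
    specimens: Sequence[Specimen],
    tree: PhyloTree | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Fit report: 8 spiracles x 4 metrics + 2 whole-animal totals.

    Each row carries the OLS fit, percentile bootstrap CI, isometry
    p-value, relative variability (point and bootstrap summary) and,
    when enabled, Bayesian HPD and pGLS columns.
    """
    rows, errors = [], []
    sub = np.random.SeedSequence(config.seed).spawn(
        len(SPIRACLE_LABELS) * len(PER_SPIRACLE_METRICS) + 2
    )
    k = 0
    for label in SPIRACLE_LABELS:
        for metric in PER_SPIRACLE_METRICS:
            masses, vals = _metric_values(
                specimens, label, metric, config.literal_semi_axes
            )
            seed_k = int(sub[k].generate_state(1)[0] % (2**31))
            k += 1
            if len(masses) < 3:
                errors.append((label, metric, "fewer than 3 measurements"))
                logger.error("skipping %s/%s: fewer than 3 measurements", label, metric)
                continue
            species = [
                s.species
                for s in specimens
                if label not in s.missing_labels
            ]
            try:
                rows.append(
                    _fit_one(masses, vals, metric, label, config,
                             species=species, tree=tree, sub_seed=seed_k)
                )
            except Exception as exc:
                errors.append((label, metric, str(exc)))
                logger.error("fit failed for %s/%s: %s", label, metric, exc)
    for which in ("total_diff", "total_adv"):
        masses, vals = _total_values(specimens, which, config.literal_semi_axes)
        seed_k = int(sub[k].generate_state(1)[0] % (2**31))
        k += 1
        if len(masses) < 3:
            errors.append(("total", which, "fewer than 3 complete specimens"))
            continue
        species = [s.species for s in specimens if not s.missing_labels]
        try:
            rows.append(
                _fit_one(masses, vals, which, "total", config,
                         species=species, tree=tree, sub_seed=seed_k)
            )
        except Exception as exc:
            errors.append(("total", which, str(exc)))
            logger.error("fit failed for total/%s: %s", which, exc)
    df = pd.DataFrame(rows)
    df.attrs["errors"] = errors
    return df


def total_diff_fit_from_report(report: pd.DataFrame) -> ScalingFit:
    row = report[report["metric"] == "total_diff"].iloc[0]
    return ScalingFit(
        slope=float(row["slope"]),
        intercept=float(row["intercept"]),
        residual_sd=float(row["residual_sd"]),
        n=int(row["n"]),
        metric="total_diff",
        label="total",
    )


def dpo2_from_conductance_line(
    mass, fit: ScalingFit, scen: MetabolicScenario,
    c: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Required dPO2 (kPa) at ``mass`` from the fitted total diffusive
    index line: G(m) = K * 10^(intercept + slope log10 m)."""
    mass = np.asarray(mass, dtype=float)
    g = c.krogh_K * 10.0 ** fit.predict_log10(mass)
    return metabolic_o2_demand(mass, scen, c) / g


def ceiling_crossing_mass(
    fit: ScalingFit, scen: MetabolicScenario,
    c: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Mass (g) where the scenario's required dPO2 reaches the 21 kPa
    atmospheric ceiling on the fitted line (closed-form inversion);
    inf when demand scales no faster than conductance."""
    if scen.exponent <= fit.slope:
        return float("inf")
    a = (
        np.log10(scen.aerobic_scope)
        + c.mr_intercept
        - np.log10(c.e_per_nl * c.nl_per_nmol)
        - np.log10(c.krogh_K)
        - fit.intercept
    )
    x = (np.log10(ATMOSPHERIC_PO2_KPA) - a) / (scen.exponent - fit.slope)
    return float(10.0**x)


def run_dpo2_curves(
    report: pd.DataFrame,
    mass_range: tuple[float, float],
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Scenario dPO2 curves on a log-spaced mass grid, evaluated from
    the fitted total-conductance regression line."""
    fit = total_diff_fit_from_report(report)
    lo, hi = mass_range
    grid = np.logspace(np.log10(lo), np.log10(hi), config.mass_grid_points)
    out = {"mass_g": grid}
    for scen in config.scenarios:
        d = dpo2_from_conductance_line(grid, fit, scen, config.constants)
        out[f"dpo2_{scen.name}_kpa"] = d
        out[f"exceeds_atm_{scen.name}"] = d > ATMOSPHERIC_PO2_KPA
    return pd.DataFrame(out)


def run_all(
    specimens: Sequence[Specimen],
    tree: PhyloTree | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Capacities + fit report + curves; optionally persisted as CSVs."""
    capacities = run_capacities(specimens, config)
    report = run_scaling(specimens, tree=tree, config=config)
    masses = capacities["mass_g"]
    curves = run_dpo2_curves(report, (masses.min(), masses.max()), config)
    results = {"capacities": capacities, "fit_report": report, "curves": curves}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return results
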