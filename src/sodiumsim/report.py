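"""Human-readable reporting: results tables, sodium trajectory plot, metadata.

Every number in a written report traces back to a raw ledger cell; rounding
to 2 significant digits happens only at presentation. A stored run
(config + seed + code version) regenerates its report bit-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .engine import PairedRun
from .outcomes import (
    CostParams,
    cost_savings,
    prevented_or_postponed,
    render_cost_results,
    render_results,
    to_usd,
)

__all__ = ["report", "baseline_totals", "plot_sodium_by_year", "write_run_outputs"]

log = logging.getLogger(__name__)


def baseline_totals(pair: PairedRun, costs: CostParams | None = None) -> dict:
    """Baseline-scenario cumulative totals: percent-of-total denominators."""
    base = pair.baseline.ledger.table
    totals = {
        "chd_cases": float(base.case_years_chd.sum()),
        "stroke_cases": float(base.case_years_stroke.sum()),
        "chd_deaths": float(base.deaths_chd.sum()),
        "stroke_deaths": float(base.deaths_stroke.sum()),
        "noncvd_deaths": float(base.deaths_other.sum()),
    }
    totals["all_deaths"] = (
        totals["chd_deaths"] + totals["stroke_deaths"] + totals["noncvd_deaths"]
    )
    if costs is not None:
        cost_total_brl = 0.0
        for disease, col in (("chd", "case_years_chd"), ("stroke", "case_years_stroke")):
            unit = costs.sus_unit_cost(disease) + costs.informal[disease]
            per_year = base[col].groupby(level="year").sum()
            disc = per_year / (1.0 + costs.discount_rate) ** (
                per_year.index.to_numpy() - costs.discount_base_year
            )
            cost_total_brl += float(disc.sum()) * unit
        totals["cost_usd_millions"] = to_usd(cost_total_brl, costs) / 1e6
    return totals


def plot_sodium_by_year(pair: PairedRun, path) -> None:
    """Median daily sodium by year for the two scenarios (policy ramp view)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for result, style in ((pair.baseline, "-"), (pair.policy, "--")):
        ax.plot(
            result.yearly.year,
            result.yearly.median_sodium,
            style,
            label=result.scenario.name,
        )
    ax.set_xlabel("year")
    ax.set_ylabel("median sodium intake (g/day)")
    ax.legend()
    ax.set_title("Median daily sodium consumption by scenario")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(
    pair: PairedRun,
    costs: CostParams | None = None,
    out_dir=None,
    config_digest: str | None = None,
    psa_summary: pd.DataFrame | None = None,
) -> dict:
    """Build the results tables (and optionally write a full report directory).

    Returns {'health': DataFrame, 'costs': DataFrame, 'yearly': DataFrame};
    with ``out_dir`` set, also writes CSV tables, the sodium-by-year plot
    and a run-metadata file. Partial inputs yield a partial report with the
    gaps logged rather than an error.
    """
    costs = costs or CostParams()
    case_diff = prevented_or_postponed(pair.baseline.ledger, pair.policy.ledger, "cases")
    death_diff = prevented_or_postponed(pair.baseline.ledger, pair.policy.ledger, "deaths")
    denominators = baseline_totals(pair, costs)
    health = render_results(case_diff, death_diff, denominators)
    savings = cost_savings(case_diff, costs)
    cost_table = render_cost_results(savings, denominators.get("cost_usd_millions"))
    yearly = pair.baseline.yearly.merge(
        pair.policy.yearly, on="year", suffixes=("_baseline", "_policy")
    )
    out = {"health": health, "costs": cost_table, "yearly": yearly, "savings": savings}
    if psa_summary is not None:
        out["psa_summary"] = psa_summary

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_run_outputs(pair, out, out_dir, config_digest=config_digest)
    return out


def write_run_outputs(pair: PairedRun, tables: dict, out_dir: Path, config_digest=None) -> None:
    pair.baseline.ledger.frame().to_csv(out_dir / "ledger_baseline.csv", index=False)
    pair.policy.ledger.frame().to_csv(out_dir / "ledger_reformulation.csv", index=False)
    tables["health"].to_csv(out_dir / "health_outcomes.csv", index=False)
    tables["costs"].to_csv(out_dir / "cost_outcomes.csv", index=False)
    tables["yearly"].to_csv(out_dir / "exposure_by_year.csv", index=False)
    if "psa_summary" in tables:
        tables["psa_summary"].to_csv(out_dir / "psa_summary.csv", index=False)
    plot_sodium_by_year(pair, out_dir / "sodium_by_year.png")
    meta = {
        "seed": pair.config.seed,
        "cohort_size": pair.config.cohort_size,
        "years": [pair.config.start_year, pair.config.end_year],
        "config_sha256": config_digest,
        "sodiumsim_version": __version__,
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    log.info("report written to %s", out_dir)
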