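"""Base case, scenario analyses, univariate sensitivity and table export.

Six alternative scenarios surround the base case (ERT started when
symptoms develop, males and females 1:1, direct and indirect medical
costs, discounting reported both at 0% and differentially at 1.5% effects /
4% costs):

1. ``s1_start40``     — ERT delayed until age 40;
2. ``s2_utility_gap`` — untreated patients live with a 0.1 lower utility in
   every alive cluster (floored at 0);
3. ``s3_classical_only`` — classical-phenotype progression (an alternative
   transition-probability preset);
4. ``s4_ace_arb``     — standard care includes ACE inhibitors / ARBs, which
   are assumed to match ERT's first-complication risk reduction in the
   comparator arm;
5. ``s5_stop_after_2`` — no ERT once a second complication has occurred;
6. ``s6_production_loss`` — production-loss costs added from age 18.

Each scenario reduces exactly to the base case when its override is
neutral.  Reports mirror the published layout: incremental effects,
incremental costs, ICERs and scenario ICERs as delimited files with run
metadata (seed, version, parameter hash) alongside.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd

from . import __version__ as _pkg_version
from .economics import PSAResult
from .engine import CEResult, Strategy, compare_strategies
from .parameters import ParameterSet

__all__ = [
    "SCENARIO_IDS",
    "ScenarioSpec",
    "run_scenario",
    "run_all_scenarios",
    "sensitivity_drug_price",
    "report_tables",
]

SCENARIO_IDS = (
    "base",
    "s1_start40",
    "s2_utility_gap",
    "s3_classical_only",
    "s4_ace_arb",
    "s5_stop_after_2",
    "s6_production_loss",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario as a set of documented overrides on the base case."""

    id: str
    strategy_rule: Optional[str] = None  # None -> base rule from the params
    utility_offset_untreated: float = 0.0
    use_classical_preset: bool = False
    comparator_first_rrr: bool = False
    include_production_loss: bool = False

    @staticmethod
    def for_id(scenario_id: str) -> "ScenarioSpec":
        table = {
            "base": ScenarioSpec("base"),
            "s1_start40": ScenarioSpec("s1_start40", strategy_rule="at-age-40"),
            "s2_utility_gap": ScenarioSpec(
                "s2_utility_gap", utility_offset_untreated=0.1
            ),
            "s3_classical_only": ScenarioSpec(
                "s3_classical_only", use_classical_preset=True
            ),
            "s4_ace_arb": ScenarioSpec("s4_ace_arb", comparator_first_rrr=True),
            "s5_stop_after_2": ScenarioSpec(
                "s5_stop_after_2", strategy_rule="stop-after-2-complications"
            ),
            "s6_production_loss": ScenarioSpec(
                "s6_production_loss", include_production_loss=True
            ),
        }
        try:
            return table[scenario_id]
        except KeyError:
            raise ValueError(
                f"unknown scenario {scenario_id!r}; choose from {SCENARIO_IDS}"
            ) from None


def run_scenario(
    spec: ScenarioSpec,
    params: ParameterSet,
    classical_params: Optional[ParameterSet] = None,
) -> CEResult:
    """Run one scenario; the returned :class:`CEResult` carries both the
    discounted and the undiscounted outcomes."""
    if spec.use_classical_preset:
        if classical_params is None:
            raise ValueError(
                "scenario s3_classical_only needs the classical parameter preset"
            )
        params = classical_params
    if spec.include_production_loss:
        params = replace(params, include_production_loss=True)
    rule = spec.strategy_rule or params.ert_start_rule
    active = Strategy.from_rule(rule)
    return compare_strategies(
        params,
        active,
        utility_offset_comparator=spec.utility_offset_untreated,
        comparator_first_rrr=spec.comparator_first_rrr,
    )


def run_all_scenarios(
    params: ParameterSet,
    classical_params: Optional[ParameterSet] = None,
    scenario_ids: Iterable[str] = SCENARIO_IDS,
) -> Dict[str, CEResult]:
    out: Dict[str, CEResult] = {}
    for sid in scenario_ids:
        spec = ScenarioSpec.for_id(sid)
        if spec.use_classical_preset and classical_params is None:
            continue  # recorded as incomplete by report_tables
        out[sid] = run_scenario(spec, params, classical_params)
    return out


def sensitivity_drug_price(params: ParameterSet, new_price: float) -> CEResult:
    """Re-run the base case with the annual ERT price replaced."""
    if new_price < 0:
        raise ValueError("price must be non-negative")
    return run_scenario(
        ScenarioSpec.for_id("base"), replace(params, cost_ert=new_price)
    )


# ---------------------------------------------------------------------------
# Table export


_GROUPS = (("ALL", "all"), ("MALES", "male"), ("FEMALES", "female"))


def _effects_table(result: CEResult) -> pd.DataFrame:
    rows = []
    for label, key in _GROUPS:
        a, c = result.active[key], result.comparator[key]
        for outcome, attr in (("YFEOD", "yfeod"), ("QALYs", "qalys")):
            rows.append(
                {
                    "group": label,
                    "outcome": outcome,
                    "ert_discounted": getattr(a, attr + "_disc"),
                    "no_ert_discounted": getattr(c, attr + "_disc"),
                    "difference_discounted": getattr(a, attr + "_disc")
                    - getattr(c, attr + "_disc"),
                    "ert_undiscounted": getattr(a, attr),
                    "no_ert_undiscounted": getattr(c, attr),
                    "difference_undiscounted": getattr(a, attr) - getattr(c, attr),
                }
            )
    return pd.DataFrame(rows)


def _costs_table(result: CEResult) -> pd.DataFrame:
    rows = []
    for label, key in _GROUPS:
        a, c = result.active[key], result.comparator[key]
        rows.append(
            {
                "group": label,
                "ert_discounted": a.cost_disc,
                "no_ert_discounted": c.cost_disc,
                "difference_discounted": a.cost_disc - c.cost_disc,
                "ert_undiscounted": a.cost,
                "no_ert_undiscounted": c.cost,
                "difference_undiscounted": a.cost - c.cost,
            }
        )
    return pd.DataFrame(rows)


def _icer_table(result: CEResult) -> pd.DataFrame:
    rows = []
    for label, key in _GROUPS:
        for outcome, attr in (("YFEOD", "yfeod"), ("QALY", "qalys")):
            rows.append(
                {
                    "group": label,
                    "outcome": outcome,
                    "icer_discounted": result.icer(attr, key, True).value,
                    "icer_undiscounted": result.icer(attr, key, False).value,
                }
            )
    return pd.DataFrame(rows)


def _scenario_table(results: Mapping[str, CEResult]) -> pd.DataFrame:
    rows = []
    for sid, res in results.items():
        rows.append(
            {
                "scenario": sid,
                "icer_yfeod_discounted": res.icer("yfeod", "all", True).value,
                "icer_yfeod_undiscounted": res.icer("yfeod", "all", False).value,
                "icer_qaly_discounted": res.icer("qalys", "all", True).value,
                "icer_qaly_undiscounted": res.icer("qalys", "all", False).value,
            }
        )
    return pd.DataFrame(rows)


def report_tables(
    results: Mapping[str, CEResult],
    out_dir: str | Path,
    params: Optional[ParameterSet] = None,
    psa: Optional[PSAResult] = None,
    seed: Optional[int] = None,
) -> Dict[str, Path]:
    """Write the effects / costs / ICER / scenario tables plus run metadata.

    ``results`` maps scenario ids to :class:`CEResult`; the base-case entry
    feeds the first three tables.  Scenarios missing from ``results`` are
    listed in the metadata as incomplete rather than silently dropped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    if "base" in results:
        base = results["base"]
        for name, frame in (
            ("table_effects", _effects_table(base)),
            ("table_costs", _costs_table(base)),
            ("table_icers", _icer_table(base)),
        ):
            path = out_dir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written[name] = path
    scen_path = out_dir / "table_scenarios.csv"
    _scenario_table(results).to_csv(scen_path, index=False)
    written["table_scenarios"] = scen_path
    if psa is not None:
        ceac_path = out_dir / "ceac.csv"
        psa.ceac_frame().to_csv(ceac_path, index=False)
        written["ceac"] = ceac_path
        draws_path = out_dir / "psa_draws.csv"
        psa.draws_frame().to_csv(draws_path, index=False)
        written["psa_draws"] = draws_path
    missing = [sid for sid in SCENARIO_IDS if sid not in results]
    meta = {
        "version": _pkg_version,
        "seed": seed,
        "parameter_hash": params.content_hash() if params is not None else None,
        "scenarios": sorted(results),
        "incomplete": missing,
        "status": "incomplete" if missing else "complete",
    }
    if psa is not None:
        meta["psa"] = {k: v for k, v in psa.settings.items()}
        meta["psa"]["seed"] = psa.seed
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    written["metadata"] = meta_path
    return written
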