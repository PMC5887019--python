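"""The decalin study: bond-set class counts, plan-count distribution,
best-TW searches, and yield-sensitivity of the plan ranking.

These drivers string the other modules together exactly the way the
headline numbers are produced: enumerate non-isomorphic bond sets of the
target skeleton, build each class's hypergraph of reactions, enumerate or
rank its hyperpaths, and score them with carbon-proportional retro yields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .hor import HoR, SynthesisPlan, build_hor_from_bond_set, hyperpath_to_plan
from .hypergraph import Hyperpath
from .ksh import RankedPlanList, enumerate_all_hyperpaths, k_shortest_hyperpaths, shortest_hyperpath
from .measures import assign_retro_yields, round_printed, tw
from .molecules import BondSet, MoleculeGraph, enumerate_bond_set_classes, remove_bonds

__all__ = [
    "DEFAULT_MODE",
    "BondSetReport",
    "PlanCountDistribution",
    "plan_count_distribution",
    "best_tw",
    "ranking_first_disagreement",
    "survey",
    "write_survey",
]

# Molecule-identity mode under which the decalin plan-count distribution
# (two 3-plan classes, one 5, one 8, max 38, total 1711) is reproduced;
# isomorphic fragments share a HoR vertex, per the same-label rule.
DEFAULT_MODE = "isomorphism"


@dataclass
class PlanCountDistribution:
    """Histogram plan-count -> number of bond-set classes."""

    histogram: dict[int, int]
    total: int
    max: int
    n_classes: int


@dataclass
class BondSetReport:
    """Everything the survey records for one bond-set class."""

    bond_set_id: int
    members: tuple[int, ...]
    component_count: int
    plan_count: int
    tw_by_rho: dict[float, list[float]]
    first_disagreement: int | None  # None means the rankings agree


def plan_count_distribution(
    target: MoleculeGraph, k: int, mode: str = DEFAULT_MODE
) -> PlanCountDistribution:
    """For every size-k bond-set class, count the synthesis plans (as
    hyperpaths of the class's HoR) and histogram the counts."""
    hist: dict[int, int] = {}
    classes = enumerate_bond_set_classes(target, k)
    for bs in classes:
        hor = build_hor_from_bond_set(target, bs, mode)
        n = len(enumerate_all_hyperpaths(hor.graph, hor.source, hor.target_vertex))
        hist[n] = hist.get(n, 0) + 1
    return PlanCountDistribution(
        histogram=dict(sorted(hist.items())),
        total=sum(n * c for n, c in hist.items()),
        max=max(hist),
        n_classes=len(classes),
    )


def best_tw(
    target: MoleculeGraph,
    k: int,
    rho_total: float,
    mode: str = DEFAULT_MODE,
) -> tuple[BondSet, SynthesisPlan, float]:
    """Minimum TW over all plans of all size-k bond-set classes, with
    carbon-proportional retro yields."""
    best: tuple[float, BondSet, HoR, Hyperpath] | None = None
    for bs in enumerate_bond_set_classes(target, k):
        hor = build_hor_from_bond_set(target, bs, mode)
        r = assign_retro_yields(hor, rho_total)
        sol = shortest_hyperpath(
            hor.graph, r, hor.source, hor.target_vertex
        )
        if sol is None:
            continue
        pi, weight = sol
        if best is None or weight < best[0]:
            best = (weight, bs, hor, pi)
    assert best is not None, "every bond set admits at least one plan"
    weight, bs, hor, pi = best
    return bs, hyperpath_to_plan(hor, pi), weight


def ranking_first_disagreement(
    a: RankedPlanList, b: RankedPlanList
) -> int | None:
    """First (1-based) position where two rankings of the same plan set
    differ as arc sets; None if they agree throughout."""
    sig_a = [p.arc_set for p in a.hyperpaths()]
    sig_b = [p.arc_set for p in b.hyperpaths()]
    if len(sig_a) != len(sig_b) or set(sig_a) != set(sig_b):
        raise ValueError("rankings do not cover the same plan set")
    for i, (x, y) in enumerate(zip(sig_a, sig_b), start=1):
        if x != y:
            return i
    return None


def survey(
    target: MoleculeGraph,
    k: int,
    rhos: Sequence[float] = (1.25, 2.5),
    mode: str = DEFAULT_MODE,
) -> list[BondSetReport]:
    """Full per-class report: plan counts, ranked TW lists at each retro
    yield total, and the first rank position where the rankings disagree."""
    reports = []
    for idx, bs in enumerate(enumerate_bond_set_classes(target, k)):
        hor = build_hor_from_bond_set(target, bs, mode)
        rankings: dict[float, RankedPlanList] = {}
        for rho in rhos:
            r = assign_retro_yields(hor, rho)
            rankings[rho] = k_shortest_hyperpaths(
                hor.graph, r, hor.source, hor.target_vertex, math.inf
            )
        counts = {len(rk) for rk in rankings.values()}
        assert len(counts) == 1, "plan count must not depend on the weights"
        disagree = None
        if len(rhos) >= 2:
            disagree = ranking_first_disagreement(
                rankings[rhos[0]], rankings[rhos[1]]
            )
        reports.append(
            BondSetReport(
                bond_set_id=idx,
                members=tuple(sorted(bs.members)),
                component_count=len(remove_bonds(target, bs.members)),
                plan_count=counts.pop(),
                tw_by_rho={rho: rankings[rho].weights() for rho in rhos},
                first_disagreement=disagree,
            )
        )
    return reports


def survey_frame(reports: Sequence[BondSetReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row: dict = {
            "bond_set_id": rep.bond_set_id,
            "members": " ".join(map(str, rep.members)),
            "component_count": rep.component_count,
            "plan_count": rep.plan_count,
            "first_disagreement": (
                "same" if rep.first_disagreement is None else rep.first_disagreement
            ),
        }
        for rho, tws in rep.tw_by_rho.items():
            row[f"best_tw_rho{rho}"] = round_printed(min(tws), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def disagreement_histogram(
    reports: Sequence[BondSetReport],
) -> dict[str, int]:
    """Count(i) per first-disagreement position, 'same' for full agreement."""
    out: dict[str, int] = {}
    for rep in reports:
        key = "same" if rep.first_disagreement is None else str(rep.first_disagreement)
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (kv[0] == "same", kv[0])))


def write_survey(
    reports: Sequence[BondSetReport],
    out_dir: str | Path,
    manifest: dict | None = None,
) -> None:
    """Write the per-class CSV, a JSON report, and a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey_frame(reports).to_csv(out / "bond_set_classes.csv", index=False)
    doc = {
        "n_classes": len(reports),
        "total_plans": sum(r.plan_count for r in reports),
        "max_plans": max((r.plan_count for r in reports), default=0),
        "first_disagreement_counts": disagreement_histogram(reports),
        "classes": [
            {
                "bond_set_id": r.bond_set_id,
                "members": list(r.members),
                "plan_count": r.plan_count,
                "tw_by_rho": {str(k): v for k, v in r.tw_by_rho.items()},
                "first_disagreement": r.first_disagreement,
            }
            for r in reports
        ],
    }
    (out / "survey.json").write_text(json.dumps(doc, indent=1))
    if manifest is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
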