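"""Traffic-light biliary viability scoring and histological bile-duct injury.

During normothermic machine perfusion (NMP), biliary viability is judged
from biochemical bile composition against per-criterion boundaries: a
measurement in the green band earns 2 points, orange 1 point, red 0.
The per-liver sum across criteria is the biliary viability score; livers
are called high or low either by a fixed point threshold or by copying
the clinical transplant decision.

Histological bile-duct injury (BDI) is graded before perfusion on four
ordinal components — vascular lesions, stromal necrosis, periluminal
peribiliary-gland (PBG) injury, and deep PBG injury.  Their sum is the
total BDI score; the cohort median of gradable totals splits livers into
high and low BDI groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_model import BileflowError, CohortMetadata

logger = logging.getLogger("bileflow")

COLOR_POINTS = {"green": 2, "orange": 1, "red": 0}

BDI_COMPONENTS = (
    "vascular_lesions",
    "stromal_necrosis",
    "periluminal_pbg_injury",
    "deep_pbg_injury",
)


@dataclass(frozen=True)
class CriterionDefinition:
    """A single bile-chemistry viability criterion.

    ``green`` and ``orange`` are boundary values in the measurement's own
    units; for ``higher_is_better`` a value >= green is green, >= orange
    is orange, else red (boundaries inclusive toward the better color).
    ``lower_is_better`` mirrors the comparisons.
    """

    name: str
    direction: str
    green: float
    orange: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("higher_is_better", "lower_is_better"):
            raise BileflowError(
                f"criterion {self.name!r}: direction must be higher_is_better "
                f"or lower_is_better, got {self.direction!r}"
            )
        if self.direction == "higher_is_better" and not self.green > self.orange:
            raise BileflowError(
                f"criterion {self.name!r}: green boundary must exceed orange "
                "for higher_is_better"
            )
        if self.direction == "lower_is_better" and not self.green < self.orange:
            raise BileflowError(
                f"criterion {self.name!r}: green boundary must lie below orange "
                "for lower_is_better"
            )


#: Representative biliary viability criteria (bile measured at the 150 min
#: viability assessment).  Boundary values are configuration, not a claim
#: about any particular center's protocol.
DEFAULT_CRITERIA = (
    CriterionDefinition("bile_ph", "higher_is_better", 7.48, 7.40, "pH"),
    CriterionDefinition("bile_bicarbonate", "higher_is_better", 18.0, 12.0, "mmol/L"),
    CriterionDefinition("bile_glucose", "lower_is_better", 4.0, 16.0, "mmol/L"),
    CriterionDefinition(
        "bile_perfusate_glucose_ratio", "lower_is_better", 0.45, 0.80, "ratio"
    ),
)


def read_criteria(path: str | Path) -> tuple[CriterionDefinition, ...]:
    """Load criterion definitions from YAML (list of mappings)."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    crits = tuple(CriterionDefinition(**entry) for entry in raw)
    names = [c.name for c in crits]
    if len(set(names)) != len(names):
        raise BileflowError("criterion names must be unique")
    return crits


def write_criteria(criteria: Sequence[CriterionDefinition], path: str | Path) -> None:
    entries = [
        dict(name=c.name, direction=c.direction, green=c.green, orange=c.orange,
             units=c.units)
        for c in criteria
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def grade_criterion(
    value: float | None,
    criterion: CriterionDefinition,
    missing_policy: str = "red",
) -> str:
    """Color a measurement green/orange/red against a criterion.

    A missing measurement defaults to red with a warning (a liver that
    produced no assessable bile fails that criterion); set
    ``missing_policy="error"`` to make it a hard error instead.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        if missing_policy == "error":
            raise BileflowError(f"missing measurement for criterion {criterion.name!r}")
        logger.warning(
            "missing measurement for criterion %r graded red", criterion.name
        )
        return "red"
    if not np.isfinite(value):
        raise BileflowError(
            f"non-finite measurement {value!r} for criterion {criterion.name!r}"
        )
    if criterion.direction == "higher_is_better":
        if value >= criterion.green:
            return "green"
        if value >= criterion.orange:
            return "orange"
        return "red"
    if value <= criterion.green:
        return "green"
    if value <= criterion.orange:
        return "orange"
    return "red"


def biliary_viability_score(colors: Sequence[str]) -> int:
    """Sum traffic-light points: green 2, orange 1, red 0."""
    if len(colors) == 0:
        raise BileflowError("at least one criterion color is required")
    bad = [c for c in colors if c not in COLOR_POINTS]
    if bad:
        raise BileflowError(f"unknown colors {bad}; expected green/orange/red")
    return sum(COLOR_POINTS[c] for c in colors)


def classify_viability(
    score: int,
    rule: str = "threshold",
    threshold: int | None = None,
    transplanted: bool | None = None,
) -> str:
    """Call a liver high or low biliary viability.

    ``rule="threshold"``: high iff score >= threshold (threshold must be
    given explicitly).  ``rule="transplant"``: copy the clinical
    transplant decision flag.
    """
    if score < 0:
        raise BileflowError("score must be nonnegative")
    if rule == "threshold":
        if threshold is None:
            raise BileflowError("threshold rule requires an explicit threshold")
        return "high" if score >= threshold else "low"
    if rule == "transplant":
        if transplanted is None:
            raise BileflowError("transplant rule requires the transplant flag")
        return "high" if transplanted else "low"
    raise BileflowError(f"unknown classification rule {rule!r}")


@dataclass
class ViabilityAssessment:
    liver_id: str
    colors: dict[str, str]
    total: int
    viability_class: str


def assess_cohort(
    chemistry: pd.DataFrame,
    criteria: Sequence[CriterionDefinition] = DEFAULT_CRITERIA,
    rule: str = "threshold",
    threshold: int | None = None,
    transplanted: Mapping[str, bool] | None = None,
    missing_policy: str = "red",
) -> pd.DataFrame:
    """Score every liver in a chemistry panel (livers x criterion columns).

    Returns a DataFrame indexed by liver id with one color column per
    criterion plus ``total`` and ``viability_class``.
    """
    rows = {}
    for liver_id, row in chemistry.iterrows():
        colors = {
            c.name: grade_criterion(row.get(c.name, np.nan), c, missing_policy)
            for c in criteria
        }
        total = biliary_viability_score(list(colors.values()))
        cls = classify_viability(
            total,
            rule=rule,
            threshold=threshold,
            transplanted=None if transplanted is None else transplanted[liver_id],
        )
        rows[liver_id] = {**colors, "total": total, "viability_class": cls}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "liver_id"
    return out


# ---------------------------------------------------------------------------
# Histological bile duct injury
# ---------------------------------------------------------------------------


@dataclass
class BDIScore:
    liver_id: str
    grades: dict[str, int | None]
    gradable: bool
    total: int | None
    bdi_class: str = "unset"


def total_bdi(
    liver_id: str,
    grades: Mapping[str, int | None],
    grade_scale: tuple[int, int] = (0, 4),
) -> BDIScore:
    """Sum the four ordinal component grades into a total BDI score.

    A liver is gradable only when all four components carry a grade; an
    ungradable liver has no total and is excluded from median splits.
    """
    missing_comp = [c for c in BDI_COMPONENTS if c not in grades]
    if missing_comp:
        raise BileflowError(f"missing BDI components: {missing_comp}")
    lo, hi = grade_scale
    clean: dict[str, int | None] = {}
    for comp in BDI_COMPONENTS:
        g = grades[comp]
        if g is None or (isinstance(g, float) and np.isnan(g)):
            clean[comp] = None
            continue
        gi = int(g)
        if gi != g or not lo <= gi <= hi:
            raise BileflowError(
                f"grade {g!r} for {comp!r} outside ordinal scale [{lo}, {hi}]"
            )
        clean[comp] = gi
    gradable = all(v is not None for v in clean.values())
    total = sum(v for v in clean.values() if v is not None) if gradable else None
    return BDIScore(liver_id, clean, gradable, total)


def classify_bdi_by_median(
    scores: Sequence[BDIScore],
    tie_to_high: bool = True,
) -> list[BDIScore]:
    """Split gradable livers at the cohort median total BDI score.

    Totals >= median are called high injury under the default tie-to-high
    policy (`tie_to_high=False` sends exact-median totals to low).
    Ungradable livers keep the ``ungradable`` class.
    """
    totals = [s.total for s in scores if s.gradable]
    if len(totals) == 0:
        raise BileflowError("no gradable livers; cannot compute median BDI")
    if len(totals) < 2:
        raise BileflowError("median split needs at least 2 gradable livers")
    median = float(np.median(totals))
    out = []
    for s in scores:
        s2 = BDIScore(s.liver_id, dict(s.grades), s.gradable, s.total)
        if not s.gradable:
            s2.bdi_class = "ungradable"
        elif s.total > median or (s.total == median and tie_to_high):
            s2.bdi_class = "high"
        else:
            s2.bdi_class = "low"
        out.append(s2)
    return out


def assess_bdi_cohort(
    histology: pd.DataFrame,
    grade_scale: tuple[int, int] = (0, 4),
    tie_to_high: bool = True,
) -> pd.DataFrame:
    """Score a histology table (livers x four component columns, NaN =
    ungradable component) and median-split the cohort.

    Returns a DataFrame indexed by liver id with component grades,
    ``total``, ``gradable`` and ``bdi_class``.
    """
    scores = [
        total_bdi(str(liver_id), row.to_dict(), grade_scale)
        for liver_id, row in histology[list(BDI_COMPONENTS)].iterrows()
    ]
    classed = classify_bdi_by_median(scores, tie_to_high=tie_to_high)
    rows = {
        s.liver_id: {
            **{c: s.grades[c] for c in BDI_COMPONENTS},
            "total": s.total,
            "gradable": s.gradable,
            "bdi_class": s.bdi_class,
        }
        for s in classed
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "liver_id"
    return out
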