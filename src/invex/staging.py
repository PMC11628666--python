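"""Histology-based staging of testis development.

Spermatogonia (SP) and elongating spermatids (ES) are counted in a handful of
histological sections per bird. The maturation index

    MI = (ES - SP) / (ES + SP)

scales between -1 (only spermatogonia) and 1 (only elongating spermatids) and,
together with two qualitative flags (elongating spermatids visible,
spermatocyte division visible), assigns each bird one of four developmental
stages:

* ``inactive``          -- no signs of spermatogenesis
* ``accelerating_I``    -- spermatocyte division but no elongating spermatids
* ``accelerating_II``   -- elongating spermatids, MI in [-0.7, 0.1]
* ``active``            -- elongating spermatids, MI in (0.1, 0.7]

For the expression analysis the four stages are pooled into two groups:
{inactive, accelerating_I} -> EARLY and {accelerating_II, active} -> LATE.

Section counts are summed per bird before the index is computed (a
depth-weighted aggregate, stable for shallow sections). The boundary MI = 0.1
belongs to accelerating_II; birds with elongating spermatids but MI outside
[-0.7, 0.7] are flagged unstageable rather than raising.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .containers import (
    EARLY_STAGES,
    LATE_STAGES,
    STAGES,
    ValidationError,
)

__all__ = [
    "UndefinedMaturationIndex",
    "StageAssignment",
    "maturation_index",
    "assign_stage",
    "stage_group",
    "pool_stage_groups",
    "call_stages",
]


class UndefinedMaturationIndex(ValidationError):
    """ES + SP = 0: the index is undefined (treat the bird via the ES = 0 rule)."""


@dataclass(frozen=True)
class StageAssignment:
    stage: str | None
    unstageable: bool


def maturation_index(es: int, sp: int) -> float:
    """(ES - SP) / (ES + SP) on counts pooled across sections; in [-1, 1]."""
    if es < 0 or sp < 0:
        raise ValidationError(f"negative histology counts: ES={es}, SP={sp}")
    total = es + sp
    if total == 0:
        raise UndefinedMaturationIndex(
            "maturation index undefined for ES + SP = 0; "
            "stage such birds through the ES = 0 rule instead"
        )
    return (es - sp) / total


def assign_stage(mi: float | None, has_es: bool, has_division: bool) -> StageAssignment:
    """Assign a developmental stage from the index and the qualitative flags.

    ``mi`` may be None when ``has_es`` is False (the index is not needed).
    With elongating spermatids present, an index outside [-0.7, 0.7] marks the
    bird unstageable (returned as a flag, not raised).
    """
    if not has_es:
        return StageAssignment("accelerating_I" if has_division else "inactive", False)
    if mi is None or not -0.7 <= mi <= 0.7:
        return StageAssignment(None, True)
    if mi <= 0.1:
        return StageAssignment("accelerating_II", False)
    return StageAssignment("active", False)


def stage_group(stage: str) -> str:
    if stage in EARLY_STAGES:
        return "EARLY"
    if stage in LATE_STAGES:
        return "LATE"
    raise ValidationError(f"unknown stage label {stage!r}; expected one of {list(STAGES)}")


def pool_stage_groups(stages: Sequence[str]) -> list[str]:
    """Pool stage labels into the EARLY/LATE analysis groups."""
    return [stage_group(s) for s in stages]


def call_stages(
    histology: pd.DataFrame,
    division_flags: Mapping[str, bool],
) -> pd.DataFrame:
    """Stage every bird in a histology table.

    ``histology`` needs columns bird_id, ES, SP (one row per section); section
    counts are summed per bird. ``division_flags`` supplies the externally
    scored has-spermatocyte-division flag per bird.

    Returns a table indexed by bird id with columns ES, SP, mi, stage,
    stage_group and unstageable.
    """
    for col in ("bird_id", "ES", "SP"):
        if col not in histology.columns:
            raise ValidationError(f"histology table lacks column {col!r}")
    pooled = histology.groupby("bird_id")[["ES", "SP"]].sum()
    rows = []
    for bird, (es, sp) in pooled.iterrows():
        if bird not in division_flags:
            raise ValidationError(f"no spermatocyte-division flag for bird {bird!r}")
        has_es = es > 0
        mi = maturation_index(int(es), int(sp)) if es + sp > 0 else None
        call = assign_stage(mi, has_es, bool(division_flags[bird]))
        rows.append(
            {
                "bird_id": bird,
                "ES": int(es),
                "SP": int(sp),
                "mi": mi,
                "stage": call.stage,
                "stage_group": stage_group(call.stage) if call.stage else None,
                "unstageable": call.unstageable,
            }
        )
    return pd.DataFrame(rows).set_index("bird_id", drop=False)
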