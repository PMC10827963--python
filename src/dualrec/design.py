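"""Experimental designs for conjoint-recognition context-memory studies.

A design is a collection of item cells. Each *target* cell is a configuration
of contextual features (e.g. a font colour crossed with a font size) with a
fixed number of study items; *distractor* cells hold the new items shown only
at test. Three probe questions (class 1?, class 2?, either?) are
counterbalanced over the items of every cell.

The built-in presets encode the three base-rate manipulations this package
was written to analyse:

``exp1-neutral`` / ``exp1-reinstated``
    81 study words in a colour (C1/C2) by font-size (Large/Small) layout
    (36/18/9/18) plus 42 distractors; in the reinstated condition the
    distractors are split 21/21 over the two font sizes.
``exp2-<font|name>-<neutral|reinstated>``
    48 colour-object-location targets, 30 in the frequent and 18 in the
    infrequent colour/location configuration, plus 18 distractors.
``exp3-high`` / ``exp3-low``
    60 targets split 48:12 (high disproportion) or 36:24 (low) over the
    frequent/infrequent configurations, plus 30 distractors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureCell",
    "DesignSpec",
    "PRESETS",
    "build_design",
    "conditional_feature_probability",
    "base_rate_odds",
    "allocate_probes",
]


@dataclass(frozen=True)
class FeatureCell:
    """One cell of the item layout: a feature configuration with its count."""

    item_class: str
    feature_values: dict[str, str] = field(default_factory=dict)
    n_items: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 0:
            raise ValueError(f"n_items must be >= 0, got {self.n_items}")


@dataclass(frozen=True)
class DesignSpec:
    """Item allocation and probe structure for one experiment arm."""

    experiment_id: str
    condition: str
    target_cells: tuple[FeatureCell, ...]
    distractor_cells: tuple[FeatureCell, ...]
    probe_types: tuple[str, ...]
    #: which feature level each probe question asks about (None = either-probe)
    probe_targets: dict[str, str | None] = field(default_factory=dict)
    counterbalance_rule: str = "equal-split"

    def __post_init__(self) -> None:
        keysets = {frozenset(c.feature_values) for c in self.target_cells}
        if len(keysets) > 1:
            raise ValueError("target cells must share the same feature names")

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_targets(self) -> int:
        return sum(c.n_items for c in self.target_cells)

    @property
    def n_distractors(self) -> int:
        return sum(c.n_items for c in self.distractor_cells)

    @property
    def all_cells(self) -> tuple[FeatureCell, ...]:
        return self.target_cells + self.distractor_cells

    @property
    def item_classes(self) -> tuple[str, ...]:
        """Distinct item classes, targets first, preserving cell order."""
        seen: list[str] = []
        for cell in self.all_cells:
            if cell.item_class not in seen:
                seen.append(cell.item_class)
        return tuple(seen)

    @property
    def target_classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cell in self.target_cells:
            if cell.item_class not in seen:
                seen.append(cell.item_class)
        return tuple(seen)

    @property
    def distractor_classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cell in self.distractor_cells:
            if cell.item_class not in seen:
                seen.append(cell.item_class)
        return tuple(seen)

    def class_features(self, item_class: str) -> dict[str, str]:
        for cell in self.all_cells:
            if cell.item_class == item_class:
                return dict(cell.feature_values)
        raise KeyError(f"unknown item class {item_class!r}")

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cell in self.all_cells:
            counts[cell.item_class] = counts.get(cell.item_class, 0) + cell.n_items
        return counts

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        def cell(c: FeatureCell) -> dict:
            return {"item_class": c.item_class, "features": dict(c.feature_values), "n": c.n_items}

        return {
            "experiment_id": self.experiment_id,
            "condition": self.condition,
            "cells": [cell(c) for c in self.target_cells],
            "distractor_cells": [cell(c) for c in self.distractor_cells],
            "probes": list(self.probe_types),
            "probe_targets": dict(self.probe_targets),
            "counterbalance_rule": self.counterbalance_rule,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        def cell(c: dict) -> FeatureCell:
            return FeatureCell(c["item_class"], dict(c.get("features", {})), int(c["n"]))

        return cls(
            experiment_id=d["experiment_id"],
            condition=d.get("condition", ""),
            target_cells=tuple(cell(c) for c in d["cells"]),
            distractor_cells=tuple(cell(c) for c in d.get("distractor_cells", [])),
            probe_types=tuple(d["probes"]),
            probe_targets=dict(d.get("probe_targets", {})),
            counterbalance_rule=d.get("counterbalance_rule", "equal-split"),
        )

    @classmethod
    def from_json(cls, s: str) -> "DesignSpec":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _exp1(condition: str) -> DesignSpec:
    targets = (
        FeatureCell("C1:Large", {"colour": "C1", "size": "Large"}, 36),
        FeatureCell("C1:Small", {"colour": "C1", "size": "Small"}, 18),
        FeatureCell("C2:Large", {"colour": "C2", "size": "Large"}, 9),
        FeatureCell("C2:Small", {"colour": "C2", "size": "Small"}, 18),
    )
    if condition == "neutral":
        # distractors appear once, in a new medium font
        distractors = (FeatureCell("distractor", {"size": "Medium"}, 42),)
    else:
        # study font sizes are reinstated at test; distractors split 50/50
        distractors = (
            FeatureCell("distractor:Large", {"size": "Large"}, 21),
            FeatureCell("distractor:Small", {"size": "Small"}, 21),
        )
    return DesignSpec(
        experiment_id="exp1",
        condition=condition,
        target_cells=targets,
        distractor_cells=distractors,
        probe_types=("C1?", "C2?", "C1or2?"),
        probe_targets={"C1?": "C1", "C2?": "C2", "C1or2?": None},
    )


def _exp2(form: str, condition: str) -> DesignSpec:
    # the two material versions (blue/red-house/store, green/yellow-forest/
    # garden) are collapsed into abstract frequent/infrequent classes
    targets = (
        FeatureCell("frequent", {"configuration": "frequent"}, 30),
        FeatureCell("infrequent", {"configuration": "infrequent"}, 18),
    )
    if condition == "neutral":
        distractors = (FeatureCell("distractor", {}, 18),)
    else:
        distractors = (
            FeatureCell("distractor", {"location": "loc1"}, 9),
            FeatureCell("distractor", {"location": "loc2"}, 9),
        )
    return DesignSpec(
        experiment_id="exp2",
        condition=f"{form}-{condition}",
        target_cells=targets,
        distractor_cells=distractors,
        probe_types=("Cf?", "Ci?", "either?"),
        probe_targets={"Cf?": "frequent", "Ci?": "infrequent", "either?": None},
    )


def _exp3(disproportion: str) -> DesignSpec:
    n_f, n_i = (48, 12) if disproportion == "high" else (36, 24)
    targets = (
        FeatureCell("frequent", {"configuration": "frequent"}, n_f),
        FeatureCell("infrequent", {"configuration": "infrequent"}, n_i),
    )
    distractors = (
        FeatureCell("distractor", {"location": "loc1"}, 15),
        FeatureCell("distractor", {"location": "loc2"}, 15),
    )
    return DesignSpec(
        experiment_id="exp3",
        condition=disproportion,
        target_cells=targets,
        distractor_cells=distractors,
        probe_types=("Cf?", "Ci?", "either?"),
        probe_targets={"Cf?": "frequent", "Ci?": "infrequent", "either?": None},
    )


PRESETS: dict[str, "DesignSpec"] = {
    "exp1-neutral": _exp1("neutral"),
    "exp1-reinstated": _exp1("reinstated"),
    "exp2-font-neutral": _exp2("font", "neutral"),
    "exp2-font-reinstated": _exp2("font", "reinstated"),
    "exp2-name-neutral": _exp2("name", "neutral"),
    "exp2-name-reinstated": _exp2("name", "reinstated"),
    "exp3-high": _exp3("high"),
    "exp3-low": _exp3("low"),
}


def build_design(preset: str) -> DesignSpec:
    """Return the :class:`DesignSpec` for a named preset.

    Raises
    ------
    ValueError
        If ``preset`` is not a known design, listing the valid names.
    """
    try:
        return PRESETS[preset]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise ValueError(f"unknown design preset {preset!r}; valid presets: {valid}") from None


# ---------------------------------------------------------------------------
# probability facts
# ---------------------------------------------------------------------------


def _level_mass(design: DesignSpec, level: str) -> float:
    """Total target count carrying feature level ``level``."""
    hits = [c.n_items for c in design.target_cells if level in c.feature_values.values()]
    if not hits:
        raise KeyError(f"feature level {level!r} not present in design {design.experiment_id}")
    return float(sum(hits))


def _joint_mass(design: DesignSpec, a: str, b: str) -> float:
    return float(
        sum(
            c.n_items
            for c in design.target_cells
            if a in c.feature_values.values() and b in c.feature_values.values()
        )
    )


def conditional_feature_probability(design: DesignSpec, feature_a: str, given: str | None = None) -> float:
    """P(feature_a | given) from the design's target cell counts.

    With ``given=None`` the marginal probability of ``feature_a`` among the
    targets is returned.
    """
    total = float(design.n_targets)
    if given is None:
        return _level_mass(design, feature_a) / total
    marginal = _level_mass(design, given)
    if marginal == 0:
        raise ZeroDivisionError(f"conditioning level {given!r} has zero marginal count")
    return _joint_mass(design, feature_a, given) / marginal


def base_rate_odds(design: DesignSpec, feature_a: str, feature_b: str, given: str | None = None) -> float:
    """Ratio P(a | given) / P(b | given); the experienced base-rate odds."""
    p_b = conditional_feature_probability(design, feature_b, given)
    if p_b == 0:
        raise ZeroDivisionError(f"P({feature_b!r} | {given!r}) is zero; odds undefined")
    return conditional_feature_probability(design, feature_a, given) / p_b


# ---------------------------------------------------------------------------
# probe counterbalancing
# ---------------------------------------------------------------------------


def allocate_probes(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Assign every item of every cell to one probe question.

    Each cell's items are split as evenly as possible over the probe types;
    when the cell count is not divisible by the number of probes, the
    surplus probes are chosen by a seeded permutation. The assignment is a
    partition: every item appears exactly once.

    Returns a DataFrame with columns ``item_id, item_class, cell_index,
    is_target, probe``.
    """
    rng = np.random.default_rng(seed)
    q = len(design.probe_types)
    rows = []
    for cell_index, cell in enumerate(design.all_cells):
        is_target = cell_index < len(design.target_cells)
        base, extra = divmod(cell.n_items, q)
        sizes = np.full(q, base, dtype=int)
        if extra:
            sizes[rng.permutation(q)[:extra]] += 1
        probes = np.repeat(np.asarray(design.probe_types, dtype=object), sizes)
        probes = probes[rng.permutation(cell.n_items)]
        for j in range(cell.n_items):
            rows.append(
                {
                    "item_id": f"{design.experiment_id}:{cell.item_class}:{cell_index}:{j:03d}",
                    "item_class": cell.item_class,
                    "cell_index": cell_index,
                    "is_target": is_target,
                    "probe": probes[j],
                }
            )
    return pd.DataFrame(rows)


def probe_cell_totals(design: DesignSpec, seed: int = 0) -> pd.DataFrame:
    """Per (probe, item class) trial totals implied by the counterbalancing.

    For cells divisible by the number of probes (all presets) this is
    independent of the seed.
    """
    table = allocate_probes(design, seed)
    out = (
        table.groupby(["probe", "item_class"], sort=False)
        .size()
        .rename("n_total")
        .reset_index()
    )
    return out
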