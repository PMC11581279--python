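"""Variable codebook for coded registry cohorts.

Every predictor is categorical and stored as a 0-based integer level index.
The default codebook is the 13-variable endometrial-cancer scheme (age group,
tumor site, grade, histological type, FIGO stage, radiotherapy/surgery
sequence, radiotherapy, chemotherapy, lymph-node resection, lymph-node
metastasis, tumor size, depth of invasion, distant metastasis). Reference
levels are the baseline categories of the Cox dummy coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = ["Variable", "VariableCodebook", "load_codebook", "default_codebook"]


@dataclass(frozen=True)
class Variable:
    name: str
    levels: tuple[str, ...]
    reference_level: int = 0

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate level names")
        if not 0 <= self.reference_level < len(self.levels):
            raise ValueError(
                f"variable {self.name!r}: reference level {self.reference_level} "
                f"not among its {len(self.levels)} levels"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class VariableCodebook:
    """Ordered collection of categorical variables with reference levels."""

    variables: tuple[Variable, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in codebook")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, key: str | int) -> Variable:
        if isinstance(key, str):
            return self.variables[self.index_of(key)]
        return self.variables[key]

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"variable {name!r} not in codebook") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(v.n_levels for v in self.variables)

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "levels": list(v.levels),
                    "reference_level": v.reference_level,
                }
                for v in self.variables
            ]
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)


# Level sets of the 13 clinicopathological predictors, in the order used
# throughout: first level of each variable is the Cox reference category.
_DEFAULT_SCHEME: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("age", ("<50", "50-59", "60-69", "70-79", ">80")),
    ("tumor_site", ("fundus_of_uterus", "rest_of_uterine_cavity")),
    ("tumor_grade", ("high_differentiation", "middle_differentiation",
                     "low_differentiation", "undifferentiation")),
    ("histological_type", ("endometrioid", "serous", "clear_cell",
                           "undifferentiated", "mixed_cell")),
    ("tumor_stage", ("I", "II", "III", "IV")),
    ("radiotherapy_surgery_sequence", ("operation_only",
                                       "postoperative_radiotherapy",
                                       "preoperative_radiotherapy")),
    ("radiotherapy", ("no", "yes")),
    ("chemotherapy", ("no", "yes")),
    ("lymph_node_resection", ("no", "yes")),
    ("lymph_node_metastasis", ("no", "yes")),
    ("tumor_size", ("<4cm", ">=4cm")),
    ("depth_of_invasion", ("confined_endometrial_layer",
                           "<1/2_muscular_layer", ">=1/2_muscular_layer")),
    ("distant_metastasis", ("no", "yes")),
)


def default_codebook() -> VariableCodebook:
    """The 13-variable endometrial-cancer codebook (38 levels in total)."""
    return VariableCodebook(
        tuple(Variable(name, levels, 0) for name, levels in _DEFAULT_SCHEME)
    )


def load_codebook(source) -> VariableCodebook:
    """Build a validated codebook.

    ``source`` may be:

    * ``None`` or ``"default"`` — the built-in 13-variable scheme;
    * a mapping with a ``variables`` list (name / levels / reference_level);
    * a path to a YAML file with that layout;
    * an iterable of ``(name, levels)`` or ``(name, levels, reference)`` tuples.
    """
    if source is None or source == "default":
        return default_codebook()
    if isinstance(source, VariableCodebook):
        return source
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source, "r", encoding="utf-8") as fh:
            source = yaml.safe_load(fh)
    if isinstance(source, Mapping):
        entries = source["variables"]
        variables = tuple(
            Variable(
                e["name"],
                tuple(e["levels"]),
                int(e.get("reference_level", 0)),
            )
            for e in entries
        )
        return VariableCodebook(variables)
    if isinstance(source, Iterable):
        variables = []
        for entry in source:
            if isinstance(entry, Variable):
                variables.append(entry)
            else:
                name, levels, *rest = entry
                ref = int(rest[0]) if rest else 0
                variables.append(Variable(name, tuple(levels), ref))
        return VariableCodebook(tuple(variables))
    raise TypeError(f"cannot build a codebook from {type(source).__name__}")
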