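"""Attribute/level schema: declare attributes, validate them, and encode alternatives.

An :class:`AttributeSet` fixes the utility specification of a choice
experiment: the ordered attributes, their numeric level codes, coding type
(linear or indicator), expected preference signs, design priors, and whether
an opt-out alternative-specific constant (ASC) is included.  Everything
downstream (design search, simulation, estimation, post-estimation) works on
rows produced by :meth:`AttributeSet.encode`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "AttributeSpec",
    "AttributeSet",
    "ConfigError",
    "EncodingError",
    "load_attribute_config",
    "load_fixture",
    "OPTOUT_NAME",
]

#: Parameter name used for the opt-out alternative-specific constant.
OPTOUT_NAME = "optout"

VALID_CODINGS = ("linear", "indicator")
VALID_SIGNS = ("positive", "negative", "none")


class ConfigError(ValueError):
    """Raised when an attribute configuration violates the schema invariants."""


class EncodingError(ValueError):
    """Raised when an alternative cannot be encoded against an AttributeSet."""


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute of the choice alternatives.

    Parameters
    ----------
    name:
        Unique attribute identifier (used as the coefficient name under
        linear coding).
    level_codes:
        Strictly increasing numeric codes that enter the utility directly
        under linear coding (e.g. months, currency amounts, ordinal 0..L-1).
    level_labels:
        Human-readable labels, one per level, unique within the attribute.
    coding:
        ``"linear"`` (one coefficient, code enters utility directly) or
        ``"indicator"`` (dummy expansion, first level is the reference).
    expected_sign:
        Prior expectation on the coefficient sign; used by design
        diagnostics (dominance checks), not by estimation.
    prior:
        Prior coefficient for D-efficient design search (point prior).
    is_cost:
        Marks the monetary attribute whose coefficient scales WTA.
    """

    name: str
    level_codes: tuple[float, ...]
    level_labels: tuple[str, ...]
    coding: str = "linear"
    expected_sign: str = "none"
    prior: float = 0.0
    is_cost: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "level_codes", tuple(float(c) for c in self.level_codes))
        object.__setattr__(self, "level_labels", tuple(str(l) for l in self.level_labels))
        if not self.name:
            raise ConfigError("attribute name must be non-empty")
        if len(self.level_codes) < 2:
            raise ConfigError(f"attribute {self.name!r}: needs at least 2 levels, got {len(self.level_codes)}")
        if len(self.level_labels) != len(self.level_codes):
            raise ConfigError(f"attribute {self.name!r}: {len(self.level_labels)} labels for {len(self.level_codes)} codes")
        if any(b <= a for a, b in zip(self.level_codes, self.level_codes[1:])):
            raise ConfigError(f"attribute {self.name!r}: level codes must be strictly increasing: {self.level_codes}")
        if len(set(self.level_labels)) != len(self.level_labels):
            raise ConfigError(f"attribute {self.name!r}: duplicate level labels")
        if self.coding not in VALID_CODINGS:
            raise ConfigError(f"attribute {self.name!r}: unknown coding {self.coding!r}")
        if self.expected_sign not in VALID_SIGNS:
            raise ConfigError(f"attribute {self.name!r}: unknown expected_sign {self.expected_sign!r}")
        if not np.isfinite(self.prior):
            raise ConfigError(f"attribute {self.name!r}: prior must be finite")

    @property
    def n_levels(self) -> int:
        return len(self.level_codes)

    @property
    def span(self) -> float:
        """max(level_codes) - min(level_codes); strictly positive by construction."""
        return self.level_codes[-1] - self.level_codes[0]

    @property
    def n_params(self) -> int:
        """Number of utility coefficients this attribute contributes."""
        return 1 if self.coding == "linear" else self.n_levels - 1

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.coding == "linear":
            return (self.name,)
        return tuple(f"{self.name}[{lab}]" for lab in self.level_labels[1:])


@dataclass(frozen=True)
class AttributeSet:
    """Ordered attribute collection defining the full utility specification."""

    attributes: tuple[AttributeSpec, ...]
    optout_asc: bool = True
    name: str = ""
    optout_prior: float = 0.0
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        names = [a.name for a in self.attributes]
        if not names:
            raise ConfigError("attribute set must contain at least one attribute")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate attribute names: {sorted(dupes)}")
        cost = [a.name for a in self.attributes if a.is_cost]
        if len(cost) > 1:
            raise ConfigError(f"at most one cost attribute allowed, got {cost}")

    @property
    def k(self) -> int:
        """Total number of utility parameters (including the opt-out ASC)."""
        return sum(a.n_params for a in self.attributes) + (1 if self.optout_asc else 0)

    @property
    def param_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for a in self.attributes:
            names.extend(a.param_names)
        if self.optout_asc:
            names.append(OPTOUT_NAME)
        return tuple(names)

    @property
    def cost_attribute(self) -> AttributeSpec | None:
        for a in self.attributes:
            if a.is_cost:
                return a
        return None

    @property
    def spans(self) -> dict[str, float]:
        """Attribute name -> max-min code span (linear-coding ranges)."""
        return {a.name: a.span for a in self.attributes}

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def n_profiles(self) -> int:
        out = 1
        for a in self.attributes:
            out *= a.n_levels
        return out

    def default_priors(self) -> np.ndarray:
        """Prior coefficient vector in parameter order (ASC slot last)."""
        vals: list[float] = []
        for a in self.attributes:
            vals.extend([a.prior] * a.n_params)
        if self.optout_asc:
            vals.append(self.optout_prior)
        return np.asarray(vals, dtype=float)

    def encode(self, assignment: Mapping[str, int] | None, is_optout: bool = False) -> np.ndarray:
        """Build the utility row of length K for one alternative.

        ``assignment`` maps attribute name -> level *index*.  Non-opt-out
        rows carry the level codes (linear coding) or dummy indicators in
        attribute order, with 0 in the ASC slot; the opt-out row is all
        zeros with 1 in the ASC slot.
        """
        row = np.zeros(self.k, dtype=float)
        if is_optout:
            if self.optout_asc:
                row[-1] = 1.0
            return row
        if assignment is None:
            raise EncodingError("non-opt-out alternative requires a level assignment")
        unknown = set(assignment) - {a.name for a in self.attributes}
        if unknown:
            raise EncodingError(f"unknown attribute name(s): {sorted(unknown)}")
        pos = 0
        for a in self.attributes:
            if a.name not in assignment:
                raise EncodingError(f"assignment missing attribute {a.name!r}")
            idx = int(assignment[a.name])
            if not 0 <= idx < a.n_levels:
                raise EncodingError(f"attribute {a.name!r}: level index {idx} out of range 0..{a.n_levels - 1}")
            if a.coding == "linear":
                row[pos] = a.level_codes[idx]
            else:
                if idx > 0:
                    row[pos + idx - 1] = 1.0
            pos += a.n_params
        return row


def _parse_attribute(block: Mapping, index: int) -> AttributeSpec:
    if not isinstance(block, Mapping):
        raise ConfigError(f"attribute #{index}: expected a mapping, got {type(block).__name__}")
    try:
        name = block["name"]
        levels = block["levels"]
    except KeyError as exc:
        raise ConfigError(f"attribute #{index}: missing required field {exc.args[0]!r}") from None
    if not isinstance(levels, Sequence) or isinstance(levels, (str, bytes)):
        raise ConfigError(f"attribute {name!r}: 'levels' must be a list")
    codes, labels = [], []
    for lev in levels:
        if not isinstance(lev, Mapping) or "code" not in lev or "label" not in lev:
            raise ConfigError(f"attribute {name!r}: each level needs 'code' and 'label'")
        codes.append(lev["code"])
        labels.append(lev["label"])
    return AttributeSpec(
        name=name,
        level_codes=tuple(codes),
        level_labels=tuple(labels),
        coding=block.get("coding", "linear"),
        expected_sign=block.get("expected_sign", "none"),
        prior=float(block.get("prior", 0.0)),
        is_cost=bool(block.get("is_cost", False)),
    )


def load_attribute_config(path: str | Path) -> AttributeSet:
    """Load and validate an attribute configuration file (YAML).

    The documented schema::

        name: pilot                # optional set name
        optout_asc: true           # include an opt-out ASC (default true)
        optout_prior: -0.1         # design prior for the ASC
        attributes:
          - name: payment_schedule
            coding: linear         # or indicator
            expected_sign: negative
            is_cost: false
            prior: -0.009
            levels:
              - {code: 1, label: "1 month"}
              - {code: 3, label: "3 months"}
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"attribute config not found: {path}")
    raw = yaml.safe_load(path.read_text())
    return _attribute_set_from_mapping(raw, source=str(path))


def _attribute_set_from_mapping(raw, source: str = "<config>") -> AttributeSet:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{source}: top level must be a mapping")
    if "attributes" not in raw:
        raise ConfigError(f"{source}: missing required field 'attributes'")
    attrs = tuple(_parse_attribute(b, i) for i, b in enumerate(raw["attributes"]))
    return AttributeSet(
        attributes=attrs,
        optout_asc=bool(raw.get("optout_asc", True)),
        name=str(raw.get("name", "")),
        optout_prior=float(raw.get("optout_prior", 0.0)),
        notes=str(raw.get("notes", "")),
    )


def load_fixture(name: str) -> AttributeSet:
    """Load one of the shipped attribute-set fixtures (``pilot`` or ``final``)."""
    ref = resources.files("capdce").joinpath("fixtures", f"{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigError(f"no shipped fixture named {name!r}") from None
    return _attribute_set_from_mapping(yaml.safe_load(text), source=f"fixture:{name}")
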