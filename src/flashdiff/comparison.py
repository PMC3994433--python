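"""Three-level diff engine for flashdump pairs.

Two exports are aligned DCU by DCU, setting by setting (MEFI key plus angle
node), parameter by parameter, and every deviation is emitted as a totally
ordered :class:`Difference`.  Numeric values are compared numerically, so
formatting-only changes are never differences; non-numeric values compare by
exact text.  A device missing on one side yields a single structural
difference, not one per parameter — its QA impact is resolved fail-safe
downstream.

The default tolerance is zero: any numeric change counts.  Suppressing small
deviations is possible only through an explicit, logged tolerance policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from collections import Counter
from enum import Enum
from typing import Iterable, Mapping, Optional, Union

import yaml

from .dumpio import DCURecord, Flashdump, ParameterValue, SettingKey

__all__ = [
    "DiffKind",
    "Difference",
    "DifferenceSet",
    "TolerancePolicy",
    "compare",
    "swap",
]


class DiffKind(str, Enum):
    CHANGED = "changed"
    DCU_ADDED = "dcu_added"
    DCU_REMOVED = "dcu_removed"
    MEFI_ADDED = "mefi_added"
    MEFI_REMOVED = "mefi_removed"
    PARAM_ADDED = "param_added"
    PARAM_REMOVED = "param_removed"


_SWAPPED = {
    DiffKind.CHANGED: DiffKind.CHANGED,
    DiffKind.DCU_ADDED: DiffKind.DCU_REMOVED,
    DiffKind.DCU_REMOVED: DiffKind.DCU_ADDED,
    DiffKind.MEFI_ADDED: DiffKind.MEFI_REMOVED,
    DiffKind.MEFI_REMOVED: DiffKind.MEFI_ADDED,
    DiffKind.PARAM_ADDED: DiffKind.PARAM_REMOVED,
    DiffKind.PARAM_REMOVED: DiffKind.PARAM_ADDED,
}


@dataclass(frozen=True)
class Difference:
    """One aligned deviation between the last and current dump."""

    dcu_id: str
    device_name: str
    kind: DiffKind
    setting: Optional[SettingKey] = None
    parameter_name: Optional[str] = None
    old_value: Optional[ParameterValue] = None
    new_value: Optional[ParameterValue] = None

    @property
    def delta(self) -> Optional[float]:
        """new − old for numeric changes, None otherwise."""
        if (self.old_value is not None and self.new_value is not None
                and self.old_value.numeric_value is not None
                and self.new_value.numeric_value is not None):
            return self.new_value.numeric_value - self.old_value.numeric_value
        return None

    @property
    def target(self) -> tuple:
        """Canonical sort/identity key: (dcu, setting, parameter)."""
        return (self.dcu_id,
                self.setting if self.setting is not None else SettingKey("", -0x7fffffff, 0, 0),
                self.parameter_name or "")

    def swapped(self) -> "Difference":
        return replace(self, kind=_SWAPPED[self.kind],
                       old_value=self.new_value, new_value=self.old_value)

    def to_dict(self) -> dict:
        def pv(v: Optional[ParameterValue]):
            if v is None:
                return None
            return {"value": v.canonical_text, "unit": v.unit}
        return {
            "dcu_id": self.dcu_id,
            "device_name": self.device_name,
            "kind": self.kind.value,
            "setting": str(self.setting) if self.setting else None,
            "parameter": self.parameter_name,
            "old": pv(self.old_value),
            "new": pv(self.new_value),
            "delta": self.delta,
        }

    def __str__(self) -> str:
        loc = self.dcu_id
        if self.setting is not None:
            loc += f"/{self.setting}"
        if self.parameter_name:
            loc += f"/{self.parameter_name}"
        if self.kind is DiffKind.CHANGED:
            return (f"{loc}: {self.old_value.canonical_text} -> "
                    f"{self.new_value.canonical_text}")
        return f"{loc}: {self.kind.value}"


@dataclass
class DifferenceSet:
    """All differences of one comparison, totally ordered, with summaries."""

    differences: list[Difference] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.differences.sort(key=lambda d: (d.target, d.kind.value))

    def __len__(self) -> int:
        return len(self.differences)

    def __iter__(self):
        return iter(self.differences)

    def __bool__(self) -> bool:
        return bool(self.differences)

    @property
    def summary(self) -> dict:
        by_kind = Counter(d.kind.value for d in self.differences)
        by_dcu = Counter(d.dcu_id for d in self.differences)
        return {"total": len(self.differences),
                "by_kind": dict(sorted(by_kind.items())),
                "by_dcu": dict(sorted(by_dcu.items()))}

    @property
    def changed_dcu_ids(self) -> set[str]:
        return {d.dcu_id for d in self.differences}

    def of_kind(self, kind: DiffKind) -> list[Difference]:
        return [d for d in self.differences if d.kind is kind]

    def to_dict(self) -> dict:
        return {"summary": self.summary,
                "differences": [d.to_dict() for d in self.differences]}

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kw)


@dataclass(frozen=True)
class ToleranceRule:
    mode: str  # "absolute" | "relative"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if self.value < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass(frozen=True)
class TolerancePolicy:
    """Numeric comparison tolerances; zero (exact) unless configured.

    ``overrides`` maps a parameter name to an absolute or relative rule.
    Relative rules scale with the magnitude of the old value.
    """

    default_tolerance: float = 0.0
    overrides: Mapping[str, ToleranceRule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default_tolerance < 0:
            raise ValueError("default tolerance must be non-negative")

    @classmethod
    def from_file(cls, path) -> "TolerancePolicy":
        """Load a policy from a YAML/JSON mapping::

            default_tolerance: 0
            parameters:
              magnet_current: {mode: absolute, value: 1e-6}
              rf_amplitude:   {mode: relative, value: 1e-9}
        """
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        overrides = {
            name: ToleranceRule(str(rule["mode"]), float(rule["value"]))
            for name, rule in (doc.get("parameters") or {}).items()
        }
        return cls(float(doc.get("default_tolerance", 0.0)), overrides)

    def equal(self, name: str, a: ParameterValue, b: ParameterValue) -> bool:
        if a.numeric_value is None or b.numeric_value is None:
            return a.raw_text == b.raw_text and a.unit == b.unit
        if a.unit != b.unit:
            return False
        rule = self.overrides.get(name)
        if rule is None:
            tol = self.default_tolerance
        elif rule.mode == "absolute":
            tol = rule.value
        else:
            tol = rule.value * abs(a.numeric_value)
        return abs(a.numeric_value - b.numeric_value) <= tol


def _diff_record(old: DCURecord, new: DCURecord,
                 policy: TolerancePolicy) -> Iterable[Difference]:
    old_keys, new_keys = set(old.settings), set(new.settings)
    for key in sorted(old_keys | new_keys):
        if key not in new_keys:
            yield Difference(old.dcu_id, old.device_name,
                             DiffKind.MEFI_REMOVED, setting=key)
            continue
        if key not in old_keys:
            yield Difference(new.dcu_id, new.device_name,
                             DiffKind.MEFI_ADDED, setting=key)
            continue
        op, np_ = old.settings[key], new.settings[key]
        for name in sorted(set(op) | set(np_)):
            if name not in np_:
                yield Difference(old.dcu_id, old.device_name,
                                 DiffKind.PARAM_REMOVED, setting=key,
                                 parameter_name=name, old_value=op[name])
            elif name not in op:
                yield Difference(new.dcu_id, new.device_name,
                                 DiffKind.PARAM_ADDED, setting=key,
                                 parameter_name=name, new_value=np_[name])
            elif not policy.equal(name, op[name], np_[name]):
                yield Difference(new.dcu_id, new.device_name,
                                 DiffKind.CHANGED, setting=key,
                                 parameter_name=name,
                                 old_value=op[name], new_value=np_[name])


def compare(last: Flashdump, current: Flashdump,
            policy: Optional[TolerancePolicy] = None) -> DifferenceSet:
    """Full three-level alignment of two dumps.

    Deterministic and totally ordered; satisfies ``compare(d, d) == empty``
    and the antisymmetry ``compare(a, b) == swap(compare(b, a))``.
    """
    policy = policy or TolerancePolicy()
    diffs: list[Difference] = []
    old_map, new_map = last.record_map, current.record_map
    for dcu_id in sorted(set(old_map) | set(new_map)):
        if dcu_id not in new_map:
            rec = old_map[dcu_id]
            diffs.append(Difference(dcu_id, rec.device_name, DiffKind.DCU_REMOVED))
        elif dcu_id not in old_map:
            rec = new_map[dcu_id]
            diffs.append(Difference(dcu_id, rec.device_name, DiffKind.DCU_ADDED))
        else:
            diffs.extend(_diff_record(old_map[dcu_id], new_map[dcu_id], policy))
    return DifferenceSet(diffs)


def swap(diffs: DifferenceSet) -> DifferenceSet:
    """Reverse the direction of a difference set (old/new, added/removed)."""
    return DifferenceSet([d.swapped() for d in diffs])
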