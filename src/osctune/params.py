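"""Named parameter sets for the oscillator models.

Every model exposes four nonnegative scalar controls on top of its fixed
constants:

``k1``
    strength with which oscillator 2 inhibits oscillator 1,
``k2``
    the reverse inhibition strength,
``pos``
    strength of the auxiliary positive-feedback loop(s),
``neg``
    strength of the auxiliary negative-feedback loop(s).

The controls are supplied as magnitudes; inhibitory edges acquire their
negative sign inside the model right-hand sides, so all four controls are
required to be >= 0.
"""

from __future__ import annotations

from collections.abc import Mapping
from typing import Iterator

__all__ = ["ParameterSet", "CONTROL_NAMES"]

CONTROL_NAMES = ("k1", "k2", "pos", "neg")


class ParameterSet(Mapping):
    """Immutable mapping from parameter name to value.

    Construction validates that the scalar controls are present and
    nonnegative.  ``with_overrides`` returns a new set; unknown keys are
    rejected so typos cannot silently leave a constant at its default.
    """

    def __init__(self, values: Mapping[str, float]):
        vals = {str(k): float(v) for k, v in values.items()}
        for name in CONTROL_NAMES:
            if name not in vals:
                raise ValueError(f"parameter set is missing control {name!r}")
            if vals[name] < 0:
                raise ValueError(
                    f"control {name!r} must be nonnegative, got {vals[name]}"
                )
        self._values = vals

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterSet({self._values!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, ParameterSet):
            return self._values == other._values
        if isinstance(other, Mapping):
            return self._values == dict(other)
        return NotImplemented

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a new set with ``overrides`` applied.

        Raises ``KeyError`` for names that are not parameters of this model.
        """
        unknown = set(overrides) - set(self._values)
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {sorted(unknown)}; "
                f"valid names are {sorted(self._values)}"
            )
        merged = dict(self._values)
        merged.update({k: float(v) for k, v in overrides.items()})
        return ParameterSet(merged)

    def to_dict(self) -> dict[str, float]:
        """Plain ``dict`` copy, suitable for JSON/YAML serialization."""
        return dict(self._values)
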