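"""The attribute set of the quality-of-life best-worst task.

Each respondent saw all attributes at once (full-profile, single task)
and picked the most and the least important one. The default set is the
six-factor QOL value matrix elicited for low-income Guilford County
communities, in the order the published score table lists them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Tuple

__all__ = ["AttributeSet", "DEFAULT_ATTRIBUTES"]


@dataclass(frozen=True)
class AttributeSet:
    """Ordered set of (attribute_id, display label) pairs."""

    items: Tuple[Tuple[str, str], ...]
    _index: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self):
        if not self.items:
            raise ValueError("AttributeSet must not be empty")
        ids = [a for a, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("attribute ids must be unique")
        object.__setattr__(self, "_index", {a: i for i, (a, _) in enumerate(self.items)})

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(a for a, _ in self.items)

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(lbl for _, lbl in self.items)

    def index(self, attribute_id: str) -> int:
        return self._index[attribute_id]

    def label(self, attribute_id: str) -> str:
        return self.items[self.index(attribute_id)][1]

    def __contains__(self, attribute_id: str) -> bool:
        return attribute_id in self._index

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.items)


DEFAULT_ATTRIBUTES = AttributeSet(
    (
        ("spiritual", "Spiritual Well-being"),
        ("food", "Food Security"),
        ("health", "Health Care"),
        ("social", "Social Connections"),
        ("economic", "Economic Opportunity"),
        ("community", "Community Assets"),
    )
)
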