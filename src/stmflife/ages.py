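"""Coarse age-group schemes for abridged mortality analysis.

The STMF weekly series reports deaths in five broad groups
(0-14, 15-64, 65-74, 75-84, 85+).  An :class:`AgeGroupScheme` describes
such a partition of the age axis: half-open intervals ``[x, x+n)`` with a
single open-ended last group.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_labels(lower_bounds: tuple[int, ...]) -> tuple[str, ...]:
    labels = []
    for i, lo in enumerate(lower_bounds):
        if i == len(lower_bounds) - 1:
            labels.append(f"{lo}+")
        else:
            labels.append(f"{lo}-{lower_bounds[i + 1] - 1}")
    return tuple(labels)


@dataclass(frozen=True)
class AgeGroupScheme:
    """A partition of ages into half-open groups ``[x, x+n)`` plus one open group.

    Parameters
    ----------
    lower_bounds:
        Strictly increasing lower bounds, starting at 0.  The last bound
        opens the unbounded final group.
    labels:
        Display labels; defaults to ``"0-14", ..., "85+"`` style.

    Invariants are checked at construction: bounds strictly increasing,
    first bound 0, labels matching the number of groups.
    """

    lower_bounds: tuple[int, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        lb = tuple(self.lower_bounds)
        object.__setattr__(self, "lower_bounds", lb)
        if len(lb) < 1:
            raise ValueError("scheme needs at least one group")
        if lb[0] != 0:
            raise ValueError("first lower bound must be 0")
        if any(b >= c for b, c in zip(lb, lb[1:])):
            raise ValueError("lower bounds must be strictly increasing")
        labels = tuple(self.labels) or _default_labels(lb)
        if len(labels) != len(lb):
            raise ValueError("one label per group required")
        object.__setattr__(self, "labels", labels)

    @property
    def n_groups(self) -> int:
        return len(self.lower_bounds)

    @property
    def open_label(self) -> str:
        return self.labels[-1]

    @property
    def closed_labels(self) -> tuple[str, ...]:
        return self.labels[:-1]

    def length(self, label: str) -> int | None:
        """Interval length ``n`` in years, or ``None`` for the open group."""
        i = self.labels.index(label)
        if i == len(self.lower_bounds) - 1:
            return None
        return self.lower_bounds[i + 1] - self.lower_bounds[i]

    def lower(self, label: str) -> int:
        return self.lower_bounds[self.labels.index(label)]

    def iter_groups(self):
        """Yield ``(label, lower_bound, n_or_None)`` in age order."""
        for i, (lo, lab) in enumerate(zip(self.lower_bounds, self.labels)):
            n = None if i == len(self.lower_bounds) - 1 else self.lower_bounds[i + 1] - lo
            yield lab, lo, n


#: The five-group STMF scheme: [0,15), [15,65), [65,75), [75,85), 85+.
STMF_SCHEME = AgeGroupScheme(
    lower_bounds=(0, 15, 65, 75, 85),
    labels=("0-14", "15-64", "65-74", "75-84", "85+"),
)
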