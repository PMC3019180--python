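"""Expression-feature layout: the 79 named conditions of the study design.

The layout is an ordered list of feature descriptors covering: mean
expression in ES and EB cells (2), two 11-point undirected-differentiation
time courses (22), a 7-point RA-induced differentiation course (7), and
eight time points for each of six factor-knockdown lines (48).
"""

from __future__ import annotations

from dataclasses import dataclass, field


EXPECTED_N_FEATURES = 79

#: (dataset tag, number of time points); None = single snapshot condition
_COURSES = (
    ("diffA", 11),
    ("diffB", 11),
    ("ra", 7),
    ("kd1", 8),
    ("kd2", 8),
    ("kd3", 8),
    ("kd4", 8),
    ("kd5", 8),
    ("kd6", 8),
)


class LayoutError(ValueError):
    """Raised when a feature layout violates the study design contract."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One expression feature: a named (dataset, condition, time point) cell."""

    name: str
    dataset: str
    condition: str
    time: int | None = None


@dataclass(frozen=True)
class StudyLayout:
    """Ordered collection of expression-feature descriptors.

    Raises :class:`LayoutError` unless there are exactly 79 descriptors
    with unique names.
    """

    descriptors: tuple[FeatureDescriptor, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise LayoutError("feature descriptor names must be unique")
        if len(names) != EXPECTED_N_FEATURES:
            raise LayoutError(
                f"layout must have {EXPECTED_N_FEATURES} descriptors, "
                f"got {len(names)}"
            )

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]


def default_layout() -> StudyLayout:
    """Build the canonical 79-feature layout.

    Order: ES mean, EB mean, then each time course in course order with
    time points ascending.
    """
    descs = [
        FeatureDescriptor("es_mean", "esc_vs_eb", "ES"),
        FeatureDescriptor("eb_mean", "esc_vs_eb", "EB"),
    ]
    for tag, n_points in _COURSES:
        for t in range(n_points):
            descs.append(
                FeatureDescriptor(f"{tag}_t{t:02d}", tag, f"t{t:02d}", time=t)
            )
    return StudyLayout(tuple(descs))
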