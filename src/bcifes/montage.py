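"""Electrode montage description for the 24-channel 10-20 recording setup.

The study montage covers frontal, central, parietal and temporal sites plus
the reference set (A1, A2).  Oz is wired in the reference region of the cap
but is treated as an occipital *analysis* channel, which reconciles the
24-electrode cap with the 22-channel analysis set used for global averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Cap layout in recording order.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "Fz", "FC3", "FC4", "FCz", "FT7", "FT8",
    "C3", "C4", "Cz",
    "CP3", "CP4", "P3", "P4", "CPz", "Pz",
    "T3", "T4", "TP7", "TP8",
    "A1", "A2", "Oz",
)

DEFAULT_REFERENCES: tuple[str, ...] = ("A1", "A2")

#: Homologous (left, right) electrode pairs for interhemispheric symmetry.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "F4"), ("FC3", "FC4"), ("FT7", "FT8"), ("C3", "C4"),
    ("CP3", "CP4"), ("P3", "P4"), ("T3", "T4"), ("TP7", "TP8"),
)

MIDLINE_CHANNELS: frozenset[str] = frozenset({"Fz", "FCz", "Cz", "CPz", "Pz", "Oz"})

LESION_SIDES = ("left", "right", "bilateral", "unknown")


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus reference set and homologous pairs.

    Parameters
    ----------
    channel_labels : tuple of str
        All electrode labels in recording order.
    reference_labels : tuple of str
        Subset of ``channel_labels`` used as recording reference; excluded
        from every analysis quantity.
    homologous_pairs : tuple of (str, str)
        (left, right) electrode pairs; both members must be analysis
        channels and midline electrodes belong to no pair.
    lesion_side : str
        One of ``left``/``right``/``bilateral``/``unknown``; annotation only.
    """

    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    reference_labels: tuple[str, ...] = DEFAULT_REFERENCES
    homologous_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    lesion_side: str = "unknown"

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        missing = set(self.reference_labels) - set(self.channel_labels)
        if missing:
            raise ValueError(f"reference labels not in montage: {sorted(missing)}")
        if self.lesion_side not in LESION_SIDES:
            raise ValueError(f"lesion_side must be one of {LESION_SIDES}")
        analysis = set(self.analysis_labels)
        for left, right in self.homologous_pairs:
            if left not in analysis or right not in analysis:
                raise ValueError(f"pair ({left}, {right}) not within analysis channels")
            if left in MIDLINE_CHANNELS or right in MIDLINE_CHANNELS:
                raise ValueError(f"midline channel in pair ({left}, {right})")

    @property
    def analysis_labels(self) -> tuple[str, ...]:
        """Channels entering analysis: all labels minus the reference set."""
        refs = set(self.reference_labels)
        return tuple(ch for ch in self.channel_labels if ch not in refs)

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    @property
    def n_analysis(self) -> int:
        return len(self.analysis_labels)

    def index(self, label: str) -> int:
        """Position of ``label`` in ``channel_labels``."""
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def analysis_index(self, label: str) -> int:
        """Position of ``label`` within the analysis channel set."""
        try:
            return self.analysis_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not an analysis channel") from None

    def subset(self, labels: tuple[str, ...] | list[str]) -> "Montage":
        """Montage restricted to ``labels`` (order preserved as given)."""
        labels = tuple(labels)
        keep = set(labels)
        return Montage(
            channel_labels=labels,
            reference_labels=tuple(r for r in self.reference_labels if r in keep),
            homologous_pairs=tuple(
                (l, r) for l, r in self.homologous_pairs if l in keep and r in keep
            ),
            lesion_side=self.lesion_side,
        )

    def to_dict(self) -> dict:
        return {
            "channel_labels": list(self.channel_labels),
            "reference_labels": list(self.reference_labels),
            "homologous_pairs": [list(p) for p in self.homologous_pairs],
            "lesion_side": self.lesion_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            channel_labels=tuple(d["channel_labels"]),
            reference_labels=tuple(d.get("reference_labels", ())),
            homologous_pairs=tuple(tuple(p) for p in d.get("homologous_pairs", ())),
            lesion_side=d.get("lesion_side", "unknown"),
        )


def default_montage(lesion_side: str = "unknown") -> Montage:
    """The study's 24-electrode 10-20 montage (22 analysis channels)."""
    return Montage(lesion_side=lesion_side)
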