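"""Controlled vocabularies for expression annotation.

Follicle-cell expression patterns are described with a small set of
recurring spatial *primitives* (domains) observed across egg-chamber
development.  The default ontology covers the germarium, the somatic cell
types surrounding the egg chamber, the anterior/dorsal patterning domains
set up by BMP and EGFR signalling, the dorsal-appendage primordium
sub-domains (roof and floor), the stage-14 eggshell structures, and a
catch-all ``OTHER`` bucket for domains outside the vocabulary.

Egg-chamber development is divided into 14 morphological stages; stage 10
is conventionally split into 10A and 10B.  The early stages (2-8) may
alternatively be annotated as one grouped pseudo-stage ``S2-8`` when
individual early stages were not resolved, but the two granularities must
not be mixed within a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_DOMAINS: tuple[str, ...] = (
    "G", "StC", "PC", "BC", "SC", "AD", "AV", "M",
    "R", "F", "D", "P", "U", "DA", "Op", "OTHER",
)

DEFAULT_DOMAIN_DESCRIPTIONS: dict[str, str] = {
    "G": "germarium",
    "StC": "stalk cells",
    "PC": "polar cells",
    "BC": "border cells",
    "SC": "stretched cells",
    "AD": "anterior dorsal",
    "AV": "anterior ventral",
    "M": "midline",
    "R": "roof (dorsal-appendage primordium)",
    "F": "floor (dorsal-appendage primordium)",
    "D": "dorsal",
    "P": "posterior",
    "U": "uniform (all follicle cells)",
    "DA": "dorsal appendages (stage 14)",
    "Op": "operculum (stage 14)",
    "OTHER": "not one of the listed domains",
}

#: Fine-grained stage labels, stage 10 split into 10A/10B.
DEFAULT_STAGES: tuple[str, ...] = (
    "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9",
    "S10A", "S10B", "S11", "S12", "S13", "S14",
)

#: Early stages collapsed to a single grouped label.
GROUPED_EARLY_STAGES: tuple[str, ...] = (
    "S2-8", "S9", "S10A", "S10B", "S11", "S12", "S13", "S14",
)

#: Labels covered by the grouped early pseudo-stage.
EARLY_FINE_STAGES: frozenset[str] = frozenset(
    {"S2", "S3", "S4", "S5", "S6", "S7", "S8"}
)


@dataclass(frozen=True)
class DomainOntology:
    """Ordered vocabulary of expression domains.

    Parameters
    ----------
    codes
        Unique domain labels, in display order.  ``OTHER`` — if present —
        must be last.
    descriptions
        Optional free-text description per label.
    """

    codes: tuple[str, ...] = DEFAULT_DOMAINS
    descriptions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_DESCRIPTIONS)
    )

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("ontology needs at least one domain code")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("domain codes must be unique")
        if "OTHER" in self.codes and self.codes[-1] != "OTHER":
            raise ValueError("OTHER must be the last domain code")
        object.__setattr__(self, "codes", tuple(self.codes))

    def __contains__(self, label: str) -> bool:
        return label in self.codes

    def __iter__(self):
        return iter(self.codes)

    def __len__(self) -> int:
        return len(self.codes)

    def index(self, label: str) -> int:
        return self.codes.index(label)

    def describe(self, label: str) -> str:
        return self.descriptions.get(label, "")


@dataclass(frozen=True)
class StageAxis:
    """Strictly ordered developmental stage labels."""

    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage axis needs at least one stage")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        object.__setattr__(self, "stages", tuple(self.stages))

    @classmethod
    def default(cls) -> "StageAxis":
        return cls(DEFAULT_STAGES)

    @classmethod
    def grouped_early(cls) -> "StageAxis":
        """Axis with stages 2-8 collapsed into a single ``S2-8`` label."""
        return cls(GROUPED_EARLY_STAGES)

    def __contains__(self, label: str) -> bool:
        return label in self.stages

    def __iter__(self):
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)

    def index(self, label: str) -> int:
        return self.stages.index(label)

    def successor(self, label: str) -> str | None:
        i = self.index(label)
        return self.stages[i + 1] if i + 1 < len(self.stages) else None

    def predecessor(self, label: str) -> str | None:
        i = self.index(label)
        return self.stages[i - 1] if i > 0 else None

    def validate_labels(self, labels) -> None:
        """Reject unknown labels and mixing of grouped/fine early stages."""
        unknown = [s for s in labels if s not in self.stages]
        if unknown:
            raise ValueError(f"unknown stage label(s): {unknown}")
        seen = set(labels)
        if "S2-8" in seen and seen & EARLY_FINE_STAGES:
            raise ValueError(
                "dataset mixes grouped early label 'S2-8' with fine early stages"
            )
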