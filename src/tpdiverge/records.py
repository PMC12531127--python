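"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

#: The three targeting destinations distinguished throughout the package.
ORGANELLES = ("mito", "plastid", "dual")

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its species (and optionally clade) of origin.

    ``protein_id`` must be unique within a species; FASTA readers take the
    token before the first whitespace of the header as the id.
    """

    protein_id: str
    species: str
    sequence: str
    clade: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


@dataclass(frozen=True)
class LocalizationCall:
    """An inferred targeting destination for one protein.

    ``evidence`` lists the seed (experimentally annotated) protein ids whose
    reciprocal-best-hit relationships produced the call; it is never empty.
    """

    protein_id: str
    species: str
    label: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in ORGANELLES:
            raise ValueError(f"unknown organelle label {self.label!r}")
        if not self.evidence:
            raise ValueError("a localization call requires at least one seed id")
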