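"""Orthology-based organelle proteome inference.

A protein of a target species is called mitochondrial, plastid, or
dual-targeted when it forms a reciprocal best hit (RBBH) with an
experimentally annotated seed protein.  Label resolution when a protein
hits several seeds:

1. any dual-labelled seed partner → ``dual``;
2. partners in both the mito and the plastid seed sets → ``dual``
   (configurable: ``conflict="drop"`` discards such proteins instead);
3. otherwise the single seed label.

Proteins without any seed RBBH receive no call.  When several seed
species exist, RBBH to at least one suffices (union semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import ORGANELLES, LocalizationCall, ProteinRecord
from .similarity import RbbhPair

CONFLICT_RULES = ("dual", "drop")


@dataclass(frozen=True)
class SeedSet:
    """Experimentally annotated organelle proteins of one species."""

    entries: dict[str, str]
    species: str
    clade: str | None = None

    def __post_init__(self) -> None:
        bad = {lab for lab in self.entries.values() if lab not in ORGANELLES}
        if bad:
            raise ValueError(f"unknown organelle labels in seed set: {sorted(bad)}")


def transfer_labels(
    target: list[ProteinRecord],
    seeds: SeedSet,
    rbbh: list[RbbhPair],
    conflict: str = "dual",
) -> list[LocalizationCall]:
    """Transfer seed organelle labels onto target proteins via RBBH pairs.

    ``rbbh`` must come from an RBBH run between the target species and the
    seed species: each pair must reference exactly one target protein; the
    other member is looked up in the seed set (non-seed partners carry no
    evidence).  Output is sorted by protein id.
    """
    if conflict not in CONFLICT_RULES:
        raise ValueError(f"unknown conflict rule {conflict!r}")
    if not seeds.entries:
        return []
    target_ids = {r.protein_id: r for r in target}
    partners: dict[str, set[str]] = {}
    for pair in rbbh:
        in_target = [pid for pid in (pair.a_id, pair.b_id) if pid in target_ids]
        if len(in_target) != 1:
            raise ValueError(
                f"rbbh pair ({pair.a_id}, {pair.b_id}) does not reference "
                "exactly one target protein"
            )
        tid = in_target[0]
        other = pair.b_id if tid == pair.a_id else pair.a_id
        if other in seeds.entries:
            partners.setdefault(tid, set()).add(other)

    calls = []
    for tid in sorted(partners):
        evidence = tuple(sorted(partners[tid]))
        labels = {seeds.entries[sid] for sid in evidence}
        if "dual" in labels:
            label = "dual"
        elif "mito" in labels and "plastid" in labels:
            if conflict == "drop":
                continue
            label = "dual"
        else:
            label = next(iter(labels))
        calls.append(
            LocalizationCall(tid, target_ids[tid].species, label, evidence)
        )
    return calls


def transfer_labels_cross_clade(
    target: list[ProteinRecord],
    donor_seeds: SeedSet,
    rbbh: list[RbbhPair],
    conflict: str = "dual",
) -> list[LocalizationCall]:
    """Label transfer from a donor clade's seed species.

    Identical logic to :func:`transfer_labels`; used when the target clade
    has no experimental proteomes of its own (e.g. streptophyte algae
    inferred from chlorophyte seeds), with the RBBH pairs computed between
    species of the two clades.
    """
    return transfer_labels(target, donor_seeds, rbbh, conflict=conflict)
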