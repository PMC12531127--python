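"""Readers and writers for the pipeline's plain-text formats.

FASTA record ids are the token before the first whitespace of the
header.  All tables are UTF-8, tab-delimited TSV with a header row and
'.' decimals.  Newick output carries branch lengths at 10 significant
digits and round-trips losslessly at that precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .features import TPFeatures
from .records import LocalizationCall, ProteinRecord
from .similarity import RbbhPair, SimilarityHit

FASTA_WRAP = 60


def read_fasta(path: str | Path, species: str | None = None,
               clade: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA; species defaults to the file stem."""
    path = Path(path)
    sp = species if species is not None else path.stem
    return [
        ProteinRecord(rec.id, sp, str(rec.seq), clade=clade)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records in order, sequences wrapped at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), FASTA_WRAP):
                fh.write(rec.sequence[i:i + FASTA_WRAP] + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def hits_frame(hits: list[SimilarityHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": [h.query_id for h in hits],
            "subject": [h.subject_id for h in hits],
            "score": [h.score for h in hits],
            "evalue": [h.evalue for h in hits],
        }
    )


def rbbh_frame(pairs: list[RbbhPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "a_id": [p.a_id for p in pairs],
            "b_id": [p.b_id for p in pairs],
            "score": [p.score for p in pairs],
        }
    )


def read_rbbh(path: str | Path) -> list[RbbhPair]:
    df = read_tsv(path)
    return [
        RbbhPair(str(r.a_id), str(r.b_id), float(r.score))
        for r in df.itertuples()
    ]


def read_seed_tsv(path: str | Path) -> tuple[dict[str, str], str | None]:
    """Seed annotations as (protein id → organelle, species of origin)."""
    df = read_tsv(path)
    entries = dict(zip(df["protein_id"].astype(str), df["organelle"].astype(str)))
    species = str(df["species"].iloc[0]) if "species" in df and len(df) else None
    return entries, species


def seeds_frame(entries: dict[str, str], species: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": sorted(entries),
            "organelle": [entries[k] for k in sorted(entries)],
            "species": species,
        }
    )


def calls_frame(calls: list[LocalizationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "species": [c.species for c in calls],
            "label": [c.label for c in calls],
            "evidence": [",".join(c.evidence) for c in calls],
        }
    )


def read_calls(path: str | Path) -> list[LocalizationCall]:
    df = read_tsv(path)
    return [
        LocalizationCall(
            str(r.protein_id), str(r.species), str(r.label),
            tuple(str(r.evidence).split(",")),
        )
        for r in df.itertuples()
    ]


def features_frame(
    features: list[TPFeatures],
    calls: list[LocalizationCall],
    windows: dict[str, str],
    clades: dict[str, str] | None = None,
) -> pd.DataFrame:
    """The per-protein feature table written by the tp-features stage."""
    call_map = {c.protein_id: c for c in calls}
    clades = clades or {}
    rows = []
    for f in features:
        c = call_map[f.protein_id]
        win = windows[f.protein_id]
        rows.append(
            {
                "protein_id": f.protein_id,
                "species": c.species,
                "clade": clades.get(c.species, ""),
                "organelle": c.label,
                "window": win,
                "length": len(win),
                "net_charge": f.net_charge,
                "phospho_count": f.phospho_count,
                "R": f.arg_count,
                "K": f.lys_count,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "species", "clade", "organelle", "window",
                 "length", "net_charge", "phospho_count", "R", "K"],
    )
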