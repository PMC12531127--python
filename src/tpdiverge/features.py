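"""First-20-residue targeting-peptide window statistics.

The N-terminal window of a targeting peptide (TP) is the first point of
contact between cargo and the organelle outer membrane.  Two integer
statistics summarise its physicochemistry:

* **net charge** — (#Lys + #Arg) − (#Asp + #Glu).  Histidine and all
  nonstandard codes contribute 0; there is no pKa/pH model, matching the
  integer charges (+5, +4, 0, −5) the quantities are meant to reproduce.
  Mitochondrial TPs (mTPs) tend toward positive values.
* **phosphorylatable count** — #Ser + #Thr, a proxy for negative charge
  acquirable by phosphorylation.  Plastid TPs (pTPs) of land plants are
  enriched in it.

The initiator methionine is counted inside positions 1..W by default
(``strip_met`` removes it first).  Sequences shorter than W are analysed
over their full length and flagged, not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .records import ProteinRecord

logger = logging.getLogger(__name__)

POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")
PHOSPHO = frozenset("ST")

#: Substitution modes for charge-editing experiments on TP windows.
SUBSTITUTION_MODES = ("neutralize", "invert", "to_serine", "swap_RK")

DEFAULT_WINDOW = 20


@dataclass(frozen=True)
class TPWindow:
    """The first ``min(W, len(sequence))`` residues of a protein."""

    protein_id: str
    residues: str
    W: int = DEFAULT_WINDOW
    short: bool = False

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("window length W must be positive")
        if len(self.residues) > self.W:
            raise ValueError("window longer than W")


@dataclass(frozen=True)
class TPFeatures:
    """Integer window statistics for one protein."""

    protein_id: str
    net_charge: int
    phospho_count: int
    arg_count: int
    lys_count: int


def extract_window(
    record: ProteinRecord, W: int = DEFAULT_WINDOW, strip_met: bool = False
) -> TPWindow:
    """Return the first *W* residues of *record* as a :class:`TPWindow`.

    A sequence shorter than *W* yields its full length with ``short=True``
    (logged).  ``strip_met`` drops a leading methionine before windowing.
    """
    if W <= 0:
        raise ValueError("window length W must be positive")
    seq = record.sequence.upper()
    if strip_met and seq.startswith("M"):
        seq = seq[1:]
    if not seq:
        raise ValueError(f"empty sequence for protein {record.protein_id!r}")
    short = len(seq) < W
    if short:
        logger.warning(
            "protein %s is shorter (%d) than the window (%d); using full length",
            record.protein_id, len(seq), W,
        )
    return TPWindow(record.protein_id, seq[:W], W=W, short=short)


def net_charge(window: TPWindow) -> int:
    """Net charge of the window: +1 per K/R, −1 per D/E, 0 otherwise."""
    charge = 0
    for aa in window.residues:
        if aa in POSITIVE:
            charge += 1
        elif aa in NEGATIVE:
            charge -= 1
    return charge


def phospho_count(window: TPWindow) -> int:
    """Number of phosphorylatable residues (serine + threonine)."""
    return sum(1 for aa in window.residues if aa in PHOSPHO)


def compute_features(window: TPWindow) -> TPFeatures:
    """All window statistics at once."""
    res = window.residues
    return TPFeatures(
        protein_id=window.protein_id,
        net_charge=net_charge(window),
        phospho_count=phospho_count(window),
        arg_count=res.count("R"),
        lys_count=res.count("K"),
    )


def substitute_charge(window: TPWindow, mode: str) -> TPWindow:
    """Apply one of the charge-editing substitutions to a window.

    Modes mirror the reporter-construct mutagenesis used to probe whether
    charge (rather than residue identity) drives targeting:

    * ``neutralize`` — K/R/D/E → A (charge becomes 0);
    * ``invert``     — K/R → D, so the sign of the basic contribution flips;
    * ``to_serine``  — K/R → S: removes the positive charge and adds
      phosphorylatable residues (the plastid-mistargeting construct);
    * ``swap_RK``    — R ↔ K: charge-preserving identity swap.
    """
    if mode not in SUBSTITUTION_MODES:
        raise ValueError(f"unknown substitution mode {mode!r}")
    table: dict[str, str]
    if mode == "neutralize":
        table = {"K": "A", "R": "A", "D": "A", "E": "A"}
    elif mode == "invert":
        table = {"K": "D", "R": "D"}
    elif mode == "to_serine":
        table = {"K": "S", "R": "S"}
    else:  # swap_RK
        table = {"R": "K", "K": "R"}
    residues = "".join(table.get(aa, aa) for aa in window.residues)
    return TPWindow(window.protein_id, residues, W=window.W, short=window.short)


def high_charge_rk_profile(
    features: list[TPFeatures], threshold: int = 3
) -> pd.DataFrame:
    """Arginine/lysine usage among strongly positive windows.

    Keeps features with ``net_charge > threshold`` (strict) and reports the
    arginine fraction R/(R+K) of each; under the filter R+K ≥ charge > 0, so
    the fraction is always defined.  Intended for mTP-labelled features,
    where a pronounced positive charge shows the R-vs-K preference.
    """
    rows = [
        {
            "protein_id": f.protein_id,
            "arg_count": f.arg_count,
            "lys_count": f.lys_count,
            "R_fraction": f.arg_count / (f.arg_count + f.lys_count),
        }
        for f in features
        if f.net_charge > threshold
    ]
    return pd.DataFrame(rows, columns=["protein_id", "arg_count", "lys_count", "R_fraction"])
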