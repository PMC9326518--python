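"""Evolutionary-conservation feature: family size plus sequence similarity.

miRNAs conserved across species tend to sit in larger miRBase families
and to keep their mature sequences similar within the family.  The
conservation feature is the sum of two terms:

* the family size |F| (member count, within and across species);
* the sequence-similarity score S_m = sum over family members m'
  (self included) of (len(m) - lev(m, m')) / len(m), where lev is the
  Levenshtein edit distance.

An identical-sequence family of size k thus scores k + k; a miRNA with
no family (or no sequence) contributes 0 for the missing part, never an
error, so the feature matrix stays total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable

import edlib
import pandas as pd

from .data_io import FamilyDB

logger = logging.getLogger(__name__)

__all__ = [
    "ConservationRecord", "levenshtein", "sequence_similarity",
    "conservation_table",
]


@dataclass
class ConservationRecord:
    mirna: str
    family_size: int
    sequence_similarity: float
    conservation: float


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def sequence_similarity(sequence: str, family: Iterable[str]) -> float:
    """Similarity of one mature sequence to its whole family.

    Each member m' (the sequence itself included) contributes
    (len(m) - lev(m, m')) / len(m).  Members with an empty sequence are
    skipped with a warning; terms may go negative when a member is more
    than len(m) edits away and are kept as computed.
    """
    if not sequence:
        logger.warning("empty query sequence; similarity 0")
        return 0.0
    length = len(sequence)
    score = 0.0
    for member in family:
        if not member:
            logger.warning("skipping family member with missing sequence")
            continue
        score += (length - levenshtein(sequence, member)) / length
    return score


def conservation_table(fam: FamilyDB,
                       universe: Iterable[str]) -> list[ConservationRecord]:
    """Conservation record for every miRNA in ``universe``.

    miRNAs absent from the family database get (0, 0, 0); miRNAs whose
    own sequence is missing get S_m = 0 but keep their family size.
    """
    records = []
    for mirna in universe:
        family = fam.family_of(mirna)
        if family is None:
            records.append(ConservationRecord(mirna, 0, 0.0, 0.0))
            continue
        size = len(family)
        seq = family.get(mirna, "")
        sim = sequence_similarity(seq, family.values()) if seq else 0.0
        records.append(ConservationRecord(mirna, size, sim, size + sim))
    return records


def conservation_frame(records: list[ConservationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mirna, r.family_size, r.sequence_similarity, r.conservation)
         for r in records],
        columns=["mirna", "family_size", "seq_similarity", "conservation"],
    ).set_index("mirna")
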