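"""Readers and writers for every external format the pipeline touches.

All miRNA identifiers are case-folded on load so that the expression
matrix, the disease-annotation table (HMDD 3.2 causal-database dialect),
the miRBase-style family definitions and the TargetScan-style target
table share a single namespace.  Matching is exact after case-folding:
no -3p/-5p stripping and no alias tables, so the reconciliation is
deterministic and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix", "DiseaseAnnotation", "FamilyDB", "TargetCounts",
    "read_expression_matrix", "read_disease_annotations", "read_family_db",
    "read_target_counts", "write_network", "read_network",
    "causal_counts_per_disease", "namespace_report",
]


@dataclass
class ExpressionMatrix:
    """miRNA x sample matrix of pre-normalized expression values."""

    mirna_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")
        if len(self.mirna_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("need at least 2 miRNAs and 2 samples")
        if self.values.shape != (len(self.mirna_ids), len(self.sample_ids)):
            raise ValueError("shape mismatch between ids and values")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids,
                            columns=self.sample_ids)


@dataclass
class DiseaseAnnotation:
    """Disease-associated and disease-causal miRNA sets for one disease.

    ``causal`` is always a subset of ``associated``: a causal miRNA is by
    definition disease-associated, and violations found at load time are
    repaired (the miRNA is added to ``associated``) with a warning.
    """

    disease_name: str
    associated: set[str]
    causal: set[str]

    def __post_init__(self) -> None:
        orphans = self.causal - self.associated
        if orphans:
            logger.warning(
                "%d causal miRNA(s) lacked an association row; added: %s",
                len(orphans), sorted(orphans))
            self.associated = self.associated | orphans


@dataclass
class FamilyDB:
    """miRNA family membership plus mature sequences (RNA alphabet)."""

    families: dict[str, dict[str, str]] = field(default_factory=dict)
    membership: dict[str, str] = field(default_factory=dict)

    def family_of(self, mirna: str) -> dict[str, str] | None:
        fam_id = self.membership.get(mirna)
        return None if fam_id is None else self.families[fam_id]

    def family_size(self, mirna: str) -> int:
        fam = self.family_of(mirna)
        return 0 if fam is None else len(fam)


@dataclass
class TargetCounts:
    """Number of predicted mRNA targets per miRNA; absent miRNAs count 0."""

    counts: dict[str, int] = field(default_factory=dict)

    def get(self, mirna: str) -> int:
        if mirna not in self.counts:
            logger.warning("miRNA %s absent from target table; count 0", mirna)
            return 0
        return self.counts[mirna]


def read_expression_matrix(path: str | Path,
                           delimiter: str = "\t") -> ExpressionMatrix:
    """Read a miRNA x sample expression table.

    First column holds miRNA names, header row holds sample names.
    Rows with any missing entry are dropped; duplicate miRNA rows are
    collapsed by their mean, each with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str).str.strip().str.casefold()

    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} "
                    f"in {path}")
            df[col] = coerced

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d row(s) with missing values", n_missing)
        df = df.dropna(axis=0)

    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning("collapsing duplicated miRNA rows by mean: %s", dups)
        df = df.groupby(level=0, sort=False).mean()

    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError(
            f"expression matrix too small after cleaning: {df.shape}")
    return ExpressionMatrix(list(df.index), [str(c) for c in df.columns],
                            df.to_numpy(dtype=float))


def _read_hmdd_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().casefold(): c for c in df.columns}
    required = {"mirna", "disease", "causality"}
    if not required <= set(cols):
        raise ValueError(
            f"annotation table must have columns {sorted(required)}; "
            f"found {list(df.columns)}")
    out = df.rename(columns={cols[k]: k for k in required})
    out["mirna"] = out["mirna"].astype(str).str.strip().str.casefold()
    out["disease"] = out["disease"].astype(str).str.strip().str.casefold()
    out["causality"] = out["causality"].astype(str).str.strip().str.casefold()
    return out


def read_disease_annotations(path: str | Path,
                             disease_name: str) -> DiseaseAnnotation:
    """Read an HMDD-3.2-style (miRNA, disease, causality) table.

    ``disease_name`` is matched exactly after case-folding; a name that
    matches no row raises with the list of available disease names.
    """
    df = _read_hmdd_table(path)
    key = disease_name.strip().casefold()
    rows = df[df["disease"] == key]
    if rows.empty:
        raise ValueError(
            f"disease {disease_name!r} not found; available diseases: "
            f"{sorted(df['disease'].unique())}")
    associated = set(rows["mirna"])
    causal = set(rows.loc[rows["causality"] == "yes", "mirna"])
    return DiseaseAnnotation(key, associated, causal)


def causal_counts_per_disease(path: str | Path) -> pd.Series:
    """Confirmed-causal miRNA count per disease name, descending.

    HMDD records the same condition under several names; this helper lets
    the user pick the name with the most confirmed causal miRNAs.
    """
    df = _read_hmdd_table(path)
    counts = (df[df["causality"] == "yes"]
              .groupby("disease")["mirna"].nunique())
    return counts.sort_values(ascending=False)


def _normalize_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def read_family_db(fam_path: str | Path, fasta_path: str | Path) -> FamilyDB:
    """Read miFam-like family stanzas plus a mature-sequence FASTA.

    Stanzas are ``ID <family>`` followed by ``MI <accession> <name>``
    member lines and a ``//`` terminator.  Sequences are normalized to
    uppercase RNA (T -> U); members with no FASTA record are retained
    with an empty sequence and a warning (they are skipped by the
    similarity score but still count toward family size).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[record.id.strip().casefold()] = _normalize_rna(
            str(record.seq))

    db = FamilyDB()
    current: str | None = None
    members: list[str] = []
    with open(fam_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            tag = line.split(maxsplit=1)[0]
            if tag == "AC":
                continue
            if tag == "ID":
                if current is not None:
                    raise ValueError(
                        f"unterminated family stanza before line {lineno}")
                current = line.split(maxsplit=1)[1].strip()
                members = []
            elif tag == "MI":
                if current is None:
                    raise ValueError(
                        f"member line outside a family stanza at line "
                        f"{lineno}")
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(
                        f"malformed member line at line {lineno}: {line!r}")
                members.append(parts[2].strip().casefold())
            elif tag == "//":
                if current is None:
                    raise ValueError(
                        f"stanza terminator without a stanza at line "
                        f"{lineno}")
                fam: dict[str, str] = {}
                for name in members:
                    if name not in sequences:
                        logger.warning(
                            "family %s member %s has no FASTA sequence",
                            current, name)
                    fam[name] = sequences.get(name, "")
                    db.membership[name] = current
                db.families[current] = fam
                current = None
            else:
                raise ValueError(
                    f"unparseable line {lineno} in {fam_path}: {line!r}")
    if current is not None:
        raise ValueError("unterminated family stanza at end of file")
    if not db.families:
        logger.warning("no families parsed from %s", fam_path)
    return db


def read_target_counts(path: str | Path) -> TargetCounts:
    """Read predicted-target counts in TargetScan-like TSV form.

    Two columns are treated as a precomputed (miRNA, count) table; more
    columns are treated as one row per miRNA-target pair and counted by
    grouping on the miRNA column (named ``miRNA`` if present, else the
    first column).
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 2:
        names = df.iloc[:, 0].astype(str).str.strip().str.casefold()
        counts = pd.to_numeric(df.iloc[:, 1])
        if (counts < 0).any():
            raise ValueError(f"negative target count in {path}")
        return TargetCounts(dict(zip(names, counts.astype(int))))
    col = next((c for c in df.columns if c.strip().casefold() == "mirna"),
               df.columns[0])
    names = df[col].astype(str).str.strip().str.casefold()
    grouped = names.value_counts()
    return TargetCounts({m: int(c) for m, c in grouped.items()})


def write_network(network, path: str | Path) -> None:
    """Write a weighted directed network as a (source, target, weight) TSV."""
    rows = []
    ids = network.mirna_ids
    w = network.weights
    src, tgt = np.nonzero(w)
    for i, j in zip(src, tgt):
        rows.append((ids[i], ids[j], float(w[i, j])))
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_network(path: str | Path):
    """Read an edge-list TSV back into a WeightedDirectedNetwork."""
    from .network_inference import WeightedDirectedNetwork

    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["source", "target", "weight"]:
        raise ValueError(
            f"expected columns source/target/weight in {path}; "
            f"found {list(df.columns)}")
    if len(df) and ((df["weight"] < 0) | (df["weight"] > 1)).any():
        bad = df.loc[(df["weight"] < 0) | (df["weight"] > 1)].iloc[0]
        raise ValueError(
            f"edge weight outside [0,1] in {path}: "
            f"{bad['source']}->{bad['target']} = {bad['weight']}")
    ids = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    index = {m: i for i, m in enumerate(ids)}
    weights = np.zeros((len(ids), len(ids)))
    for _, row in df.iterrows():
        weights[index[str(row["source"])], index[str(row["target"])]] = \
            row["weight"]
    return WeightedDirectedNetwork(ids, weights)


def namespace_report(expr: ExpressionMatrix, ann: DiseaseAnnotation,
                     fam: FamilyDB, targets: TargetCounts) -> dict[str, int]:
    """Count cross-source name mismatches against the expression namespace."""
    universe = set(expr.mirna_ids)
    return {
        "expression": len(universe),
        "annotation_unmatched": len(ann.associated - universe),
        "family_unmatched": len(set(fam.membership) - universe),
        "targets_unmatched": len(set(targets.counts) - universe),
    }
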