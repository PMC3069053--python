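"""Domain types and file I/O for the MOTU biodiversity pipeline.

The pipeline operates on four in-memory objects: an :class:`AlignedSeqSet`
(the marker alignment, ~180 bp D3 fragments of 28S rRNA in the motivating
study), a :class:`SpecimenTable` linking specimens to traps, transects,
habitats, morphospecies and sequences, a :class:`MotuPartition` assigning
sequenced specimens to molecular operational taxonomic units (MOTUs), and a
:class:`CommunityMatrix` (sampling-unit x taxon counts).  File formats are
plain text throughout: aligned FASTA, tab-separated tables, Newick and JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentError,
    ConsistencyError,
    EmptyInputError,
    FormatError,
)

#: Sentinel stored in the ``sequence_id`` column for failed amplifications.
SEQUENCING_FAILED = "SEQUENCING_FAILED"

#: Residues accepted in the alignment (after upper-casing and U->T mapping).
ALPHABET = frozenset("ACGTN-")

#: Required columns of the specimen metadata table, in canonical order.
SPECIMEN_COLUMNS = (
    "specimen_id",
    "trap_id",
    "transect_id",
    "habitat",
    "morphospecies_id",
    "sequence_id",
)

HABITATS = ("primary", "secondary")


# ---------------------------------------------------------------------------
# AlignedSeqSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedSeqSet:
    """Equal-length nucleotide sequences keyed by sequence id.

    Residues are upper-case over ``{A, C, G, T, N, -}``; the constructor
    normalises case and maps U to T.  All sequences must share one length
    (the alignment is an upstream responsibility; ragged input is refused).
    """

    records: dict[str, str]
    alignment_length: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment contains no sequences")
        cleaned: dict[str, str] = {}
        for sid, seq in self.records.items():
            if not sid:
                raise FormatError("empty sequence id")
            norm = seq.upper().replace("U", "T")
            bad = [i for i, ch in enumerate(norm) if ch not in ALPHABET]
            if bad:
                raise FormatError(
                    f"sequence {sid!r}: invalid character {seq[bad[0]]!r} "
                    f"at position {bad[0] + 1}"
                )
            cleaned[sid] = norm
        lengths = {len(s) for s in cleaned.values()}
        if len(lengths) != 1:
            offenders = sorted(
                sid for sid, s in cleaned.items()
                if len(s) != len(next(iter(cleaned.values())))
            )
            raise AlignmentError(
                "sequences are not aligned to a common length "
                f"(lengths {sorted(lengths)}; e.g. ids {offenders[:5]})"
            )
        object.__setattr__(self, "records", cleaned)
        object.__setattr__(self, "alignment_length", lengths.pop())

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sid: str) -> bool:
        return sid in self.records

    def ids(self) -> list[str]:
        return list(self.records)

    def subset(self, ids: Iterable[str]) -> "AlignedSeqSet":
        return AlignedSeqSet({i: self.records[i] for i in ids})


def read_fasta(path) -> AlignedSeqSet:
    """Read an aligned (gapped) FASTA file into an :class:`AlignedSeqSet`.

    Raises :class:`FormatError` on duplicate ids or invalid characters and
    :class:`AlignmentError` on unequal sequence lengths.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"sequence {rec.id!r} is empty")
        records[rec.id] = str(rec.seq)
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return AlignedSeqSet(records)


def write_fasta(seqs: AlignedSeqSet, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in seqs.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SpecimenTable
# ---------------------------------------------------------------------------

class SpecimenTable:
    """Per-specimen metadata: trap, transect, habitat, morphospecies, sequence.

    Invariants enforced on construction: unique specimen ids; each trap
    belongs to exactly one transect and each transect to exactly one habitat;
    habitat labels are ``primary`` or ``secondary`` (validated
    case-insensitively).  Specimens whose amplification failed carry the
    :data:`SEQUENCING_FAILED` flag in ``sequence_id`` and are excluded from
    every MOTU-based statistic, but retained so the sequencing success rate
    is computable.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"specimen table missing columns {missing}")
        df = df.loc[:, list(SPECIMEN_COLUMNS)].astype(str).reset_index(drop=True)
        df["sequence_id"] = df["sequence_id"].replace({"nan": "", "None": ""})
        df["habitat"] = df["habitat"].str.lower()
        bad_hab = sorted(set(df["habitat"]) - set(HABITATS))
        if bad_hab:
            raise FormatError(f"unknown habitat label(s) {bad_hab}")
        if df["specimen_id"].duplicated().any():
            dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"]
            raise FormatError(f"duplicate specimen id(s) {sorted(set(dups))[:5]}")
        trap_map = df.groupby("trap_id")["transect_id"].nunique()
        if (trap_map > 1).any():
            raise ConsistencyError(
                f"trap(s) mapped to multiple transects: "
                f"{sorted(trap_map[trap_map > 1].index)}"
            )
        tr_map = df.groupby("transect_id")["habitat"].nunique()
        if (tr_map > 1).any():
            raise ConsistencyError(
                f"transect(s) mapped to multiple habitats: "
                f"{sorted(tr_map[tr_map > 1].index)}"
            )
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    # -- sequencing bookkeeping --------------------------------------------

    def _failed_mask(self) -> pd.Series:
        col = self._df["sequence_id"]
        return (col == SEQUENCING_FAILED) | (col == "")

    @property
    def n_attempted(self) -> int:
        return len(self._df)

    @property
    def n_success(self) -> int:
        return int((~self._failed_mask()).sum())

    @property
    def success_rate_percent(self) -> float:
        """Sequencing success rate as a percentage, rounded to one decimal."""
        return round(100.0 * self.n_success / self.n_attempted, 1)

    def sequenced(self) -> pd.DataFrame:
        """Rows with a successful sequence."""
        return self._df[~self._failed_mask()].copy()

    def sequence_to_specimen(self) -> dict[str, str]:
        seqd = self.sequenced()
        return dict(zip(seqd["sequence_id"], seqd["specimen_id"]))

    # -- design lookups -----------------------------------------------------

    def trap_to_transect(self) -> dict[str, str]:
        return dict(
            self._df.drop_duplicates("trap_id")
            .set_index("trap_id")["transect_id"]
        )

    def transect_to_habitat(self) -> dict[str, str]:
        return dict(
            self._df.drop_duplicates("transect_id")
            .set_index("transect_id")["habitat"]
        )

    def validate_against(self, seqs: AlignedSeqSet) -> None:
        """Check every non-failed sequence id resolves in the alignment."""
        missing = sorted(
            s for s in self.sequenced()["sequence_id"] if s not in seqs
        )
        if missing:
            raise ConsistencyError(
                f"sequence id(s) not found in alignment: {missing[:5]}"
            )


def read_specimens(path) -> SpecimenTable:
    """Read the specimen metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SpecimenTable(df)


def write_specimens(table: SpecimenTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MotuPartition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotuPartition:
    """Assignment of sequenced specimens to MOTU ids at one bp threshold."""

    threshold_bp: int
    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.threshold_bp < 1:
            raise ValueError("threshold_bp must be >= 1")
        object.__setattr__(self, "assignment", dict(self.assignment))

    @property
    def n_motus(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, motu in self.assignment.items():
            out.setdefault(motu, []).append(sid)
        return {m: sorted(v) for m, v in out.items()}

    def as_sets(self) -> set[frozenset[str]]:
        """The partition as a set of specimen sets (label-free)."""
        return {frozenset(v) for v in self.members().values()}


def write_motus(partition: MotuPartition, path,
                sequence_of: Mapping[str, str] | None = None) -> None:
    """Write a MOTU table TSV: sequence_id, specimen_id, motu_id, threshold.

    ``sequence_of`` maps the partition's specimen ids to sequence ids; when
    omitted the two id namespaces are assumed identical.
    """
    rows = []
    for key in sorted(partition.assignment):
        seq = sequence_of.get(key, key) if sequence_of else key
        rows.append((seq, key, partition.assignment[key], partition.threshold_bp))
    pd.DataFrame(
        rows, columns=["sequence_id", "specimen_id", "motu_id", "threshold"]
    ).to_csv(path, sep="\t", index=False)


def read_motus(path) -> MotuPartition:
    df = pd.read_csv(path, sep="\t", dtype={"threshold": int}, keep_default_na=False)
    thresholds = set(df["threshold"])
    if len(thresholds) != 1:
        raise FormatError(f"MOTU table mixes thresholds {sorted(thresholds)}")
    return MotuPartition(
        threshold_bp=int(thresholds.pop()),
        assignment=dict(zip(df["specimen_id"].astype(str), df["motu_id"].astype(str))),
    )


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityMatrix:
    """Sampling-unit x taxon count table (abundance or 0/1 incidence)."""

    df: pd.DataFrame
    mode: Literal["abundance", "incidence"] = "abundance"

    def __post_init__(self) -> None:
        df = self.df
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise FormatError("community matrix has duplicate unit or taxon labels")
        if (df.values < 0).any():
            raise FormatError("community matrix has negative counts")
        if self.mode == "incidence" and not df.isin([0, 1]).all().all():
            raise FormatError("incidence matrix must contain only 0/1")
        object.__setattr__(self, "df", df.astype(int))

    @property
    def units(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.columns)

    def incidence(self) -> "CommunityMatrix":
        return CommunityMatrix((self.df > 0).astype(int), mode="incidence")

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="unit")


def read_community_matrix(path, mode: str = "abundance") -> CommunityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="unit")
    df.index = df.index.astype(str)
    return CommunityMatrix(df, mode=mode)  # type: ignore[arg-type]


def build_community_matrix(
    specimens: SpecimenTable,
    taxon_source: Literal["morphospecies", "motu"] = "morphospecies",
    unit_level: Literal["trap", "transect"] = "trap",
    partition: MotuPartition | None = None,
    mode: Literal["abundance", "incidence"] = "abundance",
    include_failed: bool = True,
) -> CommunityMatrix:
    """Cross-tabulate specimens into a unit x taxon community matrix.

    With ``taxon_source='motu'`` only sequenced specimens are counted (a
    partition is required); with ``'morphospecies'`` sequencing failures are
    included by default (``include_failed``), since morphological labels do
    not depend on amplification success.
    """
    if len(specimens) == 0:
        raise EmptyInputError("empty specimen table")
    unit_col = "trap_id" if unit_level == "trap" else "transect_id"
    if taxon_source == "motu":
        if partition is None:
            raise ConsistencyError("taxon_source='motu' requires a MotuPartition")
        df = specimens.sequenced()
        unknown = sorted(set(df["specimen_id"]) - set(partition.assignment))
        if unknown:
            raise ConsistencyError(
                f"sequenced specimen(s) missing from partition: {unknown[:5]}"
            )
        taxa = df["specimen_id"].map(dict(partition.assignment))
    else:
        df = specimens.df if include_failed else specimens.sequenced()
        taxa = df["morphospecies_id"]
    counts = pd.crosstab(df[unit_col], taxa)
    counts = counts.sort_index(axis=0).sort_index(axis=1)
    counts.index.name = None
    counts.columns.name = None
    if mode == "incidence":
        counts = (counts > 0).astype(int)
    return CommunityMatrix(counts, mode=mode)


# ---------------------------------------------------------------------------
# ResultsReport
# ---------------------------------------------------------------------------

class ResultsReport(dict):
    """Nested key->value report; serialises to/from JSON losslessly."""

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ResultsReport":
        with open(path) as fh:
            return cls(json.load(fh))
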