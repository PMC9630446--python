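"""Input handling for missense-variant tables, paralog alignments and coordinate maps.

Variant positions are 1-based and live in each protein's own full-length
(UniProt-style) numbering.  A per-member *offset* — the full-length residue
number of the first residue inside the aligned construct — converts between
full-length numbering, construct-local numbering and alignment columns.
Alignment columns are 1-based throughout the public API.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: canonical column order for variant tables (extra columns are preserved as-is)
CANONICAL_COLUMNS = [
    "protein_id", "position", "wt_aa", "mut_aa",
    "activity_me0", "activity_me1", "activity_sd",
    "fathmm", "polyphen2", "opai", "fi_score", "vc_score", "vs_score",
    "ddg", "datoms", "dcharge", "dhydro", "dvolume", "dhdonors",
    "dhacceptors", "blosum62",
]

REQUIRED_COLUMNS = ["protein_id", "position", "wt_aa", "mut_aa"]


class FormatError(ValueError):
    """Malformed input file (missing headers, ragged alignment, ...)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


@dataclass(frozen=True)
class MissenseVariant:
    """One amino-acid substitution in one family member."""

    protein_id: str
    position: int          # 1-based, full-length numbering of the protein
    wt_aa: str
    mut_aa: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET or self.mut_aa not in AA_ALPHABET:
            raise ValidationError(
                f"{self.protein_id}:{self.position} uses a nonstandard residue "
                f"({self.wt_aa}->{self.mut_aa})"
            )
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"{self.protein_id}:{self.position} is synonymous ({self.wt_aa})"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")


class VariantTable:
    """An ordered collection of missense variants with attached named columns.

    Wraps a :class:`pandas.DataFrame` whose first four columns are the variant
    key (``protein_id, position, wt_aa, mut_aa``); every other column is an
    attachment (activities, predictor scores, ...) carried through the
    pipeline untouched.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"variant table missing mandatory columns: {missing}")
        df = df.reset_index(drop=True).copy()
        df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
        for row in df.itertuples(index=True):
            # constructor enforces per-variant invariants, naming the row
            try:
                MissenseVariant(str(row.protein_id), int(row.position),
                                str(row.wt_aa), str(row.mut_aa))
            except ValidationError as exc:
                raise ValidationError(f"row {row.Index}: {exc}") from None
        key = df[["protein_id", "position", "mut_aa"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate variant {dup.protein_id}:{dup.position}{dup.mut_aa}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, VariantTable) and self.df.equals(other.df)

    @property
    def variants(self) -> Iterator[MissenseVariant]:
        for row in self.df.itertuples(index=False):
            yield MissenseVariant(str(row.protein_id), int(row.position),
                                  str(row.wt_aa), str(row.mut_aa))

    @property
    def attachments(self) -> list[str]:
        return [c for c in self.df.columns if c not in REQUIRED_COLUMNS]

    def require_columns(self, names: Sequence[str], stage: str) -> None:
        """Downstream stages declare their needs; the reader never imputes."""
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise FormatError(f"stage '{stage}' requires missing columns: {missing}")


def read_variant_table(path: str | Path, dialect: str = "tsv") -> VariantTable:
    """Read a delimited variant table (header row mandatory)."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory header columns {missing}")
    bad = pd.to_numeric(df["position"], errors="coerce").isna()
    if bad.any():
        rows = list(df.index[bad])
        raise FormatError(f"{path}: unparseable positions in rows {rows}")
    return VariantTable(df)


def write_variant_table(table: VariantTable, path: str | Path,
                        dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    cols = [c for c in CANONICAL_COLUMNS if c in table.df.columns]
    cols += [c for c in table.df.columns if c not in cols]
    table.df[cols].to_csv(path, sep=sep, index=False)


@dataclass
class ParalogAlignment:
    """A gapped multiple alignment of family members, with optional clade labels."""

    sequences: dict[str, str]
    clades: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise FormatError("alignment needs at least 2 sequences")
        norm = {}
        widths = set()
        for pid, seq in self.sequences.items():
            seq = seq.upper().replace(".", "-")
            norm[pid] = seq
            widths.add(len(seq))
        if len(widths) != 1:
            raise FormatError(f"ragged alignment: lengths {sorted(widths)}")
        self.sequences = norm

    @property
    def width(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def members(self) -> list[str]:
        return list(self.sequences)

    def ungapped(self, protein_id: str) -> str:
        return self.sequences[protein_id].replace("-", "")

    def column(self, col: int) -> dict[str, str]:
        """Residue (or '-') of each member at 1-based alignment column ``col``."""
        return {pid: seq[col - 1] for pid, seq in self.sequences.items()}

    def subset(self, members: Sequence[str]) -> "ParalogAlignment":
        seqs = {m: self.sequences[m] for m in members}
        clades = {m: self.clades[m] for m in members if m in self.clades}
        if len(seqs) == 1:  # keep single-member subsets usable for conservation
            aln = ParalogAlignment.__new__(ParalogAlignment)
            aln.sequences, aln.clades = seqs, clades
            return aln
        return ParalogAlignment(seqs, clades)


def read_alignment(path: str | Path, format: str = "fasta",
                   clades: Mapping[str, str] | None = None) -> ParalogAlignment:
    """Read a FASTA or Clustal alignment via Bio.AlignIO."""
    if format not in ("fasta", "clustal"):
        raise FormatError(f"unsupported alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    ids = [rec.id for rec in aln]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sequence ids")
    return ParalogAlignment({rec.id: str(rec.seq) for rec in aln},
                            dict(clades) if clades else {})


def write_alignment_fasta(aln: ParalogAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in aln.sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def load_member_config(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Load the sidecar config mapping protein_id -> {clade, offset} (YAML or JSON)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    clades = {pid: str(v["clade"]) for pid, v in data.items()}
    offsets = {pid: int(v["offset"]) for pid, v in data.items()}
    return clades, offsets


class CoordinateMap:
    """Bijection between member-local residue positions and alignment columns.

    Local positions count ungapped residues of the aligned construct (1-based);
    full-length numbering is ``offset + local - 1``.  Gap columns carry no
    local position for that member.
    """

    def __init__(self, aln: ParalogAlignment, reference_id: str,
                 offsets: Mapping[str, int]):
        if reference_id not in aln.sequences:
            raise ValidationError(f"reference {reference_id!r} absent from alignment")
        for pid in aln.members:
            if pid not in offsets:
                raise ValidationError(f"no offset for member {pid!r}")
            if offsets[pid] < 1:
                raise ValidationError(f"offset for {pid!r} must be >= 1")
        self.alignment = aln
        self.reference_id = reference_id
        self.offsets = {pid: int(offsets[pid]) for pid in aln.members}
        # _cols[pid][local-1] = 1-based column of the local-th residue
        self._cols: dict[str, np.ndarray] = {}
        self._locals: dict[str, dict[int, int]] = {}
        for pid, seq in aln.sequences.items():
            cols = np.flatnonzero(np.frombuffer(seq.encode(), dtype="S1") != b"-") + 1
            self._cols[pid] = cols
            self._locals[pid] = {int(c): i + 1 for i, c in enumerate(cols)}

    def n_residues(self, protein_id: str) -> int:
        return len(self._cols[protein_id])

    def column_from_local(self, protein_id: str, local: int) -> int:
        cols = self._cols[protein_id]
        if not 1 <= local <= len(cols):
            raise ValidationError(
                f"{protein_id} local position {local} outside construct (1..{len(cols)})")
        return int(cols[local - 1])

    def local_from_column(self, protein_id: str, column: int) -> int | None:
        """Local position at a column, or None if the member has a gap there."""
        return self._locals[protein_id].get(int(column))

    def column_from_full(self, protein_id: str, full_pos: int) -> int:
        return self.column_from_local(protein_id,
                                      full_pos - self.offsets[protein_id] + 1)

    def full_from_column(self, protein_id: str, column: int) -> int | None:
        local = self.local_from_column(protein_id, column)
        return None if local is None else self.offsets[protein_id] + local - 1

    def reference_label(self, column: int) -> str:
        """Reference full-length numbering of a column.

        Columns where the reference is gapped fall back to the nearest
        preceding reference residue with a ``+`` suffix.
        """
        full = self.full_from_column(self.reference_id, column)
        if full is not None:
            return str(full)
        cols = self._cols[self.reference_id]
        prev = cols[cols < column]
        if len(prev) == 0:
            return f"<{self.offsets[self.reference_id]}"
        local = int(np.searchsorted(cols, column))  # count of ref residues before col
        return f"{self.offsets[self.reference_id] + local - 1}+"


def build_coordinate_map(aln: ParalogAlignment, reference_id: str,
                         offsets: Mapping[str, int]) -> CoordinateMap:
    return CoordinateMap(aln, reference_id, offsets)


def validate_variants(table: VariantTable, aln: ParalogAlignment,
                      offsets: Mapping[str, int]) -> pd.DataFrame:
    """Cross-check each variant against the alignment; report-producing, never raises.

    Flags: ``ok``, ``unknown_protein``, ``out_of_range`` (position outside the
    aligned construct) and ``wt_mismatch`` (stated wild-type residue disagrees
    with the sequence).
    """
    flags = []
    for row in table.df.itertuples(index=False):
        pid = str(row.protein_id)
        if pid not in aln.sequences or pid not in offsets:
            flags.append("unknown_protein")
            continue
        local = int(row.position) - int(offsets[pid]) + 1
        seq = aln.ungapped(pid)
        if not 1 <= local <= len(seq):
            flags.append("out_of_range")
        elif seq[local - 1] != row.wt_aa:
            flags.append("wt_mismatch")
        else:
            flags.append("ok")
    report = table.df[REQUIRED_COLUMNS].copy()
    report["flag"] = flags
    return report
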