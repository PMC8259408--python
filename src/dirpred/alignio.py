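"""Alignment I/O, coordinate maps and cross-alignment plumbing.

Alignments are rectangular matrices of gapped amino-acid sequences.  All
scoring downstream works on a strict 21-symbol alphabet: the 20 canonical
amino acids plus the gap ``-``.  Reading normalizes common FASTA dialects
(lowercase, ``.`` gaps) and replaces ambiguity codes (B, Z, X, J) and
non-standard residues (U, O, ``*``) with gaps so that conservation,
mutual-information and simulation machinery all share one clean alphabet.

Coordinate conventions: reference residue positions are 1-based over the
ungapped reference sequence (so "Asn-32" style residue names match);
alignment columns are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .exceptions import (
    AlignmentShapeError,
    AlphabetError,
    ConsistencyError,
    DegenerateInputError,
    IdentityError,
    InputError,
    PairingError,
)

#: Canonical amino-acid alphabet, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Integer code of the gap symbol; amino acids are coded 0..19.
GAP_CODE = 20

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AMBIGUOUS = set("BZXJUO*")

_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _a, _i in _AA_INDEX.items():
    _ENCODE_TABLE[ord(_a)] = _i
_ENCODE_TABLE[ord(GAP)] = GAP_CODE


def normalize_sequence(seq: str) -> str:
    """Upper-case, unify '.'/'-' gaps and map ambiguity codes to gaps."""
    out = []
    for ch in seq.upper():
        if ch == ".":
            ch = GAP
        if ch in _AMBIGUOUS:
            ch = GAP
        out.append(ch)
    return "".join(out)


def encode(seq: str) -> np.ndarray:
    """Encode a normalized gapped sequence as int8 codes (gap == 20)."""
    codes = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise AlphabetError(f"non amino-acid characters after normalization: {bad}")
    return codes


def default_species_tag(identifier: str) -> str:
    """Default species rule: the last underscore-separated token."""
    return identifier.rsplit("_", 1)[-1]


def species_tagger(rule: str | Callable[[str], str] | None) -> Callable[[str], str]:
    """Build a species-extraction callable from a regex (first group) or
    callable; ``None`` gives the last-underscore-token default."""
    if rule is None:
        return default_species_tag
    if callable(rule):
        return rule
    pattern = re.compile(rule)

    def _tag(identifier: str) -> str:
        m = pattern.search(identifier)
        if m is None:
            raise IdentityError(f"species rule {rule!r} does not match {identifier!r}")
        return m.group(1) if m.groups() else m.group(0)

    return _tag


@dataclass
class Alignment:
    """A rectangular gapped alignment with unique row identifiers."""

    ids: list[str]
    seqs: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.ids:
            raise InputError("alignment has no rows")
        if len(self.ids) != len(set(self.ids)):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise IdentityError(f"duplicate identifiers: {dup}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"ragged alignment, row lengths {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """(n_rows, n_cols) int8 matrix; cached."""
        if self._codes is None:
            self._codes = np.vstack([encode(s) for s in self.seqs])
        return self._codes

    def row(self, identifier: str) -> str:
        try:
            return self.seqs[self.ids.index(identifier)]
        except ValueError:
            raise IdentityError(f"identifier {identifier!r} not in alignment") from None

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.seqs)

    def species(self, rule=None) -> list[str]:
        tag = species_tagger(rule)
        return [tag(i) for i in self.ids]

    def subset(self, identifiers: Sequence[str]) -> "Alignment":
        idx = {i: k for k, i in enumerate(self.ids)}
        return Alignment(list(identifiers), [self.seqs[idx[i]] for i in identifiers])


def read_alignment(path: str | Path, require_equal_length: bool = True) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Sequences are normalized (upper case, ``.`` -> ``-``, ambiguity codes
    to gaps).  With ``require_equal_length`` (the default) ragged input
    raises :class:`AlignmentShapeError`; without it, shorter rows are
    right-padded with gaps.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise InputError(f"cannot read {path}") from None
    if not records:
        raise InputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [normalize_sequence(str(r.seq)) for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        if require_equal_length:
            raise AlignmentShapeError(
                f"{path}: rows have differing lengths {sorted(lengths)}"
            )
        width = max(lengths)
        seqs = [s.ljust(width, GAP) for s in seqs]
    aln = Alignment(ids, seqs)
    aln.codes()  # validate alphabet eagerly
    return aln


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for identifier, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{identifier}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


@dataclass
class ReferenceMap:
    """Monotone map from 1-based reference residue positions to 0-based
    alignment columns."""

    ref_id: str
    columns: np.ndarray  # columns[i] is the column of position i+1
    residues: str  # ungapped reference sequence

    @property
    def n_sites(self) -> int:
        return len(self.columns)

    def column_of(self, position: int) -> int:
        if not 1 <= position <= self.n_sites:
            raise IndexError(f"reference position {position} out of 1..{self.n_sites}")
        return int(self.columns[position - 1])

    def residue_of(self, position: int) -> str:
        return self.residues[position - 1]

    def position_of_column(self) -> dict[int, int]:
        return {int(c): i + 1 for i, c in enumerate(self.columns)}


def build_reference_map(aln: Alignment, ref_id: str) -> ReferenceMap:
    """Map each non-gap residue of the reference row to its column."""
    row = aln.row(ref_id)
    cols = np.nonzero(np.array(list(row)) != GAP)[0]
    if len(cols) == 0:
        raise DegenerateInputError(f"reference row {ref_id!r} is all gaps")
    residues = "".join(row[c] for c in cols)
    return ReferenceMap(ref_id, cols, residues)


@dataclass
class PairedAlignment:
    """A ligand and a receptor ortholog alignment restricted to shared
    species, with identical row order (one row per species)."""

    ligand_block: Alignment
    receptor_block: Alignment
    species_order: list[str]


def pair_by_species(
    ligand_orth: Alignment,
    receptor_orth: Alignment,
    species_rule=None,
) -> PairedAlignment:
    """Pair two ortholog alignments row-by-row on the species tag.

    Species present in only one alignment are dropped; species with more
    than one row in either alignment are dropped entirely (cross-species
    MI needs exactly one row per species).  Row order follows the ligand
    alignment.
    """
    tag = species_tagger(species_rule)

    def unique_rows(aln: Alignment) -> dict[str, str]:
        seen: dict[str, list[str]] = {}
        for identifier in aln.ids:
            seen.setdefault(tag(identifier), []).append(identifier)
        return {sp: ids[0] for sp, ids in seen.items() if len(ids) == 1}

    lig = unique_rows(ligand_orth)
    rec = unique_rows(receptor_orth)
    shared = [tag(i) for i in ligand_orth.ids if tag(i) in lig and tag(i) in rec]
    # preserve ligand order, dedupe (unique_rows already guarantees one row)
    if not shared:
        raise PairingError("no species shared between ligand and receptor alignments")
    ligand_block = ligand_orth.subset([lig[sp] for sp in shared])
    receptor_block = receptor_orth.subset([rec[sp] for sp in shared])
    return PairedAlignment(ligand_block, receptor_block, shared)


@dataclass
class ProjectedOrthologs:
    """Per-paralog ortholog alignments re-expressed in the column system
    of the paralog master alignment."""

    master_cols: int
    blocks: dict[str, Alignment]

    def joint(self) -> Alignment:
        """Vertical stack of all blocks (the joint ortholog alignment)."""
        ids: list[str] = []
        seqs: list[str] = []
        for name in self.blocks:
            ids.extend(self.blocks[name].ids)
            seqs.extend(self.blocks[name].seqs)
        return Alignment(ids, seqs)


def project_orthologs_onto_master(
    master: Alignment,
    orth_msas: Mapping[str, Alignment],
    ref_ids: Mapping[str, str],
) -> ProjectedOrthologs:
    """Project each paralog's ortholog alignment onto master columns.

    For each paralog, every master column is routed through that
    paralog's master row to a reference residue position and then through
    the ortholog alignment's reference map to an ortholog column.  Master
    columns where the paralog's master row is gapped become all-gap
    columns; ortholog-alignment insertion columns (gapped in the
    reference row) are discarded.
    """
    blocks: dict[str, Alignment] = {}
    for paralog, orth in orth_msas.items():
        ref_id = ref_ids[paralog]
        master_row = master.row(ref_id)
        orth_map = build_reference_map(orth, ref_id)
        master_ungapped = master_row.replace(GAP, "")
        if master_ungapped != orth_map.residues:
            raise ConsistencyError(
                f"paralog {paralog!r}: reference sequence differs between the "
                f"master alignment and its ortholog alignment"
            )
        gap_row = GAP * orth.n_rows
        cols: list[str] = []
        pos = 0  # running reference position (1-based after increment)
        for c, ch in enumerate(master_row):
            if ch == GAP:
                cols.append(gap_row)
            else:
                pos += 1
                cols.append(orth.column(orth_map.column_of(pos)))
        seqs = ["".join(col[r] for col in cols) for r in range(orth.n_rows)]
        blocks[paralog] = Alignment(list(orth.ids), seqs)
    return ProjectedOrthologs(master.n_cols, blocks)
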