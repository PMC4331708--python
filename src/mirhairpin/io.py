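"""Sequence and structure file I/O and dataset assembly.

Conventions used throughout the package:

* coordinates are 1-based and intervals are closed on both ends;
* DNA input is accepted and normalised to RNA (``T``/``t`` mapped to ``U``,
  everything upper-cased);
* IUPAC ambiguity codes (``N``, ``R``, ``Y``, ...) are rejected by default
  because the structure/thermodynamic features are undefined on them; readers
  accept ``skip_invalid=True`` to drop such records with a warning instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    FastaParseError,
    SamplingError,
    SequenceValidationError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_NORMALISE = str.maketrans("acgut", "ACGUU") | str.maketrans({"T": "U"})

POSITIVE = "positive"
NEGATIVE = "negative"

#: Provenance tags a record may carry in a :class:`LabeledDataset`.
SOURCE_TAGS = (
    "viral_pre_mirna",
    "genome_fragment",
    "human_pre_mirna",
    "pseudo_coding",
    "synthetic",
)


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with an identifier.

    ``residues`` only ever contains ``A``/``C``/``G``/``U``; use
    :meth:`from_raw` to normalise arbitrary DNA/RNA input.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: invalid residues {sorted(bad)}; "
                "only A/C/G/U (or T, mapped to U) are accepted"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "RnaSequence":
        """Build from raw input, applying T->U and case normalisation."""
        return cls(id=id, residues=raw.translate(_NORMALISE))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def L(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, skip_invalid: bool = False) -> list[RnaSequence]:
    """Read a FASTA file into validated :class:`RnaSequence` records.

    Record order is preserved.  Raises :class:`FastaParseError` (with line
    number) on malformed files and :class:`SequenceValidationError` naming the
    record on disallowed residues, unless ``skip_invalid`` drops them.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: expected a '>' header before sequence data", line=lineno
                )
            break
        else:
            raise FastaParseError(f"{path}: no FASTA records found", line=None)

    records: list[RnaSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(RnaSequence.from_raw(rec.id, str(rec.seq)))
        except SequenceValidationError:
            if skip_invalid:
                logger.warning("skipping record %r: disallowed residues", rec.id)
                continue
            raise
    return records


def write_fasta(records: Iterable[RnaSequence], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_structure_file(path: str | Path):
    """Read a Vienna-style 3-line structure file.

    Dialect: ``>id`` header, sequence line, then a dot-bracket line ending in
    the free energy in parentheses, e.g. ``(((...))) (-1.20)``.

    Returns a list of ``(RnaSequence, SecondaryStructure)`` tuples.
    """
    from .folding import SecondaryStructure  # local import to avoid a cycle

    path = Path(path)
    out = []
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if len(lines) % 3 != 0 or not lines:
        raise StructureParseError(
            f"{path}: expected blocks of 3 lines (header/sequence/structure)"
        )
    for k in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[k : k + 3]
        if not header.startswith(">"):
            raise StructureParseError(f"{path}: block {k // 3 + 1}: missing '>' header")
        rec_id = header[1:].split()[0]
        seq = RnaSequence.from_raw(rec_id, seq_line.strip())
        lpar = struct_line.rfind("(")
        if lpar <= 0 or not struct_line.rstrip().endswith(")"):
            raise StructureParseError(
                f"{path}: record {rec_id!r}: structure line must end in '(MFE)'"
            )
        dotbracket = struct_line[:lpar].strip()
        try:
            mfe = float(struct_line[lpar + 1 :].rstrip().rstrip(")"))
        except ValueError as exc:
            raise StructureParseError(
                f"{path}: record {rec_id!r}: cannot parse MFE value"
            ) from exc
        if len(dotbracket) != len(seq):
            raise StructureParseError(
                f"{path}: record {rec_id!r}: structure length {len(dotbracket)} "
                f"!= sequence length {len(seq)}"
            )
        try:
            structure = SecondaryStructure.from_dotbracket(dotbracket, mfe=mfe)
        except StructureParseError as exc:
            raise StructureParseError(f"{path}: record {rec_id!r}: {exc}") from exc
        out.append((seq, structure))
    return out


def write_structure_file(entries, path: str | Path) -> None:
    """Inverse of :func:`read_structure_file`."""
    with open(path, "w") as fh:
        for seq, structure in entries:
            fh.write(f">{seq.id}\n{seq.residues}\n")
            fh.write(f"{structure.dotbracket} ({structure.mfe:.2f})\n")


def sample_negative_fragments(
    genome: RnaSequence,
    n: int,
    fragment_length: int = 120,
    exclude: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    max_draw_factor: int = 1000,
) -> list[RnaSequence]:
    """Sample ``n`` non-excluded fragments of fixed length from a genome.

    Start positions are drawn uniformly (rejection sampling, without
    replacement of start positions) over ``[1, L - fragment_length + 1]``; a
    fragment is rejected if it overlaps any 1-based closed ``exclude``
    interval by at least one nucleotide.  Raises :class:`SamplingError` after
    ``max_draw_factor * n`` draws rather than silently returning fewer
    fragments.
    """
    L = len(genome)
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    if L < fragment_length:
        raise SamplingError(
            f"genome {genome.id!r} ({L} nt) shorter than fragment_length {fragment_length}"
        )
    rng = np.random.default_rng(seed)
    max_start = L - fragment_length + 1
    chosen: list[int] = []
    seen: set[int] = set()
    draws = 0
    cap = max_draw_factor * max(n, 1)
    while len(chosen) < n:
        if draws >= cap:
            raise SamplingError(
                f"could not place {n} fragments in genome {genome.id!r} after "
                f"{cap} draws ({len(chosen)} placed); excluded regions too large "
                "or genome too short"
            )
        draws += 1
        start = int(rng.integers(1, max_start + 1))
        if start in seen:
            continue
        end = start + fragment_length - 1
        if any(start <= e and s <= end for s, e in exclude):
            seen.add(start)
            continue
        seen.add(start)
        chosen.append(start)
    return [
        RnaSequence(
            id=f"{genome.id}|{s}-{s + fragment_length - 1}",
            residues=genome.residues[s - 1 : s - 1 + fragment_length],
        )
        for s in chosen
    ]


@dataclass
class LabeledDataset:
    """Records with class labels, source tags and (optionally) features.

    ``features`` is a DataFrame aligned row-for-row with ``records`` whose
    columns are the canonical feature names.
    """

    records: list[tuple[RnaSequence, str, str]] = field(default_factory=list)
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for _, label, source in self.records:
            if label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}, got {label!r}")
            if source not in SOURCE_TAGS:
                raise ValueError(f"unknown source tag {source!r}")
        if self.features is not None and len(self.features) != len(self.records):
            raise ValueError(
                f"feature matrix has {len(self.features)} rows for "
                f"{len(self.records)} records"
            )

    @classmethod
    def from_sequences(
        cls,
        positives: Iterable[RnaSequence],
        negatives: Iterable[RnaSequence],
        positive_source: str = "viral_pre_mirna",
        negative_source: str = "genome_fragment",
    ) -> "LabeledDataset":
        records = [(s, POSITIVE, positive_source) for s in positives]
        records += [(s, NEGATIVE, negative_source) for s in negatives]
        return cls(records=records)

    @property
    def sequences(self) -> list[RnaSequence]:
        return [seq for seq, _, _ in self.records]

    @property
    def ids(self) -> list[str]:
        return [seq.id for seq, _, _ in self.records]

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = positive, 0 = negative."""
        return np.array([1 if lab == POSITIVE else 0 for _, lab, _ in self.records])

    def check_trainable(self) -> None:
        y = self.y
        if len(y) == 0 or y.min() == y.max():
            raise ValueError("dataset must contain at least one record of each class")

    def with_features(self, features: pd.DataFrame) -> "LabeledDataset":
        return LabeledDataset(records=list(self.records), features=features)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as TSV with the record id as first column."""
    features.to_csv(path, sep="\t", index=True, index_label="id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
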