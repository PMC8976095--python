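"""Sequence records, FASTA I/O and the primitive operations shared by every stage.

Sequences are held internally in the RNA alphabet {A, C, G, U}: the sensors act
on transcripts, so DNA inputs are converted (T -> U) on ingestion.  Coordinates
are 0-based, half-open throughout.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

CANONICAL = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")
# IUPAC ambiguity codes resolved (opt-in) to their first canonical base, in the
# conventional A<C<G<U order of the code's member set.
_AMBIGUITY_FIRST = {
    "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A",
}


class AlphabetPolicy(enum.Enum):
    """How non-canonical residues are treated on ingestion."""

    STRICT = "strict"            # reject ambiguity codes
    RESOLVE_FIRST = "resolve"    # map each IUPAC code to its first canonical base


class SequenceError(ValueError):
    """Malformed sequence input (bad residue, duplicate id, bad FASTA record)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named RNA sequence.

    ``residues`` are canonical RNA; ``source_alphabet`` records whether the
    original input was DNA (converted on ingestion) or RNA.
    """

    id: str
    residues: str
    description: str = ""
    source_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in CANONICAL:
                raise SequenceError(
                    f"record {self.id!r}: non-canonical residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class BarcodeGene:
    """One species x marker barcode sequence (e.g. Dalbergia maritima MatK)."""

    species: str
    marker: str
    record: SequenceRecord

    @property
    def sequence(self) -> str:
        return self.record.residues

    def __len__(self) -> int:
        return len(self.record)


def clean_residues(
    raw: str,
    policy: AlphabetPolicy = AlphabetPolicy.STRICT,
    record_id: str = "<anonymous>",
) -> tuple[str, str]:
    """Canonicalize a raw sequence string; returns (rna_residues, source_alphabet)."""
    upper = raw.upper().replace(" ", "")
    source = "DNA" if "T" in upper and "U" not in upper else "RNA"
    out = []
    for pos, ch in enumerate(upper):
        if ch == "T":
            ch = "U"
        if ch in CANONICAL:
            out.append(ch)
        elif ch in _AMBIGUITY_FIRST:
            if policy is AlphabetPolicy.STRICT:
                raise SequenceError(
                    f"record {record_id!r}: ambiguity code {ch!r} at position {pos} "
                    "(use AlphabetPolicy.RESOLVE_FIRST to accept)"
                )
            out.append(_AMBIGUITY_FIRST[ch])
        else:
            raise SequenceError(
                f"record {record_id!r}: invalid character {ch!r} at position {pos}"
            )
    return "".join(out), source


def parse_fasta(
    path: str | Path,
    alphabet_policy: AlphabetPolicy = AlphabetPolicy.STRICT,
) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into canonical RNA records.

    T is mapped to U for DNA inputs; ids and record order are preserved.
    Duplicate ids, empty sequences and (under the strict policy) ambiguity
    codes are rejected with the offending record named.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for index, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise SequenceError(f"{path}: record {index}: missing id in FASTA header")
        if rec.id in seen:
            raise SequenceError(f"{path}: record {index}: duplicate id {rec.id!r}")
        if len(rec.seq) == 0:
            raise SequenceError(f"{path}: record {index} ({rec.id!r}): empty sequence")
        residues, source = clean_residues(str(rec.seq), alphabet_policy, rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, residues, desc, source))
        seen.add(rec.id)
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as RNA FASTA (round-trips losslessly with parse_fasta)."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def reverse_complement(s: SequenceRecord | str) -> SequenceRecord | str:
    """Watson-Crick RNA reverse complement; an involution."""
    if isinstance(s, SequenceRecord):
        return replace(s, residues=reverse_complement(s.residues))
    for pos, ch in enumerate(s):
        if ch not in CANONICAL:
            raise SequenceError(f"non-canonical residue {ch!r} at position {pos}")
    return s.translate(_COMPLEMENT)[::-1]


def hamming_mismatches(a: str, b: str) -> tuple[int, list[int]]:
    """Count mismatching positions between two equal-length strings.

    Returns (count, 0-based positions).
    """
    if len(a) != len(b):
        raise SequenceError(
            f"hamming_mismatches requires equal lengths, got {len(a)} and {len(b)}"
        )
    positions = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    return len(positions), positions


def sliding_windows(
    s: SequenceRecord | str, width: int, step: int = 1
) -> list[tuple[int, str]]:
    """All [start, start+width) windows at the given stride; 0-based starts."""
    if width < 1 or step < 1:
        raise ValueError(f"width and step must be >= 1 (got width={width}, step={step})")
    seq = s.residues if isinstance(s, SequenceRecord) else s
    if width > len(seq):
        warnings.warn(
            f"window width {width} exceeds sequence length {len(seq)}; no windows",
            stacklevel=2,
        )
        return []
    return [(i, seq[i : i + width]) for i in range(0, len(seq) - width + 1, step)]


def transcribe_context(gene: BarcodeGene, region: tuple[int, int]) -> SequenceRecord:
    """Extract a [start, end) slice of a barcode gene as an RNA record."""
    start, end = region
    if not (0 <= start < end <= len(gene)):
        raise SequenceError(
            f"region [{start}, {end}) out of bounds for {gene.species}/{gene.marker} "
            f"of length {len(gene)}"
        )
    return SequenceRecord(
        id=f"{gene.record.id}:{start}-{end}",
        residues=gene.sequence[start:end],
        description=f"{gene.species} {gene.marker} [{start},{end})",
        source_alphabet=gene.record.source_alphabet,
    )


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best if seq else 0


def load_study_set(manifest_path: str | Path) -> list[BarcodeGene]:
    """Load a study set from a CSV manifest (species,marker,fasta_path,record_id).

    FASTA paths are resolved relative to the manifest's directory.  The
    (species, marker) pair must be unique.
    """
    import pandas as pd

    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    required = {"species", "marker", "fasta_path", "record_id"}
    if missing := required - set(table.columns):
        raise SequenceError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    genes: list[BarcodeGene] = []
    seen: set[tuple[str, str]] = set()
    cache: dict[Path, dict[str, SequenceRecord]] = {}
    for _, row in table.iterrows():
        key = (row["species"], row["marker"])
        if key in seen:
            raise SequenceError(f"{manifest_path}: duplicate (species, marker) {key}")
        seen.add(key)
        fasta = (manifest_path.parent / row["fasta_path"]).resolve()
        if fasta not in cache:
            cache[fasta] = {r.id: r for r in parse_fasta(fasta)}
        try:
            rec = cache[fasta][row["record_id"]]
        except KeyError:
            raise SequenceError(
                f"{manifest_path}: record {row['record_id']!r} not found in {fasta}"
            ) from None
        genes.append(BarcodeGene(row["species"], row["marker"], rec))
    return genes
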