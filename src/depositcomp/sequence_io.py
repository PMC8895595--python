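"""Protein sequence and tabular I/O.

Sequences are plain FASTA read through Biopython.  Measured compositions are
two-column TSV tables (``channel<TAB>fraction``) as exported from an
amino-acid analyzer run; they are renormalized on read because the analyzer
reports relative content, and the raw column sum is kept as metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 canonical residues.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: Tolerated ambiguity codes: B = Asn/Asp, Z = Gln/Glu, X = unknown,
#: U = selenocysteine.
AMBIGUOUS = "BZXU"
ALPHABET = frozenset(CANONICAL + AMBIGUOUS)


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein sequence.

    The sequence is normalized to uppercase and restricted to the 20 canonical
    one-letter residues plus the tolerated ambiguity codes B, Z, X and U.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)
        for code in AMBIGUOUS:
            n = seq.count(code)
            if n:
                logger.warning(
                    "record %r: %d ambiguity code(s) %r in sequence", self.id, n, code
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateManifest:
    """(description, accession) pairs for a candidate-protein list."""

    entries: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        accs = [a for _, a in self.entries]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accession in manifest")

    @property
    def accessions(self) -> list[str]:
        return [a for _, a in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved and sequences are uppercased.  An empty file is an
    error; so is any character outside the accepted alphabet (the error names
    the record and the 1-based position).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60 columns per sequence line."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqs)


def read_composition_table(path: str | Path, scheme) -> "CompositionVector":
    """Read a measured composition TSV (``channel<TAB>fraction``).

    Channel names must belong to *scheme*'s channel set; fractions are
    renormalized to sum to 1 and the raw sum is recorded on the vector.
    """
    from depositcomp.composition import CompositionVector

    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["channel", "fraction"]:
        raise ValueError(
            f"{path}: expected TSV header 'channel<TAB>fraction', got {list(df.columns)}"
        )
    allowed = list(scheme.channels)
    seen: dict[str, float] = {}
    for _, row in df.iterrows():
        ch = str(row["channel"])
        frac = float(row["fraction"])
        if ch not in allowed:
            raise ValueError(
                f"{path}: unknown channel {ch!r} for scheme {scheme.name!r}; "
                f"allowed: {', '.join(allowed)}"
            )
        if ch in seen:
            raise ValueError(f"{path}: duplicate channel {ch!r}")
        if frac < 0:
            raise ValueError(f"{path}: negative fraction for channel {ch!r}")
        seen[ch] = frac
    raw_sum = sum(seen.values())
    if raw_sum <= 0:
        raise ValueError(f"{path}: fractions sum to zero")
    fractions = {ch: seen.get(ch, 0.0) / raw_sum for ch in allowed}
    return CompositionVector(
        scheme_name=scheme.name, fractions=fractions, raw_sum=raw_sum
    )


def write_composition_table(vector, path: str | Path) -> None:
    """Write a composition vector as a ``channel<TAB>fraction`` TSV."""
    df = pd.DataFrame(
        {"channel": list(vector.fractions), "fraction": list(vector.fractions.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def load_table1_manifest() -> CandidateManifest:
    """Load the packaged candidate manifest of deposit proteins identified in
    the diseased brain (19 entries, UniProt accessions verbatim)."""
    ref = resources.files("depositcomp.data").joinpath("table1_candidates.tsv")
    with ref.open("r") as handle:
        df = pd.read_csv(handle, sep="\t")
    entries = tuple(
        (str(r["description"]), str(r["accession"])) for _, r in df.iterrows()
    )
    return CandidateManifest(entries=entries)
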