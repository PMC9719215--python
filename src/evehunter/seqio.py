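"""Sequence records, FASTA I/O and nucleotide/protein primitives.

All coordinates in this package are 0-based half-open on the forward
strand; they are converted to 1-based inclusive only when writing GFF3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

NT_ALPHABET = set("ACGTNRYSWKMBDHV")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

# IUPAC nucleotide complement table (upper case only; input is upper-cased).
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)

# IUPAC ambiguity expansion used by the conservative translator.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Standard genetic code, written out explicitly.
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
CODON_TABLE = _CODE

ALL_FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class SequenceRecord:
    """One FASTA entry.

    ``residues`` are upper case and conform to ``alphabet`` ("nt" or "aa");
    ``id`` carries no whitespace, ``description`` is free text after the id.
    """

    id: str
    residues: str
    alphabet: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        self.residues = self.residues.upper()
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} residue {ch!r} at position {pos} "
                    f"in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def tags(self) -> dict:
        """Parse ``key=value`` tokens from the description (bait/panel tags)."""
        out = {}
        for token in self.description.split():
            if "=" in token:
                k, _, v = token.partition("=")
                out[k] = v
        return out


def parse_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (residues upper-cased).

    An empty file yields an empty list with a warning; an illegal residue
    raises, naming the record and position.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append(
                SequenceRecord(header, "".join(chunks), alphabet=alphabet, description=desc)
            )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ValueError(f"empty FASTA header in {path}")
                header = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(s: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (involution)."""
    bad = set(s.upper()) - NT_ALPHABET
    if bad:
        raise ValueError(f"not a nucleotide sequence (saw {sorted(bad)})")
    return s.upper().translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; ambiguity translates to X unless all resolutions agree."""
    if len(codon) != 3:
        raise ValueError("codon must have length 3")
    if codon in CODON_TABLE:
        return CODON_TABLE[codon]
    sets = [IUPAC.get(b) for b in codon]
    if any(s is None for s in sets):
        raise ValueError(f"illegal base in codon {codon!r}")
    n = len(sets[0]) * len(sets[1]) * len(sets[2])
    if n > 16:  # too ambiguous to enumerate usefully
        return "X"
    aas = {
        CODON_TABLE[a + b + c]
        for a in sets[0]
        for b in sets[1]
        for c in sets[2]
    }
    return aas.pop() if len(aas) == 1 else "X"


def translate(s: str) -> str:
    """Translate a nucleotide string in frame +1, dropping the trailing partial codon."""
    s = s.upper()
    return "".join(translate_codon(s[i : i + 3]) for i in range(0, len(s) - len(s) % 3, 3))


def translate_frames(s: str, frames: Sequence[int] = ALL_FRAMES) -> dict[int, str]:
    """Six-frame conceptual translation.

    Frames +1..+3 read the forward strand with offsets 0..2; frames -1..-3
    read the reverse complement with the same offsets. Stop codons are '*',
    ambiguous codons 'X'.
    """
    s = s.upper()
    bad = set(s) - NT_ALPHABET
    if bad:
        raise ValueError(f"not a nucleotide sequence (saw {sorted(bad)})")
    rc = reverse_complement(s)
    out: dict[int, str] = {}
    for f in frames:
        if f not in ALL_FRAMES:
            raise ValueError(f"bad frame {f}")
        src = s if f > 0 else rc
        out[f] = translate(src[abs(f) - 1 :])
    return out


def frame_to_genome_span(aa_start: int, aa_end: int, frame: int, seq_len: int) -> tuple[int, int]:
    """Map an aa span on a translated frame back to forward-strand nt coordinates."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    return seq_len - off - 3 * aa_end, seq_len - off - 3 * aa_start
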