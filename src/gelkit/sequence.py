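"""Gelatin chain construction from a collagen sequence.

The pipeline is: parse a collagen FASTA record, substitute hydroxyproline
(written ``X``) for prolines in the Y position of the collagen G-X-Y repeat,
digest with trypsin rules (cut C-terminal to K/R unless followed by P), and
assemble a chain of a target length from the resulting peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 standard one-letter amino acid codes plus X for hydroxyproline.
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}

HydroxylationMode = Literal["gxy", "all", "none"]


@dataclass(frozen=True)
class AminoAcidSequence:
    """One-letter residue string over the 21-letter gelatin alphabet.

    Parameters
    ----------
    residues : str
        Uppercase one-letter codes; ``X`` denotes hydroxyproline.
    id : str
        Free-text label (FASTA header word).
    """

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        for i, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"illegal residue symbol {ch!r} at position {i} "
                    f"in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, item) -> str:
        return self.residues[item]

    def __iter__(self):
        return iter(self.residues)


@dataclass(frozen=True)
class PeptideFragment:
    """Contiguous slice of a parent sequence, 0-based end-exclusive."""

    residues: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")
        if self.end - self.start != len(self.residues):
            raise ValueError("fragment span does not match residue count")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DigestResult:
    """Outcome of a simulated proteolytic digest.

    ``cleavage_sites`` holds 0-based indices i meaning "cut after residue i".
    Fragments concatenated in order reproduce the parent exactly.
    """

    parent: AminoAcidSequence
    fragments: tuple[PeptideFragment, ...]
    cleavage_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if list(self.cleavage_sites) != sorted(set(self.cleavage_sites)):
            raise ValueError("cleavage sites must be strictly increasing")
        joined = "".join(f.residues for f in self.fragments)
        if joined != self.parent.residues:
            raise ValueError("fragments do not partition the parent sequence")
        if len(self.parent) > 0 and len(self.fragments) != len(self.cleavage_sites) + 1:
            raise ValueError("fragment count must equal site count + 1")


def parse_fasta(text: str) -> list[AminoAcidSequence]:
    """Parse FASTA text into validated amino-acid sequences.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved. Raises ``ValueError`` on empty input or on a symbol outside
    the 21-letter alphabet (the error names the offending position).
    """
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found in input")
    out = []
    for rec in records:
        residues = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        out.append(AminoAcidSequence(residues=residues, id=rec.id))
    return out


def write_fasta(seqs: Iterable[AminoAcidSequence], width: int = 60) -> str:
    """Render sequences as FASTA text; inverse of :func:`parse_fasta`."""
    handle = StringIO()
    records = [
        SeqRecord(Seq(s.residues), id=s.id or f"seq{i}", description="")
        for i, s in enumerate(seqs)
    ]
    if not records:
        return ""
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(records)
    return handle.getvalue()


def hydroxylate_prolines(
    seq: AminoAcidSequence, mode: HydroxylationMode = "gxy"
) -> AminoAcidSequence:
    """Substitute hydroxyproline (X) for proline.

    ``mode='gxy'`` (default) replaces only prolines in the Y position of a
    greedy G-X-Y triplet scan: at each glycine a triplet is anchored and the
    scan jumps past it, otherwise it advances one residue. ``'all'`` replaces
    every proline, ``'none'`` returns the sequence unchanged. Length is
    always preserved and the operation is idempotent.
    """
    if mode == "none":
        return seq
    res = list(seq.residues)
    if mode == "all":
        res = ["X" if r == "P" else r for r in res]
        return AminoAcidSequence("".join(res), seq.id)
    if mode != "gxy":
        raise ValueError(f"unknown hydroxylation mode {mode!r}")
    i = 0
    n = len(res)
    while i < n:
        if res[i] == "G" and i + 2 < n:
            if res[i + 2] == "P":
                res[i + 2] = "X"
            i += 3
        else:
            i += 1
    return AminoAcidSequence("".join(res), seq.id)


def cleavage_sites(residues: str) -> list[int]:
    """0-based positions after which trypsin cuts.

    Cut C-terminal to K or R, blocked when the next residue is proline (P);
    hydroxyproline (X) does not block. A terminal K/R yields no cut.
    """
    return [
        i
        for i in range(len(residues) - 1)
        if residues[i] in "KR" and residues[i + 1] != "P"
    ]


def trypsin_digest(seq: AminoAcidSequence) -> DigestResult:
    """Simulate a trypsin digest of ``seq``.

    Applies :func:`cleavage_sites` and slices the parent into fragments whose
    in-order concatenation reproduces it exactly.
    """
    if len(seq) == 0:
        raise ValueError("cannot digest an empty sequence")
    sites = cleavage_sites(seq.residues)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    fragments = tuple(
        PeptideFragment(seq.residues[a:b], a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
    )
    return DigestResult(parent=seq, fragments=fragments, cleavage_sites=tuple(sites))


def assemble_chain(
    digest: DigestResult,
    target_length: int,
    policy: str = "ordered",
) -> AminoAcidSequence:
    """Assemble a chain of approximately ``target_length`` residues.

    The default ``'ordered'`` policy concatenates fragments in parent order
    until the cumulative length first reaches ``target_length``; a fragment
    that would overshoot is dropped, so the result ends on a whole-fragment
    boundary with length <= target. The achieved length is logged when it
    differs from the target; the caller reads it off the returned sequence.
    """
    if target_length <= 0:
        raise ValueError("target_length must be positive")
    if target_length > len(digest.parent):
        raise ValueError(
            f"target_length {target_length} exceeds parent length "
            f"{len(digest.parent)}"
        )
    if policy != "ordered":
        raise ValueError(f"unknown assembly policy {policy!r}")
    pieces: list[str] = []
    total = 0
    for frag in digest.fragments:
        if total + len(frag) > target_length:
            break  # keep the last whole-fragment boundary <= target
        pieces.append(frag.residues)
        total += len(frag)
        if total == target_length:
            break
    if total != target_length:
        logger.warning(
            "assembled chain has %d residues (target %d): no fragment "
            "combination reaches the target under policy %r",
            total,
            target_length,
            policy,
        )
    return AminoAcidSequence("".join(pieces), id=f"{digest.parent.id}|assembled")


def load_collagen_alpha1() -> AminoAcidSequence:
    """Packaged human collagen alpha-1(I) chain (1464 residues)."""
    text = (
        resources.files("gelkit")
        .joinpath("data/collagen_alpha1_human.fasta")
        .read_text()
    )
    return parse_fasta(text)[0]
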