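"""Genome and variant I/O plus the single-nucleotide token vocabulary.

Sequences are modelled one chromosome at a time, one haploid sequence per
sample.  Tokenisation is position-wise (no k-mer merging): each nucleotide
maps to one id, so the model retains single-base resolution.  The fixed
mapping A=0, T=1, C=2, G=3, PAD=4, SEP=5, UNK=6 is part of the on-disk
contract and hashed into window containers and checkpoints.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeSequence",
    "VariantSite",
    "TokenVocabulary",
    "VOCAB",
    "read_fasta",
    "write_fasta",
    "read_variants",
    "tokenize",
    "detokenize",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending line."""


@dataclass
class GenomeSequence:
    """One chromosome's nucleotide string for one sample."""

    sample_id: str
    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValueError("chrom_id must be non-empty")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP site; ``pos`` is 0-based (converted from VCF on ingest)."""

    chrom_id: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in {"A", "C", "G", "T"}:
                raise ValueError(f"allele {allele!r} is not a single A/C/G/T base")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")


@dataclass(frozen=True)
class TokenVocabulary:
    """Nucleotide vocabulary: 4 base tokens plus PAD/SEP/UNK specials."""

    base_tokens: dict = field(
        default_factory=lambda: {"A": 0, "T": 1, "C": 2, "G": 3}
    )
    pad_id: int = 4
    sep_id: int = 5
    unk_id: int = 6

    @property
    def size(self) -> int:
        return len(self.base_tokens) + 3

    def content_hash(self) -> str:
        payload = ",".join(
            f"{k}:{v}" for k, v in sorted(self.base_tokens.items())
        ) + f"|{self.pad_id},{self.sep_id},{self.unk_id}"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def id_to_char(self) -> dict:
        table = {v: k for k, v in self.base_tokens.items()}
        table[self.pad_id] = "-"
        table[self.sep_id] = "|"
        table[self.unk_id] = "N"
        return table


VOCAB = TokenVocabulary()


def read_fasta(path, sample_id: str | None = None) -> list[GenomeSequence]:
    """Read a multi-record FASTA into :class:`GenomeSequence` objects.

    One record per chromosome; record order is preserved and sequences are
    uppercased.  ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sample_id is None:
        sample_id = path.stem
    _validate_fasta_lines(path)
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        out.append(
            GenomeSequence(
                sample_id=sample_id, chrom_id=record.id, sequence=str(record.seq)
            )
        )
    return out


def _validate_fasta_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise FastaParseError(
                f"{path}:{lineno}: expected FASTA header '>' but found {stripped[:30]!r}"
            )


def write_fasta(genomes: Iterable[GenomeSequence], path) -> None:
    """Write chromosomes of (one sample's) genome to FASTA."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.chrom_id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variants(path) -> list[VariantSite]:
    """Read biallelic SNPs from a VCF (v4.x) file.

    Multi-allelic records and indels are skipped; the skip count is logged.
    Positions are converted from VCF 1-based to internal 0-based.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sites: list[VariantSite] = []
    skipped = 0
    for v in VCF(str(path)):
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        ref, alt = v.REF.upper(), alts[0].upper()
        if ref not in "ACGT" or alt not in "ACGT":
            skipped += 1
            continue
        sites.append(
            VariantSite(chrom_id=v.CHROM, pos=v.POS - 1, ref_allele=ref, alt_allele=alt)
        )
    if skipped:
        logger.info("read_variants: skipped %d non-biallelic-SNP records", skipped)
    return sites


def tokenize(sequence: str, vocab: TokenVocabulary = VOCAB) -> np.ndarray:
    """Map a nucleotide string to token ids (uint8), one id per base.

    A/C/G/T map to their base ids; any other letter (N, IUPAC ambiguity
    codes, ...) maps to UNK.  Total function: never raises.
    """
    table = np.full(256, vocab.unk_id, dtype=np.uint8)
    for base, idx in vocab.base_tokens.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return table[raw]


def detokenize(ids, vocab: TokenVocabulary = VOCAB) -> str:
    """Inverse of :func:`tokenize` on base tokens; PAD renders as '-', UNK as 'N'."""
    table = vocab.id_to_char()
    ids = np.asarray(ids)
    out = []
    for i in ids.reshape(-1).tolist():
        if i not in table:
            raise ValueError(f"token id {i} outside vocabulary (size {vocab.size})")
        out.append(table[i])
    return "".join(out)
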