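"""Chromosome-to-window segmentation under the two input modes.

All-sequence mode tiles each chromosome into consecutive non-overlapping
fragments of ``L_in`` tokens (the last fragment right-padded).  SNP-sequence
mode extracts one ``L_in`` window per variant site with ``L_in/2`` flanking
bases on either side, so the variant base always sits at offset ``L_in/2``;
windows clipped at chromosome ends are padded on the clipped side to keep
that offset fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

from .genome_io import VOCAB, GenomeSequence, TokenVocabulary, VariantSite, tokenize

__all__ = ["Mode", "Window", "segment_all", "snp_windows", "window_stream",
           "write_windows", "read_windows", "write_bed"]


class Mode(str, Enum):
    ALL_SEQUENCE = "all"
    SNP_SEQUENCE = "snp"


@dataclass
class Window:
    """A tokenised fragment of fixed length ``L_in`` with padding mask."""

    sample_id: str
    chrom_id: str
    start: int  # 0-based inclusive, on the chromosome
    end: int  # 0-based exclusive
    token_ids: np.ndarray  # uint8 [L_in]
    pad_mask: np.ndarray  # bool [L_in], True = real base
    mode: Mode
    anchor_offset: int | None = None  # SNP mode: offset of the variant base

    def __post_init__(self) -> None:
        self.token_ids = np.asarray(self.token_ids, dtype=np.uint8)
        self.pad_mask = np.asarray(self.pad_mask, dtype=bool)
        if self.token_ids.shape != self.pad_mask.shape:
            raise ValueError("token_ids and pad_mask must have the same length")
        if self.end - self.start > len(self.token_ids):
            raise ValueError("window span exceeds L_in")


def segment_all(
    genome: GenomeSequence, l_in: int, vocab: TokenVocabulary = VOCAB
) -> list[Window]:
    """Tile a chromosome into ceil(length / L_in) non-overlapping windows."""
    if l_in < 2:
        raise ValueError("L_in must be >= 2")
    ids = tokenize(genome.sequence, vocab)
    n = len(ids)
    windows = []
    for start in range(0, n, l_in):
        end = min(start + l_in, n)
        tok = np.full(l_in, vocab.pad_id, dtype=np.uint8)
        tok[: end - start] = ids[start:end]
        mask = np.zeros(l_in, dtype=bool)
        mask[: end - start] = True
        windows.append(
            Window(
                sample_id=genome.sample_id,
                chrom_id=genome.chrom_id,
                start=start,
                end=end,
                token_ids=tok,
                pad_mask=mask,
                mode=Mode.ALL_SEQUENCE,
            )
        )
    return windows


def snp_windows(
    genome: GenomeSequence,
    sites: Sequence[VariantSite],
    l_in: int,
    vocab: TokenVocabulary = VOCAB,
) -> list[Window]:
    """One window per variant site, the variant base fixed at offset L_in/2.

    The window spans ``[pos - L_in/2, pos + L_in/2)`` on the chromosome;
    spans clipped by either chromosome end are PAD-filled on the clipped
    side so the anchor offset is preserved.  Overlapping windows are kept
    (one window per site).
    """
    if l_in % 2 != 0:
        raise ValueError("L_in must be even in SNP mode")
    half = l_in // 2
    ids = tokenize(genome.sequence, vocab)
    n = len(ids)
    windows = []
    for site in sites:
        if site.chrom_id != genome.chrom_id:
            raise ValueError(
                f"site on {site.chrom_id} does not match chromosome {genome.chrom_id}"
            )
        if not (0 <= site.pos < n):
            raise ValueError(
                f"variant at 0-based position {site.pos} outside chromosome "
                f"{genome.chrom_id} of length {n}"
            )
        lo, hi = site.pos - half, site.pos + half
        clip_lo, clip_hi = max(lo, 0), min(hi, n)
        tok = np.full(l_in, vocab.pad_id, dtype=np.uint8)
        mask = np.zeros(l_in, dtype=bool)
        off = clip_lo - lo  # left padding width
        tok[off : off + (clip_hi - clip_lo)] = ids[clip_lo:clip_hi]
        mask[off : off + (clip_hi - clip_lo)] = True
        windows.append(
            Window(
                sample_id=genome.sample_id,
                chrom_id=genome.chrom_id,
                start=clip_lo,
                end=clip_hi,
                token_ids=tok,
                pad_mask=mask,
                mode=Mode.SNP_SEQUENCE,
                anchor_offset=half,
            )
        )
    return windows


def window_stream(
    genomes: Iterable[GenomeSequence],
    l_in: int,
    mode: Mode = Mode.ALL_SEQUENCE,
    sites: Sequence[VariantSite] | None = None,
    vocab: TokenVocabulary = VOCAB,
) -> Iterator[Window]:
    """Lazily yield windows grouped by (sample, chromosome), in input order.

    Within a chromosome, windows are ordered by ascending start (all mode)
    or by the order of the supplied sites (SNP mode).  Deterministic: a
    repeated invocation on the same inputs yields an identical sequence.
    """
    mode = Mode(mode)
    if mode is Mode.SNP_SEQUENCE and not sites:
        raise ValueError("SNP mode requires a non-empty variant site list")
    for genome in genomes:
        if mode is Mode.ALL_SEQUENCE:
            yield from segment_all(genome, l_in, vocab)
        else:
            chrom_sites = [s for s in sites if s.chrom_id == genome.chrom_id]
            yield from snp_windows(genome, chrom_sites, l_in, vocab)


# ---------------------------------------------------------------------------
# persistence


def write_windows(windows: Sequence[Window], path, l_in: int,
                  vocab: TokenVocabulary = VOCAB) -> None:
    """Persist windows to an .npz container (header + packed arrays)."""
    header = {"l_in": l_in, "vocab_hash": vocab.content_hash()}
    np.savez_compressed(
        path,
        header=json.dumps(header),
        sample_ids=np.array([w.sample_id for w in windows]),
        chrom_ids=np.array([w.chrom_id for w in windows]),
        starts=np.array([w.start for w in windows], dtype=np.int64),
        ends=np.array([w.end for w in windows], dtype=np.int64),
        token_ids=np.stack([w.token_ids for w in windows]) if windows else
        np.zeros((0, l_in), dtype=np.uint8),
        pad_masks=np.stack([w.pad_mask for w in windows]) if windows else
        np.zeros((0, l_in), dtype=bool),
        modes=np.array([w.mode.value for w in windows]),
        anchors=np.array(
            [-1 if w.anchor_offset is None else w.anchor_offset for w in windows],
            dtype=np.int64,
        ),
    )


def read_windows(path, vocab: TokenVocabulary = VOCAB) -> list[Window]:
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["header"]))
    if header["vocab_hash"] != vocab.content_hash():
        raise ValueError("window container was written with a different vocabulary")
    out = []
    for i in range(len(data["starts"])):
        anchor = int(data["anchors"][i])
        out.append(
            Window(
                sample_id=str(data["sample_ids"][i]),
                chrom_id=str(data["chrom_ids"][i]),
                start=int(data["starts"][i]),
                end=int(data["ends"][i]),
                token_ids=data["token_ids"][i],
                pad_mask=data["pad_masks"][i],
                mode=Mode(str(data["modes"][i])),
                anchor_offset=None if anchor < 0 else anchor,
            )
        )
    return out


def write_bed(windows: Sequence[Window], path) -> None:
    """Write window coordinates as BED (chrom, start, end, mode) for inspection."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom_id}\t{w.start}\t{w.end}\t{w.mode.value}\n")
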