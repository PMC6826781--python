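"""Shared low-level sequence utilities: 2-bit codecs, canonical k-mers, FASTA/FASTQ io.

All k-mer machinery works on numpy uint64 values (2 bits per base, A=0 C=1
G=2 T=3, most-significant base first) so that spectra over tens of millions
of k-mers stay vectorized.  k must be odd and <= 31 so a k-mer fits in one
word and can never equal its own reverse complement.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes; non-ACGT bases become 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid k-mer windows of a code array.

    Returns (positions, values): start positions of windows containing only
    ACGT codes, and their packed uint64 values.  Windows touching a code >3
    (ambiguous base or record separator) are dropped.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    m = n - k + 1
    c64 = codes.astype(np.uint64)
    vals = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        np.left_shift(vals, two, out=vals)
        np.bitwise_or(vals, c64[j : j + m], out=vals)
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    ok = (bad[k:] - bad[:-k]) == 0
    pos = np.nonzero(ok)[0]
    return pos, vals[pos]


def revcomp_values(vals: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mer values."""
    mask = np.uint64((1 << (2 * k)) - 1)
    x = (vals ^ mask).astype(np.uint64)
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = x.byteswap()
    return x >> np.uint64(64 - 2 * k)


def canonical_values(vals: np.ndarray, k: int) -> np.ndarray:
    """Canonical form (elementwise min of value and reverse complement)."""
    return np.minimum(vals, revcomp_values(vals, k))


def value_to_kmer(val: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append("ACGT"[(int(val) >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def kmer_to_value(kmer: str) -> int:
    v = 0
    for b in kmer:
        v = (v << 2) | int(_CODE[ord(b)])
    return v


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return min(kmer, rc)


# ---------------------------------------------------------------------------
# io helpers


def read_fasta(path) -> list[tuple[str, str]]:
    """[(id, sequence)] from a FASTA file; id is the first header token."""
    with open(path) as fh:
        return [(h.split()[0], s.upper()) for h, s in SimpleFastaParser(fh)]


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input; message names the record index."""


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) records, validating as we go."""
    idx = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(f"malformed FASTQ record {idx}: {exc}") from exc
            title, seq, qual = rec
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"malformed FASTQ record {idx}: sequence/quality length mismatch"
                )
            yield rec
            idx += 1


def iter_read_batches(paths, batch_size: int = 200_000) -> Iterator[list[str]]:
    """Stream read sequences from one or more FASTQ files in fixed-size batches."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    chain = itertools.chain.from_iterable(iter_fastq(p) for p in paths)
    while True:
        batch = [seq for _, seq, _ in itertools.islice(chain, batch_size)]
        if not batch:
            return
        yield batch


def batch_kmers(
    batch: list[str], k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Canonical k-mer values for a batch of reads.

    Returns (read_index, offset, canonical_value, is_forward) for every
    valid window, where is_forward says the window's forward value equals
    its canonical form; reads shorter than k contribute nothing.
    """
    if not batch:
        z = np.empty(0, dtype=np.int64)
        return z, z, np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    # concatenate with a separator code so windows never cross reads
    joined = ("N".join(batch)).encode("ascii")
    codes = _CODE[np.frombuffer(joined, dtype=np.uint8)]
    pos, vals = kmer_values(codes, k)
    starts = np.zeros(len(batch), dtype=np.int64)
    lens = np.fromiter((len(s) for s in batch), dtype=np.int64, count=len(batch))
    starts[1:] = np.cumsum(lens[:-1] + 1)
    ridx = np.searchsorted(starts, pos, side="right") - 1
    offset = pos - starts[ridx]
    canon = canonical_values(vals, k)
    return ridx, offset, canon, vals == canon
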