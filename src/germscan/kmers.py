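"""Canonical k-mer spectra of read sets and the modal-copy-number threshold.

High-copy repeats are found by counting canonical k-mers (k = 31) in each
tissue's reads, locating the modal copy number of the spectrum (the peak
contributed by single-copy sequence) and keeping k-mers whose count is at
least ``multiplier`` (default 3) times the mode.  Counting streams the
reads; only the aggregated spectrum is held in memory, as packed uint64
values for k <= 31 and as a plain dictionary for larger k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ParameterError
from . import seqs

_CHUNK_KMERS = 80_000_000  # aggregate partial spectra once this many values accrue


@dataclass
class KmerSpectrum:
    """Counts of canonical k-mers plus the modal copy number and threshold."""

    k: int
    kmers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    modal_copy_number: int | None = None
    abundance_threshold: float | None = None

    def __len__(self) -> int:
        return int(self.kmers.size)

    @property
    def total_instances(self) -> int:
        return int(self.counts.sum())

    def histogram(self) -> dict[int, int]:
        """count value -> number of distinct k-mers with that count."""
        if self.counts.size == 0:
            return {}
        vals, mult = np.unique(self.counts, return_counts=True)
        return {int(v): int(m) for v, m in zip(vals, mult)}

    def count_of(self, kmer: str) -> int:
        v = np.uint64(seqs.kmer_to_value(seqs.canonical_kmer(kmer)))
        i = np.searchsorted(self.kmers, v)
        if i < self.kmers.size and self.kmers[i] == v:
            return int(self.counts[i])
        return 0

    def as_dict(self) -> dict[str, int]:
        """Spectrum as {canonical k-mer string: count} (small spectra only)."""
        return {
            seqs.value_to_kmer(int(v), self.k): int(c)
            for v, c in zip(self.kmers, self.counts)
        }

    # -- persistence ------------------------------------------------------
    def to_tsv(self, path, sidecar=None) -> None:
        with open(path, "w") as fh:
            for v, c in zip(self.kmers, self.counts):
                fh.write(f"{seqs.value_to_kmer(int(v), self.k)}\t{int(c)}\n")
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump(
                    {
                        "k": self.k,
                        "modal_copy_number": self.modal_copy_number,
                        "abundance_threshold": self.abundance_threshold,
                    },
                    fh,
                )

    @classmethod
    def from_tsv(cls, path, k: int | None = None, sidecar=None) -> "KmerSpectrum":
        kmers, counts = [], []
        with open(path) as fh:
            for line in fh:
                km, c = line.split()
                if k is None:
                    k = len(km)
                kmers.append(seqs.kmer_to_value(km))
                counts.append(int(c))
        spec = cls(k=k or 31)
        order = np.argsort(np.asarray(kmers, dtype=np.uint64))
        spec.kmers = np.asarray(kmers, dtype=np.uint64)[order]
        spec.counts = np.asarray(counts, dtype=np.int64)[order]
        if sidecar is not None:
            with open(sidecar) as fh:
                meta = json.load(fh)
            spec.modal_copy_number = meta.get("modal_copy_number")
            spec.abundance_threshold = meta.get("abundance_threshold")
        return spec


def _merge_chunks(chunks: list[tuple[np.ndarray, np.ndarray]]):
    kmers = np.concatenate([c[0] for c in chunks])
    counts = np.concatenate([c[1] for c in chunks])
    order = np.argsort(kmers, kind="stable")
    kmers, counts = kmers[order], counts[order]
    uniq, start = np.unique(kmers, return_index=True)
    summed = np.add.reduceat(counts, start)
    return uniq, summed


def _iter_sequences(reads, batch_size: int = 200_000):
    """Yield sequence-string batches from paths, FASTQ/FASTA files or str iterables."""
    import os

    if isinstance(reads, (str, os.PathLike)):
        reads = [reads]
    reads = list(reads)
    if reads and (isinstance(reads[0], os.PathLike) or (isinstance(reads[0], str) and os.path.exists(reads[0]))):
        for path in reads:
            with open(path) as fh:
                first = fh.read(1)
            if first == ">":
                yield [s for _, s in seqs.read_fasta(path)]
            else:
                yield from seqs.iter_read_batches(path, batch_size)
    else:
        batch: list[str] = []
        for s in reads:
            batch.append(str(s))
            if len(batch) >= batch_size:
                yield batch
                batch = []
        if batch:
            yield batch


def count_kmers(reads, k: int = 31) -> KmerSpectrum:
    """Count canonical k-mers over a read set.

    ``reads`` may be FASTQ/FASTA paths (or a list of them) or an iterable
    of raw sequence strings.  Reads shorter than k contribute nothing and
    non-ACGT bases break k-mer windows.  k must be odd so no k-mer is its
    own reverse complement.
    """
    if k % 2 == 0 or not 3 <= k <= 63:
        raise ParameterError("k must be odd and within [3, 63]")
    if k > 31:
        return _count_kmers_dict(reads, k)
    spectrum = KmerSpectrum(k=k)
    raw: list[np.ndarray] = []
    chunks: list[tuple[np.ndarray, np.ndarray]] = []
    pending = 0
    for batch in _iter_sequences(reads):
        _, _, vals, _ = seqs.batch_kmers(batch, k)
        if vals.size == 0:
            continue
        raw.append(vals)
        pending += vals.size
        if pending > _CHUNK_KMERS:
            uniq, cnt = np.unique(np.concatenate(raw), return_counts=True)
            chunks.append((uniq, cnt.astype(np.int64)))
            raw, pending = [], 0
    if raw:
        uniq, cnt = np.unique(np.concatenate(raw), return_counts=True)
        chunks.append((uniq, cnt.astype(np.int64)))
    if chunks:
        spectrum.kmers, spectrum.counts = _merge_chunks(chunks)
    return spectrum


def _count_kmers_dict(reads, k: int) -> KmerSpectrum:
    # plain dictionary fallback for k > 31 (values no longer fit in uint64)
    table: dict[str, int] = {}
    for batch in _iter_sequences(reads):
        for s in batch:
            s = s.upper()
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if any(b not in "ACGT" for b in w):
                    continue
                table[seqs.canonical_kmer(w)] = table.get(seqs.canonical_kmer(w), 0) + 1
    spec = KmerSpectrum(k=k)
    spec._table = dict(sorted(table.items()))  # type: ignore[attr-defined]
    spec.counts = np.asarray(list(spec._table.values()), dtype=np.int64)  # type: ignore[attr-defined]
    return spec


def modal_copy_number(spectrum: KmerSpectrum, error_peak_min: int = 5) -> int:
    """Count value with the most distinct k-mers among counts >= error_peak_min.

    The low-count error peak of a real spectrum is excluded via
    ``error_peak_min``; ties break toward the larger count.
    """
    hist = spectrum.histogram()
    best = None
    for count, mult in hist.items():
        if count < error_peak_min:
            continue
        if best is None or mult > best[1] or (mult == best[1] and count > best[0]):
            best = (count, mult)
    if best is None:
        raise EstimationError(
            f"no k-mers with count >= {error_peak_min}; cannot locate the modal copy number"
        )
    spectrum.modal_copy_number = int(best[0])
    return spectrum.modal_copy_number


def abundant_kmers(spectrum: KmerSpectrum, multiplier: float = 3.0) -> set[str]:
    """Canonical k-mers with count >= multiplier x modal copy number (inclusive)."""
    if spectrum.modal_copy_number is None:
        modal_copy_number(spectrum)
    threshold = multiplier * spectrum.modal_copy_number
    spectrum.abundance_threshold = threshold
    keep = spectrum.counts >= threshold
    return {
        seqs.value_to_kmer(int(v), spectrum.k) for v in spectrum.kmers[keep]
    }


def abundant_kmer_values(spectrum: KmerSpectrum, multiplier: float = 3.0) -> np.ndarray:
    """Packed-value variant of :func:`abundant_kmers` (large spectra)."""
    if spectrum.modal_copy_number is None:
        modal_copy_number(spectrum)
    threshold = multiplier * spectrum.modal_copy_number
    spectrum.abundance_threshold = threshold
    return spectrum.kmers[spectrum.counts >= threshold]
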