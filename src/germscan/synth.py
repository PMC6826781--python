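"""Synthetic germline/somatic genome pairs with planted satellite families.

Programmed DNA elimination produces a germline genome that carries
high-copy tandem satellite families absent from the soma, alongside
pericentromeric satellites shared by both tissues.  This module plants
both kinds of family into random backbone chromosomes, simulates shotgun
reads from each genome, and records a ground-truth table so that every
downstream stage (spectrum, assembly, enrichment, clustering, annotation)
can be tested for parameter recovery without external data.

Coordinates are 0-based half-open; orientation is "+"/"-".  All
randomness derives from one integer seed via fixed stream offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .seqs import _CODE, revcomp, write_fasta

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-stage offsets for deriving independent RNG streams from one seed
_STREAM_BACKBONE = 1
_STREAM_FAMILY = 2
_STREAM_PLACE = 3
_STREAM_READS_GERM = 4
_STREAM_READS_SOMA = 5


def _rng(seed: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *offsets])


@dataclass
class FamilySpec:
    """One planted satellite family.

    A family is a short core unit repeated head-to-tail; arrays may be
    disrupted by small junction indels, carry point substitutions, and
    contain cassettes of units duplicated in inverted orientation.
    Germline-restricted families have ``copies_somatic == 0``.
    """

    family_id: str
    unit_seq: str
    copies_germline: int
    copies_somatic: int = 0
    indel_rate: float = 0.0           # per unit junction
    substitution_rate: float = 0.0    # per base
    inverted_cassette_prob: float = 0.0  # per cassette
    cassette_size: int = 20           # units per cassette
    n_arrays: int = 1                 # arrays the copies are split across

    def __post_init__(self) -> None:
        if len(self.unit_seq) < 5:
            raise ParameterError(f"{self.family_id}: unit length must be >= 5 bp")
        if self.copies_germline < 0 or self.copies_somatic < 0:
            raise ParameterError(f"{self.family_id}: copy numbers must be >= 0")
        if self.copies_somatic > self.copies_germline:
            raise ParameterError(
                f"{self.family_id}: somatic copies may not exceed germline copies"
            )
        for name in ("indel_rate", "substitution_rate", "inverted_cassette_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{self.family_id}: {name} must be in [0, 1]")
        if self.cassette_size < 1 or self.n_arrays < 1:
            raise ParameterError(f"{self.family_id}: cassette_size/n_arrays must be >= 1")

    @property
    def restricted(self) -> bool:
        return self.copies_somatic == 0


@dataclass
class ArrayPlacement:
    """One planted array of one family in one genome sequence."""

    family_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    units: list[tuple[int, int, str]]  # per-unit (start, end, strand), genome coords
    cassettes: list[tuple[int, int]]   # inverted-cassette intervals, genome coords

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class SyntheticTruth:
    """Ground truth for a genome pair: placements, realized copies, expected scores."""

    families: list[FamilySpec]
    germline: list[ArrayPlacement] = field(default_factory=list)
    somatic: list[ArrayPlacement] = field(default_factory=list)

    def realized_copies(self, family_id: str) -> tuple[int, int]:
        g = sum(a.n_units for a in self.germline if a.family_id == family_id)
        s = sum(a.n_units for a in self.somatic if a.family_id == family_id)
        return g, s

    def planted_span(self, family_id: str, genome: str = "germline") -> int:
        arrays = self.germline if genome == "germline" else self.somatic
        return sum(a.end - a.start for a in arrays if a.family_id == family_id)

    def expected_score(self, family_id: str, coverage: float, depth_floor: float = 1.0) -> float:
        """Expected log2 enrichment: germline vs somatic standardized coverage.

        The somatic depth is floored at ``depth_floor`` read-depth units,
        matching the floor the enrichment stage applies, so a restricted
        family's expectation is finite and reproducible from this table.
        """
        g, s = self.realized_copies(family_id)
        num = g * coverage
        den = max(s * coverage, depth_floor)
        if num <= 0:
            return float("-inf")
        return math.log2(num / den)

    def to_table(self, coverage: float, depth_floor: float = 1.0):
        import pandas as pd

        rows = []
        for genome, arrays in (("germline", self.germline), ("somatic", self.somatic)):
            for a in arrays:
                g, s = self.realized_copies(a.family_id)
                rows.append(
                    dict(
                        family_id=a.family_id,
                        genome=genome,
                        seq_id=a.seq_id,
                        start=a.start,
                        end=a.end,
                        strand=a.strand,
                        n_units=a.n_units,
                        copies_germline=g,
                        copies_somatic=s,
                        expected_score=self.expected_score(a.family_id, coverage, depth_floor),
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class ReadSimConfig:
    read_length: int = 100
    mean_coverage: float = 40.0
    error_rate: float = 0.001      # substitutions per base; no simulated indels
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ParameterError("mean_coverage must be > 0")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ParameterError("error_rate must be in [0, 0.1]")
        if self.read_length < 1:
            raise ParameterError("read_length must be positive")


# ---------------------------------------------------------------------------
# unit and array construction


def make_repeat_unit(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """A random core unit of exactly ``length`` bases at the given GC content."""
    if not 5 <= length <= 500:
        raise ParameterError(f"unit length {length} outside [5, 500]")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ParameterError("gc_fraction must be in [0, 1]")
    rng = _rng(seed, _STREAM_FAMILY, length)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _ASCII[codes].tobytes().decode("ascii")


def _mutate_unit(unit: str, sub_rate: float, rng: np.random.Generator) -> str:
    if sub_rate <= 0:
        return unit
    n = len(unit)
    hits = np.nonzero(rng.random(n) < sub_rate)[0]
    if hits.size == 0:
        return unit
    chars = list(unit)
    for i in hits:
        chars[i] = "ACGT"[(("ACGT".index(chars[i])) + 1 + rng.integers(3)) % 4]
    return "".join(chars)


def expand_tandem_array(
    spec: FamilySpec, copies: int, seed: int = 0
) -> tuple[str, list[tuple[int, int, str]], list[tuple[int, int]]]:
    """Concatenate ``copies`` mutated unit instances into one array.

    Units are grouped into cassettes of ``spec.cassette_size``; each
    cassette is emitted reverse-complemented with probability
    ``spec.inverted_cassette_prob``.  With probability ``spec.indel_rate``
    a unit junction gains a 1-3 bp insertion or loses 1-3 bp.

    Returns (array sequence, per-unit placements, inverted-cassette
    intervals), coordinates local to the array.
    """
    if copies < 1:
        raise ParameterError("copies must be >= 1")
    rng = _rng(seed, _STREAM_FAMILY, 7)
    pieces: list[str] = []
    units: list[tuple[int, int, str]] = []
    cassettes: list[tuple[int, int]] = []
    pos = 0
    done = 0
    while done < copies:
        csize = min(spec.cassette_size, copies - done)
        inverted = rng.random() < spec.inverted_cassette_prob
        # build the cassette forward first
        cas_pieces: list[str] = []
        cas_units: list[tuple[int, int]] = []
        cpos = 0
        for j in range(csize):
            u = _mutate_unit(spec.unit_seq, spec.substitution_rate, rng)
            if j > 0 and rng.random() < spec.indel_rate:
                d = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion of random bases at the junction
                    ins = _ASCII[rng.integers(0, 4, size=d)].tobytes().decode("ascii")
                    cas_pieces.append(ins)
                    cpos += d
                else:  # deletion clips the head of this unit
                    u = u[d:]
            cas_pieces.append(u)
            cas_units.append((cpos, cpos + len(u)))
            cpos += len(u)
        cas_seq = "".join(cas_pieces)
        if inverted:
            L = len(cas_seq)
            cas_seq = revcomp(cas_seq)
            cas_units = [(L - e, L - s) for s, e in reversed(cas_units)]
            cassettes.append((pos, pos + L))
            strand = "-"
        else:
            strand = "+"
        for s, e in cas_units:
            units.append((pos + s, pos + e, strand))
        pieces.append(cas_seq)
        pos += len(cas_seq)
        done += csize
    return "".join(pieces), units, cassettes


# ---------------------------------------------------------------------------
# genome pair


def _random_backbone(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def build_genome_pair(
    families: list[FamilySpec],
    backbone_length: int = 2_000_000,
    n_sequences: int = 4,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], SyntheticTruth]:
    """Build (germline FASTA records, somatic FASTA records, truth).

    Both genomes share one backbone; shared families are written at the
    same coordinates in both (the somatic array truncated when
    ``copies_somatic < copies_germline``), so coverage ratios are exact.
    Restricted spans revert to backbone in the soma.
    """
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate family_id")
    seq_len = backbone_length // n_sequences
    rng_b = _rng(seed, _STREAM_BACKBONE)
    rng_p = _rng(seed, _STREAM_PLACE)

    # realize every array of every family (germline copy numbers)
    arrays = []  # (family, array_seq, unit placements, cassettes, keep_units_soma)
    for fi, fam in enumerate(families):
        per = [fam.copies_germline // fam.n_arrays] * fam.n_arrays
        for j in range(fam.copies_germline % fam.n_arrays):
            per[j] += 1
        soma_per = [0] * fam.n_arrays
        if fam.copies_somatic:
            frac = fam.copies_somatic / fam.copies_germline
            soma_per = [int(round(c * frac)) for c in per]
        for ai, (c, sc) in enumerate(zip(per, soma_per)):
            if c == 0:
                continue
            seq, units, cassettes = expand_tandem_array(fam, c, seed=seed * 131 + fi * 17 + ai)
            arrays.append((fam, seq, units, cassettes, min(sc, c)))

    total = sum(len(a[1]) for a in arrays)
    if total >= backbone_length:
        raise ParameterError(
            f"planted material ({total} bp) exceeds backbone ({backbone_length} bp)"
        )

    # assign arrays to sequences, largest first, balancing planted load
    order = sorted(range(len(arrays)), key=lambda i: -len(arrays[i][1]))
    load = [0] * n_sequences
    assigned: list[list[int]] = [[] for _ in range(n_sequences)]
    for i in order:
        s = int(np.argmin(load))
        if load[s] + len(arrays[i][1]) >= seq_len:
            raise ParameterError("planted material does not fit across sequences")
        assigned[s].append(i)
        load[s] += len(arrays[i][1])

    seq_ids = [f"chr{c + 1}" for c in range(n_sequences)]
    germ_records: list[tuple[str, str]] = []
    soma_records: list[tuple[str, str]] = []
    truth = SyntheticTruth(families=families)

    for s, sid in enumerate(seq_ids):
        backbone = _random_backbone(seq_len, rng_b)
        germ = backbone.copy()
        soma = backbone.copy()
        items = assigned[s]
        planted = sum(len(arrays[i][1]) for i in items)
        free = seq_len - planted
        gaps = rng_p.multinomial(free, [1.0 / (len(items) + 1)] * (len(items) + 1)) if items else [free]
        pos = 0
        for gi, i in enumerate(items):
            pos += int(gaps[gi])
            fam, seq, units, cassettes, soma_units = arrays[i]
            codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            germ[pos : pos + len(seq)] = codes
            g_units = [(pos + a, pos + b, st) for a, b, st in units]
            g_cas = [(pos + a, pos + b) for a, b in cassettes]
            truth.germline.append(
                ArrayPlacement(fam.family_id, sid, pos, pos + len(seq), "+", g_units, g_cas)
            )
            if soma_units > 0:
                cut = units[soma_units - 1][1]  # end of last kept unit, array coords
                soma[pos : pos + cut] = codes[:cut]
                s_units = [(pos + a, pos + b, st) for a, b, st in units[:soma_units]]
                s_cas = [(pos + a, pos + b) for a, b in cassettes if b <= cut]
                truth.somatic.append(
                    ArrayPlacement(fam.family_id, sid, pos, pos + cut, "+", s_units, s_cas)
                )
            pos += len(seq)
        germ_records.append((sid, _ASCII[germ].tobytes().decode("ascii")))
        soma_records.append((sid, _ASCII[soma].tobytes().decode("ascii")))

    return germ_records, soma_records, truth


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: list[tuple[str, str]],
    config: ReadSimConfig,
    out_path=None,
    stream_offset: int = _STREAM_READS_GERM,
):
    """Simulate uniform shotgun reads (substitution errors only).

    Returns the list of read sequences; when ``out_path`` is given the
    reads are also written as Phred+33 FASTQ with constant quality "I".
    Deterministic for a fixed ``config.seed``.
    """
    if not genome:
        raise ParameterError("genome is empty")
    L = config.read_length
    if any(len(s) < L for _, s in genome):
        raise ParameterError("read_length exceeds the shortest genome sequence")
    rng = _rng(config.seed, stream_offset)
    reads: list[np.ndarray] = []
    for _, seqstr in genome:
        codes = _CODE[np.frombuffer(seqstr.encode("ascii"), dtype=np.uint8)]
        n = len(seqstr)
        if config.paired:
            ins_min = max(L, 1)
            n_frag = int(round(config.mean_coverage * n / (2 * L)))
            ins = np.clip(
                np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_frag)),
                ins_min,
                n,
            ).astype(np.int64)
            starts = (rng.random(n_frag) * (n - ins + 1)).astype(np.int64)
            idx1 = starts[:, None] + np.arange(L)
            r1 = codes[idx1]
            idx2 = (starts + ins)[:, None] - np.arange(L) - 1
            r2 = 3 - codes[idx2]  # reverse complement of the fragment tail
            mat = np.concatenate([r1, r2], axis=0)
        else:
            n_read = int(round(config.mean_coverage * n / L))
            starts = rng.integers(0, n - L + 1, size=n_read)
            mat = codes[starts[:, None] + np.arange(L)]
        if config.error_rate > 0:
            err = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
            mat[err] = (mat[err] + shift) % 4
        reads.append(mat)
    mat = np.concatenate(reads, axis=0)
    seqs = _ASCII[mat]
    read_list = [row.tobytes().decode("ascii") for row in seqs]
    if out_path is not None:
        qual = "I" * L
        with open(out_path, "w") as fh:
            for i, s in enumerate(read_list):
                fh.write(f"@read{i}\n{s}\n+\n{qual}\n")
    return read_list


# ---------------------------------------------------------------------------
# the packaged standard scenario

#: Unit lengths of the six germline-restricted families (bp); they bracket
#: the 13-57 bp core-size range observed for germline satellites.
RESTRICTED_UNITS = (13, 21, 30, 38, 47, 57)
#: Copies chosen so each family's planted span is ~66 kb (>60 kb).
RESTRICTED_COPIES = (5100, 3150, 2200, 1740, 1400, 1160)
#: Shared pericentromeric families: (unit bp, copies in both genomes).
SHARED_FAMILIES = ((25, 2000), (40, 1200), (55, 900))

STANDARD_BACKBONE = 2_000_000
STANDARD_N_SEQUENCES = 4
STANDARD_COVERAGE = 40.0
STANDARD_READ_LENGTH = 100
STANDARD_ERROR_RATE = 0.001


def standard_scenario_families(seed: int = 0) -> list[FamilySpec]:
    """The packaged standard scenario's family roster.

    Rates model young, homogenized satellite arrays: rare point variants
    (1-2e-4/base), occasional unit-junction indels (1-2%/junction) and a
    5% chance per 20-unit cassette of inverted duplication.
    """
    fams: list[FamilySpec] = []
    for i, (p, c) in enumerate(zip(RESTRICTED_UNITS, RESTRICTED_COPIES)):
        unit = make_repeat_unit(p, gc_fraction=0.40, seed=seed * 1009 + i)
        fams.append(
            FamilySpec(
                family_id=f"restricted{i + 1}",
                unit_seq=unit,
                copies_germline=c,
                copies_somatic=0,
                indel_rate=0.01,
                substitution_rate=1e-4,
                inverted_cassette_prob=0.05,
                cassette_size=20,
                n_arrays=2,
            )
        )
    for i, (p, c) in enumerate(SHARED_FAMILIES):
        unit = make_repeat_unit(p, gc_fraction=0.40, seed=seed * 1009 + 100 + i)
        fams.append(
            FamilySpec(
                family_id=f"shared{i + 1}",
                unit_seq=unit,
                copies_germline=c,
                copies_somatic=c,
                indel_rate=0.02,
                substitution_rate=2e-4,
                inverted_cassette_prob=0.05,
                cassette_size=20,
                n_arrays=3,
            )
        )
    return fams


def standard_scenario(seed: int = 0):
    """Build the standard scenario: genomes, truth, and read-sim configs.

    Returns (germline records, somatic records, truth, germ ReadSimConfig,
    soma ReadSimConfig).
    """
    fams = standard_scenario_families(seed)
    germ, soma, truth = build_genome_pair(
        fams,
        backbone_length=STANDARD_BACKBONE,
        n_sequences=STANDARD_N_SEQUENCES,
        seed=seed,
    )
    cfg_g = ReadSimConfig(
        read_length=STANDARD_READ_LENGTH,
        mean_coverage=STANDARD_COVERAGE,
        error_rate=STANDARD_ERROR_RATE,
        paired=True,
        seed=seed,
    )
    cfg_s = ReadSimConfig(
        read_length=STANDARD_READ_LENGTH,
        mean_coverage=STANDARD_COVERAGE,
        error_rate=STANDARD_ERROR_RATE,
        paired=True,
        seed=seed + 1,
    )
    return germ, soma, truth, cfg_g, cfg_s


def write_scenario(out_dir, seed: int = 0) -> dict:
    """Materialize the standard scenario to ``out_dir``; returns file paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    germ, soma, truth, cfg_g, cfg_s = standard_scenario(seed)
    paths = {
        "germline_fasta": os.path.join(out_dir, "germline.fa"),
        "somatic_fasta": os.path.join(out_dir, "somatic.fa"),
        "germline_reads": os.path.join(out_dir, "germline_reads.fq"),
        "somatic_reads": os.path.join(out_dir, "somatic_reads.fq"),
        "truth_table": os.path.join(out_dir, "truth.tsv"),
    }
    write_fasta(paths["germline_fasta"], germ)
    write_fasta(paths["somatic_fasta"], soma)
    simulate_reads(germ, cfg_g, out_path=paths["germline_reads"], stream_offset=_STREAM_READS_GERM)
    simulate_reads(soma, cfg_s, out_path=paths["somatic_reads"], stream_offset=_STREAM_READS_SOMA)
    truth.to_table(cfg_g.mean_coverage).to_csv(paths["truth_table"], sep="\t", index=False)
    return paths
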