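"""Shared fixtures: small deterministic sequences and a mini pipeline run."""

from __future__ import annotations

import random

import pytest

from germscan import synth
from germscan.pipeline import PipelineConfig, run_pipeline


def random_dna(n: int, seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def mini_scenario(tmp_path_factory):
    """A small two-family scenario (400 kb genomes, 40x reads) on disk.

    One germline-restricted 20 bp family and one shared 30 bp family —
    large enough for every stage to engage, small enough for unit tests.
    """
    workdir = tmp_path_factory.mktemp("mini")
    fams = [
        synth.FamilySpec(
            "restrictedA", synth.make_repeat_unit(20, 0.4, 11), 2600, 0,
            indel_rate=0.01, substitution_rate=1e-4,
            inverted_cassette_prob=0.05, cassette_size=20, n_arrays=1,
        ),
        synth.FamilySpec(
            "sharedA", synth.make_repeat_unit(30, 0.4, 12), 800, 800,
            indel_rate=0.02, substitution_rate=2e-4,
            inverted_cassette_prob=0.05, cassette_size=20, n_arrays=1,
        ),
    ]
    germ, soma, truth = synth.build_genome_pair(fams, 400_000, 2, seed=5)
    gfa = workdir / "germ.fa"
    sfa = workdir / "soma.fa"
    gr = workdir / "germ.fq"
    sr = workdir / "soma.fq"
    from germscan.seqs import write_fasta

    write_fasta(gfa, germ)
    write_fasta(sfa, soma)
    synth.simulate_reads(germ, synth.ReadSimConfig(seed=5), out_path=gr)
    synth.simulate_reads(
        soma, synth.ReadSimConfig(seed=6), out_path=sr, stream_offset=5
    )
    return dict(
        workdir=workdir, families=fams, truth=truth,
        germ_fasta=str(gfa), soma_fasta=str(sfa),
        germ_reads=str(gr), soma_reads=str(sr),
        germ_records=germ, soma_records=soma, coverage=40.0,
    )


@pytest.fixture(scope="session")
def mini_result(mini_scenario):
    """Full pipeline run on the mini scenario."""
    config = PipelineConfig.paper_defaults(
        germline_reads=[mini_scenario["germ_reads"]],
        somatic_reads=[mini_scenario["soma_reads"]],
        scaffolds=mini_scenario["germ_fasta"],
        out_dir=str(mini_scenario["workdir"] / "out"),
        seed=5,
    )
    return run_pipeline(config)
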