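from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from splicerescue import synthetic
from splicerescue.align import AlignerConfig, first_pass, second_pass
from splicerescue.cli import RunConfig, run_pipeline
from splicerescue.refbuild import build_expanded_genome, build_junction_flanks
from splicerescue.splitcore import half_queries, split_read

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Default synthetic case/control fixture, written once per session."""
    out = tmp_path_factory.mktemp("fixture")
    return synthetic.generate_fixture(out, seed=synthetic.DEFAULT_SEED)


@pytest.fixture(scope="session")
def toy_genome():
    """Small genome + gene models shared by reference-construction tests."""
    return synthetic.make_genome(seed=7)


@pytest.fixture(scope="session")
def het_half_pool(toy_genome):
    """Second-pass half alignments of the Het sample, split at the smallest
    MS of interest, plus everything needed to re-call junctions at other
    parameter values."""
    genome, genes = toy_genome
    het, ko, truth = synthetic.make_case_control_reads(genome, genes, seed=7)
    flanks = build_junction_flanks(genes, genome, truth.read_length)
    expanded = build_expanded_genome(genome, flanks)
    cfg = AlignerConfig()
    _, unmapped = first_pass(het, expanded, cfg)
    halves = []
    for read in unmapped:
        halves.extend(half_queries(split_read(read, 8)))
    half_alignments = second_pass(halves, genome, cfg)
    return {
        "genome": genome,
        "genes": genes,
        "expanded": expanded,
        "flanks": flanks,
        "het": het,
        "ko": ko,
        "truth": truth,
        "unmapped": unmapped,
        "half_alignments": half_alignments,
    }


def default_run_config(fixture_paths, out_dir: Path, **overrides) -> RunConfig:
    base = dict(
        genome_path=fixture_paths["genome"],
        known_genes_path=fixture_paths["known_genes"],
        fastq_a=[fixture_paths["het_fastq"]],
        fastq_b=[fixture_paths["ko_fastq"]],
        out_dir=out_dir,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def default_run(fixture_paths, tmp_path_factory):
    """One comparative pipeline run on the default fixture."""
    out = tmp_path_factory.mktemp("run")
    config = default_run_config(fixture_paths, out, keep_intermediates=True)
    return run_pipeline(config)
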