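import pysam
import pytest
from hypothesis import HealthCheck, settings

from hybridtx import GeneratorConfig, PipelineConfig, PipelineInputs, run_pipeline
from hybridtx.simulate import build_genome, generate_inputs

import numpy as np

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 1


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic fixture (seed 1)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_inputs(SEED, outdir, GeneratorConfig())


@pytest.fixture(scope="session")
def pipeline_out(dataset, tmp_path_factory):
    """Full pipeline run on the default fixture: (outdir, summary)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    inputs = PipelineInputs.from_dict(dataset.paths())
    summary = run_pipeline(PipelineConfig(), inputs, outdir)
    return outdir, summary


@pytest.fixture(scope="session")
def genome_and_genes():
    """In-memory synthetic genome with its planted gene models."""
    config = GeneratorConfig()
    genome, genes = build_genome(config, np.random.default_rng(SEED))
    return genome, genes


def make_sam(path, records, scaffolds=None):
    """Write a small SAM file; records are (name, flag, scaffold, pos0, cigar)."""
    scaffolds = scaffolds or {"s1": 5_000_000, "s2": 5_000_000}
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": k, "LN": v} for k, v in scaffolds.items()]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for name, flag, scaffold, pos, cigar in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = name
            seg.flag = flag
            if scaffold is not None:
                seg.reference_id = header.get_tid(scaffold)
                seg.reference_start = pos
                seg.cigarstring = cigar
                seg.mapping_quality = 60
            fh.write(seg)
    return path
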