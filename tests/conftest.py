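"""Shared fixtures: small gene models and a session-scoped synthetic run."""

from __future__ import annotations

import pandas as pd
import pytest

from cispair.annotation import GeneRecord
from cispair.pipeline import PipelineConfig, run_all
from cispair.simulate import SimConfig, TruthManifest, simulate_cohort, write_cohort


def make_gene(
    gene_id="G1", chrom="chr1", start=1000, end=2000, strand="+",
    biotype="coding", exons=None,
):
    return GeneRecord(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        biotype=biotype, exons=exons or [(start, end)],
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default desk-scale synthetic cohort (fixed seed)."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(default_cohort, out)
    return out


@pytest.fixture(scope="session")
def pipeline_config(cohort_dir):
    return PipelineConfig(
        gtf=str(cohort_dir / "annotation.gtf"),
        chrom_sizes=str(cohort_dir / "chrom.sizes"),
        cohort_index=str(cohort_dir / "cohort_index.tsv"),
        conservation=str(cohort_dir / "conservation.bedgraph"),
        meth_index=str(cohort_dir / "meth_index.tsv"),
        probe_manifest=str(cohort_dir / "probe_manifest.tsv"),
        rci=str(cohort_dir / "rci.tsv"),
        categories={
            "driver_like": str(cohort_dir / "categories" / "driver_like.txt"),
            "housekeeping_like": str(cohort_dir / "categories" / "housekeeping_like.txt"),
        },
        seed=1,
    )


@pytest.fixture(scope="session")
def default_run(pipeline_config, tmp_path_factory):
    """Full pipeline results on the default synthetic cohort."""
    outdir = tmp_path_factory.mktemp("run")
    paths = run_all(pipeline_config, outdir)
    return {
        "paths": paths,
        "outdir": outdir,
        "summaries": pd.read_csv(paths["summaries"], sep="\t"),
        "meth_flags": pd.read_csv(paths["methylation_flags"], sep="\t"),
    }


@pytest.fixture(scope="session")
def default_truth(cohort_dir):
    return TruthManifest.from_json(cohort_dir / "truth.json")
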