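import warnings
from pathlib import Path

import pytest
from pyfaidx import Fasta

from splicemap.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_reference,
    write_cohort,
    write_compendium,
)

warnings.filterwarnings("ignore", message="optimal-cutoff log-rank p is nominal")


def write_fasta(path, contigs: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return Fasta(str(path))


def write_gtf(path, rows):
    """rows: (chrom, start_1based, end_closed, strand, gene_id, tx_id)."""
    with open(path, "w") as fh:
        for chrom, s, e, strand, gid, tid in rows:
            fh.write(
                f"{chrom}\ttest\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";\n'
            )
    return path


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but full synthetic reference bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(seed=11, n_regulated_up=12, n_regulated_down=18,
                           n_reference_genes=50)
    bundle = generate_reference(cfg, outdir)
    return cfg, bundle


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    cfg, bundle = small_bundle
    cohort, manifest = generate_cohort(cfg, bundle.regulated_events)
    return cohort, manifest


@pytest.fixture(scope="session")
def pipeline_inputs(tmp_path_factory, small_bundle, small_cohort):
    cfg, bundle = small_bundle
    cohort, _ = small_cohort
    outdir = tmp_path_factory.mktemp("cohort_files")
    paths = write_cohort(cohort, outdir)
    compendium = write_compendium(cfg, outdir / "compendium.meme")
    return {
        "genome": str(bundle.genome_path),
        "gtf": str(bundle.gtf_path),
        "regulated_events": str(bundle.regulated_table),
        "psi": str(paths["psi"]),
        "expression": str(paths["expression"]),
        "sample_meta": str(paths["sample_meta"]),
        "compendium": str(compendium),
    }
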