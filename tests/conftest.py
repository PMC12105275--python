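import warnings

import pytest

from allelecall.synthetic import CohortConfig, generate_cohort
from allelecall.workflow import InputSet, classify_cohort

TOY_GTF = """\
##description: toy annotation
chr1\ttoy\tgene\t100\t649\t.\t+\t.\tgene_id "GA";
chr1\ttoy\ttranscript\t100\t399\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T1";
chr1\ttoy\texon\t100\t199\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T1"; exon_id "GA:E1";
chr1\ttoy\texon\t300\t399\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T1"; exon_id "GA:E2";
chr1\ttoy\ttranscript\t300\t649\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T2";
chr1\ttoy\texon\t300\t399\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T2"; exon_id "GA:E2";
chr1\ttoy\texon\t500\t649\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T2"; exon_id "GA:E3";
chrX\ttoy\tgene\t100\t299\t.\t+\t.\tgene_id "GX";
chrX\ttoy\ttranscript\t100\t299\t.\t+\t.\tgene_id "GX"; transcript_id "GX.T1";
chrX\ttoy\texon\t100\t299\t.\t+\t.\tgene_id "GX"; transcript_id "GX.T1"; exon_id "GX:E1";
chr1\ttoy\tgene\t2000\t2099\t.\t+\t.\tgene_id "GM";
chr1\ttoy\ttranscript\t2000\t2099\t.\t+\t.\tgene_id "GM"; transcript_id "GM.T1";
chr1\ttoy\texon\t2000\t2099\t.\t+\t.\tgene_id "GM"; transcript_id "GM.T1"; exon_id "GM:E1";
chr5\ttoy\texon\t100\t199\t.\t+\t.\tgene_id "GM"; transcript_id "GM.T1"; exon_id "GM:E2";
"""


@pytest.fixture(scope="session")
def toy_gtf_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


def write_vcf(path, sample_id, records):
    """records: iterable of (chrom, pos, ref, alt, gt) tuples, pre-sorted."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for i in list(range(1, 23)) + ["X"]:
            fh.write(f"##contig=<ID=chr{i}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for chrom, pos, ref, alt, gt in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
    return path


@pytest.fixture(scope="session")
def noise_free_cohort(tmp_path_factory):
    """Small deterministic cohort plus its classification (noise-free)."""
    outdir = tmp_path_factory.mktemp("cohort_nf")
    cfg = CohortConfig(seed=7, n_samples=12, n_genes=30).noise_free()
    bundle = generate_cohort(cfg, outdir)
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # re-ingest must be warning-free
        result = classify_cohort(InputSet.from_bundle(outdir))
    return bundle, result


@pytest.fixture(scope="session")
def noisy_cohort(tmp_path_factory):
    """Cohort with overdispersed counts and copy-number noise."""
    outdir = tmp_path_factory.mktemp("cohort_noisy")
    cfg = CohortConfig(
        seed=11, n_samples=24, n_genes=80, fraction_imprinted=0.25, n_agents=12
    )
    bundle = generate_cohort(cfg, outdir)
    result = classify_cohort(InputSet.from_bundle(outdir))
    return bundle, result
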