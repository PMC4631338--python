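import pytest

from strainprior import SimConfig, simulate_all
from strainprior.formats_io import VariantRecord


def make_snv(chrom="chr1", pos=100, ref="A", alt="G", case="1/1",
             control="0/0", qc=None, **extra_gts):
    """A well-formed SNV record with passing QC unless overridden."""
    site_qc = {
        "depth": 20, "allele_number": 4, "base_quality": 35.0,
        "quality_by_depth": 12.0, "zero_mapq_count": 0,
    }
    if qc:
        site_qc.update(qc)
    alts = alt if isinstance(alt, list) else [alt]
    return VariantRecord(
        chromosome=chrom, position=pos, ref_allele=ref, alt_alleles=alts,
        genotypes={"GK_SLAC": case, "WISTAR_SLAC": control, **extra_gts},
        site_qc=site_qc,
    )


def make_indel(chrom="chr1", pos=100, ref="AT", alt="A", case="1/1",
               control="0/0", depth=12, allele_number=4):
    return VariantRecord(
        chromosome=chrom, position=pos, ref_allele=ref, alt_alleles=[alt],
        genotypes={"GK_SLAC": case, "WISTAR_SLAC": control},
        site_qc={"depth": depth, "allele_number": allele_number},
    )


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """One default-scale synthetic study shared by integration tests."""
    cfg = SimConfig(seed=7)
    outdir = tmp_path_factory.mktemp("sim") / "study"
    paths, truth = simulate_all(cfg, outdir)
    return cfg, paths, truth
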