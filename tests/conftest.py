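import numpy as np
import pytest

from smorfval._seq import Genome, encode
from smorfval.constraint_model import MutationRateTable
from smorfval.synthetic_cohort import SelectionProfile, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def rate_table():
    return MutationRateTable.default()


@pytest.fixture(scope="session")
def uniform_rate_table():
    """All contexts at the same rate: removes context effects from oracles."""
    df = MutationRateTable.default().df.copy()
    df["mu"] = 5.0e-7
    return MutationRateTable(df)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-structure cohort shared across read-only tests."""
    cfg = SimulationConfig(
        genome_length=180_000,
        n_genes=24,
        n_smorfs=60,
        n_array_snvs=800,
        n_gwas_snvs=200,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def neutral_cohort():
    """Genes + smORFs with no planted selection (for calibration checks)."""
    cfg = SimulationConfig(
        genome_length=400_000,
        n_genes=60,
        n_smorfs=150,
        selection_profile=SelectionProfile(
            smorf_constrained_fraction=0.0,
            gene_mis_slope=0.0,
            gene_lof_slope=0.0,
        ),
        fraction_refseq_decoy=0.0,
        fraction_reverse_decoy=0.0,
        fraction_peptide_decoy=0.0,
        fraction_offlist_category=0.0,
        seed=7,
    )
    return simulate_cohort(cfg, with_conservation=False, with_gwas=False)


def make_genome(seq: str, chrom: str = "chrT") -> Genome:
    return Genome({chrom: seq})


@pytest.fixture
def toy_genome():
    """120 bp with a 10-codon ORF (ATG + 8 codons + TAA) planted at 30."""
    rng = np.random.default_rng(5)
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
    orf = "ATG" + "GAA" + "TTT" + "CTG" + "TAT" + "CCA" + "GGC" + "AAA" + "GAC" + "TAA"
    tail = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    return Genome({"chrT": flank + orf + tail})
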