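import pytest

from neovax import CohortSpec, simulate_cohort
from neovax.epitopes import CandidatePeptide
from neovax.variant_intake import NONSYNONYMOUS, SomaticVariant


def make_variant(
    gene="g1",
    protein_pos=5,
    aa_ref="A",
    aa_alt="R",
    alt_depth=50,
    total_depth=100,
    consequence=NONSYNONYMOUS,
    chrom="1",
    pos=1000,
):
    return SomaticVariant(
        gene=gene, chrom=chrom, pos=pos, aa_ref=aa_ref, aa_alt=aa_alt,
        protein_pos=protein_pos, alt_depth=alt_depth, total_depth=total_depth,
        consequence=consequence,
    )


def make_peptide(sequence, mhc_class="I", gene="g1", start=1, offset=1, **variant_kw):
    """A CandidatePeptide whose source variant is consistent with the sequence."""
    aa_alt = sequence[offset - 1]
    aa_ref = "A" if aa_alt != "A" else "G"
    variant = make_variant(
        gene=gene, protein_pos=start + offset - 1, aa_ref=aa_ref, aa_alt=aa_alt,
        **variant_kw,
    )
    return CandidatePeptide(
        sequence=sequence, start=start, mutation_offset=offset,
        mhc_class=mhc_class, source_variant=variant,
    )


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec(n_genes=30, n_variants=120, seed=42)


@pytest.fixture(scope="session")
def cohort(cohort_spec):
    return simulate_cohort(cohort_spec)
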