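"""27-mer extension, pentatope assembly, reverse translation and outputs."""

import random

import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from neovax.constructs import (
    DEFAULT_CENTRAL_LINKER,
    DEFAULT_MITD,
    DEFAULT_SIGNAL_PEPTIDE,
    DEFAULT_TERMINAL_LINKER,
    ConstructLayout,
    assemble_construct,
    build_vaccine_pair,
    extend_to_27mer,
    reverse_translate,
    write_outputs,
)
from neovax.epitopes import CLASS_I, CLASS_II, mutate_protein

from conftest import make_variant

AA = "ACDEFGHIKLMNPQRSTVWY"


def protein_of(n, seed=0):
    rng = random.Random(seed)
    return "M" + "".join(rng.choice(AA) for _ in range(n - 1))


def epitope_at(pos, protein=None, n=60, aa_alt="W", affinity=None, mhc_class=CLASS_I):
    protein = protein or protein_of(n, seed=pos)
    aa_ref = protein[pos - 1]
    if aa_ref == aa_alt:
        aa_alt = "C"
    v = make_variant(gene=f"g{pos}", protein_pos=pos, aa_ref=aa_ref, aa_alt=aa_alt)
    mutant = mutate_protein(protein, pos, aa_ref, aa_alt)
    return extend_to_27mer(mutant, pos, v, affinity_nm=affinity, mhc_class=mhc_class)


class TestExtendTo27mer:
    def test_interior_mutation_centered(self):
        epi = epitope_at(30, n=60)
        assert len(epi.sequence) == 27
        assert epi.mutation_offset == 14
        assert not epi.shifted
        assert epi.sequence[13] == epi.source_variant.aa_alt

    def test_near_n_terminus_slides(self):
        epi = epitope_at(5, n=60)
        assert len(epi.sequence) == 27
        assert epi.mutation_offset == 5
        assert epi.shifted

    def test_near_c_terminus_slides(self):
        epi = epitope_at(58, n=60)
        assert len(epi.sequence) == 27
        assert epi.mutation_offset == 27 - (60 - 58)
        assert epi.shifted

    def test_short_protein_returned_whole(self):
        epi = epitope_at(10, n=20)
        assert len(epi.sequence) == 20
        assert epi.mutation_offset == 10
        assert epi.shifted

    def test_out_of_range_rejected(self):
        v = make_variant(protein_pos=99)
        with pytest.raises(ValueError):
            extend_to_27mer(protein_of(60), 99, v)

    @settings(max_examples=300, deadline=None)
    @given(n=st.integers(27, 120), p_frac=st.floats(0, 1))
    def test_slide_rule_against_brute_force(self, n, p_frac):
        """The window always has 27 residues, stays inside the protein, covers
        the mutation, and centers it at 14 whenever both flanks allow."""
        p = max(1, min(n, round(1 + p_frac * (n - 1))))
        epi = epitope_at(p, n=n)
        assert len(epi.sequence) == 27
        assert epi.sequence[epi.mutation_offset - 1] == epi.source_variant.aa_alt
        if 14 <= p <= n - 13:
            assert epi.mutation_offset == 14 and not epi.shifted


class TestAssembly:
    def test_five_epitope_pentatope_length_and_layout(self):
        epis = [epitope_at(30 + i, n=80) for i in range(5)]
        construct = assemble_construct(epis, name="penta")
        expected = 26 + 10 + 5 * 27 + 4 * 10 + 10 + 55
        assert len(construct.protein) == expected == 276
        assert construct.protein.startswith(DEFAULT_SIGNAL_PEPTIDE + DEFAULT_TERMINAL_LINKER)
        assert construct.protein.endswith(DEFAULT_TERMINAL_LINKER + DEFAULT_MITD)
        names = [n for n, _, _ in construct.feature_map]
        assert names.count("central_linker") == 4
        assert names.count("terminal_linker") == 2

    def test_single_epitope_length(self):
        layout = ConstructLayout(epitopes_per_construct=1)
        construct = assemble_construct([epitope_at(30)], layout)
        assert len(construct.protein) == 26 + 10 + 27 + 10 + 55 == 128
        assert "central_linker" not in [n for n, _, _ in construct.feature_map]

    def test_feature_map_partitions_protein(self):
        construct = assemble_construct([epitope_at(30 + i) for i in range(5)])
        rebuilt = "".join(
            construct.protein[start - 1 : end] for _, start, end in construct.feature_map
        )
        assert rebuilt == construct.protein
        cursor = 1
        for _, start, end in construct.feature_map:
            assert start == cursor and end >= start
            cursor = end + 1
        assert cursor == len(construct.protein) + 1

    @settings(max_examples=50, deadline=None)
    @given(n_epitopes=st.integers(1, 8))
    def test_closed_form_length(self, n_epitopes):
        layout = ConstructLayout(epitopes_per_construct=n_epitopes)
        epis = [epitope_at(30 + i, n=80) for i in range(n_epitopes)]
        construct = assemble_construct(epis, layout)
        assert len(construct.protein) == layout.protein_length(n_epitopes)

    def test_count_mismatch_warns_or_raises(self):
        epis = [epitope_at(30), epitope_at(31)]
        with pytest.warns(UserWarning, match="expects 5"):
            assemble_construct(epis)
        with pytest.raises(ValueError, match="expects 5"):
            assemble_construct(epis, strict=True)

    def test_zero_epitopes_rejected(self):
        with pytest.raises(ValueError):
            assemble_construct([])


class TestReverseTranslate:
    @pytest.mark.parametrize("protein,cds", [("M", "ATGTGA"), ("W", "TGGTGA")])
    def test_unique_codons(self, protein, cds):
        assert reverse_translate(protein) == cds

    @settings(max_examples=100, deadline=None)
    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    def test_round_trip_standard_code(self, protein):
        cds = reverse_translate(protein)
        assert str(Seq(cds).translate()) == protein + "*"

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            reverse_translate("MX")


class TestVaccinePair:
    def make_pools(self):
        class_i = [epitope_at(30 + i, affinity=100.0 * (5 - i)) for i in range(5)]
        class_ii = [
            epitope_at(40 + i, affinity=50.0 * (i + 1), mhc_class=CLASS_II)
            for i in range(5)
        ]
        return class_i, class_ii

    def test_two_constructs_one_per_class(self):
        c1, c2 = build_vaccine_pair(*self.make_pools())
        assert (c1.mhc_class, c2.mhc_class) == (CLASS_I, CLASS_II)
        assert len(c1.epitopes) == len(c2.epitopes) == 5

    def test_empty_class_pool_rejected(self):
        class_i, _ = self.make_pools()
        with pytest.raises(ValueError, match="class II"):
            build_vaccine_pair(class_i, [])

    def test_epitopes_ordered_strongest_first(self):
        c1, c2 = build_vaccine_pair(*self.make_pools())
        for construct in (c1, c2):
            affinities = [e.affinity_nm for e in construct.epitopes]
            assert affinities == sorted(affinities)

    def test_cds_translates_to_protein(self):
        for construct in build_vaccine_pair(*self.make_pools()):
            assert str(Seq(construct.cds).translate()) == construct.protein + "*"


class TestOutputs:
    @pytest.fixture
    def written(self, tmp_path):
        pair = build_vaccine_pair(
            *TestVaccinePair().make_pools()
        )
        return pair, write_outputs(pair, tmp_path)

    def test_genbank_reparse_matches_feature_map(self, written):
        pair, paths = written
        records = {r.id: r for r in SeqIO.parse(str(paths["genbank"]), "genbank")}
        assert len(records) == 2
        for construct in pair:
            rec = records[construct.name]
            assert str(rec.seq) == construct.protein
            got = [
                (f.qualifiers["label"][0], int(f.location.start) + 1, int(f.location.end))
                for f in rec.features
            ]
            assert got == construct.feature_map

    def test_genbank_feature_count(self, written):
        pair, paths = written
        for rec in SeqIO.parse(str(paths["genbank"]), "genbank"):
            n = 5
            assert len(rec.features) == 2 + 2 + n + (n - 1)  # SP+MITD, 2 terminal, epitopes, central

    def test_report_rows_equal_total_epitopes(self, written):
        import pandas as pd

        pair, paths = written
        report = pd.read_csv(paths["report"], sep="\t")
        assert len(report) == sum(len(c.epitopes) for c in pair)
        assert set(report["construct"]) == {c.name for c in pair}

    def test_fasta_sequences_match(self, written):
        pair, paths = written
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["protein_fasta"]), "fasta")}
        cds = {r.id: str(r.seq) for r in SeqIO.parse(str(paths["cds_fasta"]), "fasta")}
        for c in pair:
            assert proteins[c.name] == c.protein
            assert cds[c.name] == c.cds
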