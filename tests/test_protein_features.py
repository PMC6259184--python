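import numpy as np
import pytest

from pathwaykit import (
    ConfigurationError,
    PathwayGraph,
    aa_composition,
    aggregate_pathway,
    compute_standardization,
    ctd,
    default_alphabets,
    load_alphabets,
    protein_descriptors,
    pseudo_sequence,
    standardize,
)
from pathwaykit.core import PNH_CLASSES
from pathwaykit.protein_features import ACC_ALPHABET, DEFAULT_PROPERTY_GROUPS

from conftest import make_protein


class TestPseudoSequence:
    def test_hydrophobicity_substitution(self):
        hydro = default_alphabets()["hydrophobicity"]
        assert pseudo_sequence("LLL", hydro) == "HHH"
        assert pseudo_sequence("RKE", hydro) == "PPP"
        assert pseudo_sequence("GRC", hydro) == "NPH"

    def test_all_twenty_residues_covered_by_every_property(self):
        for name, alphabet in default_alphabets().items():
            classified = pseudo_sequence("ACDEFGHIKLMNPQRSTVWY", alphabet)
            assert set(classified) <= set(alphabet.classes), name

    def test_unknown_residue_raises_unless_skipped(self):
        hydro = default_alphabets()["hydrophobicity"]
        with pytest.raises(ConfigurationError):
            pseudo_sequence("LXL", hydro)
        assert pseudo_sequence("LXL", hydro, skip_unknown=True) == "HH"

    def test_mapless_alphabet_rejects_substitution(self):
        with pytest.raises(ConfigurationError):
            pseudo_sequence("HEH", ACC_ALPHABET)

    def test_yaml_override(self, tmp_path):
        path = tmp_path / "alpha.yaml"
        path.write_text("custom:\n  A: 'ACDEFGHIK'\n  B: 'LMNPQRSTVWY'\n")
        alphabets = load_alphabets(path)
        assert pseudo_sequence("ALA", alphabets["custom"]) == "ABA"


class TestCTD:
    def test_three_class_worked_example(self):
        got = ctd("PNHPN", PNH_CLASSES)
        expected = [
            40.0, 40.0, 20.0,            # composition P, N, H
            50.0, 25.0, 25.0,            # transitions PN, PH, NH
            20.0, 20.0, 20.0, 80.0, 80.0,        # distribution P
            40.0, 40.0, 40.0, 100.0, 100.0,      # distribution N
            60.0, 60.0, 60.0, 60.0, 60.0,        # distribution H
        ]
        assert got == pytest.approx(expected)
        assert len(got) == 21

    def test_two_class_reports_first_class_only(self):
        got = ctd("HEH", ("H", "E"))
        assert got == pytest.approx(
            [200 / 3, 100.0, 100 / 3, 100 / 3, 100 / 3, 100.0, 100.0]
        )
        assert len(got) == 7

    def test_absent_class_gives_zero_distribution(self):
        got = ctd("PPP", PNH_CLASSES)
        assert got[1] == got[2] == 0.0          # composition N, H
        assert np.all(got[11:21] == 0.0)        # distributions N, H

    def test_single_symbol_string(self):
        got = ctd("P", PNH_CLASSES)
        assert got[0] == 100.0
        assert np.all(got[3:6] == 0.0)          # no transitions at L = 1
        assert np.all(got[6:11] == 100.0)

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ConfigurationError):
            ctd("", PNH_CLASSES)
        with pytest.raises(ConfigurationError):
            ctd("PXN", PNH_CLASSES)


class TestDescriptors:
    def test_aa_composition(self):
        got = aa_composition("AACD")
        assert got.sum() == pytest.approx(100.0)
        by_aa = dict(zip("ACDEFGHIKLMNPQRSTVWY", got))
        assert by_aa["A"] == 50.0 and by_aa["C"] == 25.0 and by_aa["D"] == 25.0

    def test_descriptor_vector_layout(self):
        p = make_protein("p", {0}, seq="LLRK", ss="HEHC", acc="HEHE")
        vec = protein_descriptors(p)
        assert vec.shape == (132,)
        # 4 properties x 21, then accessibility 7, ss 21, AA composition 20
        assert np.isfinite(vec).all()
        assert vec[84:91] == pytest.approx(ctd("HEHE", ("H", "E")))
        assert vec[91:112] == pytest.approx(ctd("HEHC", ("H", "E", "C")))
        assert vec[112:] == pytest.approx(aa_composition("LLRK"))

    def test_default_groups_partition_the_alphabet(self):
        for name, groups in DEFAULT_PROPERTY_GROUPS.items():
            joined = "".join(groups.values())
            assert sorted(joined) == sorted("ACDEFGHIKLMNPQRSTVWY"), name


class TestStandardization:
    def test_zscore_with_population_sd(self):
        m = np.array([[1.0], [3.0]])
        stats = compute_standardization(m)
        assert stats.mean[0] == 2.0 and stats.std[0] == 1.0
        assert standardize(m, stats)[:, 0] == pytest.approx([-1.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        m = np.array([[5.0, 1.0], [5.0, 2.0]])
        out = standardize(m, compute_standardization(m))
        assert np.all(out[:, 0] == 0.0)
        assert out[:, 1] == pytest.approx([-1.0, 1.0])


class TestAggregation:
    def test_mean_and_max_interleaved(self):
        rows = {
            "a": np.full(132, 1.0),
            "b": np.full(132, 3.0),
            "c": np.arange(132, dtype=float),
        }
        g = PathwayGraph("g", ["a", "b", "c"], [("a", "b"), ("b", "c")])
        out = aggregate_pathway(g, rows)
        assert out.shape == (264,)
        for d in range(132):
            vals = [1.0, 3.0, float(d)]
            assert out[2 * d] == pytest.approx(np.mean(vals))
            assert out[2 * d + 1] == pytest.approx(np.max(vals))

    def test_missing_protein_row_raises(self):
        g = PathwayGraph("g", ["a", "b", "c"], [("a", "b")])
        with pytest.raises(ConfigurationError, match="c"):
            aggregate_pathway(g, {"a": np.zeros(132), "b": np.zeros(132)})
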