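"""Domain types, delimited I/O, and integrity of the packaged tables."""

import numpy as np
import pytest

from chemoqsar import (
    LabeledTable,
    ParseError,
    ValidationError,
    load_fixture,
    read_report,
    read_table,
    write_report,
    write_table,
)
from chemoqsar.core_data import fixture_notes
from chemoqsar.ligand_rules import RuleReport, ThresholdRule


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTable:
    def test_minimal_two_row_file(self, tmp_path):
        p = _write(tmp_path, (
            "serial_id,name,label,q-\n"
            "1,alpha,attractant,-310\n"
            "2,beta,non_attractant,-250\n"
        ))
        t = read_table(p)
        assert len(t) == 2
        assert t.descriptor_names == ("q-",)
        assert t.records[0].descriptors["q-"] == -310

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = _write(tmp_path, "serial_id\tname\tlabel\tq-\n1\ta\tattractant\t-300\n2\tb\tnon_attractant\t-260\n")
        assert len(read_table(p)) == 2

    def test_unicode_minus_and_paper_exponent(self, tmp_path):
        p = _write(tmp_path, (
            "serial_id,name,label,k_d,q-\n"
            "14,L-Aspartate,attractant,6.E−08,−300\n"
        ))
        rec = read_table(p).records[0]
        assert rec.k_d == pytest.approx(6e-8)
        assert rec.descriptors["q-"] == -300

    def test_nonpositive_kd_rejected(self, tmp_path):
        p = _write(tmp_path, "serial_id,name,label,k_d\n1,a,attractant,0\n")
        with pytest.raises(ValidationError, match="k_d"):
            read_table(p)

    def test_duplicate_serial_ids_rejected(self, tmp_path):
        p = _write(tmp_path, (
            "serial_id,name,label\n1,a,attractant\n1,b,non_attractant\n"
        ))
        with pytest.raises(ValidationError, match="duplicate"):
            read_table(p)

    def test_unknown_label_rejected(self, tmp_path):
        p = _write(tmp_path, "serial_id,name,label\n1,a,agonist\n")
        with pytest.raises(ValidationError, match="agonist"):
            read_table(p)

    def test_non_numeric_descriptor_cell_names_row_and_column(self, tmp_path):
        p = _write(tmp_path, (
            "serial_id,name,label,q-\n7,a,attractant,oops\n"
        ))
        with pytest.raises(ParseError, match=r"'oops'.*row 7.*'q-'"):
            read_table(p)

    def test_unknown_columns_preserved_as_annotations(self, tmp_path):
        p = _write(tmp_path, (
            "serial_id,name,label,q-,vendor\n1,a,attractant,-300,acme\n"
        ))
        t = read_table(p)
        assert t.records[0].annotations["vendor"] == "acme"
        assert t.descriptor_names == ("q-",)

    def test_r_distance_requires_two_carboxyls(self, tmp_path):
        p = _write(tmp_path, (
            "serial_id,name,label,n_carboxyl,r_distance\n1,a,attractant,1,3.0\n"
        ))
        with pytest.raises(ValidationError, match="carboxyl"):
            read_table(p)


class TestFixtures:
    def test_table4_shape_and_classes(self, table4):
        assert len(table4) == 17
        assert table4.n_attractant == 13
        assert table4.n_non_attractant == 4
        assert sum(r.k_d is not None for r in table4.records) == 13

    def test_table4_l_aspartate_row(self, table4):
        rec = {r.serial_id: r for r in table4.records}[14]
        assert rec.k_d == pytest.approx(6e-8)
        assert rec.r_distance == pytest.approx(2.950)
        assert rec.n_carbon == 2 and rec.n_nh2 == 1

    def test_table4_transcription(self, table4):
        # literal transcription of the printed analog table
        printed = {
            14: ("L-Aspartate", 6e-8, 2, 1, 2.950),
            35: ("DL-alpha-Methylaspartate", 5e-7, 2, 1, 2.958),
            36: ("DL-beta-Methylaspartate", 3e-4, 2, 1, 2.991),
            44: ("Oxaloacetate", None, 2, 0, 3.002),
            37: ("N-Methyl-DL-aspartate", 1e-3, 2, 0, 3.006),
            13: ("D-Aspartate", 1e-5, 2, 1, 3.084),
            33: ("L-Malate", 6e-4, 2, 0, 3.151),
            27: ("DL-threo-beta-Hydroxyaspartate", 1e-4, 2, 1, 3.218),
            53: ("L-Glutamate", 5e-6, 3, 1, 3.269),
            2: ("N-Acetyl-L-aspartate", 1e-3, 2, 0, 3.282),
            22: ("Fumarate", 3e-4, 2, 0, 3.764),
            42: ("2-Methylsuccinate", 5e-3, 2, 0, 3.803),
            52: ("Succinate", 2e-4, 2, 0, 3.820),
            26: ("DL-erythro-beta-Hydroxyaspartate", 5e-4, 2, 1, 3.861),
            38: ("DL-alpha-Methylglutamate", None, 3, 1, 4.444),
            31: ("alpha-Ketoglutarate", None, 3, 0, 5.063),
            5: ("L-alpha-Aminoadipate", None, 4, 1, 6.358),
        }
        assert {r.serial_id for r in table4.records} == set(printed)
        for r in table4.records:
            name, kd, ncarbon, nnh2, rdist = printed[r.serial_id]
            assert r.name == name
            if kd is None:
                assert r.k_d is None and r.label == "non_attractant"
            else:
                assert r.k_d == pytest.approx(kd) and r.label == "attractant"
            assert r.n_carbon == ncarbon
            assert r.n_nh2 == nnh2
            assert r.r_distance == pytest.approx(rdist)
            assert r.n_carboxyl == 2

    def test_table1_spot_values_and_invariants(self, table1):
        assert table1.get("E", "E_aq") == pytest.approx(0.99)
        assert table1.get("E_H", "q-") == pytest.approx(-0.76)
        assert table1.get("V_CPK", "A_CPK") == pytest.approx(1.00)
        assert np.allclose(table1.rho, table1.rho.T)
        assert np.allclose(np.diag(table1.rho), 1.0)
        assert np.all(np.abs(table1.rho) <= 1.0)
        assert len(table1.names) == 20

    def test_table1_transcription_checksum(self, table1):
        # lower triangle exactly as printed, row by row
        tri = {
            "E": [1.00],
            "E_aq": [0.99, 1.00],
            "E_sol": [0.56, 0.64, 1.00],
            "M_W": [-0.77, -0.81, -0.73, 1.00],
            "E_H": [0.48, 0.43, -0.01, -0.06, 1.00],
            "E_L": [0.68, 0.68, 0.43, -0.47, 0.46, 1.00],
            "E_H-E_L": [-0.26, -0.29, -0.26, 0.33, 0.22, -0.61, 1.00],
            "D": [-0.14, -0.17, -0.54, 0.41, 0.23, -0.13, 0.18, 1.00],
            "A_CPK": [-0.62, -0.66, -0.63, 0.95, 0.11, -0.29, 0.34, 0.39, 1.00],
            "PSA": [-0.70, -0.75, -0.86, 0.82, -0.16, -0.48, 0.25, 0.42, 0.71, 1.00],
            "V_CPK": [-0.62, -0.66, -0.63, 0.95, 0.11, -0.30, 0.34, 0.39, 1.00, 0.70, 1.00],
            "O_CPK": [-0.58, -0.62, -0.61, 0.92, 0.11, -0.25, 0.31, 0.34, 0.98, 0.71, 0.97, 1.00],
            "AA": [-0.50, -0.54, -0.55, 0.88, 0.22, -0.23, 0.40, 0.37, 0.97, 0.61, 0.97, 0.95, 1.00],
            "PA": [-0.69, -0.74, -0.81, 0.87, -0.15, -0.50, 0.28, 0.49, 0.80, 0.83, 0.80, 0.77, 0.71, 1.00],
            "q-": [-0.49, -0.46, -0.04, 0.16, -0.76, -0.54, 0.02, -0.25, 0.00, 0.17, 0.01, -0.03, -0.07, 0.19, 1.00],
            "APA": [-0.66, -0.71, -0.79, 0.81, -0.19, -0.55, 0.34, 0.49, 0.73, 0.80, 0.73, 0.69, 0.66, 0.97, 0.28, 1.00],
            "q_ion-": [-0.23, -0.21, 0.04, 0.14, -0.27, -0.17, 0.16, -0.09, 0.18, 0.12, 0.17, 0.15, 0.19, 0.10, 0.19, 0.16, 1.00],
            "q+": [-0.59, -0.60, -0.49, 0.42, -0.28, -0.84, 0.50, 0.13, 0.25, 0.47, 0.25, 0.21, 0.19, 0.41, 0.47, 0.45, -0.05, 1.00],
            "LogP": [0.12, 0.19, 0.74, -0.42, -0.19, 0.05, 0.03, -0.62, -0.36, -0.65, -0.36, -0.40, -0.32, -0.53, 0.28, -0.48, 0.32, -0.18, 1.00],
            "P": [-0.62, -0.66, -0.63, 0.95, 0.12, -0.32, 0.39, 0.39, 0.99, 0.70, 1.00, 0.96, 0.97, 0.79, 0.02, 0.73, 0.17, 0.27, -0.34, 1.00],
        }
        assert list(table1.names) == list(tri)
        for i, a in enumerate(table1.names):
            for j in range(i + 1):
                assert table1.rho[i, j] == pytest.approx(tri[a][j], abs=1e-12), (a, table1.names[j])

    def test_table2_q_minus_row(self, table2):
        q = table2["q-"]
        assert (q.attractant_mean, q.attractant_sd, q.attractant_n) == (-300, 31, 38)
        assert (q.non_attractant_mean, q.non_attractant_sd, q.non_attractant_n) == (-269, 36, 15)
        assert (q.p_printed, q.d_printed) == (0.003, 0.96)
        assert len(table2) == 7

    def test_table3_ids_and_dicarboxyl_count(self):
        t3 = load_fixture("table3_misclassified")
        assert [m.serial_id for m in t3] == [4, 5, 8, 22, 24, 27, 33, 36, 38, 42, 52]
        assert sum(m.n_carboxyl == 2 for m in t3) == 8

    def test_unknown_fixture_name(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            load_fixture("table9")

    def test_fixture_notes_record_known_discrepancies(self):
        notes = fixture_notes()
        assert any("Succinate" in v or "succinate" in k for k, v in notes.items())
        assert any("oxaloacetate" in k.lower() for k in notes)


class TestRoundTrips:
    def test_read_write_read_identity_on_table4(self, table4, tmp_path):
        p = tmp_path / "t4.csv"
        write_table(table4, p)
        again = read_table(p)
        assert len(again) == len(table4)
        for a, b in zip(table4.records, again.records):
            assert (a.serial_id, a.name, a.label) == (b.serial_id, b.name, b.label)
            assert a.k_d == pytest.approx(b.k_d) if a.k_d else b.k_d is None
            assert a.r_distance == pytest.approx(b.r_distance)
            assert (a.n_carboxyl, a.n_carbon, a.n_nh2) == (b.n_carboxyl, b.n_carbon, b.n_nh2)

    def test_rule_report_json_round_trip(self, tmp_path):
        rep = RuleReport(
            rule=ThresholdRule("q-", -280.0, "below_is_attractant"),
            tp=30, fp=3, tn=12, fn=8, accuracy=42 / 53,
            misclassified=[4, 5, 8], subgroup_accuracies={"other": (33, 36)},
        )
        p = tmp_path / "rep.json"
        write_report(rep, p, format="json")
        back = read_report(p)
        assert isinstance(back, RuleReport)
        assert (back.tp, back.fp, back.tn, back.fn) == (30, 3, 12, 8)
        assert back.accuracy == rep.accuracy
        assert back.misclassified == [4, 5, 8]
        assert back.rule.threshold == -280.0

    def test_search_report_delimited_count_preserved(self, tmp_path, default_synthetic_table):
        import pandas as pd

        from chemoqsar import run_search

        rep = run_search(
            default_synthetic_table, ["q-", "D", "E_sol"],
            k_folds=5, repeats=2, base_seed=0,
        )
        p = tmp_path / "search.csv"
        write_report(rep, p, format="csv")
        assert len(pd.read_csv(p)) == 7  # 2^3 - 1 subsets

    def test_empty_report_is_valid(self, tmp_path):
        p = tmp_path / "empty.json"
        write_report([], p, format="json")
        assert read_report(p) == []
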