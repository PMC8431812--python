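import numpy as np
import pytest
from click.testing import CliRunner

from eecfold.dock2d import PatchImage
from eecfold.harness import config as cfgmod
from eecfold.harness import io as hio
from eecfold.harness.cli import main as cli_main
from eecfold.harness.fixtures import (
    FixtureSpec,
    generate_ball_cluster,
    generate_patch_pair,
    generate_sequence,
)
from eecfold.residue_model import UnknownResidueError

PDB_THREE_ATOMS = """\
ATOM      1  N   LEU A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  LEU A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  O   LEU A   1      12.050   8.092  -6.400  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA ASER A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BSER A   1       9.000   9.000   9.000  0.40  0.00           C
END
"""

PDB_HETATM_ONLY = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
END
"""


class TestFasta:
    def test_round_trip(self, tmp_path):
        records = [
            hio.FastaRecord(id="a", seq="LVLVLV"),
            hio.FastaRecord(id="b", seq="GPGATK" * 15),
        ]
        path = tmp_path / "x.fasta"
        hio.write_fasta(records, path)
        assert hio.read_fasta(path) == records

    def test_lowercase_upcased(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">r\nlvlv\n")
        assert hio.read_fasta(path)[0].seq == "LVLV"

    def test_illegal_character_positioned(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">r\nLVXL\n")
        with pytest.raises(UnknownResidueError) as err:
            hio.read_fasta(path)
        assert err.value.position == 2

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">r\nLV\n>r\nLV\n")
        with pytest.raises(ValueError, match="duplicate"):
            hio.read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            hio.read_fasta(path)


class TestPdb:
    def test_three_atom_block(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(PDB_THREE_ATOMS)
        model, seq = hio.read_pdb_atoms(path)
        assert seq == "L"
        assert len(model.atoms) == 3
        # element radii from the fixed table: N, C, O
        assert model.atoms[0].radius == 1.55
        assert model.atoms[1].radius == 1.70
        assert model.atoms[2].radius == 1.52
        assert model.atoms[0].z == 7
        assert all(a.hclass == 1 for a in model.atoms)  # leucine: hydrophobic

    def test_hetatm_only_is_error(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(PDB_HETATM_ONLY)
        with pytest.raises(ValueError, match="no ATOM"):
            hio.read_pdb_atoms(path)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(PDB_ALTLOC)
        model, seq = hio.read_pdb_atoms(path)
        assert seq == "S"
        assert len(model.atoms) == 1
        assert model.atoms[0].center == (0.0, 0.0, 0.0)  # occupancy 0.60 wins


class TestBallModelIO:
    def test_round_trip(self, tmp_path):
        model = generate_ball_cluster(5, seed=3, charged=True)
        path = tmp_path / "m.model"
        hio.write_ball_model(model, path)
        back = hio.read_ball_model(path)
        assert back.class_count == model.class_count
        assert len(back.atoms) == 5
        np.testing.assert_allclose(back.centers, model.centers, atol=1e-6)
        np.testing.assert_allclose(back.radii, model.radii, atol=1e-6)


class TestPatchIO:
    @pytest.mark.parametrize("name", ["p.pgm", "p.csv"])
    def test_round_trip(self, tmp_path, name):
        a, _, _ = generate_patch_pair(seed=1)
        path = tmp_path / name
        hio.write_patch(a, path)
        back = hio.read_patch(path)
        assert np.array_equal(back.grid, a.grid)
        assert back.spacing == a.spacing


class TestConfig:
    def test_load_and_typed_params(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text(
            "# comment\n"
            "predictor.min_strand_len = 4\n"
            "predictor.strand_density_min = 0.6\n"
            "thermo.temperature = 310\n"
            "gibbs.omega = 0.05 -0.05\n"
        )
        cfg = cfgmod.load_config(path)
        pp = cfgmod.predictor_params(cfg)
        assert pp.min_strand_len == 4
        assert pp.strand_density_min == 0.6
        tp = cfgmod.thermo_params(cfg)
        assert tp.temperature == 310.0
        gp = cfgmod.gibbs_params(cfg)
        assert gp.omega == (0.05, -0.05)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("predictor.bogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            cfgmod.predictor_params(cfgmod.load_config(path))

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("not a pair\n")
        with pytest.raises(ValueError, match="key = value"):
            cfgmod.load_config(path)


class TestGenerators:
    def test_planned_sequence_labels(self):
        spec = FixtureSpec(
            plan=(("strand", 6), ("turn_linker", 2), ("strand", 6)), seed=7
        )
        seq, labels = generate_sequence(spec)
        assert len(seq) == 14
        assert labels == "EEEEEETTEEEEEE"

    def test_determinism(self):
        spec = FixtureSpec(plan=(("helix", 8), ("coil", 5)), seed=42)
        assert generate_sequence(spec) == generate_sequence(spec)

    def test_mutation_rate_hamming(self):
        plan = (("strand", 50), ("helix", 50), ("coil", 50), ("strand", 50))
        n = 200
        rate = 0.1
        clean, _ = generate_sequence(FixtureSpec(plan=plan, seed=9))
        noisy, _ = generate_sequence(
            FixtureSpec(plan=plan, seed=9, mutation_rate=rate)
        )
        hamming = sum(a != b for a, b in zip(clean, noisy))
        sigma = (n * rate * (1 - rate)) ** 0.5
        assert abs(hamming - n * rate) <= 3 * sigma

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            FixtureSpec(plan=(("loop", 5),))
        with pytest.raises(ValueError):
            FixtureSpec(plan=(("helix", 0),))
        with pytest.raises(ValueError):
            FixtureSpec(plan=(("helix", 5),), mutation_rate=1.5)

    def test_ball_cluster(self):
        m1 = generate_ball_cluster(1, seed=0)
        assert len(m1.atoms) == 1
        a = generate_ball_cluster(6, seed=1)
        b = generate_ball_cluster(6, seed=1)
        assert a == b
        c = generate_ball_cluster(6, seed=2)
        assert c != a

    def test_patch_pairs_differ_between_seeds(self):
        a1, _, _ = generate_patch_pair(seed=0)
        a2, _, _ = generate_patch_pair(seed=1)
        assert not np.array_equal(a1.grid, a2.grid)


class TestCli:
    def test_classify(self):
        result = CliRunner().invoke(cli_main, ["classify", "LKG"])
        assert result.exit_code == 0
        assert "FULL_HYDROPHOBIC" in result.output
        assert "NEGLIGIBLE" in result.output

    def test_classify_table(self):
        result = CliRunner().invoke(cli_main, ["classify", "--table"])
        assert result.exit_code == 0
        assert result.output.count("\n") == 21

    def test_predict_ss(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">s\nVTVTVTVT\n")
        result = CliRunner().invoke(
            cli_main, ["predict-ss", "--fasta", str(fasta), "--fmt", "fasta"]
        )
        assert result.exit_code == 0
        assert "EEEEEEEE" in result.output

    def test_thermo_ledger(self):
        result = CliRunner().invoke(cli_main, ["thermo"])
        assert result.exit_code == 0
        assert "delta_h_kcal\t2.7000" in result.output

    def test_evaluate_manifest(self, tmp_path):
        fasta = tmp_path / "s.fasta"
        fasta.write_text(">s\nVTVTVGGVTVTV\n")
        ann = tmp_path / "s.ann"
        ann.write_text("EEEEETTEEEEE\n")
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("s.fasta\ts.ann\n")
        result = CliRunner().invoke(
            cli_main, ["evaluate", "--manifest", str(manifest)]
        )
        assert result.exit_code == 0
        assert "E_coverage\t1.0000" in result.output

    def test_dock_cli(self, tmp_path):
        from eecfold.harness.fixtures import generate_patch_pair

        a, b, planted = generate_patch_pair(seed=4)
        pa, pb = tmp_path / "a.pgm", tmp_path / "b.pgm"
        hio.write_patch(a, pa)
        hio.write_patch(b, pb)
        result = CliRunner().invoke(
            cli_main,
            ["dock2d", str(pa), str(pb), "--rotation-step", "90", "--min-hb", "3"],
        )
        assert result.exit_code == 0
        lines = result.output.strip().splitlines()
        top = lines[1].split("\t")
        assert int(top[4]) == planted.score

    def test_gibbs_cli(self, tmp_path):
        model = generate_ball_cluster(2, seed=1)
        path = tmp_path / "m.model"
        hio.write_ball_model(model, path)
        result = CliRunner().invoke(cli_main, ["gibbs", "--model", str(path)])
        assert result.exit_code == 0
        assert "area_total" in result.output

    def test_simulate_sequences(self, tmp_path):
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "sequences", "--out-dir", str(tmp_path), "--count", "3"],
        )
        assert result.exit_code == 0
        assert (tmp_path / "sequences.fasta").exists()
        assert len(hio.read_fasta(tmp_path / "sequences.fasta")) == 3
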