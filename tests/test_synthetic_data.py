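import numpy as np
import pytest

from pocketscreen import structure_io
from pocketscreen.compound_prep import dedupe_by_key, druglike_filter
from pocketscreen.pocket_similarity import align_pockets, pair_score_matrix
from pocketscreen.synthetic_data import (
    GeneratorConfig,
    gen_cell_series,
    gen_compound_table,
    gen_polymerization,
    gen_toy_complex,
    perturb_pocket,
)

from conftest import pocket_features


class TestGenToyComplex:
    def test_pocket_count_by_construction(self):
        model = gen_toy_complex(5, 3, seed=1)
        lig = structure_io.list_ligand_instances(model)[0]
        pocket = structure_io.extract_pocket(model, lig)
        assert len(pocket) == 5

    def test_single_residue_pocket_self_pfs(self):
        model = gen_toy_complex(1, 0, seed=12)
        fs = pocket_features(model)
        assert align_pockets(fs, fs).pfs == pytest.approx(-1.0)

    def test_same_seed_identical_coordinates(self):
        a = gen_toy_complex(6, 2, seed=42)
        b = gen_toy_complex(6, 2, seed=42)
        for ra, rb in zip(a.residues, b.residues):
            np.testing.assert_array_equal(ra.heavy_coords(), rb.heavy_coords())

    def test_different_seed_differs(self):
        a = gen_toy_complex(6, 0, seed=1)
        b = gen_toy_complex(6, 0, seed=2)
        assert not np.array_equal(a.residues[0].heavy_coords(), b.residues[0].heavy_coords())

    def test_planted_distances_exact(self):
        distances = [3.0, 4.5, 5.9]
        model = gen_toy_complex(3, 0, seed=7, pocket_distances=distances)
        lig_xyz = model.ligands[0].heavy_coords()
        for res, d in zip(model.residues, distances):
            dmin = np.min(
                np.linalg.norm(
                    res.heavy_coords()[:, None, :] - lig_xyz[None, :, :], axis=-1
                )
            )
            assert dmin == pytest.approx(d, abs=1e-9)

    def test_written_pdb_reparses(self, tmp_path):
        model = gen_toy_complex(5, 2, seed=3)
        path = tmp_path / "toy.pdb"
        structure_io.write_pdb(model, path)
        back = structure_io.parse_structure(path)
        assert len(back.residues) == 7
        assert len(back.ligands) == 1


class TestPerturbPocket:
    def test_identity_perturbation_preserves_pfs(self):
        model = gen_toy_complex(6, 0, seed=5)
        pert, truth = perturb_pocket(model, jitter_sd=0.0, relabel_fraction=0.0, seed=1)
        assert truth["relabeled_residues"] == []
        fs = pocket_features(model)
        fs_p = pocket_features(pert)
        assert align_pockets(fs, fs_p).pfs == pytest.approx(align_pockets(fs, fs).pfs)

    def test_full_relabel_lowers_mean_similarity(self):
        """Paired comparison over 50 seeds: relabeling every residue strictly
        lowers the mean pairwise microenvironment similarity."""
        deltas = []
        for seed in range(50):
            model = gen_toy_complex(6, 0, seed=seed)
            fs = pocket_features(model)
            same, _ = perturb_pocket(model, relabel_fraction=0.0, seed=seed + 1)
            relabeled, _ = perturb_pocket(model, relabel_fraction=1.0, seed=seed + 1)
            t_same = pair_score_matrix(fs, pocket_features(same)).T.mean()
            t_rel = pair_score_matrix(fs, pocket_features(relabeled)).T.mean()
            deltas.append(t_same - t_rel)
        assert np.mean(deltas) > 0
        assert np.sum(np.array(deltas) > 0) >= 45  # strictly lower in almost all runs

    def test_truth_records_relabeled_residues(self):
        model = gen_toy_complex(10, 0, seed=8)
        pert, truth = perturb_pocket(model, relabel_fraction=0.3, seed=2)
        assert len(truth["relabeled_residues"]) == 3
        changed = {
            r.key for r, p in zip(model.residues, pert.residues) if r.res_type != p.res_type
        }
        assert changed == set(map(tuple, truth["relabeled_residues"]))


class TestGenCompoundTable:
    def test_empty_table(self):
        records, truth = gen_compound_table(0, 0.5, 0.0, seed=1)
        assert records == [] and truth["survivor_ids"] == []

    @pytest.mark.parametrize("seed", range(5))
    def test_filter_and_dedupe_ground_truth(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 150))
        records, truth = gen_compound_table(
            n,
            druglike_fraction=float(rng.uniform(0.2, 0.8)),
            dup_fraction=float(rng.uniform(0.0, 0.3)),
            seed=seed,
        )
        survivors = dedupe_by_key(druglike_filter(records))
        assert [r.ligand_id for r in survivors] == truth["survivor_ids"]

    def test_half_druglike(self):
        records, _ = gen_compound_table(100, 0.5, 0.0, seed=2)
        assert len(druglike_filter(records)) == 50

    def test_deterministic(self):
        a, _ = gen_compound_table(30, 0.5, 0.2, seed=9)
        b, _ = gen_compound_table(30, 0.5, 0.2, seed=9)
        assert [(r.ligand_id, r.mw, r.structure_key) for r in a] == [
            (r.ligand_id, r.mw, r.structure_key) for r in b
        ]


class TestGenPolymerization:
    def test_noiseless_truth_recovery(self):
        from pocketscreen.assay_analysis import curve_stats, normalize_polymerization

        curves, truth = gen_polymerization(v_true=2.8, plateau=34.5, noise_sd=0.0, seed=1)
        norm = normalize_polymerization(curves, "TAX")
        st = curve_stats(norm["TEST"])
        assert st.vmax == pytest.approx(truth["vmax"]["TEST"], rel=0.05)
        assert st.mep == pytest.approx(truth["mep"]["TEST"], rel=1e-6)

    def test_planted_fc_recovered_under_noise(self):
        from pocketscreen.assay_analysis import curve_stats, fold_changes, normalize_polymerization

        # plateau chosen so the planted MEP fold change is exactly 1.7
        curves, truth = gen_polymerization(
            v_true=2.8, plateau=1.7 * 20.5, noise_sd=1.0, seed=6
        )
        assert truth["fc_mep"]["TEST"] == pytest.approx(1.7)
        norm = normalize_polymerization(curves, "TAX")
        fc = fold_changes(curve_stats(norm["TEST"]), curve_stats(norm["DMSO"]))
        assert fc.fc_mep == pytest.approx(1.7, abs=0.1)

    def test_plateau_equal_to_control_gives_unit_fc(self):
        curves, truth = gen_polymerization(v_true=1.2, plateau=20.5, noise_sd=0.0, seed=2)
        assert truth["fc_mep"]["TEST"] == pytest.approx(1.0)

    def test_unreachable_vmax_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            gen_polymerization(v_true=0.5, plateau=40.0)


class TestGenCellSeries:
    def test_noiseless_growth_recovery(self):
        from pocketscreen.assay_analysis import growth_ec50

        growth, _, vehicle, truth = gen_cell_series(ec50_true=25.0, noise_sd=0.0, seed=4)
        est = growth_ec50(growth, vehicle)
        assert est.value == pytest.approx(truth["ec50_p"], rel=0.10)

    def test_out_of_range_ec50_marked_not_assigned(self):
        from pocketscreen.assay_analysis import growth_ec50

        growth, _, vehicle, truth = gen_cell_series(
            ec50_true=5000.0, noise_sd=0.0, seed=4
        )
        assert truth["ec50_p"] is None
        assert not growth_ec50(growth, vehicle).assigned

    def test_deterministic(self):
        a = gen_cell_series(noise_sd=2.0, seed=11)
        b = gen_cell_series(noise_sd=2.0, seed=11)
        np.testing.assert_array_equal(a[2][1], b[2][1])


def test_generator_config_serializes(tmp_path):
    cfg = GeneratorConfig(seed=3, params={"n": 10}, ground_truth={"ids": ["a"]})
    text = cfg.to_json()
    assert '"seed": 3' in text and '"ids"' in text
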