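"""Design engine: annealer mechanics, scan tables, clash filtering and the
localized-surface scoring pathway."""
import numpy as np
import pandas as pd
import pytest

from surfcraft import (AnnealSchedule, DesignTask, PatchSpec, PatchScorer,
                       design_mc, design_site_scan, extract_patch,
                       load_rotamer_library, compute_ses_cloud, select_top,
                       ssm_scan)
from surfcraft.design import ScanTable


@pytest.fixture(scope="module")
def small_task(toy_complex, toy_interface):
    """Single-position task over a reduced alphabet (fast)."""
    target, binder = toy_complex
    pos = ("A", 7)
    scorer = PatchScorer(reference=None, patch_residues={pos},
                         objective="similarity", context=binder, density=1.5)
    ref = scorer.patch_cloud(target)
    return DesignTask(scaffold=target, designable=[pos],
                      reference_surface=ref, context=binder, density=1.5,
                      allowed_aas=("ALA", "LYS", "SER", "ASP"),
                      schedule=AnnealSchedule(n_steps=120), seed=11)


class TestRotamerLibrary:
    def test_priors_sum_to_one_and_chi_counts_match(self):
        lib = load_rotamer_library()
        from surfcraft import params
        for res in params.STANDARD_RESIDUES:
            rots = lib[res]
            assert abs(sum(p for _, p in rots) - 1.0) < 1e-6
            assert all(len(c) == params.n_chi()[res] for c, _ in rots)
            assert 1 <= len(rots) <= 9


class TestAnnealSchedule:
    def test_geometric_interpolation(self):
        s = AnnealSchedule(t_start=1.0, t_end=0.01, n_steps=3)
        temps = [s.temperature(k, 3) for k in range(3)]
        assert np.allclose(temps, [1.0, 0.1, 0.01])

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            AnnealSchedule(t_start=0.001, t_end=0.01)


class TestDesignMc:
    def test_empty_designable_returns_input(self, toy_complex, small_task):
        target, binder = toy_complex
        task = DesignTask(scaffold=target, designable=[],
                          reference_surface=small_task.reference_surface,
                          patch_residues={("A", 7)}, context=binder,
                          density=1.5)
        res = design_mc(task)
        assert len(res.trajectory) == 0
        assert np.array_equal(res.final_structure.coords(), target.coords())

    def test_seeded_determinism(self, small_task):
        r1 = design_mc(small_task)
        r2 = design_mc(small_task)
        assert r1.trajectory.equals(r2.trajectory)
        assert r1.best_score == r2.best_score
        assert np.array_equal(r1.best_structure.coords(),
                              r2.best_structure.coords())

    def test_best_score_never_decreases_along_trajectory(self, small_task):
        res = design_mc(small_task)
        acc = res.trajectory[res.trajectory.accepted]["score"]
        assert res.best_score >= acc.max()
        running = acc.cummax()
        assert (running.diff().dropna() >= 0).all()

    def test_native_reference_recovers_native(self, small_task, toy_complex):
        target, _ = toy_complex
        res = design_mc(small_task)
        assert res.best_structure.residue_type("A", 7) == "LYS"
        assert res.best_score > 0.999


class TestSiteScan:
    def test_single_position_equals_phase_one_argmax(self, small_task):
        res = design_site_scan(small_task, top_k=1)
        table = res.scan_table
        row = table.scores.loc["A:7"]
        assert res.best_score == row.max()
        assert res.final_structure.residue_type("A", 7) == row.idxmax()

    def test_scan_table_complete(self, small_task):
        res = design_site_scan(small_task, top_k=2)
        assert set(res.scan_table.scores.columns) >= \
            set(small_task.allowed_aas) - {"GLY"}  # all-clash would drop
        assert res.scan_table.native[("A", 7)] == "LYS"

    def test_bad_top_k_raises(self, small_task):
        with pytest.raises(ValueError):
            design_site_scan(small_task, top_k=0)


class TestSelectTop:
    def _table(self, rows):
        return ScanTable(scores=pd.DataFrame(rows).T, best_chi={},
                         native={})

    def test_k1_is_argmax(self):
        t = self._table({"A:1": {"LEU": 0.9, "VAL": 0.7, "ILE": 0.8}})
        assert select_top(t, 1) == {"A:1": ["LEU"]}

    def test_k_exceeding_candidates_returns_all_in_order(self):
        t = self._table({"A:1": {"LEU": 0.9, "VAL": 0.7, "ILE": 0.8}})
        assert select_top(t, 19) == {"A:1": ["LEU", "ILE", "VAL"]}

    def test_ties_break_alphabetically(self):
        t = self._table({"A:1": {"LEU": 0.9, "ILE": 0.9, "VAL": 0.7}})
        assert select_top(t, 1) == {"A:1": ["ILE"]}

    def test_nan_entries_never_rank(self):
        t = self._table({"A:1": {"LEU": np.nan, "VAL": 0.1}})
        assert select_top(t, 4) == {"A:1": ["VAL"]}

    def test_k_below_one_raises(self):
        with pytest.raises(ValueError):
            select_top(self._table({"A:1": {"LEU": 0.9, "VAL": 0.7}}), 0)


class TestLocalizedScoring:
    def test_localized_patch_matches_full_recomputation(self, toy_complex,
                                                        toy_interface):
        """The region-cropped surface restricted to the patch equals the
        patch extracted from a full-structure computation on the same
        lattice, up to boundary sampling noise."""
        from surfcraft.similarity import shape_similarity
        from surfcraft.structure import merge
        target, binder = toy_complex
        patch = set(toy_interface.positions)
        scorer = PatchScorer(reference=None, patch_residues=patch,
                             objective="similarity", context=binder,
                             density=2.0)
        local = scorer.patch_cloud(target)
        full_cloud = compute_ses_cloud(merge(target, binder), density=2.0,
                                       frame="world")
        full_patch = extract_patch(full_cloud, PatchSpec(residues=patch))
        s = shape_similarity(local, full_patch)
        assert s > 0.99
        assert abs(len(local) - len(full_patch)) < 0.15 * len(full_patch)


class TestSsmScan:
    def test_table_matches_independent_rotamer_loop(self, toy_complex,
                                                    toy_interface):
        """Each table entry equals an independent loop over the residue's
        rotamers that substitutes, clash-filters and calls the
        complementarity scorer directly; the entry is never below the exact
        native-rotamer score."""
        target, binder = toy_complex
        table = ssm_scan(target, binder, positions=[("A", 7)], density=1.5,
                         allowed_aas=("LYS", "ALA", "TRP"))
        from surfcraft.structure import mutate_positions, select_interface
        from surfcraft.design import _candidate_clashes
        b_sel = select_interface(binder, target)
        b_scorer = PatchScorer(reference=None,
                               patch_residues=set(b_sel.positions),
                               objective="complementarity", density=1.5)
        b_cloud = b_scorer.patch_cloud(binder)
        t_scorer = PatchScorer(reference=b_cloud,
                               patch_residues=set(toy_interface.positions),
                               objective="complementarity", density=1.5)
        lib = load_rotamer_library()
        for aa in ("LYS", "ALA", "TRP"):
            best = -np.inf
            for chis, _ in lib[aa]:
                if _candidate_clashes(target, binder, ("A", 7), aa, chis):
                    continue
                trial = mutate_positions(target, {("A", 7): (aa, chis)})
                best = max(best, t_scorer.score(trial))
            entry = table.scores.loc["A:7", aa]
            if np.isfinite(best):
                assert abs(entry - best) < 1e-9, aa
            else:
                assert np.isnan(entry), aa
        # the native rotamer is in the library, so the native residue's
        # entry cannot fall below the unperturbed complex's S_C
        native_sc = t_scorer.score(target)
        assert table.scores.loc["A:7", "LYS"] >= native_sc - 1e-9

    def test_off_interface_position_warns(self, toy_complex):
        target, binder = toy_complex
        with pytest.warns(RuntimeWarning, match="not at the interface"):
            ssm_scan(target, binder, positions=[("A", 2)], density=1.5,
                     allowed_aas=("ALA", "SER"))
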