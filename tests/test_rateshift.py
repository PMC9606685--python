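"""Rate-shift typing, permutation significance, fixation stages, collections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylowave.constants import AMINO_ACIDS, grantham
from phylowave.rateshift import (
    GroupColumnStats,
    classify_site,
    collect_coevolved,
    conservation_profile,
    divergence_score,
    fixation_stage,
    permutation_test,
    rate_shift_scan,
    RateShiftCall,
    FixationStage,
)
from phylowave.synthetic import (
    PlantedSite,
    SyntheticSpec,
    default_succession_spec,
    generate_msa,
)

from conftest import make_alignment


def _stats(modal, freq, gap=0.0, usable=10):
    return GroupColumnStats(modal, freq, gap, usable)


class TestConservationProfile:
    def test_modal_residue_and_frequency(self, tiny_grouped_alignment):
        profile = conservation_profile(tiny_grouped_alignment)
        s = profile.get("g1", 1)
        assert (s.modal_residue, s.modal_freq) == ("D", 1.0)

    def test_alphabetical_tie_break(self):
        aln = make_alignment(
            {"a": "A", "b": "C", "x": "A", "y": "A"},
            {"a": "g", "b": "g", "x": "o", "y": "o"},
            ["g", "o"],
        )
        s = conservation_profile(aln).get("g", 1)
        assert (s.modal_residue, s.modal_freq) == ("A", 0.5)

    def test_gap_heavy_column_uncallable(self):
        # strictly more than half gaps -> uncallable; exactly half is still fine
        aln = make_alignment(
            {"a": "AA", "b": "-A", "c": "--", "d": "A-", "e": "-A"},
            {k: "g" for k in "abcde"},
            ["g"],
        )
        profile = conservation_profile(aln)
        assert not profile.get("g", 1).callable          # 3/5 gaps
        assert profile.get("g", 2).callable              # 2/5 gaps

    def test_matches_brute_force_tally(self, rng):
        mat = rng.choice(list(AMINO_ACIDS[:6] + "-X"), size=(12, 40))
        rows = {f"s{i:02d}": "".join(r) for i, r in enumerate(mat)}
        labels = {k: ("g1" if i < 6 else "g2") for i, k in enumerate(rows)}
        aln = make_alignment(rows, labels, ["g1", "g2"])
        profile = conservation_profile(aln)
        for g in ("g1", "g2"):
            members = [rows[k] for k in rows if labels[k] == g]
            for col in range(1, 41):
                residues = [m[col - 1] for m in members]
                usable = [r for r in residues if r not in "-X"]
                s = profile.get(g, col)
                assert s.usable == len(usable)
                if usable:
                    best = min(
                        set(usable), key=lambda r: (-usable.count(r), r)
                    )
                    assert s.modal_residue == best
                    assert s.modal_freq == pytest.approx(
                        usable.count(best) / len(usable)
                    )


class TestClassifySite:
    def test_radical_fixed_difference_is_type_ii(self):
        assert grantham("D", "R") >= 60
        t, _ = classify_site(_stats("D", 1.0), _stats("R", 1.0))
        assert t == "II"

    def test_conserved_vs_variable_is_type_i(self):
        t, _ = classify_site(_stats("A", 1.0), _stats("A", 0.25))
        assert t == "I"

    def test_shared_conserved_residue_is_none(self):
        t, _ = classify_site(_stats("A", 1.0), _stats("A", 1.0))
        assert t == "none"

    def test_conservative_fixed_difference_is_mixed(self):
        assert grantham("D", "E") < 60
        t, _ = classify_site(_stats("D", 1.0), _stats("E", 1.0))
        assert t == "I_II"

    def test_intermediate_conservation_with_new_residue_is_mixed(self):
        t, _ = classify_site(_stats("D", 0.95), _stats("R", 0.75))
        assert t == "I_II"

    def test_uncallable_column_flagged(self):
        t, reason = classify_site(
            _stats("D", 1.0), GroupColumnStats("A", 1.0, 0.8, 2)
        )
        assert (t, reason) == ("none", "uncallable")

    def test_symmetric_up_to_side_relabel(self):
        a, b = _stats("A", 0.95), _stats("C", 0.3)
        assert classify_site(a, b)[0] == classify_site(b, a)[0] == "I"


class TestPermutationTest:
    def _two_group(self, col1, col2):
        rows = {}
        labels = {}
        for i, r in enumerate(col1):
            rows[f"a{i:02d}"] = r
            labels[f"a{i:02d}"] = "g1"
        for i, r in enumerate(col2):
            rows[f"b{i:02d}"] = r
            labels[f"b{i:02d}"] = "g2"
        return make_alignment(rows, labels, ["g1", "g2"])

    def test_degenerate_column_p_one(self):
        aln = self._two_group("AAAAA", "AAAAA")
        _, p = permutation_test(aln, 1, "g1", "g2", B=199, seed=0)
        assert p == 1.0

    def test_p_floor(self):
        aln = self._two_group("D" * 20, "R" * 20)
        d, p = permutation_test(aln, 1, "g1", "g2", B=99, seed=0)
        assert d == pytest.approx(2.0)
        assert p >= 1 / 100
        assert p == pytest.approx(1 / 100)

    def test_planted_contrast_significant_across_seeds(self):
        """A fixed D-vs-R contrast with 20 sequences per group reaches
        p <= 0.01 in at least 95% of 100 permutation seeds."""
        aln = self._two_group("D" * 19 + "A", "R" * 19 + "C")
        hits = 0
        for seed in range(100):
            _, p = permutation_test(aln, 1, "g1", "g2", B=999, seed=seed)
            hits += p <= 0.01
        assert hits >= 95

    def test_null_pvalues_super_uniform(self):
        """Across 200 exchangeable null columns, the rejection fraction at
        0.05 stays within 0.05 + 3 standard errors."""
        spec = SyntheticSpec(
            group_order=("g1", "g2"),
            sizes=(("g1", 15), ("g2", 15)),
            length=200,
            gap_rate=0.0,
            seed=77,
        )
        aln, _ = generate_msa(spec)
        rng = np.random.default_rng(101)
        rejections = 0
        for col in range(1, 201):
            _, p = permutation_test(aln, col, "g1", "g2", B=199, rng=rng)
            rejections += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / 200)
        assert rejections / 200 <= 0.05 + 3 * se

    def test_divergence_score_definition(self):
        g1 = np.array([3, 3, 3, 0])  # D D D A
        g2 = np.array([1, 1, 3, 3])  # C C D D (modal C by tie-break? no: tie 2-2 -> C)
        d = divergence_score(g1, g2)
        # modal(g1)=D(freq in g2 = 0.5); modal(g2)=C (freq in g1 = 0)
        assert d == pytest.approx((1 - 0.0) + (1 - 0.5))


class TestRateShiftScan:
    def test_bh_adjustment_bounds(self, tiny_grouped_alignment):
        calls = rate_shift_scan(tiny_grouped_alignment, "g1", "g2", B=99, seed=1)
        for c in calls:
            if c.p is not None:
                assert 0 < c.p <= 1
                assert c.q is not None and c.q >= c.p - 1e-12

    def test_planted_type_ii_called(self):
        site = PlantedSite(column=3, kind="typeII",
                           modal=(("g1", "D"), ("g2", "R")), conservation=1.0)
        spec = SyntheticSpec(
            group_order=("g1", "g2"), sizes=(("g1", 20), ("g2", 20)),
            length=30, planted_sites=(site,), gap_rate=0.0, seed=5,
        )
        aln, _ = generate_msa(spec)
        calls = {c.column: c for c in rate_shift_scan(aln, "g1", "g2", seed=6)}
        assert calls[3].type == "II"
        assert calls[3].q is not None and calls[3].q <= 0.05


class TestFixationStage:
    def _succession(self, cols_by_group):
        """cols_by_group: dict group -> list of per-column strings (len n)."""
        rows, labels = {}, {}
        order = list(cols_by_group)
        for g, seq_rows in cols_by_group.items():
            for i, r in enumerate(seq_rows):
                sid = f"{g}_{i}"
                rows[sid] = r
                labels[sid] = g
        return make_alignment(rows, labels, order)

    def test_family_wide_conservation_maps_to_outgroup(self):
        aln = self._succession({
            "og": ["D", "D"], "g1": ["D", "D"], "g2": ["D", "D"],
        })
        st_ = fixation_stage(aln, 1)
        assert (st_.stage, st_.residue) == ("og", "D")

    def test_fixed_from_second_group(self):
        aln = self._succession({
            "og": ["A", "C"], "g1": ["D", "D"], "g2": ["D", "D"],
        })
        assert fixation_stage(aln, 1).stage == "g1"

    def test_unfixed_when_last_group_variable(self):
        aln = self._succession({
            "og": ["D", "D"], "g1": ["D", "D"], "g2": ["A", "C"],
        })
        assert fixation_stage(aln, 1).stage == "unfixed"

    def test_planted_stages_recovered_exactly(self):
        spec = default_succession_spec(123)
        aln, truth = generate_msa(spec)
        profile = conservation_profile(aln)
        for col, site in truth.sites.items():
            assert fixation_stage(aln, col, profile=profile).stage == site.stage

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(0, 10**6))
    def test_monotone_in_conservation_threshold(self, seed):
        """Raising c_hi never moves a fixation stage earlier."""
        spec = default_succession_spec(seed % 1000, length=20, n_per_stage=1)
        aln, _ = generate_msa(spec)
        order = ["unfixed"] + list(reversed(aln.group_order))
        rank = {g: i for i, g in enumerate(order)}
        col = int(np.random.default_rng(seed).integers(1, aln.length + 1))
        lo = fixation_stage(aln, col, c_hi=0.7)
        hi = fixation_stage(aln, col, c_hi=0.95)
        # later-or-equal stage (or unfixed) when the bar is raised
        assert rank[hi.stage] <= rank[lo.stage] or hi.stage == "unfixed"


class TestCollectCoevolved:
    def _calls(self, cols):
        return [RateShiftCall(c, "II", 1.8, 0.001, 0.004) for c in cols]

    def _stages(self, cols, stage):
        return {c: FixationStage(c, stage, "D") for c in cols}

    def test_single_stage_without_network_is_one_collection(self):
        cols = [3, 7, 9]
        out = collect_coevolved(self._calls(cols), self._stages(cols, "mh"))
        assert len(out) == 1
        assert out[0].columns == (3, 7, 9)

    def test_two_stages_split(self):
        calls = self._calls([1, 2, 3, 4])
        stages = {**self._stages([1, 2], "ma"), **self._stages([3, 4], "mh")}
        out = collect_coevolved(calls, stages, stage_order=["ma", "mh"])
        assert len(out) == 2
        assert [c.stage for c in out] == ["ma", "mh"]

    def test_spatial_split_recovers_planted_clusters(self):
        from phylowave.structmap import neighbor_network
        from phylowave.synthetic import StructureSpec, generate_structures

        model_a, _, colmap, truth = generate_structures(StructureSpec(), seed=2)
        sites = sorted(colmap.mapping)
        net = neighbor_network(model_a, colmap, sites, cutoff=10.0)
        out = collect_coevolved(
            self._calls(sites), self._stages(sites, "mh"), network=net
        )
        got = sorted(c.columns for c in out)
        planted: dict[int, list[int]] = {}
        for col, cid in truth.structure_clusters.items():
            planted.setdefault(cid, []).append(col)
        assert got == sorted(tuple(sorted(v)) for v in planted.values())

    def test_non_significant_sites_excluded(self):
        calls = [RateShiftCall(1, "II", 1.8, 0.001, 0.004),
                 RateShiftCall(2, "none", 0.2, 0.8, 0.9),
                 RateShiftCall(3, "I", 1.2, 0.2, 0.4)]
        out = collect_coevolved(calls, self._stages([1, 2, 3], "ma"))
        assert out[0].columns == (1,)
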