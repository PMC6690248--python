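import numpy as np
import pytest

from mirest.fold import HairpinMetrics, extract_hairpin, fold_mfe
from mirest.synthetic import make_synthetic_precursor
from mirest.validate import (ClusterCall, ReferenceInfo, ValidationCriteria,
                             characterize, detect_clusters,
                             detect_fixture_clusters, validate_candidate)


def _metrics(pairs=21, arm="5'", asym=0, in_stem=True):
    return HairpinMetrics(arm=arm, mature_span=(1, 21), star_span=(30, 50),
                          mature_star_pairs=pairs, largest_asymmetry=asym,
                          in_stem=in_stem)


class TestValidateCandidate:
    def test_perfect_hairpin_accepted(self):
        rep = validate_candidate("c", -45.0, _metrics(), 0, True)
        assert rep.accepted and all(rep.flags.values())
        assert not rep.relaxation_used

    def test_weak_mfe_without_reference_rejected(self):
        with pytest.warns(UserWarning):
            rep = validate_candidate("c", -12.0, _metrics(), 0, True)
        assert not rep.mfe_ok and not rep.accepted

    def test_reference_relaxation_accepts_weak_hairpin(self):
        # mirrors the retained -10.60 kcal/mol hairpin whose reference
        # fold is itself weak
        ref = ReferenceInfo("ref", mfe=-9.0)
        rep = validate_candidate("c", -10.6, _metrics(pairs=18), 0, True,
                                 reference=ref)
        assert rep.accepted and rep.relaxation_used

    def test_each_flag_fails_independently(self):
        rep = validate_candidate("c", -45.0, _metrics(pairs=15), 0, True)
        assert rep.flags == {"mfe_ok": True, "pairs_ok": False, "in_stem": True,
                             "mismatch_ok": True, "noncoding_ok": True}
        rep = validate_candidate("c", -45.0, _metrics(), 5, True)
        assert not rep.mismatch_ok and rep.mfe_ok and rep.pairs_ok
        rep = validate_candidate("c", -45.0, _metrics(), 0, False)
        assert not rep.noncoding_ok and rep.mismatch_ok

    def test_large_internal_loop_breaks_in_stem(self):
        rep = validate_candidate("c", -45.0, _metrics(asym=9), 0, True)
        assert not rep.in_stem

    def test_criteria_bounds(self):
        with pytest.raises(ValueError):
            ValidationCriteria(mfe_max=5.0)
        with pytest.raises(ValueError):
            ValidationCriteria(min_pairs=0)

    def test_tightening_never_grows_accepted_set(self, rng):
        """Monotonicity of the screen under stricter thresholds."""
        cands = []
        for k in range(12):
            mfe = float(-5 - 4 * k)
            cands.append(("c%d" % k, mfe, _metrics(pairs=12 + k),
                          int(rng.integers(0, 6))))
        accepted_at = []
        for min_pairs in (14, 16, 18, 20):
            crit = ValidationCriteria(min_pairs=min_pairs,
                                      allow_reference_relaxation=False)
            acc = {c[0] for c in cands
                   if validate_candidate(c[0], c[1], c[2], c[3], True,
                                         criteria=crit).accepted}
            accepted_at.append(acc)
        for tight, loose in zip(accepted_at[1:], accepted_at[:-1]):
            assert tight <= loose
        accepted_at = []
        for mfe_max in (-10.0, -18.0, -25.0, -40.0):
            crit = ValidationCriteria(mfe_max=mfe_max,
                                      allow_reference_relaxation=False)
            acc = {c[0] for c in cands
                   if validate_candidate(c[0], c[1], c[2], c[3], True,
                                         criteria=crit).accepted}
            accepted_at.append(acc)
        for tight, loose in zip(accepted_at[1:], accepted_at[:-1]):
            assert tight <= loose


class TestCharacterize:
    def test_fixture_mature_lengths(self, table1):
        s = characterize(table1)
        assert s["mature_length"]["min"] == 18
        assert s["mature_length"]["max"] == 26
        assert s["mature_length"]["mean_rounded"] == 21

    def test_fixture_precursor_stats_over_distinct_precursors(self, table1):
        s = characterize(table1)
        assert s["n_precursors"] == 45
        assert s["precursor_length"]["min"] == 46
        assert s["precursor_length"]["max"] == 381
        assert s["precursor_length"]["mean_rounded"] == 159

    def test_fixture_mismatch_and_mfe(self, table1):
        s = characterize(table1)
        assert s["mismatches"]["mean_rounded"] == 3
        assert set(s["mismatch_hist"]) <= {0, 1, 2, 3, 4}
        assert s["mfe"]["min"] == pytest.approx(-132.02)
        # the recomputed precursor-level mean; the prose's -40 does not
        # recompute from the printed column (flagged by validate_fixtures)
        assert s["mfe"]["mean"] == pytest.approx(-41.488, abs=0.01)

    def test_single_row(self, table1):
        s = characterize(table1[:1])
        assert s["mature_length"]["min"] == s["mature_length"]["max"] == 21

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            characterize([])


class TestClusters:
    def test_two_nonoverlapping_matures_is_cluster(self):
        calls = detect_clusters({"p1": [(11, 31), (45, 65)]})
        assert calls[0].is_cluster and len(calls[0].mature_spans) == 2

    def test_single_mature_not_cluster(self):
        assert not detect_clusters({"p1": [(11, 31)]})[0].is_cluster

    def test_overlapping_matures_merged_with_note(self):
        (call,) = detect_clusters({"p1": [(11, 31), (20, 40)]})
        assert not call.is_cluster
        assert call.mature_spans == [(11, 40)] and call.notes

    def test_fixture_has_exactly_one_cluster_family(self, table1):
        clusters = [c for c in detect_fixture_clusters(table1) if c.is_cluster]
        assert len(clusters) == 1
        assert clusters[0].precursor_id.startswith("vun-mir4414")

    def test_same_mature_two_families_not_cluster(self, table1):
        # two reference families hit the same EST region: one mature
        ids = [c.precursor_id for c in detect_fixture_clusters(table1)
               if c.is_cluster]
        assert not any("2606" in i or "2609" in i for i in ids)


class TestPlantedConstructs:
    def test_pass_construct_accepted_and_pairs_violator_fails_pairs(self, rng):
        mature = "GGCAUCGUGGAAGCUUCCAGG"  # 21 nt
        for muts, expect_pairs_ok in [(0, True), (6, False)]:
            pre, truth = make_synthetic_precursor(mature, loop_len=8,
                                                  star_mutations=muts, rng=rng)
            st = fold_mfe(pre)
            m = extract_hairpin(st, truth["mature_span"])
            rep = validate_candidate("c", st.energy, m, 0, True)
            assert rep.pairs_ok == expect_pairs_ok
            assert rep.accepted == expect_pairs_ok
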