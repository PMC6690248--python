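import pytest

from mirest.pipeline import parse_printed_duplex
from mirest.sequence_io import reverse_complement
from mirest.targets import (categorize_function, evaluate_duplex, filter_targets,
                            render_duplex, scan_target_sites,
                            summarize_categories)

MIR413 = "UUAGUUUCUCUUGUUCUGCUU"          # vun-mir413 mature, RNA
TC18010_SITE = "AAGCAGAACAAGAGAAACUAA"    # printed 21-nt target site


class TestScan:
    def test_exact_complement_found_with_full_coverage(self):
        site = reverse_complement(MIR413)
        tr = "A" * 40 + site + "A" * 40
        spans = scan_target_sites(MIR413, tr)
        assert spans == [(41, 61)]

    def test_incompatible_transcript_empty(self):
        assert scan_target_sites("GCGCGCGCGCGCGCGCGCGCG", "A" * 200) == []

    def test_transcript_shorter_than_mature_empty(self):
        assert scan_target_sites(MIR413, "ACGU") == []

    def test_three_mismatches_within_budget_reported(self):
        site = list(reverse_complement(MIR413))
        # break pairing at miRNA positions 15, 17, 19 (outside both seeds)
        for mpos in (15, 17, 19):
            t = len(MIR413) - mpos
            site[t] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[t]]
        tr = "C" * 30 + "".join(site) + "C" * 30
        spans = scan_target_sites(MIR413, tr)
        assert (31, 51) in spans  # coverage 18/21 >= 0.75, penalty 3.0

    def test_exhaustive_window_agreement(self):
        # every reported window must beat the coverage rule; every skipped
        # in-bounds window must fail coverage or penalty
        mature = "GGAUCCAAGG"  # short toy for an exhaustive check
        tr = "CCUUGGAUCCAAAAACCUUGGAUCA"
        spans = set(scan_target_sites(mature, tr, min_coverage=0.75))
        m = len(mature)
        for i in range(len(tr) - m + 1):
            window = tr[i:i + m]
            rev = window[::-1]
            paired = gu = 0
            for a, b in zip(mature, rev):
                if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
                    paired += 1
                elif (a, b) in {("G", "U"), ("U", "G")}:
                    paired += 1
                    gu += 1
            ok = (paired / m >= 0.75
                  and (m - paired) * 1.0 + gu * 0.5 <= 3.0)
            if (i + 1, i + m) in spans:
                assert ok
            elif ok:
                # must have been merged into an overlapping better window
                assert any(s <= i + m and i + 1 <= e for s, e in spans)


class TestDuplex:
    def test_printed_all_paired_duplex(self):
        dx = evaluate_duplex(MIR413, TC18010_SITE)
        assert dx.n_paired == 21
        assert dx.seed_2_7 and dx.seed_8_13 and dx.supplementary_ok

    def test_position_3_flip_breaks_first_seed_only(self):
        site = list(TC18010_SITE)
        t = len(MIR413) - 3
        site[t] = "C"  # opposite miRNA position 3 (A): no longer pairs
        dx = evaluate_duplex(MIR413, "".join(site))
        assert not dx.seed_2_7 and dx.seed_8_13

    def test_gc_rich_perfect_duplex_clears_energy_rule(self):
        mature = "GCGGCCGCAUGGCCGGCGCCG"
        dx = evaluate_duplex(mature, reverse_complement(mature))
        assert dx.n_paired == 21
        assert dx.hybrid_energy <= -20.0

    def test_gu_counts_paired_but_not_in_seed(self):
        mature = "AGGGGGGGGGGGGGGGGGGGA"
        site = list(reverse_complement(mature))
        site[-2] = "U"  # G:U opposite miRNA position 2
        dx = evaluate_duplex(mature, "".join(site))
        assert dx.pair_string[1] == "."
        assert not dx.seed_2_7 and dx.n_paired == 21

    def test_zero_length_site_rejected(self):
        with pytest.raises(ValueError):
            evaluate_duplex(MIR413, "")

    def test_render_symbols(self):
        dx = evaluate_duplex(MIR413, TC18010_SITE)
        text = render_duplex(dx)
        assert ":" * 21 in text and TC18010_SITE in text


class TestFilter:
    def test_energy_and_seed_rules(self):
        good = evaluate_duplex(MIR413, TC18010_SITE)
        assert len(filter_targets([("f", "t", good)])) == 1
        weak = evaluate_duplex("AUAUAUAUAUAUAUAU",
                               reverse_complement("AUAUAUAUAUAUAUAU"))
        assert weak.hybrid_energy > -20.0
        assert filter_targets([("f", "t", weak)]) == []

    def test_seed_requirement_toggle(self):
        site = list(TC18010_SITE)
        for mpos in (3, 10):
            t = len(MIR413) - mpos
            site[t] = "C"
        broken = evaluate_duplex(MIR413, "".join(site))
        assert not broken.seed_2_7 and not broken.seed_8_13
        assert filter_targets([("f", "t", broken)]) == []
        assert len(filter_targets([("f", "t", broken)], require_seed=False)) == 1


class TestCategorize:
    @pytest.mark.parametrize("desc,cat", [
        ("Pectin methylesterase", "Metabolism"),
        ("Heat shock protein", "Stress related"),
        ("Predicted protein", "Hypothetical protein"),
        ("SNF1 related protein kinase", "Signal transduction"),
        ("MYB", "Transcription factor"),
        ("Auxin influx transport protein", "Transporter"),
    ])
    def test_keyword_rules(self, desc, cat):
        assert categorize_function(desc) == cat

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            categorize_function("")


class TestSummaries:
    def test_fixture_counts(self, table2):
        s = summarize_categories(table2)
        assert s["total"] == 138
        assert s["counts"]["Metabolism"] == 37
        assert s["percent"]["Metabolism"] == 27

    def test_permutation_invariant_and_sum_conserving(self, table2):
        import random
        shuffled = table2[:]
        random.Random(5).shuffle(shuffled)
        a, b = summarize_categories(table2), summarize_categories(shuffled)
        assert a["counts"] == b["counts"]
        assert sum(a["counts"].values()) == a["total"]

    def test_single_call(self):
        s = summarize_categories(["Metabolism"])
        assert s["percent"] == {"Metabolism": 100}


class TestPrintedDuplexParity:
    def test_all_colon_rows_fully_paired(self, table1, table2):
        """Every printed alignment that is an unbroken colon run must
        evaluate to a fully paired duplex of the printed length."""
        checked = 0
        for row in table2:
            parsed = parse_printed_duplex(row.duplex_text)
            if parsed is None:
                continue
            mirna, sym, site, _ = parsed
            if set(sym) != {":"} or len(sym) != len(mirna):
                continue
            dx = evaluate_duplex(mirna, site)
            assert dx.n_paired == len(mirna), row.target_acc
            checked += 1
        assert checked >= 10
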