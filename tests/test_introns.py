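import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicedyn.events import enumerate_events
from splicedyn.introns import (
    SpliceSiteModel,
    acceptor_window,
    all_constitutive_introns,
    bps_matrix,
    compare_feature_distributions,
    donor_window,
    extract_introns,
    gc_content,
    relative_position,
    score_bps,
    score_splice_site,
    train_splice_model,
    IntronFeatureRecord,
)
from splicedyn.io import GeneModel, TranscriptModel
from splicedyn.simulate import simulate_intron_features

from oracles import exact_mannwhitney_p


def _ri_gene(gene_id="g", strand="+"):
    """Four-exon gene: RI event between exons 1 and 2, two shared introns."""
    spliced = [(0, 100), (200, 300), (500, 600), (800, 900)]
    retained = [(0, 100), (200, 600), (800, 900)]
    return GeneModel(
        gene_id,
        [
            TranscriptModel(f"{gene_id}.ret", gene_id, "s1", strand, retained),
            TranscriptModel(f"{gene_id}.spl", gene_id, "s1", strand, spliced),
        ],
    )


class TestExtraction:
    def test_ri_gene_yields_one_alt_and_two_cons_introns(self):
        gene = _ri_gene()
        events = enumerate_events(gene)
        assert [e.event_type for e in events] == ["RI"]
        labels = {events[0].event_id: "over"}
        out = extract_introns([gene], events, labels)
        cats = sorted(iv.category for iv in out)
        assert cats == ["alt_over", "cons_over", "cons_over"]
        alt = next(iv for iv in out if iv.category == "alt_over")
        assert (alt.start, alt.end) == (300, 500)

    def test_normal_label_propagates_to_constitutive_set(self):
        gene = _ri_gene()
        events = enumerate_events(gene)
        out = extract_introns([gene], events, {events[0].event_id: "normal"})
        assert {iv.category for iv in out} == {"alt_normal", "cons_normal"}

    def test_intron_absent_from_one_isoform_but_not_ri_is_excluded(self):
        # exon-skipping gene: the variable-region introns are neither
        # retained-intron alternatives nor constitutive
        inclusion = [(0, 100), (200, 300), (400, 500)]
        skipping = [(0, 100), (400, 500)]
        gene = GeneModel("g", [
            TranscriptModel("g.i", "g", "s1", "+", inclusion),
            TranscriptModel("g.s", "g", "s1", "+", skipping),
        ])
        events = enumerate_events(gene)
        out = extract_introns([gene], events, {})
        assert out == []

    def test_unlabelled_genes_contribute_nothing(self):
        gene = _ri_gene()
        events = enumerate_events(gene)
        assert extract_introns([gene], events, {}) == []

    def test_matches_per_isoform_intersection_oracle(self):
        rng = np.random.default_rng(13)
        from oracles import random_gene_structures

        for _ in range(50):
            structs = random_gene_structures(rng)
            gene = GeneModel("g", [
                TranscriptModel(f"t{i}", "g", "s1", "+", ex)
                for i, ex in enumerate(structs)
            ])
            events = enumerate_events(gene)
            cons = {(iv.start, iv.end)
                    for iv in all_constitutive_introns([gene], events)}
            # oracle: literal per-isoform intersection minus event junctions
            inter = None
            for ex in structs:
                introns = {(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)}
                inter = introns if inter is None else inter & introns
            from splicedyn.events import form_junctions

            banned = set()
            for ev in events:
                banned |= form_junctions(ev)
            assert cons == (inter or set()) - banned


class TestScalarFeatures:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5), ("GGCC", 1.0), ("ANGC", 2 / 3), ("AT", 0.0),
    ])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_gc_content_rejects_all_n(self):
        with pytest.raises(ValueError):
            gc_content("NNN")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gc_plus_at_is_one(self, seq):
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert gc_content(seq) + at == pytest.approx(1.0)

    def test_relative_position_examples(self):
        plus = GeneModel("g", [TranscriptModel("t", "g", "s1", "+", [(0, 40), (100, 1000)])])
        assert relative_position(100, 150, plus) == pytest.approx(0.1)
        assert relative_position(0, 10, plus) == 0.0
        minus = GeneModel("g", [TranscriptModel("t", "g", "s1", "-", [(0, 40), (100, 1000)])])
        assert relative_position(850, 900, minus) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            relative_position(900, 1100, plus)


class TestSpliceModel:
    def test_frequencies_match_hand_tally_on_toy_set(self):
        sites = ["CAGGTAAGT"] * 6 + ["CAGGTAAGA"] * 4
        model = train_splice_model(sites, "donor", min_sites=5, pseudocount=0.5)
        # last position: 6 T + 4 A with pseudocount 0.5 over 10 + 2 total
        assert model.freq[8, 3] == pytest.approx((6 + 0.5) / 12)
        assert model.freq[8, 0] == pytest.approx((4 + 0.5) / 12)
        assert model.freq[8, 1] == pytest.approx(0.5 / 12)
        # invariant GT at intronic positions 1-2 of the donor
        assert model.freq[3, 2] == pytest.approx(10.5 / 12)
        assert model.freq[4, 3] == pytest.approx(10.5 / 12)

    def test_requires_minimum_training_sites(self):
        with pytest.raises(ValueError, match=">= 50"):
            train_splice_model(["CAGGTAAGT"] * 10, "donor")

    def test_identical_training_sites_make_consensus_maximal(self):
        model = train_splice_model(["CAGGTAAGT"] * 60, "donor")
        top = score_splice_site(model, "CAGGTAAGT")
        rng = np.random.default_rng(1)
        for _ in range(50):
            other = "".join(rng.choice(list("ACGT"), 9))
            assert score_splice_site(model, other) <= top + 1e-9

    def test_consensus_maximizes_score_over_random_models(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            freq = rng.dirichlet(np.ones(4) * 0.7, size=9)
            bg = rng.dirichlet(np.ones(4) * 5)
            model = SpliceSiteModel("donor", freq, bg)
            top = score_splice_site(model, model.consensus)
            for _ in range(40):
                other = "".join(rng.choice(list("ACGT"), 9))
                assert score_splice_site(model, other) <= top + 1e-9

    def test_toy_score_equals_hand_computed_sum(self):
        freq = np.tile([0.4, 0.3, 0.2, 0.1], (9, 1))
        model = SpliceSiteModel("donor", freq, np.full(4, 0.25))
        want = 3 * np.log2(0.4 / 0.25) + 3 * np.log2(0.3 / 0.25) + 3 * np.log2(0.1 / 0.25)
        assert score_splice_site(model, "AACACCTTT") == pytest.approx(want)

    def test_length_mismatch_rejected(self):
        model = train_splice_model(["CAGGTAAGT"] * 60, "donor")
        with pytest.raises(ValueError, match="length"):
            score_splice_site(model, "CAGG")


class TestWindows:
    def test_strand_aware_window_extraction(self):
        exon1, intron, exon2 = "AAACAG", "GTAAGT" + "T" * 20 + "TCTCAG", "GTGAAA"
        genome = {"s1": exon1 + intron + exon2}
        start, end = len(exon1), len(exon1) + len(intron)
        assert donor_window(genome, "s1", start, end, "+") == exon1[-3:] + intron[:6]
        assert acceptor_window(genome, "s1", start, end, "+") == intron[-20:] + exon2[:3]
        # - strand: windows read from the other end, reverse-complemented
        from splicedyn.io import reverse_complement

        rc = reverse_complement
        assert donor_window(genome, "s1", start, end, "-") == rc(
            intron[-6:] + exon2[:3]
        )
        assert acceptor_window(genome, "s1", start, end, "-") == rc(
            exon1[-3:] + intron[:20]
        )


class TestBps:
    def test_matrix_shape_and_informative_positions(self):
        m = bps_matrix()
        assert m.shape == (7, 4)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        assert m[5, 0] > 0.8          # branch adenosine
        assert m[3, 1] + m[3, 3] > 0.8  # pyrimidine position

    def test_planted_site_found_at_offset(self):
        rng = np.random.default_rng(3)
        body = "".join(rng.choice(list("CG"), 300))
        planted = body[:300 - 25] + "TACTAAC" + body[300 - 18:]
        score, pos = score_bps(planted)
        assert pos == -25
        assert score > 2.0

    def test_pyrimidine_free_intron_scores_minimal(self):
        score, _ = score_bps("G" * 200)
        best_possible = np.log2(np.array([0.45, 0.85]) / 0.25).sum()
        assert score < 0 < best_possible

    def test_short_intron_undefined(self):
        score, pos = score_bps("GTAG")
        assert np.isnan(score) and np.isnan(pos)

    def test_window_scan_matches_brute_force(self):
        rng = np.random.default_rng(4)
        lo = np.log2(bps_matrix() / 0.25)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(50, 120))))
            L = len(seq)
            best = None
            for off in range(18, 45):
                p = L - off
                if p < 0 or p + 7 > L:
                    continue
                s = sum(lo[i, idx[b]] for i, b in enumerate(seq[p:p + 7]))
                if best is None or s > best[0]:
                    best = (s, p - L)
            score, pos = score_bps(seq)
            assert score == pytest.approx(best[0], abs=1e-12)
            assert pos == best[1]


class TestComparisons:
    def _records(self, values_by_cat, feature="length"):
        recs = []
        for cat, values in values_by_cat.items():
            for i, v in enumerate(values):
                recs.append(IntronFeatureRecord(
                    intron_id=f"{cat}{i}", gene_id="g", category=cat,
                    length=v if feature == "length" else 100,
                    gc=v if feature == "gc" else 0.5,
                    relative_position=0.5, ss5_score=0.0, ss3_score=0.0,
                    bps_score=0.0, bps_position=-20,
                ))
        return recs

    def test_identical_distributions_similar(self):
        recs = self._records({"alt_over": range(10, 30), "cons_over": range(10, 30)})
        out = compare_feature_distributions(recs, features=("length",))
        row = out.iloc[0]
        assert row["direction"] == "similar"
        assert row["p_value"] > 0.9

    def test_small_groups_match_exact_u_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = list(rng.normal(0, 1, int(rng.integers(3, 8))))
            b = list(rng.normal(0.8, 1, int(rng.integers(3, 8))))
            if len(set(a + b)) < len(a) + len(b):
                continue
            recs = self._records({"alt_over": a, "cons_over": b})
            out = compare_feature_distributions(recs, features=("length",))
            assert out.iloc[0]["p_value"] == pytest.approx(
                exact_mannwhitney_p(a, b), abs=1e-9
            )

    def test_label_swap_flips_direction_preserves_p(self):
        recs = self._records({"alt_over": range(0, 20), "cons_over": range(10, 30)})
        out = compare_feature_distributions(recs, features=("length",)).iloc[0]
        swapped = self._records({"cons_over": range(0, 20), "alt_over": range(10, 30)})
        out2 = compare_feature_distributions(swapped, features=("length",)).iloc[0]
        assert out["p_value"] == pytest.approx(out2["p_value"])
        assert {out["direction"], out2["direction"]} == {"greater", "less"}

    def test_too_small_category_skipped_with_reason(self):
        recs = self._records({"alt_over": [1.0], "cons_over": [1.0, 2.0, 3.0]})
        out = compare_feature_distributions(recs, features=("length",))
        assert out.iloc[0]["direction"].startswith("skipped")


class TestPlantedFeatureStudy:
    def test_direction_table_recovers_planted_pattern(self):
        planted = simulate_intron_features(seed=7, n_per_category=80)
        cons = [p for p in planted if p.category.startswith("cons")]
        dm = train_splice_model([p.donor_window for p in cons], "donor")
        am = train_splice_model([p.acceptor_window for p in cons], "acceptor")
        recs = []
        for i, p in enumerate(planted):
            b, pos = score_bps(p.sequence)
            recs.append(IntronFeatureRecord(
                f"i{i}", "g", p.category, len(p.sequence),
                gc_content(p.sequence), p.relative_position,
                score_splice_site(dm, p.donor_window),
                score_splice_site(am, p.acceptor_window), b, pos,
            ))
        out = compare_feature_distributions(recs).set_index(
            ["feature", "category_a", "category_b"]
        )

        def check(feature, a, b, direction, significant=True):
            row = out.loc[(feature, a, b)]
            assert row["direction"] == direction
            if significant:
                assert row["p_value"] < 0.01

        # length: over-alternative LONG, normal-alternative SHORT
        check("length", "alt_over", "cons_over", "greater")
        check("length", "alt_normal", "cons_normal", "less")
        # GC: alternative HIGH in both dynamics classes
        check("gc", "alt_over", "cons_over", "greater")
        check("gc", "alt_normal", "cons_normal", "greater")
        # splice sites: alternative WEAK, normal-alternative weakest
        check("ss5_score", "alt_over", "cons_over", "less")
        check("ss5_score", "alt_normal", "cons_normal", "less")
        check("ss5_score", "alt_over", "alt_normal", "greater")
        check("ss3_score", "alt_over", "cons_over", "less")
        check("ss3_score", "alt_normal", "cons_normal", "less")
        # branch point: alternative WEAK in both classes
        check("bps_score", "alt_over", "cons_over", "less")
        check("bps_score", "alt_normal", "cons_normal", "less")
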