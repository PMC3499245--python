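"""HGT index, alien index and transcript classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hgtscan.index import (
    HitProfile,
    ProfileError,
    attribute_source_taxon,
    build_profiles,
    classify,
    compute_alien_index,
    compute_h,
    crossref_gene_set,
    evaluate_profiles,
    summarize,
)
from hgtscan.taxa import FOREIGN_TAXA, METAZOA, TAXA


def profile(**taxon_hits):
    """Shorthand: profile('Metazoa'=[(120, 1e-30)], Fungi=[(150, 1e-40)])."""
    return HitProfile(transcript_id="t", hits=dict(taxon_hits))


def hit_row(tid, taxon, bitscore, evalue):
    return {"qseqid": tid, "taxon": taxon, "bitscore": bitscore, "evalue": evalue}


class TestBuildProfiles:
    def test_passing_transcript_retained(self):
        df = pd.DataFrame([hit_row("t1", "Metazoa", 60, 1e-6)])
        profiles, n_excluded = build_profiles(df)
        assert len(profiles) == 1 and n_excluded == 0

    def test_failing_transcript_excluded_and_tallied(self):
        df = pd.DataFrame([hit_row("t1", "Metazoa", 20, 1e-4)])
        profiles, n_excluded = build_profiles(df)
        assert profiles == [] and n_excluded == 1

    def test_top_k_retention_keeps_global_best(self):
        # 7 hits: 5 retained, but the best bitscore equals the max of all 7
        scores = [50, 90, 70, 100, 60, 80, 40]
        df = pd.DataFrame(
            [hit_row("t1", "Eubacteria", s, 10.0 ** -s) for s in scores]
        )
        profiles, _ = build_profiles(df)
        rows = profiles[0].hits["Eubacteria"]
        assert len(rows) == 5
        assert profiles[0].best_bitscore("Eubacteria") == max(scores)
        assert [r[0] for r in rows] == sorted(scores, reverse=True)[:5]

    def test_empty_input(self):
        profiles, n = build_profiles(pd.DataFrame())
        assert profiles == [] and n == 0


class TestComputeH:
    def test_equal_bests_give_zero(self):
        p = profile(Metazoa=[(100, 1e-20)], Fungi=[(100, 1e-20)])
        assert compute_h(p) == 0.0

    def test_absent_metazoan_side_contributes_zero(self):
        p = profile(Eubacteria=[(85, 1e-15)])
        assert compute_h(p) == 85.0

    def test_absent_nonmetazoan_side(self):
        p = profile(Metazoa=[(85, 1e-15)])
        assert compute_h(p) == -85.0

    def test_threshold_case(self):
        p = profile(
            Metazoa=[(120, 1e-30)], Fungi=[(150, 1e-40)], Eubacteria=[(140, 1e-35)]
        )
        assert compute_h(p) == 30.0
        assert classify(compute_h(p)) == "foreign"

    def test_no_hits_is_contract_violation(self):
        with pytest.raises(ProfileError):
            compute_h(HitProfile(transcript_id="t"))

    @given(
        s_met=st.floats(10, 500),
        s_non=st.floats(10, 500),
    )
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, s_met, s_non):
        """Swapping metazoan and best non-metazoan scores negates h."""
        a = profile(Metazoa=[(s_met, 1e-10)], Fungi=[(s_non, 1e-10)])
        b = profile(Metazoa=[(s_non, 1e-10)], Fungi=[(s_met, 1e-10)])
        assert compute_h(a) == pytest.approx(-compute_h(b))

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_h_equals_brute_force_max_scan(self, data):
        """h agrees with an exhaustive scan over all retained hits."""
        hits = {}
        for taxon in TAXA:
            n = data.draw(st.integers(0, 4))
            if n:
                hits[taxon] = [
                    (data.draw(st.floats(1, 1000)), data.draw(st.floats(0, 1)))
                    for _ in range(n)
                ]
        if not hits:
            return
        p = HitProfile(transcript_id="t", hits=hits)
        best_non = max(
            (s for t in FOREIGN_TAXA for s, _ in hits.get(t, [])), default=0.0
        )
        best_met = max((s for s, _ in hits.get(METAZOA, [])), default=0.0)
        assert compute_h(p) == pytest.approx(best_non - best_met)


class TestAlienIndex:
    def test_equal_evidence_is_zero(self):
        p = profile(Metazoa=[(100, 1e-30)], Fungi=[(100, 1e-30)])
        assert compute_alien_index(p) == 0.0

    def test_closed_form_value(self):
        p = profile(Metazoa=[(100, 1e-50)], Fungi=[(200, 1e-100)])
        assert compute_alien_index(p) == pytest.approx(50 * math.log(10), rel=1e-9)

    def test_zero_evalues_clamp_symmetrically(self):
        p = profile(Metazoa=[(1000, 0.0)], Fungi=[(1000, 0.0)])
        assert compute_alien_index(p) == 0.0

    def test_negative_evalue_rejected(self):
        p = profile(Metazoa=[(100, -1e-5)])
        with pytest.raises(ValueError):
            compute_alien_index(p)

    def test_sign_agreement_with_h_on_consistent_profiles(self):
        """When E-values are monotone consistent with bitscores, the two
        indices agree in sign."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            s_met, s_non = rng.uniform(50, 400, size=2)
            p = profile(
                Metazoa=[(s_met, float(4e9 * 2.0 ** -s_met))],
                Eubacteria=[(s_non, float(4e9 * 2.0 ** -s_non))],
            )
            h = compute_h(p)
            ai = compute_alien_index(p)
            assert h == 0 or np.sign(h) == np.sign(ai)


class TestClassify:
    @pytest.mark.parametrize(
        "h,expected",
        [(30, "foreign"), (0, "metazoan"), (15, "indeterminate"),
         (-50, "metazoan"), (29.999, "indeterminate"), (1000, "foreign")],
    )
    def test_boundaries(self, h, expected):
        assert classify(h) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"))


class TestAttribution:
    def test_argmax(self):
        p = profile(Eubacteria=[(140, 1e-40)], Fungi=[(120, 1e-30)])
        assert attribute_source_taxon(p) == "Eubacteria"

    def test_tie_broken_by_lower_evalue(self):
        p = profile(Eubacteria=[(140, 1e-50)], Fungi=[(140, 1e-60)])
        assert attribute_source_taxon(p) == "Fungi"

    def test_full_tie_broken_by_taxon_order(self):
        p = profile(Fungi=[(140, 1e-50)], Eubacteria=[(140, 1e-50)])
        assert attribute_source_taxon(p) == "Eubacteria"

    def test_metazoan_only_profile_has_no_source(self):
        assert attribute_source_taxon(profile(Metazoa=[(100, 1e-20)])) is None


class TestSummarize:
    def _records(self, profiles, **kwargs):
        return evaluate_profiles(profiles, **kwargs)

    def test_all_metazoan_set_has_zero_foreign(self):
        profiles = [
            HitProfile(transcript_id=f"t{i}", hits={METAZOA: [(100, 1e-30)]})
            for i in range(10)
        ]
        s = summarize(self._records(profiles), profiles)
        assert s.foreign == 0 and s.foreign_fraction == 0.0

    def test_stricter_epsilon_recomputes_bests(self):
        # non-metazoan best passes 1e-5 but fails 1e-10: at the stricter cut
        # the transcript flips from foreign to metazoan
        p = HitProfile(
            transcript_id="t1",
            hits={
                METAZOA: [(100, 1e-30)],
                "Eubacteria": [(140, 1e-6)],
            },
        )
        records = self._records([p])
        assert records[0].category == "foreign"
        s = summarize(records, [p], alt_epsilons=(1e-10,))
        matched, foreign, frac = s.reanalysis[1e-10]
        assert (matched, foreign) == (1, 0)

    def test_matched_count_monotone_in_epsilon(self, small_study):
        hits, _, _ = small_study
        profiles, _ = build_profiles(hits)
        records = self._records(profiles)
        s = summarize(records, profiles, alt_epsilons=(1e-10, 1e-15))
        assert s.matched >= s.reanalysis[1e-10][0] >= s.reanalysis[1e-15][0]

    def test_foreign_count_monotone_in_theta(self, small_study):
        hits, _, _ = small_study
        profiles, _ = build_profiles(hits)
        counts = []
        for theta in (10, 30, 60, 120):
            records = self._records(profiles, theta=theta)
            counts.append(sum(r.category == "foreign" for r in records))
        assert counts == sorted(counts, reverse=True)

    def test_no_metazoan_fraction_counts_missing_not_weak(self):
        # one foreign transcript with NO metazoan hit, one with a weak one:
        # only the first lacks a *significant* metazoan match
        p1 = HitProfile(transcript_id="a", hits={"Eubacteria": [(200, 1e-60)]})
        p2 = HitProfile(
            transcript_id="b",
            hits={"Eubacteria": [(200, 1e-60)], METAZOA: [(60, 1e-8)]},
        )
        records = self._records([p1, p2])
        s = summarize(records, [p1, p2])
        assert s.foreign == 2
        assert s.foreign_without_metazoan == 1


class TestCrossref:
    def _records(self):
        ps = [
            HitProfile(transcript_id="f1", hits={"Eubacteria": [(200, 1e-60)]}),
            HitProfile(transcript_id="m1", hits={METAZOA: [(200, 1e-60)]}),
        ]
        return evaluate_profiles(ps)

    def test_empty_reference(self):
        out = crossref_gene_set(self._records(), pd.DataFrame(columns=["qseqid", "evalue"]))
        assert out[1e-5] == (0.0, 0.0)

    def test_all_matched(self):
        ref = pd.DataFrame({"qseqid": ["f1", "m1"], "evalue": [1e-9, 1e-9]})
        assert crossref_gene_set(self._records(), ref)[1e-5] == (1.0, 1.0)

    def test_metazoan_only_spike(self):
        ref = pd.DataFrame({"qseqid": ["m1"], "evalue": [1e-9]})
        f_frac, m_frac = crossref_gene_set(self._records(), ref)[1e-5]
        assert f_frac < m_frac


class TestParameterRecovery:
    def test_foreign_fraction_recovered_on_synthetic_data(self):
        """|estimated f - 0.10| <= 0.015 at n=5000 with well-separated scores."""
        from hgtscan.simulate import SimParams, generate_hit_table

        params = SimParams(n_transcripts=5000, foreign_fraction=0.10, seed=42)
        hits, truth = generate_hit_table(params)
        profiles, _ = build_profiles(hits)
        records = evaluate_profiles(profiles)
        s = summarize(records, profiles, alt_epsilons=())
        assert abs(s.foreign_fraction - 0.10) <= 0.015

    def test_source_attribution_accuracy(self):
        from hgtscan.simulate import SimParams, generate_hit_table

        params = SimParams(n_transcripts=2000, foreign_fraction=0.2, seed=7)
        hits, truth = generate_hit_table(params)
        profiles, _ = build_profiles(hits)
        records = evaluate_profiles(profiles)
        foreign = [r for r in records if r.category == "foreign"]
        correct = sum(
            truth.origins[r.transcript_id] == r.best_nonmetazoan_taxon
            for r in foreign
        )
        assert correct / len(foreign) >= 0.99


class TestSummaryTableEquivalence:
    def test_summary_export_reproduces_full_profile_classification(self, tmp_path, small_study):
        """A per-taxon best-pair export (supplementary-table style) yields the
        same h, category and source attribution as the full top-5 profiles."""
        import pandas as pd

        from hgtscan.io import profiles_from_summary, read_summary_table
        from hgtscan.taxa import TAXA

        hits, _, _ = small_study
        profiles, _ = build_profiles(hits)
        full_records = {r.transcript_id: r for r in evaluate_profiles(profiles)}

        rows = []
        for p in profiles:
            row = {"transcript_id": p.transcript_id, "length": p.length}
            for taxon in TAXA:
                s = p.best_bitscore(taxon)
                if s is not None:
                    row[f"{taxon}_bitscore"] = s
                    row[f"{taxon}_evalue"] = p.min_evalue(taxon)
            rows.append(row)
        path = tmp_path / "summary.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

        back = profiles_from_summary(read_summary_table(path))
        for r in evaluate_profiles(back):
            full = full_records[r.transcript_id]
            assert r.h == pytest.approx(full.h)
            assert r.category == full.category
            assert r.best_nonmetazoan_taxon == full.best_nonmetazoan_taxon
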