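"""Homology filtering, partitioning, spectra, and the completeness correction."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_filter
from orphanaudit.errors import ConsistencyError, DegenerateInputError
from orphanaudit.homology import (
    CorrectionInput,
    OUTFMT6_COLUMNS,
    corrected_matching,
    evalue_spectrum,
    filter_hits,
    intraspecific_rate,
    partition,
    read_outfmt6,
    taxon_breakdown,
)
from orphanaudit.synth import SimConfig, gen_homology_table, write_hits


def _hits(rows):
    """Minimal hit frame from (query, subject, e_value, aligned_length[, bit])."""
    df = pd.DataFrame(
        rows, columns=["query_id", "subject_id", "e_value", "aligned_length"]
    )
    df["bit_score"] = 50.0
    return df


class TestFilterHits:
    def test_boundaries_are_inclusive(self):
        kept = filter_hits(_hits([("q", "s", 1e-5, 33)]))
        assert len(kept) == 1

    @pytest.mark.parametrize("e, length", [(2e-5, 100), (1e-9, 32)])
    def test_each_filter_drops_independently(self, e, length):
        assert len(filter_hits(_hits([("q", "s", e, length)]))) == 0

    def test_synthetic_decoy_table_matches_row_scan(self, small_config):
        hit = gen_homology_table(small_config)
        kept = filter_hits(hit.hits)
        rows = list(zip(hit.hits["e_value"], hit.hits["aligned_length"]))
        expected_idx = brute_force_filter(rows)
        assert len(kept) == len(expected_idx)
        assert kept["query_id"].tolist() == hit.hits.iloc[expected_idx]["query_id"].tolist()

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1e-3, allow_nan=False),
                st.integers(min_value=1, max_value=200),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=100)
    def test_filter_agrees_with_row_scan(self, pairs):
        rows = [(f"q{i}", "s", e, length) for i, (e, length) in enumerate(pairs)]
        kept = filter_hits(_hits(rows))
        assert len(kept) == len(brute_force_filter(pairs))

    def test_roundtrip_through_tabular_file(self, tmp_path, small_config):
        hit = gen_homology_table(small_config)
        path = tmp_path / "hits.tsv"
        write_hits(hit.hits, path)
        back = read_outfmt6(path)
        assert len(back) == len(hit.hits)
        assert np.allclose(back["e_value"], hit.hits["e_value"])


class TestPartition:
    def test_no_hits_means_all_unmatched(self):
        part = partition(["a", "b"], {"ds": _hits([])})
        assert part.marginals()["n_match"].tolist() == [0]
        assert part.union_count() == 0

    def test_unknown_query_raises(self):
        with pytest.raises(ConsistencyError):
            partition(["a"], {"ds": _hits([("zzz", "s", 1e-9, 50)])})

    def test_published_marginal_fraction_reproduces(self):
        """A 3,592-of-14,310 flag table yields the printed 25.1% marginal."""
        ids = [f"q{i}" for i in range(14310)]
        hits = _hits([(f"q{i}", "s", 1e-9, 50) for i in range(3592)])
        part = partition(ids, {"peptides": hits})
        marg = part.marginals()
        assert marg.loc[0, "n_match"] == 3592
        assert marg.loc[0, "n_nomatch"] == 10718
        assert round(100 * marg.loc[0, "match_fraction"], 1) == 25.1

    def test_complete_reference_flags_equal_truth(self):
        cfg = replace(
            SimConfig(), seed=3, n_ests=200, reference_completeness=1.0, redundancy=0.0
        )
        hit = gen_homology_table(cfg)
        ids = [f"AAEST{i + 1:06d}" for i in range(200)]
        part = partition(ids, {"ref": filter_hits(hit.hits)})
        flagged = set(part.flags.index[part.flags["ref"]])
        assert flagged == set(hit.truth.homologs)

    def test_marginals_contingencies_and_union_match_per_query_scan(self):
        rng = np.random.default_rng(23)
        ids = [f"q{i:03d}" for i in range(300)]
        tables = {}
        membership = {}
        for ds in ("d1", "d2", "d3"):
            chosen = [q for q in ids if rng.random() < 0.3]
            membership[ds] = set(chosen)
            tables[ds] = _hits([(q, "s", 1e-9, 50) for q in chosen])
        part = partition(ids, tables)
        marg = part.marginals().set_index("dataset_id")
        for ds in tables:
            assert marg.loc[ds, "n_match"] == len(membership[ds])
            assert marg.loc[ds, "n_match"] + marg.loc[ds, "n_nomatch"] == len(ids)
        table = part.contingency("d1", "d2")
        both = sum(1 for q in ids if q in membership["d1"] and q in membership["d2"])
        assert table.loc["match", "match"] == both
        assert table.to_numpy().sum() == len(ids)
        union = set().union(*membership.values())
        assert part.union_count() == len(union)


class TestEvalueSpectrum:
    def test_all_highly_significant(self):
        spec = evalue_spectrum(_hits([(f"q{i}", "s", 1e-60, 50) for i in range(4)]))
        assert spec.frac_le_1e10 == 1.0 and spec.frac_le_1e50 == 1.0

    def test_mixed_best_hits(self):
        spec = evalue_spectrum(
            _hits(
                [("a", "s", 1e-6, 50), ("b", "s", 1e-12, 50),
                 ("c", "s", 1e-55, 50), ("d", "s", 1e-80, 50)]
            )
        )
        assert spec.frac_le_1e10 == pytest.approx(0.75)
        assert spec.frac_le_1e50 == pytest.approx(0.5)

    def test_zero_evalue_lands_in_most_significant_bin(self):
        spec = evalue_spectrum(_hits([("a", "s", 0.0, 50), ("b", "s", 1e-6, 50)]))
        assert spec.frac_le_1e50 == pytest.approx(0.5)
        assert spec.histogram["log10_bin"].min() == -200

    def test_best_hit_per_query_is_used(self):
        spec = evalue_spectrum(
            _hits([("a", "s1", 1e-60, 50), ("a", "s2", 1e-6, 50)])
        )
        assert spec.frac_le_1e50 == 1.0


class TestTaxonBreakdown:
    def test_single_taxon_map(self):
        out = taxon_breakdown(
            _hits([("a", "s1", 1e-9, 50), ("b", "s1", 1e-9, 50)]), {"s1": "Acari"}
        )
        assert out.to_dict("records") == [{"taxon": "Acari", "n_queries": 2}]

    def test_matches_brute_force_tally_with_nested_groups(self):
        rng = np.random.default_rng(31)
        taxa = ["Acari", "Insecta", "Coxiellaceae", "OtherBacteria"]
        groups = {
            "Acari": "eukaryote", "Insecta": "eukaryote",
            "Coxiellaceae": "bacteria", "OtherBacteria": "bacteria",
        }
        rows, expected = [], {}
        taxon_map = {}
        for i in range(150):
            t = taxa[rng.integers(0, 4)]
            s = f"s{i}"
            taxon_map[s] = t
            rows.append((f"q{i}", s, 1e-9, 50))
            expected[t] = expected.get(t, 0) + 1
        out = taxon_breakdown(_hits(rows), taxon_map, groups)
        assert dict(zip(out["taxon"], out["n_queries"])) == expected
        bacteria = out[out["group"] == "bacteria"]["n_queries"].sum()
        assert bacteria == expected.get("Coxiellaceae", 0) + expected.get("OtherBacteria", 0)


class TestIntraspecificRate:
    def test_published_counts(self):
        assert intraspecific_rate(128738, 194460) == pytest.approx(0.662, abs=5e-4)

    def test_all_matched(self):
        assert intraspecific_rate(100, 100) == 1.0

    def test_synthetic_rate_within_three_se_of_completeness(self):
        c = 0.55
        cfg = replace(
            SimConfig(),
            seed=19, n_ests=8000, true_match_frac=1.0,
            reference_completeness=c, redundancy=0.0, decoy_fraction=0.0,
        )
        hit = gen_homology_table(cfg)
        rate = intraspecific_rate(filter_hits(hit.hits), 8000)
        assert abs(rate - c) <= 3 * math.sqrt(c * (1 - c) / 8000)


class TestCorrectedMatching:
    @pytest.mark.parametrize(
        "n_total, n_match, n_nomatch, p_intra, expected_pct",
        [
            (14310, 3592, 10718, 0.662, 34),
            (14309, 2365, 11944, 0.373, 35),
            (14310, 4124, 10186, 0.541, 43),
        ],
    )
    def test_published_corrections(self, n_total, n_match, n_nomatch, p_intra, expected_pct):
        corr = corrected_matching(
            CorrectionInput(n_total, n_match, n_nomatch, p_intra)
        )
        assert corr.corrected_percent == expected_pct

    def test_perfect_reference_equals_raw(self):
        corr = corrected_matching(CorrectionInput(100, 30, 70, 1.0))
        assert corr.corrected_fraction == pytest.approx(corr.raw_fraction)

    def test_degenerate_all_discarded_raises(self):
        with pytest.raises(DegenerateInputError):
            corrected_matching(CorrectionInput(100, 0, 100, 0.0))

    def test_inconsistent_marginals_raise(self):
        with pytest.raises(ConsistencyError):
            CorrectionInput(100, 30, 60, 0.5)

    @given(
        n_total=st.integers(min_value=2, max_value=100000),
        match_frac=st.floats(min_value=0.01, max_value=1.0),
        p_intra=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200)
    def test_correction_never_lowers_the_fraction(self, n_total, match_frac, p_intra):
        n_match = max(1, int(match_frac * n_total))
        inp = CorrectionInput(n_total, n_match, n_total - n_match, p_intra)
        corr = corrected_matching(inp)
        assert corr.corrected_fraction >= corr.raw_fraction - 1e-12
        # strict inequality checked away from the float-precision boundary
        if p_intra <= 0.99 and inp.n_nomatch > 0:
            assert corr.corrected_fraction > corr.raw_fraction
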