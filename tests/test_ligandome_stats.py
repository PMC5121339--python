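"""Ligandome analytics: lengths, coverage, correlations, quartiles, phospho."""

import numpy as np
import pandas as pd
import pytest

from neoligand.ligandome_stats import (
    antigen_correlation,
    coverage_profile,
    intensity_rank_projection,
    length_distribution,
    map_peptides_to_proteome,
    phospho_summaries,
)


def table_from(rows):
    return pd.DataFrame(
        rows, columns=["sequence", "patient", "hla_class", "intensity", "modifications"]
    )


class TestLengthDistribution:
    def test_all_9mers_single_bin(self):
        t = table_from([("A" * 9, "Mel1", "I", 1.0, "")] * 4)
        dist = length_distribution(t)
        assert dist.to_dict() == {9: 4}

    def test_empty_table(self):
        assert length_distribution(table_from([])).empty

    def test_generator_weights_recovered(self, small_cohort):
        """Fixture length histogram lands within multinomial error of the
        configured weights."""
        dist = length_distribution(small_cohort["table"])
        n = int(dist.sum())
        for length, weight in small_cohort["config"].length_weights.items():
            observed = int(dist.get(length, 0))
            sd = np.sqrt(n * weight * (1 - weight))
            assert abs(observed - n * weight) <= 4 * sd + 1


def brute_force_coverage(proteome, intervals):
    """Interval-stabbing oracle: count per residue by direct iteration."""
    counts = {pid: np.zeros(len(seq), dtype=int) for pid, seq in proteome.items()}
    for pid, start, end in intervals:
        for i in range(start, end):
            counts[pid][i] += 1
    return counts


class TestCoverage:
    PROTEOME = {"P1": "MKTAYIAKQRQISFVKSHFSRQ", "P2": "MWWAAAACCCAAAAWW"}

    def test_single_peptide_plateau(self):
        t = table_from([("KTAYIAKQ", "Mel1", "I", 1.0, "")])
        prof = coverage_profile(t, self.PROTEOME)["P1"]
        np.testing.assert_array_equal(prof.ligand_count[1:9], 1)
        assert prof.ligand_count.sum() == 8

    def test_two_patients_same_peptide(self):
        t = table_from(
            [("KTAYIAKQ", "Mel1", "I", 1.0, ""), ("KTAYIAKQ", "Mel2", "I", 2.0, "")]
        )
        prof = coverage_profile(t, self.PROTEOME)["P1"]
        np.testing.assert_array_equal(prof.patient_count[1:9], 2)
        np.testing.assert_array_equal(prof.ligand_count[1:9], 2)

    def test_staircase_matches_interval_oracle(self, rng):
        proteome = {"P": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50))}
        rows, intervals = [], []
        for k, patient in enumerate(["Mel1", "Mel2", "Mel3"] * 4):
            start = int(rng.integers(0, 40))
            length = int(rng.integers(8, 11))
            seq = proteome["P"][start : start + length]
            rows.append((seq, patient, "I", 1.0, ""))
        t = table_from(rows)
        hits = map_peptides_to_proteome(t["sequence"], proteome)
        for _, row in t.iterrows():
            for pid, start in hits[row["sequence"]]:
                intervals.append((pid, start, start + len(row["sequence"])))
        oracle = brute_force_coverage(proteome, intervals)
        prof = coverage_profile(t, proteome)["P"]
        np.testing.assert_array_equal(prof.ligand_count, oracle["P"])

    def test_hot_spot_needs_three_patients(self):
        rows = [("KTAYIAKQ", f"Mel{i}", "I", 1.0, "") for i in (1, 2, 3)]
        prof = coverage_profile(table_from(rows), self.PROTEOME)["P1"]
        assert prof.hot_spots == [(1, 9)]
        prof2 = coverage_profile(table_from(rows[:2]), self.PROTEOME)["P1"]
        assert prof2.hot_spots == []


class TestAntigenCorrelation:
    def _table(self, counts):
        rows = []
        for patient, n in counts.items():
            rows += [("KTAYIAKQ", patient, "I", 1.0, "")] * n
            rows += [("WWAAAACC", patient, "I", 1.0, "")] * (20 - n)
        return table_from(rows)

    PROTEOME = {"P1": "MKTAYIAKQRQISFVKSHFSRQ", "P2": "MWWAAAACCCAAAAWW"}

    def test_perfectly_linear_gives_r_one(self):
        counts = {"Mel1": 1, "Mel2": 4, "Mel3": 9, "Mel4": 16}
        cov = pd.DataFrame(
            {"AG": [np.sqrt(v / 20) for v in counts.values()]},
            index=list(counts),
        )
        (summary,) = antigen_correlation(
            self._table(counts), {"AG": "P1"}, cov, self.PROTEOME
        )
        assert summary.pearson_r == pytest.approx(1.0)
        assert summary.corrected_p == pytest.approx(summary.p_value)  # Holm, m=1

    def test_normalized_counts_are_fractions(self):
        counts = {"Mel1": 5, "Mel2": 10, "Mel3": 15}
        cov = pd.DataFrame({"AG": [1.0, 2.0, 3.0]}, index=list(counts))
        (summary,) = antigen_correlation(
            self._table(counts), {"AG": "P1"}, cov, self.PROTEOME
        )
        assert summary.normalized_counts == {
            "Mel1": 0.25, "Mel2": 0.5, "Mel3": 0.75
        }

    def test_independent_covariate_rarely_significant(self):
        """Permuted covariate: corrected p > 0.05 in >= 95% of replicates."""
        counts = {f"Mel{i}": 2 + (i % 7) for i in range(10)}
        t = self._table(counts)
        rng = np.random.default_rng(0)
        base = np.arange(10, dtype=float)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            cov = pd.DataFrame({"AG": rng.permutation(base)}, index=list(counts))
            (s,) = antigen_correlation(t, {"AG": "P1"}, cov, self.PROTEOME)
            if s.corrected_p > 0.05:
                hits += 1
        assert hits >= 95

    def test_zero_variance_covariate_reported_missing(self):
        counts = {"Mel1": 5, "Mel2": 10, "Mel3": 15}
        cov = pd.DataFrame({"AG": [1.0, 1.0, 1.0]}, index=list(counts))
        (s,) = antigen_correlation(self._table(counts), {"AG": "P1"}, cov, self.PROTEOME)
        assert np.isnan(s.pearson_r)

    def test_fewer_than_three_patients_rejected(self):
        cov = pd.DataFrame({"AG": [1.0, 2.0]}, index=["Mel1", "Mel2"])
        with pytest.raises(ValueError):
            antigen_correlation(self._table({"Mel1": 1, "Mel2": 2}),
                                {"AG": "P1"}, cov, self.PROTEOME)


class TestIntensityRanks:
    def _table(self, intensities):
        rows = [(f"PEPTIDE{chr(65 + i)}", "Mel1", "I", v, "")
                for i, v in enumerate(intensities)]
        return table_from(rows)

    def test_global_maximum_in_top_quartile(self):
        t = self._table([10.0, 5.0, 3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        ranked = intensity_rank_projection(t, ["PEPTIDEA"])
        row = ranked[ranked["in_subset"]].iloc[0]
        assert row["rank"] == 1 and row["quartile"] == 1

    def test_median_of_odd_table_sits_at_q2_q3_boundary(self):
        # documented convention: quartile = floor(4 * (rank-1) / n) + 1,
        # which puts the middle element of 2k+1 rows in quartile 2
        t = self._table([float(v) for v in range(9, 0, -1)])
        ranked = intensity_rank_projection(t, [])
        median_seq = t.sort_values("intensity")["sequence"].iloc[4]
        assert int(ranked.loc[ranked["sequence"] == median_seq, "quartile"].iloc[0]) == 2

    def test_quartile_partition_balanced(self, rng):
        for n in (8, 9, 10, 11, 101):
            t = self._table(list(rng.random(min(n, 26))))
            sizes = intensity_rank_projection(t, [])["quartile"].value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_uniform_subset_occupies_quartiles_evenly(self, rng):
        rows = [(f"P{i:04d}AAA", "Mel1", "I", float(v), "")
                for i, v in enumerate(rng.random(400))]
        t = table_from(rows)
        subset = list(t["sequence"].sample(100, random_state=1))
        ranked = intensity_rank_projection(t, subset)
        occ = ranked[ranked["in_subset"]]["quartile"].value_counts(normalize=True)
        assert all(abs(occ.get(q, 0) - 0.25) < 0.15 for q in (1, 2, 3, 4))

    def test_missing_intensity_excluded(self):
        t = self._table([3.0, 2.0])
        t.loc[1, "intensity"] = np.nan
        ranked = intensity_rank_projection(t, [])
        assert len(ranked) == 1


class TestPhosphoSummaries:
    def test_unique_to_one_patient_shared_zero(self):
        t = table_from(
            [("AKSLYR"[0:6], "Mel1", "I", 1.0, "ph@3"),
             ("AKTLYR", "Mel2", "I", 1.0, "ph@3")]
        )
        assert phospho_summaries(t).shared_fraction == 0.0

    def test_shared_fraction_counts_multi_patient_sequences(self):
        t = table_from(
            [("AKSLYR", "Mel1", "I", 1.0, "ph@3"),
             ("AKSLYR", "Mel2", "I", 1.0, "ph@3"),
             ("AKTLYR", "Mel1", "I", 1.0, "ph@3")]
        )
        assert phospho_summaries(t).shared_fraction == pytest.approx(0.5)

    def test_all_serine_sites(self):
        t = table_from([("AKSLYR", "Mel1", "I", 1.0, "ph@3"),
                        ("GGSAAK", "Mel2", "I", 1.0, "ph@3")])
        fr = phospho_summaries(t).residue_fractions
        assert fr == {"S": 1.0, "T": 0.0, "Y": 0.0}

    def test_position_matrix_mode_at_planted_position(self):
        rows = [(f"AAA{st}AAAK{'ACDEFGHIKL'[i]}", "Mel1", "I", 1.0, "ph@4")
                for i, st in enumerate("S" * 8 + "T" * 2)]
        summary = phospho_summaries(table_from(rows))
        matrix = summary.site_position_matrix
        assert matrix.loc[9].idxmax() == 4 and matrix.loc[9, 4] == 10

    def test_p1_residue_frequencies(self):
        t = table_from([("RKSLYA", "Mel1", "I", 1.0, "ph@3"),
                        ("RASLYC", "Mel1", "I", 1.0, "ph@3"),
                        ("KASLYD", "Mel1", "I", 1.0, "ph@3")])
        p1 = phospho_summaries(t).p1_residue_freqs
        assert p1.to_dict() == {"K": 1, "R": 2}

    def test_logo_matrix_rows_sum_to_peptide_count(self):
        t = table_from([("AKSLYRAAA", "Mel1", "I", 1.0, "ph@3"),
                        ("GKSLYRAAC", "Mel2", "I", 1.0, "ph@3")])
        logo = phospho_summaries(t).logo_matrices[9]
        assert (logo.sum(axis=1) == 2).all()
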