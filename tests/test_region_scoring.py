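import numpy as np
import pandas as pd
import pytest

from pcsrscan.region_scoring import (
    RegionFrequencyTable,
    chromosome_chi_square,
    chromosome_frequencies,
    participation_percent,
    region_frequencies,
    select_pcsrs,
)


def annotation_for(bands, probes_per_band=4):
    rows = []
    for b_i, (chrom, band) in enumerate(bands):
        for j in range(probes_per_band):
            rows.append((f"pr_{band}_{j}", chrom, band, b_i * 1000 + j))
    return pd.DataFrame(rows, columns=["probe_id", "chromosome", "band", "position"])


class TestRegionFrequencies:
    def test_no_altered_probes(self):
        ann = annotation_for([("1", "1p1"), ("1", "1q1")])
        freq = region_frequencies({"c1": pd.DataFrame(columns=["probe_id", "direction"])}, ann)
        assert (freq.table["over_total"] == 0).all()
        assert (freq.table["ftp"] == 4).all()

    def test_direct_count(self):
        ann = annotation_for([("1", "1p1")])
        calls = pd.DataFrame(
            {"probe_id": ["pr_1p1_0", "pr_1p1_1", "pr_1p1_2"], "direction": "over"}
        )
        freq = region_frequencies({"c1": calls}, ann)
        row = freq.table.iloc[0]
        assert row["over_total"] == 3 and row["ftp"] == 4

    def test_matches_brute_force_tally(self, rng):
        ann = annotation_for([("1", "1p1"), ("1", "1q1"), ("2", "2p1")], probes_per_band=10)
        calls = {}
        for cancer in ("ca", "cb", "cc"):
            chosen = rng.choice(ann["probe_id"], size=12, replace=False)
            calls[cancer] = pd.DataFrame(
                {"probe_id": chosen, "direction": rng.choice(["over", "down"], size=12)}
            )
        freq = region_frequencies(calls, ann)
        band_of = dict(zip(ann["probe_id"], ann["band"]))
        for _, row in freq.table.iterrows():
            expected_over = sum(
                (band_of[p] == row["band"]) and (d == "over")
                for t in calls.values()
                for p, d in zip(t["probe_id"], t["direction"])
            )
            assert row["over_total"] == expected_over

    def test_conservation_per_cancer(self, rng):
        """Band contributions sum to the number of mapped altered calls."""
        ann = annotation_for([("1", "1p1"), ("2", "2q1")], probes_per_band=8)
        chosen = rng.choice(ann["probe_id"], size=10, replace=False)
        calls = {"c1": pd.DataFrame({"probe_id": chosen, "direction": "over"})}
        freq = region_frequencies(calls, ann)
        assert freq.per_cancer["over"].sum() == 10

    def test_unknown_probe_rejected(self):
        ann = annotation_for([("1", "1p1")])
        calls = {"c1": pd.DataFrame({"probe_id": ["pr_1p1_0", "nope"], "direction": "over"})}
        with pytest.raises(ValueError, match="missing from annotation"):
            region_frequencies(calls, ann)

    def test_disjoint_universe_rejected(self):
        ann = annotation_for([("1", "1p1")])
        calls = {"c1": pd.DataFrame({"probe_id": ["alien1"], "direction": "over"})}
        with pytest.raises(ValueError, match="chip mismatch"):
            region_frequencies(calls, ann)


class TestParticipationPercent:
    def _freq(self, over, ftp, n):
        table = pd.DataFrame(
            {"chromosome": "1", "band": ["1p1"], "start": 0, "ftp": [ftp],
             "over_total": [over], "down_total": [0]}
        )
        return RegionFrequencyTable(table=table, per_cancer=pd.DataFrame(), n_cancers=n)

    def test_maximum_is_100(self):
        scores = participation_percent(self._freq(over=30, ftp=10, n=3))
        assert scores["percent_over"].iloc[0] == pytest.approx(100.0)

    def test_zero(self):
        assert participation_percent(self._freq(0, 10, 3))["percent_over"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        # 100 * 6 / (3 * 10) = 20%
        assert participation_percent(self._freq(6, 10, 3))["percent_over"].iloc[0] == pytest.approx(20.0)

    def test_pooled_denominator(self):
        scores = participation_percent(self._freq(6, 10, 3), denominator="pooled")
        assert scores["percent_over"].iloc[0] == pytest.approx(60.0)

    def test_ftp_zero_omitted(self):
        freq = self._freq(0, 0, 3)
        assert len(participation_percent(freq)) == 0

    def test_monotone_in_over_calls(self):
        a = participation_percent(self._freq(5, 10, 3))["percent_over"].iloc[0]
        b = participation_percent(self._freq(6, 10, 3))["percent_over"].iloc[0]
        assert b > a


class TestSelectPcsrs:
    def _scores(self, percents, chrom="1"):
        return pd.DataFrame(
            {"chromosome": chrom, "band": [f"{chrom}b{i}" for i in range(len(percents))],
             "start": np.arange(len(percents)) * 100, "percent_over": percents,
             "percent_down": 0.0}
        )

    def test_exactly_five(self):
        pcsrs = select_pcsrs(self._scores([1, 2, 3, 4, 5]))
        assert len(pcsrs.over["1"]) == 5

    def test_fewer_than_five(self):
        pcsrs = select_pcsrs(self._scores([1, 2, 3]))
        assert len(pcsrs.over["1"]) == 3

    def test_tie_at_rank_matches_sort_oracle(self):
        percents = [9, 8, 7, 6, 5, 5, 4, 3]
        scores = self._scores(percents)
        pcsrs = select_pcsrs(scores, k=5)
        oracle = sorted(
            scores.itertuples(index=False),
            key=lambda r: (-r.percent_over, r.start, r.band),
        )[:5]
        assert [b for b, _ in pcsrs.over["1"]] == [r.band for r in oracle]
        # the genomically earlier of the two tied 5s wins
        assert pcsrs.over["1"][-1][0] == "1b4"

    def test_per_chromosome_grouping(self):
        scores = pd.concat([self._scores([1, 2], "1"), self._scores([3, 4], "2")])
        pcsrs = select_pcsrs(scores)
        assert set(pcsrs.over) == {"1", "2"}


class TestChromosomeChiSquare:
    def _freq(self, observed, fctp):
        table = pd.DataFrame(
            {"chromosome": [str(i + 1) for i in range(len(observed))],
             "band": [str(i + 1) for i in range(len(observed))],
             "start": 0, "ftp": fctp, "over_total": observed, "down_total": 0}
        )
        return RegionFrequencyTable(table=table, per_cancer=pd.DataFrame(),
                                    n_cancers=1, level="chromosome")

    def test_proportional_gives_zero(self):
        stat, df, p = chromosome_chi_square(self._freq([10, 20, 30], [100, 200, 300]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_example(self):
        stat, df, p = chromosome_chi_square(self._freq([10, 0], [50, 50]))
        assert stat == pytest.approx(10.0)  # (10-5)^2/5 + (0-5)^2/5
        assert df == 1

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="merge or exclude"):
            chromosome_chi_square(self._freq([10, 5], [100, 0]))

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            chromosome_chi_square(self._freq([10], [100]))


def test_chromosome_frequencies_sum_bands(rng):
    ann = annotation_for([("1", "1p1"), ("1", "1q1"), ("2", "2p1")], probes_per_band=6)
    chosen = rng.choice(ann["probe_id"], size=8, replace=False)
    calls = {"c1": pd.DataFrame({"probe_id": chosen, "direction": "over"})}
    freq = region_frequencies(calls, ann)
    chrom = chromosome_frequencies(freq)
    by_band = freq.table.groupby("chromosome")[["ftp", "over_total"]].sum()
    for _, row in chrom.table.iterrows():
        assert row["ftp"] == by_band.loc[row["chromosome"], "ftp"]
        assert row["over_total"] == by_band.loc[row["chromosome"], "over_total"]
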