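"""SSR detection (MISA-style) and TE hit filtering."""

import numpy as np
import pandas as pd
import pytest

from marseq.repeats import find_ssrs, read_blast_tab, ssr_class_summary, te_hit_filter
from marseq.synthetic import make_te_hits

from oracles import ssr_oracle, te_filter_oracle

from conftest import random_dna


def simple(records):
    return [(r.unit, r.n_reps, r.start, r.end) for r in records if r.kind == "simple"]


class TestFindSSRs:
    def test_tetranucleotide_in_random_flanks(self, rng):
        flank1, flank2 = random_dna(rng, 60), random_dna(rng, 60)
        seq = flank1 + "ACGT" * 5 + flank2
        recs = [r for r in find_ssrs(seq) if r.kind == "simple"]
        # the planted run is recovered; a chance flank base may extend the
        # periodic region and rotate the reported unit frame
        rotations = {"ACGT"[i:] + "ACGT"[:i] for i in range(4)}
        assert any(
            r.unit in rotations
            and r.n_reps >= 5
            and min(r.end, 80) - max(r.start, 60) >= 16
            for r in recs
        )

    def test_pentanucleotide_telomeric_unit(self):
        seq = "GGC" + "TTAGG" * 5 + "CCA"
        recs = simple(find_ssrs(seq))
        assert recs == [("TTAGG", 5, 3, 28)]

    def test_compound_grouping_within_interruption(self):
        seq = "AT" * 6 + "G" * 40 + "ACGT" * 5
        recs = find_ssrs(seq)
        kinds = [(r.kind, r.unit) for r in recs]
        assert ("simple", "AT") in kinds and ("simple", "ACGT") in kinds
        compound = [r for r in recs if r.kind == "compound"]
        assert len(compound) == 1
        assert compound[0].spacers == (40,)
        assert len(compound[0].members) == 2

    def test_no_compound_beyond_interruption(self):
        seq = "AT" * 6 + "G" * 150 + "ACGT" * 5
        assert all(r.kind == "simple" for r in find_ssrs(seq))

    def test_run_maximality_single_record(self):
        seq = "CCG" + "AT" * 7 + "GCC"
        recs = simple(find_ssrs(seq))
        assert recs == [("AT", 7, 3, 17)]

    def test_tandem_of_smaller_unit_reported_once(self):
        # (ATAT)n is (AT)2n: only the dinucleotide record appears
        seq = "G" * 5 + "AT" * 10 + "G" * 5
        recs = find_ssrs(seq)
        assert simple(recs) == [("AT", 10, 5, 25)]

    def test_mononucleotide_runs_excluded(self):
        assert find_ssrs("G" * 30 + "A" * 30) == []

    def test_every_span_revalidates_as_perfect_tandem(self, rng):
        seq = random_dna(rng, 3000, at=0.8)
        for r in find_ssrs(seq, min_reps=3):
            if r.kind == "simple":
                assert seq[r.start : r.end] == r.unit * r.n_reps

    def test_same_unit_size_spans_never_overlap(self):
        # adjacent periodic regions of the same size, one base apart
        seq = "ACACACACAC" + "GCGCGCGCG"
        recs = simple(find_ssrs(seq, min_reps=4))
        by_size: dict[int, list] = {}
        for unit, reps, start, end in recs:
            by_size.setdefault(len(unit), []).append((start, end))
        for spans in by_size.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(150):
            seq = random_dna(rng, 400, at=0.85)
            got = simple(find_ssrs(seq, min_reps=3))
            assert got == ssr_oracle(seq, min_reps=3)

    def test_background_rejection_at_default_threshold(self, rng):
        # uniform random sequence virtually never reaches 5 perfect copies
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        n_background = len(simple(find_ssrs(seq)))
        assert n_background <= 5

    def test_planted_runs_recovered_exactly(self, rng):
        background = "".join(rng.choice(list("ACGT"), size=5000))
        plants = [("TATT", 5, 500), ("TGAA", 6, 1500), ("TACCAA", 5, 3000)]
        seq = background
        for unit, reps, pos in plants:
            run = unit * reps
            # guard bases prevent chance extension into the flanks
            left = next(b for b in "ACGT" if b != unit[-1])
            right = next(b for b in "ACGT" if b != unit[0])
            seq = seq[: pos - 1] + left + run + right + seq[pos + len(run) + 1 :]
        recs = simple(find_ssrs(seq))
        for unit, reps, pos in plants:
            assert (unit, reps, pos, pos + len(unit) * reps) in recs


class TestSSRSummary:
    def test_counts_per_unit(self):
        recs = find_ssrs("TTAGG" * 5 + "C" * 200 + "TTAGG" * 5)
        summary = ssr_class_summary(recs)
        row = summary[summary["unit"] == "TTAGG"]
        assert row["count"].item() == 2
        assert row["unit_size"].item() == 5

    def test_empty_summary(self):
        assert ssr_class_summary([]).empty

    def test_planted_frequencies_rank_correctly(self, rng):
        recs = []
        for unit, count in (("TATT", 30), ("TGAA", 20)):
            for i in range(count):
                recs.extend(
                    r
                    for r in find_ssrs("G" + unit * 5 + "C", seq_id=f"{unit}{i}")
                    if r.kind == "simple"
                )
        summary = ssr_class_summary(recs)
        tetra = summary[summary["unit_size"] == 4].reset_index(drop=True)
        assert list(tetra["unit"]) == ["TATT", "TGAA"]
        assert list(tetra["count"]) == [30, 20]


class TestTEFilter:
    def hits_frame(self, rows):
        return pd.DataFrame(
            [
                {
                    "qseqid": "L1Bm",
                    "sseqid": "chr1",
                    "pident": pident,
                    "length": length,
                    "mismatch": 0,
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": length,
                    "sstart": sstart,
                    "send": sstart + length - 1,
                    "evalue": 0.0,
                    "bitscore": 1.0,
                }
                for pident, length, sstart in rows
            ]
        )

    def test_threshold_semantics_with_boundaries(self):
        hits = self.hits_frame(
            [(95.0, 150, 1), (95.0, 80, 1), (85.0, 200, 1), (90.0, 100, 1)]
        )
        kept, _ = te_hit_filter(hits)
        assert list(kept["pident"]) == [95.0, 90.0]  # boundary hit retained

    def test_occupancy_merges_overlapping_spans(self):
        # spans 0-150 and 100-250 on the same target: 250 bp, not 300
        hits = self.hits_frame([(95.0, 150, 1), (95.0, 150, 101)])
        _, per_te = te_hit_filter(hits)
        assert per_te["L1Bm"] == 250

    def test_monotone_in_both_thresholds(self, rng):
        rows = [
            (float(rng.uniform(70, 100)), int(rng.integers(50, 300)), int(rng.integers(1, 1000)))
            for _ in range(200)
        ]
        hits = self.hits_frame(rows)
        n_base = len(te_hit_filter(hits)[0])
        assert len(te_hit_filter(hits, min_identity=95)[0]) <= n_base
        assert len(te_hit_filter(hits, min_length=200)[0]) <= n_base

    def test_matches_predicate_oracle(self, rng):
        rows = [
            (float(rng.uniform(70, 100)), int(rng.integers(50, 300)), 1)
            for _ in range(300)
        ]
        hits = self.hits_frame(rows)
        kept, _ = te_hit_filter(hits)
        expected_idx = te_filter_oracle([(p, l) for p, l, _ in rows])
        assert list(kept["pident"]) == [rows[i][0] for i in expected_idx]

    def test_synthetic_table_round_trip(self, tmp_path, rng):
        hits, n_pass = make_te_hits(rng)
        path = tmp_path / "hits.tsv"
        hits.to_csv(path, sep="\t", header=False, index=False)
        kept, per_te = te_hit_filter(read_blast_tab(path))
        assert len(kept) == n_pass
        assert (per_te > 0).all()
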