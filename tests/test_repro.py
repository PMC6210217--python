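"""False-positive/false-negative counters, signatures, and volcano classes."""

import numpy as np
import pandas as pd
import pytest

from diaforge.core import ValidationError
from diaforge.repro import (
    ComparisonSet,
    count_false_negatives,
    count_false_positives,
    extract_signature,
    volcano_table,
)


def _cs(records):
    return ComparisonSet(
        pd.DataFrame(records, columns=["protein", "population", "batch", "log2fc", "adj_p"])
    )


def brute_force_fp(table, population, batch, alpha, fc=2.0):
    """Independent re-scan of the comparison table."""
    lfc = np.log2(fc)
    sub = table[table.population == population]
    focal = sub[sub.batch == batch]
    n = 0
    for _, row in focal.iterrows():
        if not (row.adj_p < alpha and abs(row.log2fc) >= lfc):
            continue
        others = sub[(sub.batch != batch) & (sub.protein == row.protein)]
        if row.log2fc > 0 and (others.log2fc <= -lfc).any():
            n += 1
        elif row.log2fc < 0 and (others.log2fc >= lfc).any():
            n += 1
    return n


def brute_force_fn(table, population, batch, alpha, fc=2.0):
    lfc = np.log2(fc)
    sub = table[table.population == population]
    focal = sub[sub.batch == batch]
    n = 0
    for _, row in focal.iterrows():
        consensus = np.sign(sub[sub.protein == row.protein].log2fc.mean())
        if consensus != 0 and row.log2fc * consensus >= lfc and row.adj_p >= alpha:
            n += 1
    return n


class TestFalsePositives:
    def test_reversed_direction_counted(self):
        cs = _cs(
            [
                ("p1", "A", "PS1", np.log2(2.1), 0.001),
                ("p1", "A", "PS2", np.log2(0.45), 0.5),
            ]
        )
        assert count_false_positives(cs, "A", "PS1", 0.05) == 1

    def test_same_direction_not_counted(self):
        cs = _cs(
            [("p1", "A", f"PS{i}", np.log2(v), 0.001) for i, v in enumerate([2.1, 1.8, 2.3, 2.0], 1)]
        )
        assert count_false_positives(cs, "A", "PS1", 0.05) == 0

    def test_single_batch_rejected(self):
        cs = _cs([("p1", "A", "PS1", 1.0, 0.01)])
        with pytest.raises(ValidationError):
            count_false_positives(cs, "A", "PS1", 0.05)


class TestFalseNegatives:
    def test_large_fc_not_significant_counted(self):
        cs = _cs(
            [
                ("p1", "A", "PS1", np.log2(2.2), 0.001),
                ("p1", "A", "PS2", np.log2(2.1), 0.001),
                ("p1", "A", "PS3", np.log2(2.2), 0.2),
            ]
        )
        assert count_false_negatives(cs, "A", "PS3", 0.05) == 1

    def test_below_fc_threshold_not_counted(self):
        cs = _cs(
            [
                ("p1", "A", "PS1", np.log2(2.2), 0.001),
                ("p1", "A", "PS3", np.log2(1.5), 0.2),
            ]
        )
        assert count_false_negatives(cs, "A", "PS3", 0.05) == 0

    def test_significant_not_counted(self):
        cs = _cs(
            [
                ("p1", "A", "PS1", np.log2(2.2), 0.001),
                ("p1", "A", "PS3", np.log2(2.2), 0.01),
            ]
        )
        assert count_false_negatives(cs, "A", "PS3", 0.05) == 0

    def test_alpha_widening_never_increases_fn(self):
        rng = np.random.default_rng(8)
        recs = []
        for p in range(30):
            for b in ("PS1", "PS2", "PS3", "PS4"):
                recs.append((f"p{p}", "A", b, rng.normal(0, 1.5), rng.uniform(0, 0.2)))
        cs = _cs(recs)
        for b in ("PS1", "PS2", "PS3", "PS4"):
            assert count_false_negatives(cs, "A", b, 0.05) <= count_false_negatives(
                cs, "A", b, 0.01
            )


class TestSignatures:
    def test_all_batches_required_direction(self):
        recs = [("up1", "A", f"PS{i}", 1.2, 0.001) for i in (1, 2, 3, 4)]
        recs += [("down1", "A", f"PS{i}", -1.4, 0.001) for i in (1, 2, 3, 4)]
        recs += [("part", "A", f"PS{i}", 1.2, 0.001 if i < 4 else 0.2) for i in (1, 2, 3, 4)]
        up, down = extract_signature(_cs(recs), "A", 0.05, 2.0)
        assert up == ["up1"] and down == ["down1"]

    def test_missing_batch_rejected(self):
        recs = [("p1", "A", "PS1", 1.2, 0.001), ("p1", "A", "PS2", 1.2, 0.001),
                ("p2", "A", "PS1", 1.2, 0.001)]
        with pytest.raises(ValidationError, match="missing batches"):
            extract_signature(_cs(recs), "A", 0.05)

    def test_mutually_exclusive_roles(self):
        """A protein cannot be FP-counted, FN-counted and signature member at once."""
        rng = np.random.default_rng(9)
        recs = []
        for p in range(40):
            for b in ("PS1", "PS2"):
                recs.append((f"p{p}", "A", b, rng.normal(0, 1.5), rng.uniform(0, 0.1)))
        cs = _cs(recs)
        table = cs.table
        up, down = extract_signature(cs, "A", 0.05)
        sig = set(up) | set(down)
        lfc = np.log2(2.0)
        for b in ("PS1", "PS2"):
            focal = table[(table.batch == b)]
            for _, row in focal.iterrows():
                roles = 0
                others = table[(table.batch != b) & (table.protein == row.protein)]
                is_sig = row.adj_p < 0.05 and abs(row.log2fc) >= lfc
                if is_sig and (
                    (row.log2fc > 0 and (others.log2fc <= -lfc).any())
                    or (row.log2fc < 0 and (others.log2fc >= lfc).any())
                ):
                    roles += 1
                consensus = np.sign(table[table.protein == row.protein].log2fc.mean())
                if consensus != 0 and row.log2fc * consensus >= lfc and row.adj_p >= 0.05:
                    roles += 1
                if row.protein in sig and roles:
                    pytest.fail(f"{row.protein} has conflicting roles in {b}")
                assert roles <= 1


class TestBruteForceEquivalence:
    def test_counts_match_exhaustive_rescan(self):
        rng = np.random.default_rng(10)
        recs = []
        for p in range(50):
            for pop in ("A", "B"):
                for b in ("PS1", "PS2", "PS3", "PS4"):
                    recs.append((f"p{p}", pop, b, rng.normal(0, 1.2), rng.uniform(0, 0.15)))
        cs = _cs(recs)
        for pop in ("A", "B"):
            for b in ("PS1", "PS2", "PS3", "PS4"):
                for alpha in (0.01, 0.05):
                    assert count_false_positives(cs, pop, b, alpha) == brute_force_fp(
                        cs.table, pop, b, alpha
                    )
                    assert count_false_negatives(cs, pop, b, alpha) == brute_force_fn(
                        cs.table, pop, b, alpha
                    )


class TestVolcano:
    def test_class_labels(self):
        cs = _cs(
            [
                ("p1", "A", "PS1", np.log2(2.5), 0.005),
                ("p2", "A", "PS1", np.log2(2.5), 0.03),
                ("p3", "A", "PS1", np.log2(1.1), 0.5),
            ]
        )
        vt = volcano_table(cs, "A", "PS1").set_index("protein")
        assert vt.loc["p1", "class"] == "significant p<0.01 elevated"
        assert vt.loc["p2", "class"] == "significant p<0.05 only elevated"
        assert vt.loc["p3", "class"] == "not significant"

    def test_fc_clipping(self):
        cs = _cs([("p1", "A", "PS1", 3.0, 0.001)])  # FC = 8
        vt = volcano_table(cs, "A", "PS1")
        assert vt.loc[0, "log2fc"] == pytest.approx(2.0)  # clipped at FC 4
        assert bool(vt.loc[0, "clipped"]) is True
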