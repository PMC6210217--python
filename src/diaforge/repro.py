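"""Cross-sampling reproducibility statistics and population proteome signatures.

Each population is compared one-vs-rest within every sampling batch; a protein
is *significant* in a (population, batch) when its BH-adjusted p falls below
alpha and its fold change is at least the FC threshold.  False positives are
significant proteins whose fold change reverses direction beyond the
reciprocal threshold in another batch; false negatives exceed the FC threshold
in the consensus direction but miss significance.  A population's signature is
the set of proteins significantly elevated (reduced) in every batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError


@dataclass
class ComparisonSet:
    """One record per (protein, population, sampling_batch)."""

    table: pd.DataFrame  # protein, population, batch, log2fc, adj_p

    def __post_init__(self):
        required = {"protein", "population", "batch", "log2fc", "adj_p"}
        if not required.issubset(self.table.columns):
            raise ValidationError(f"comparison table must have columns {sorted(required)}")
        dup = self.table.duplicated(subset=["protein", "population", "batch"])
        if dup.any():
            raise ValidationError("one record per (protein, population, batch) required")

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["batch"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["population"].unique())

    def subset(self, population: str) -> pd.DataFrame:
        if population not in set(self.table["population"]):
            raise ValidationError(f"unknown population {population!r}")
        return self.table[self.table["population"] == population]


def _significant(df: pd.DataFrame, alpha: float, fc_threshold: float) -> pd.Series:
    return (df["adj_p"] < alpha) & (np.abs(df["log2fc"]) >= np.log2(fc_threshold))


def count_false_positives(
    cs: ComparisonSet, population: str, batch: str, alpha: float, fc_threshold: float = 2.0
) -> int:
    """Significant proteins in the focal batch whose FC reverses in another batch.

    A protein counts when it is significant in the focal batch and its fold
    change in ANY other batch lies beyond the reciprocal threshold in the
    opposite direction (e.g. FC ≥ 2 here but ≤ 0.5 elsewhere).
    """
    sub = cs.subset(population)
    if batch not in set(sub["batch"]):
        raise ValidationError(f"unknown batch {batch!r}")
    if len(set(sub["batch"])) < 2:
        raise ValidationError("false-positive counting needs at least 2 batches")
    focal = sub[sub["batch"] == batch].set_index("protein")
    others = sub[sub["batch"] != batch]
    lfc_thr = np.log2(fc_threshold)
    count = 0
    for protein, row in focal.iterrows():
        if not (row["adj_p"] < alpha and abs(row["log2fc"]) >= lfc_thr):
            continue
        other_fc = others[others["protein"] == protein]["log2fc"]
        if row["log2fc"] > 0:
            reversed_ = (other_fc <= -lfc_thr).any()
        else:
            reversed_ = (other_fc >= lfc_thr).any()
        if reversed_:
            count += 1
    return count


def count_false_negatives(
    cs: ComparisonSet, population: str, batch: str, alpha: float, fc_threshold: float = 2.0
) -> int:
    """Proteins beyond the FC threshold in the consensus direction but not significant.

    The consensus direction is the sign of the mean log2 fold change across
    batches.
    """
    sub = cs.subset(population)
    if batch not in set(sub["batch"]):
        raise ValidationError(f"unknown batch {batch!r}")
    if len(set(sub["batch"])) < 2:
        raise ValidationError("false-negative counting needs at least 2 batches")
    lfc_thr = np.log2(fc_threshold)
    consensus = sub.groupby("protein")["log2fc"].mean()
    focal = sub[sub["batch"] == batch].set_index("protein")
    count = 0
    for protein, row in focal.iterrows():
        direction = np.sign(consensus.get(protein, 0.0))
        if direction == 0:
            continue
        if row["log2fc"] * direction >= lfc_thr and row["adj_p"] >= alpha:
            count += 1
    return count


def extract_signature(
    cs: ComparisonSet, population: str, alpha: float, fc_threshold: float = 2.0
) -> tuple[list[str], list[str]]:
    """(up, down) lists of proteins significant in EVERY batch in one direction."""
    sub = cs.subset(population)
    batches = sorted(set(sub["batch"]))
    lfc_thr = np.log2(fc_threshold)
    up: list[str] = []
    down: list[str] = []
    for protein, grp in sub.groupby("protein"):
        present = set(grp["batch"])
        if present != set(batches):
            raise ValidationError(
                f"protein {protein!r} missing batches {sorted(set(batches) - present)}"
            )
        sig_up = ((grp["adj_p"] < alpha) & (grp["log2fc"] >= lfc_thr)).all()
        sig_down = ((grp["adj_p"] < alpha) & (grp["log2fc"] <= -lfc_thr)).all()
        if sig_up:
            up.append(protein)
        elif sig_down:
            down.append(protein)
    return sorted(up), sorted(down)


@dataclass
class ReproReport:
    counts: pd.DataFrame  # population, batch, alpha, false_positives, false_negatives
    signatures: dict[str, tuple[list[str], list[str]]]


def repro_report(
    cs: ComparisonSet,
    alphas: tuple[float, ...] = (0.05, 0.01),
    fc_threshold: float = 2.0,
    signature_alpha: float = 0.05,
) -> ReproReport:
    rows = []
    for population in cs.populations:
        for batch in cs.batches:
            for alpha in alphas:
                rows.append(
                    {
                        "population": population,
                        "batch": batch,
                        "alpha": alpha,
                        "false_positives": count_false_positives(
                            cs, population, batch, alpha, fc_threshold
                        ),
                        "false_negatives": count_false_negatives(
                            cs, population, batch, alpha, fc_threshold
                        ),
                    }
                )
    signatures = {
        pop: extract_signature(cs, pop, signature_alpha, fc_threshold)
        for pop in cs.populations
    }
    return ReproReport(counts=pd.DataFrame(rows), signatures=signatures)


def volcano_table(
    cs: ComparisonSet,
    population: str,
    batch: str,
    fc_threshold: float = 2.0,
    fc_clip: float = 4.0,
) -> pd.DataFrame:
    """Per-protein volcano coordinates with the standard class labels.

    Classes: "significant p<0.01 elevated/reduced", "significant p<0.05 only
    elevated/reduced", "not significant".  Fold changes beyond ±fc_clip are
    clipped in plot coordinates and flagged.
    """
    sub = cs.subset(population)
    focal = sub[sub["batch"] == batch]
    lfc_thr = np.log2(fc_threshold)
    lfc_clip = np.log2(fc_clip)
    rows = []
    for r in focal.itertuples(index=False):
        direction = "elevated" if r.log2fc > 0 else "reduced"
        if r.adj_p < 0.01 and abs(r.log2fc) >= lfc_thr:
            label = f"significant p<0.01 {direction}"
        elif r.adj_p < 0.05 and abs(r.log2fc) >= lfc_thr:
            label = f"significant p<0.05 only {direction}"
        else:
            label = "not significant"
        clipped = abs(r.log2fc) > lfc_clip
        rows.append(
            {
                "protein": r.protein,
                "log2fc": float(np.clip(r.log2fc, -lfc_clip, lfc_clip)),
                "neg_log10_adj_p": float(-np.log10(max(r.adj_p, 1e-300))),
                "class": label,
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows)
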