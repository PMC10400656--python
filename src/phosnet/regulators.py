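"""Prior regulator lists and classifier-evaluation utilities.

Only proteins annotated as kinases or phosphatases may act as regulators
in the network.  Annotations can come from a classifier (with a
probability per protein), from HMM searches, from orthology, or from the
user; this module loads such lists, picks a probability threshold by the
cost rule Cost = FDR - 3 TPR, and summarizes how annotation sources
overlap and how a set of proteins splits into families.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

KINASE = "KINASE"
PHOSPHATASE = "PHOSPHATASE"
ROLES = (KINASE, PHOSPHATASE)
SOURCES = ("neural", "hmm", "ortholog", "user")


@dataclass
class RegulatorList:
    """protein_id -> (role, source); ids unique, roles mandatory."""

    entries: pd.DataFrame  # index protein_id, columns role, source

    def __post_init__(self) -> None:
        if self.entries.index.has_duplicates:
            raise ValueError("duplicate protein ids in regulator list")
        bad = ~self.entries["role"].isin(ROLES)
        if bad.any():
            raise ValueError(
                f"unknown role(s): {sorted(self.entries.loc[bad, 'role'].unique())}"
            )

    @property
    def proteins(self) -> set:
        return set(self.entries.index)

    def role_of(self, protein_id) -> str:
        return self.entries.loc[protein_id, "role"]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, protein_id) -> bool:
        return protein_id in self.entries.index


def load_regulator_list(source) -> RegulatorList:
    """Load a regulator TSV (protein_id, role[, source]).

    Roles are upper-cased; duplicate ids with the same role collapse to
    one entry, conflicting roles are an error.
    """
    df = pd.read_csv(source, sep="\t")
    for col in ("protein_id", "role"):
        if col not in df.columns:
            raise ValueError(f"regulator list missing column {col!r}")
    if "source" not in df.columns:
        df["source"] = "user"
    df["role"] = df["role"].astype(str).str.upper()
    bad = ~df["role"].isin(ROLES)
    if bad.any():
        raise ValueError(f"unknown role(s): {sorted(df.loc[bad, 'role'].unique())}")
    df = df.drop_duplicates(subset=["protein_id", "role"])
    conflict = df["protein_id"].duplicated(keep=False)
    if conflict.any():
        raise ValueError(
            "conflicting roles for protein(s): "
            f"{sorted(df.loc[conflict, 'protein_id'].unique())}"
        )
    return RegulatorList(df.set_index("protein_id")[["role", "source"]])


def regulator_list_from_records(records) -> RegulatorList:
    """Build a RegulatorList from (protein_id, role[, source]) tuples."""
    rows = [
        (r[0], str(r[1]).upper(), r[2] if len(r) > 2 else "user") for r in records
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "role", "source"])
    return RegulatorList(df.drop_duplicates("protein_id").set_index("protein_id"))


# ---------------------------------------------------------------------------
# Threshold scan


@dataclass
class ThresholdScan:
    """Per-threshold TPR/FDR/cost and the selected threshold.

    ``table`` has columns threshold, tp, fp, fn, tpr, fdr, cost;
    ``selected`` is the largest threshold attaining the minimum cost.
    """

    table: pd.DataFrame
    selected: float

    @property
    def min_cost(self) -> float:
        return float(self.table["cost"].min())


def threshold_grid(n: int = 100) -> np.ndarray:
    """n evenly spaced thresholds 0.01 .. 1.00 (endpoints of (0, 1] closed
    on the right; predictions count positive at probability >= threshold)."""
    return np.round(np.linspace(1.0 / n, 1.0, n), 10)


def select_probability_threshold(
    preds: pd.DataFrame, truth: set, n_thresholds: int = 100
) -> ThresholdScan:
    """Scan probability thresholds for one predicted family.

    ``preds`` needs columns protein_id and probability.  At each
    threshold the positives are the predictions with probability >= the
    threshold; TPR = TP/(TP+FN) against ``truth`` and FDR = FP/(FP+TP)
    (0 when there are no positives); Cost = FDR - 3 TPR.  The selected
    threshold is the largest one attaining the minimal cost (most
    stringent at equal cost).
    """
    if not truth:
        raise ValueError("empty ground-truth set: TPR undefined")
    if preds.empty:
        raise ValueError("empty prediction table")
    probs = preds["probability"].to_numpy(dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    ids = preds["protein_id"].to_numpy()
    is_true = np.isin(ids, list(truth))
    n_truth = len(truth)
    rows = []
    for thr in threshold_grid(n_thresholds):
        positive = probs >= thr
        tp = int((positive & is_true).sum())
        fp = int((positive & ~is_true).sum())
        fn = n_truth - tp
        tpr = tp / (tp + fn)
        fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
        rows.append((thr, tp, fp, fn, tpr, fdr, fdr - 3.0 * tpr))
    table = pd.DataFrame(
        rows, columns=["threshold", "tp", "fp", "fn", "tpr", "fdr", "cost"]
    )
    min_cost = table["cost"].min()
    selected = float(table.loc[table["cost"] == min_cost, "threshold"].max())
    return ThresholdScan(table, selected)


# ---------------------------------------------------------------------------
# Annotation overlap and composition


def overlap_stats(named_sets: dict) -> dict:
    """Intersection regions and pairwise sharing percentages.

    Returns ``{"regions": {frozenset(labels): count}, "pairwise":
    DataFrame}`` where regions are the exclusive upset-style cells over
    all sets, and for each ordered pair (A, B) the pairwise table gives
    ``shared_pct`` = 100 |A∩B| / |A| and ``missed_pct`` = 100 |A\\B| / |A|,
    rounded to one decimal.  Percentages of an empty A are NaN.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    labels = list(named_sets)
    sets = {k: set(v) for k, v in named_sets.items()}
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for item in universe:
        members = frozenset(k for k in labels if item in sets[k])
        regions[members] = regions.get(members, 0) + 1
    rows = []
    for a in labels:
        for b in labels:
            if a == b:
                continue
            na = len(sets[a])
            if na == 0:
                shared = missed = float("nan")
            else:
                inter = len(sets[a] & sets[b])
                shared = round(100.0 * inter / na, 1)
                missed = round(100.0 * (na - inter) / na, 1)
            rows.append((a, b, len(sets[a] & sets[b]), shared, missed))
    pairwise = pd.DataFrame(
        rows, columns=["set_a", "set_b", "intersection", "shared_pct", "missed_pct"]
    )
    return {"regions": regions, "pairwise": pairwise}


def class_composition(labeled_ids: dict) -> pd.DataFrame:
    """Family counts and percentages (integer half-up + one decimal)."""
    if not labeled_ids:
        raise ValueError("empty label map")
    counts = pd.Series(labeled_ids).value_counts()
    total = int(counts.sum())
    pct = 100.0 * counts / total
    pct_int = pct.map(
        lambda x: int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    )
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "pct": pct_int,
            "pct_1dp": pct.round(1),
        }
    )
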