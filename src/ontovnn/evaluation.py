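"""Cross-validation fold construction and correlation metrics.

Three fold schemes match three experimental questions:

* ``standard`` — random partition of (cell, drug) pairs: how well are known
  drugs predicted on known cell lines for unseen combinations;
* ``lelo`` (leave-lines-out) — partition of cell lines: drug repositioning,
  predictions for never-seen cell lines;
* ``leco`` (leave-compounds-out) — partition of drugs: in-silico sensitivity
  for never-seen compounds.

A validation subset is always drawn from the training portion, respecting
the unit of the scheme (whole cell lines / whole drugs under lelo / leco).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ResponsePairSet

__all__ = ["FoldPlan", "MetricReport", "make_folds", "overall_metrics", "per_drug_metrics"]

#: per-drug correlations need at least this many pairs to be scored
MIN_PAIRS_PER_DRUG = 3
HIGH_CONFIDENCE_THRESHOLD = 0.5


@dataclass
class FoldPlan:
    scheme: str
    K: int
    seed: int
    folds: list[dict[str, np.ndarray]]  # keys: train, val, test (pair indices)

    def __iter__(self):
        return iter(self.folds)


@dataclass
class MetricReport:
    pearson: float
    spearman: float
    undefined: bool = False
    per_drug: pd.DataFrame | None = None  # columns: drug, correlation, n, scored
    high_confidence_fraction: float | None = None


def _pair_keys(pairs: ResponsePairSet) -> np.ndarray:
    """Row-order-independent sort keys for the pair records."""
    rec = pairs.records
    keys = (
        rec["cell"].astype(str)
        + "\x00" + rec["drug"].astype(str)
        + "\x00" + rec["study"].astype(str)
        + "\x00" + rec["response"].map("{:.12g}".format)
    )
    return keys.to_numpy()


def make_folds(
    pairs: ResponsePairSet,
    scheme: str = "standard",
    K: int = 5,
    seed: int = 0,
    validation_fraction: float = 0.1,
) -> FoldPlan:
    """Partition the pairs into K test folds according to the scheme.

    The partition is deterministic under a fixed seed and independent of the
    input row order (records/units are sorted before shuffling).  Validation
    indices are carved out of each fold's training portion; under lelo/leco
    whole units are held out so validation cells/drugs never appear in the
    fold's training set either.
    """
    rng = np.random.default_rng(seed)
    rec = pairs.records
    n = len(rec)

    if scheme == "standard":
        order = np.argsort(_pair_keys(pairs), kind="stable")
        shuffled = order[rng.permutation(n)]
        groups = np.array_split(shuffled, K)
        unit_of_pair = None
    elif scheme in ("lelo", "leco"):
        col = "cell" if scheme == "lelo" else "drug"
        units = np.array(sorted(rec[col].unique()))
        if K > len(units):
            raise ValueError(f"K={K} exceeds the number of {col} units ({len(units)})")
        units = units[rng.permutation(len(units))]
        unit_groups = np.array_split(units, K)
        unit_of_pair = rec[col].to_numpy()
        groups = [
            np.flatnonzero(np.isin(unit_of_pair, ug)) for ug in unit_groups
        ]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "standard" and K > n:
        raise ValueError(f"K={K} exceeds the number of pairs ({n})")

    folds = []
    for i, test in enumerate(groups):
        trainval = np.concatenate([g for j, g in enumerate(groups) if j != i])
        if scheme == "standard":
            tv = trainval[rng.permutation(len(trainval))]
            n_val = int(round(validation_fraction * len(tv)))
            val, train = tv[:n_val], tv[n_val:]
        else:
            tv_units = np.array(sorted(set(unit_of_pair[trainval])))
            tv_units = tv_units[rng.permutation(len(tv_units))]
            n_val_units = int(round(validation_fraction * len(tv_units)))
            val_units = set(tv_units[:n_val_units])
            in_val = np.isin(unit_of_pair[trainval], list(val_units))
            val, train = trainval[in_val], trainval[~in_val]
        folds.append({"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)})
    return FoldPlan(scheme=scheme, K=K, seed=seed, folds=folds)


def overall_metrics(measured, predicted) -> MetricReport:
    """Pearson and Spearman correlation between measured and predicted values.

    Zero-variance input is flagged as undefined rather than silently reported
    as 0.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(m) == 0 or np.ptp(p) == 0:
        return MetricReport(pearson=np.nan, spearman=np.nan, undefined=True)
    pear = stats.pearsonr(m, p).statistic
    spear = stats.spearmanr(m, p).statistic
    return MetricReport(pearson=float(pear), spearman=float(spear))


def per_drug_metrics(records: pd.DataFrame) -> MetricReport:
    """Per-drug Pearson correlations and the high-confidence drug fraction.

    ``records`` needs columns ``drug``, ``measured``, ``predicted``.  Drugs
    with fewer than 3 pairs (or zero variance) are flagged, not scored, and
    excluded from the fraction's denominator.  The per-drug table is returned
    in waterfall order (descending correlation).
    """
    rows = []
    for drug, grp in records.groupby("drug", sort=True):
        n = len(grp)
        if n < MIN_PAIRS_PER_DRUG:
            rows.append((drug, np.nan, n, False))
            continue
        m = grp["measured"].to_numpy(dtype=float)
        p = grp["predicted"].to_numpy(dtype=float)
        if np.ptp(m) == 0 or np.ptp(p) == 0:
            rows.append((drug, np.nan, n, False))
            continue
        rows.append((drug, float(stats.pearsonr(m, p).statistic), n, True))
    table = pd.DataFrame(rows, columns=["drug", "correlation", "n", "scored"])
    table = table.sort_values("correlation", ascending=False, na_position="last").reset_index(
        drop=True
    )
    scored = table[table["scored"]]
    frac = (
        float((scored["correlation"] > HIGH_CONFIDENCE_THRESHOLD).mean())
        if len(scored)
        else np.nan
    )
    overall = overall_metrics(records["measured"], records["predicted"]) if len(records) >= 3 \
        else MetricReport(np.nan, np.nan, undefined=True)
    overall.per_drug = table
    overall.high_confidence_fraction = frac
    return overall
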