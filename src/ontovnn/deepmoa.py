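"""Mechanism-of-action prediction from VNN attribution scores.

Pipeline: per-drug DeepLIFT tensors are aggregated over cell lines into a
drugs x (term, neuron) feature matrix; known drug->GO-term annotations are
closed upward along the ontology; and for every term annotated in enough
drugs an RBF-kernel SVM with Platt-scaled probabilities learns to recognise
the term from the drug's k attribution features.  Out-of-fold probabilities
from a drug-level cross-validation give an unbiased probability matrix, and
a logit-difference ranking surfaces terms predicted for a drug beyond its
known annotations (candidate novel mechanisms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .attribution import AttributionTensor
from .ontology import OntologyGraph

__all__ = [
    "MoAFeatureMatrix",
    "MoALabelMatrix",
    "TermSVMSet",
    "aggregate_features",
    "build_label_matrix",
    "train_term_svms",
    "auroc_by_term",
    "auroc_by_drug",
    "rank_by_logit_difference",
]

MIN_ANNOTATED_DRUGS = 16
LOGIT_EPS = 1e-3


@dataclass
class MoAFeatureMatrix:
    """Drugs x (term, neuron 1..k) normalized aggregated attribution scores."""

    values: np.ndarray  # (n_drugs, n_terms * k)
    drugs: list[str]
    terms: list[str]
    k: int
    zero_spread_terms: list[tuple[str, int]] = field(default_factory=list)

    def term_features(self, term: str) -> np.ndarray:
        i = self.terms.index(term)
        return self.values[:, i * self.k : (i + 1) * self.k]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_product([self.terms, range(1, self.k + 1)],
                                          names=["term", "neuron"])
        return pd.DataFrame(self.values, index=self.drugs, columns=cols)


@dataclass
class MoALabelMatrix:
    """Binary drug x term labels, upward-closed, with a known/unknown drug mask."""

    labels: pd.DataFrame  # drugs x terms, 0/1
    known: pd.Series  # drug -> has at least one annotation


@dataclass
class TermSVMSet:
    """Per-term SVM fold models and the assembled probability matrix.

    ``probabilities`` holds Platt-scaled out-of-fold probabilities for
    annotated drugs and the mean over fold models for unknown drugs; entries
    stay NaN where every covering fold was skipped (single-class training
    data).
    """

    probabilities: pd.DataFrame  # drugs x terms
    fold_of: pd.Series  # known drug -> fold id
    models: dict[str, list]  # term -> one fitted SVC per fold (None if skipped)
    gamma: dict[str, float]
    skipped: list[tuple[str, int]]
    min_drugs: int = MIN_ANNOTATED_DRUGS


def aggregate_features(tensors: dict[str, AttributionTensor]) -> MoAFeatureMatrix:
    """Sum each drug's scores over cell lines and normalize per column.

    Only real ontology terms contribute columns (virtual pass-through nodes
    are bookkeeping, not GO terms).  Each (term, neuron) column is divided by
    its population standard deviation across drugs; zero-spread columns are
    left unscaled and flagged.  Requires at least 2 drugs.
    """
    if len(tensors) < 2:
        raise ValueError("feature normalization requires at least 2 drugs")
    drugs = sorted(tensors)
    first = tensors[drugs[0]]
    real = ~first.is_virtual
    terms = [n for n, v in zip(first.nodes, first.is_virtual) if not v]
    k = first.node_scores.shape[2]

    rows = []
    for d in drugs:
        t = tensors[d]
        if t.nodes != first.nodes:
            raise ValueError("attribution tensors disagree on node order")
        rows.append(t.node_scores.sum(axis=0)[real].reshape(-1))
    values = np.asarray(rows, dtype=float)

    std = values.std(axis=0)  # population std
    zero = std == 0.0
    scale = np.where(zero, 1.0, std)
    values = values / scale
    flagged = [
        (terms[i // k], i % k + 1) for i in np.flatnonzero(zero)
    ]
    if flagged:
        warnings.warn(f"{len(flagged)} zero-spread feature column(s) left unscaled",
                      stacklevel=2)
    return MoAFeatureMatrix(values=values, drugs=drugs, terms=terms, k=k,
                            zero_spread_terms=flagged)


def build_label_matrix(
    annotations: pd.DataFrame,
    graph: OntologyGraph,
    drugs: list[str] | None = None,
) -> MoALabelMatrix:
    """Upward-closed binary label matrix from a (drug, term) annotation table.

    If a drug is annotated to a term it is also annotated to all of the
    term's ancestors.  Annotations naming terms absent from the graph are
    rejected with a warning; drugs without any surviving annotation are
    marked unknown.  Closure is idempotent.
    """
    g = graph.to_networkx()
    terms = sorted(graph.terms)
    ann = annotations.iloc[:, :2].copy()
    ann.columns = ["drug", "term"]
    ann["drug"] = ann["drug"].astype(str)
    bad = ~ann["term"].isin(graph.terms)
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} annotation(s) to terms absent from the graph",
            stacklevel=2,
        )
        ann = ann[~bad]
    if drugs is None:
        drugs = sorted(ann["drug"].unique())
    labels = pd.DataFrame(0, index=list(drugs), columns=terms, dtype=np.int8)
    for drug, term in zip(ann["drug"], ann["term"]):
        if drug not in labels.index:
            continue
        labels.loc[drug, term] = 1
        for anc in nx.ancestors(g, term):
            labels.loc[drug, anc] = 1
    known = labels.sum(axis=1) > 0
    return MoALabelMatrix(labels=labels, known=known)


def train_term_svms(
    features: MoAFeatureMatrix,
    labels: MoALabelMatrix,
    folds: int = 4,
    seed: int = 0,
    min_drugs: int = MIN_ANNOTATED_DRUGS,
    gamma_mode: str = "pooled",
) -> TermSVMSet:
    """Per-term RBF SVMs with Platt scaling, evaluated drug-fold-wise.

    Annotated drugs are partitioned into ``folds`` groups; each qualifying
    term (>= ``min_drugs`` positive drugs) gets one model per fold, trained
    on the out-of-fold annotated drugs with C=1,
    gamma = 1 / (n_features * variance) and class weights inversely
    proportional to class frequencies.  A fold whose training labels are
    single-class is skipped and flagged.  ``gamma_mode`` chooses the variance:
    the pooled full feature matrix ("pooled") or the term's own columns
    ("per-term").
    """
    drugs = features.drugs
    lab = labels.labels.reindex(index=drugs).fillna(0).astype(int)
    known = labels.known.reindex(index=drugs).fillna(False).to_numpy(dtype=bool)
    known_drugs = [d for d, kn in zip(drugs, known) if kn]
    if folds > len(known_drugs):
        raise ValueError(f"{folds} folds but only {len(known_drugs)} annotated drugs")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(known_drugs))
    fold_of = pd.Series(
        {known_drugs[i]: int(j % folds) for j, i in enumerate(order)}, name="fold"
    )

    qualifying = [
        t for t in features.terms
        if int(lab.loc[known_drugs, t].sum()) >= min_drugs
    ]
    if not qualifying:
        raise ValueError(f"no term is annotated in at least {min_drugs} drugs")

    pooled_var = float(features.values.var())
    probs = pd.DataFrame(np.nan, index=drugs, columns=features.terms, dtype=float)
    models: dict[str, list] = {}
    gammas: dict[str, float] = {}
    skipped: list[tuple[str, int]] = []
    unknown_drugs = [d for d, kn in zip(drugs, known) if not kn]
    didx = {d: i for i, d in enumerate(drugs)}

    for term in qualifying:
        X = features.term_features(term)
        var = pooled_var if gamma_mode == "pooled" else float(X.var())
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        gammas[term] = gamma
        y = lab[term].to_numpy()
        fold_models: list = []
        unknown_probs = []
        for f in range(folds):
            train_d = [d for d in known_drugs if fold_of[d] != f]
            test_d = [d for d in known_drugs if fold_of[d] == f]
            ytr = y[[didx[d] for d in train_d]]
            counts = np.bincount(ytr, minlength=2)
            if counts.min() < 2:  # single-class (or uncalibratable) training fold
                skipped.append((term, f))
                fold_models.append(None)
                continue
            svc = SVC(C=1.0, kernel="rbf", gamma=gamma, class_weight="balanced",
                      random_state=seed)
            # Platt scaling: sigmoid calibration on internally cross-fitted
            # decision values of the training fold
            clf = CalibratedClassifierCV(
                svc, method="sigmoid", ensemble=False, cv=int(min(5, counts.min()))
            )
            clf.fit(X[[didx[d] for d in train_d]], ytr)
            fold_models.append(clf)
            if test_d:
                p = clf.predict_proba(X[[didx[d] for d in test_d]])[:, 1]
                probs.loc[test_d, term] = p
            if unknown_drugs:
                unknown_probs.append(
                    clf.predict_proba(X[[didx[d] for d in unknown_drugs]])[:, 1]
                )
        if unknown_drugs and unknown_probs:
            probs.loc[unknown_drugs, term] = np.mean(unknown_probs, axis=0)
        models[term] = fold_models

    return TermSVMSet(
        probabilities=probs,
        fold_of=fold_of,
        models=models,
        gamma=gammas,
        skipped=skipped,
        min_drugs=min_drugs,
    )


def _term_cols(features: MoAFeatureMatrix, term: str) -> slice:
    i = features.terms.index(term)
    return slice(i * features.k, (i + 1) * features.k)


def _auroc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    mask = np.isfinite(probabilities)
    labels, probabilities = labels[mask], probabilities[mask]
    if len(np.unique(labels)) < 2:
        return float("nan")  # flagged undefined
    return float(roc_auc_score(labels, probabilities))


def auroc_by_term(labels_column, probabilities_column) -> float:
    """AUROC of one term's probabilities against its labels across drugs.

    Equals the Mann-Whitney concordance statistic; NaN (flagged) when only
    one class is present.
    """
    return _auroc(np.asarray(labels_column, dtype=float),
                  np.asarray(probabilities_column, dtype=float))


def auroc_by_drug(labels_row, probabilities_row) -> tuple[float, np.ndarray]:
    """AUROC of one drug's probabilities across terms, plus the confusion
    matrix at probability 0.5 (rows: true 0/1, columns: predicted 0/1)."""
    y = np.asarray(labels_row, dtype=float)
    p = np.asarray(probabilities_row, dtype=float)
    mask = np.isfinite(p)
    y, p = y[mask], p[mask]
    pred = (p >= 0.5).astype(int)
    confusion = np.array(
        [[(1 - y)[pred == 0].sum(), (1 - y)[pred == 1].sum()],
         [y[pred == 0].sum(), y[pred == 1].sum()]]
    ).astype(int)
    return _auroc(y, p), confusion


def rank_by_logit_difference(
    probabilities_row: pd.Series,
    labels_row: pd.Series,
    top_n: int = 30,
    eps: float = LOGIT_EPS,
) -> pd.DataFrame:
    """Rank a drug's terms by logit(predicted) - logit(label).

    Labels are clipped to {eps, 1-eps} before the logit (the logit of a hard
    0/1 diverges).  Large positive differences mark terms the models predict
    far beyond the known annotation — candidate novel mechanisms; correctly
    predicted annotated terms score near zero.  The ordering is invariant to
    any strictly monotone rescaling applied through the same logit map.
    """
    p = probabilities_row.dropna()
    if p.empty:
        raise ValueError("drug has no term probabilities")
    y = labels_row.reindex(p.index).fillna(0).astype(float).clip(eps, 1 - eps)
    pc = p.clip(eps, 1 - eps)
    logit = lambda v: np.log(v / (1 - v))  # noqa: E731
    diff = logit(pc) - logit(y)
    out = pd.DataFrame(
        {"term": p.index, "probability": p.values, "label": labels_row.reindex(p.index).values,
         "logit_difference": diff.values}
    ).sort_values("logit_difference", ascending=False, kind="mergesort")
    return out.head(top_n).reset_index(drop=True)
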