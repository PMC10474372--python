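"""Synthetic fixtures with planted structure for end-to-end testing.

Real inputs to the pipeline (GO subgraphs, screening panels, dose-response
tables, MoA annotations) are large downloads; every stage here can instead be
exercised on generated data whose ground truth is known:

* :func:`generate_ontology` — a single-rooted term tree of chosen depth and
  branching, with a fraction of edges rewired to skip levels (exercising
  virtual-node insertion) and genes annotated to the bottom terms;
* :func:`generate_cohort` — cell-line features drawn i.i.d. per gene, random
  binary "fingerprints" (a drug-identity signal, not chemistry), and
  responses where each responsive drug's effect is driven by the genes of
  one planted causal term, on the AUDRC scale (1 = no effect);
* :func:`generate_dose_response` — 4PL curves with known parameters and
  recorded ground-truth standardized AUDRC.

The generated data emulate the *structure* of screening data, not its
distributions: no real GO topology statistics, assay noise heteroscedasticity
or chemistry are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    CellFeatureMatrix,
    FingerprintVector,
    ResponsePairSet,
    assemble_pairs,
)
from .dose_response import (
    AUDRCValue,
    DoseResponseCurve,
    FourPLParams,
    audrc_standardized,
)
from .ontology import OntologyGraph

__all__ = ["FixtureSpec", "SyntheticCohort", "GeneratedCurve",
           "generate_ontology", "generate_cohort", "generate_dose_response"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and noise parameters of the synthetic fixtures.

    Ontology: ``depth`` term levels below the root, ``branching`` children
    per term, ``skip_edge_fraction`` of deep edges rewired to a higher
    ancestor, ``genes_per_bottom_term`` unique genes per bottom term.
    Cohort: ``n_cells`` x ``n_drugs`` screen in which ``n_responsive_drugs``
    drugs act through ``n_causal_terms`` planted causal terms with
    ``effect_size`` on the AUDRC scale and Gaussian ``noise_sd``.
    Dose grid: ``dose_points`` log-spaced concentrations in
    [``dose_cmin``, ``dose_cmax``] molar.
    """

    seed: int = 0
    # ontology shape
    depth: int = 3
    branching: int = 2
    skip_edge_fraction: float = 0.0
    genes_per_bottom_term: int = 5
    # cohort shape
    n_cells: int = 200
    n_drugs: int = 40
    n_responsive_drugs: int = 36
    n_causal_terms: int = 2
    effect_size: float = 0.8
    noise_sd: float = 0.05
    fingerprint_bits: int = 2048
    # dose grid
    dose_points: int = 10
    dose_cmin: float = 1e-10
    dose_cmax: float = 1e-4
    dose_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("depth", "branching", "genes_per_bottom_term", "n_cells",
                     "n_drugs", "dose_points", "fingerprint_bits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.skip_edge_fraction < 1.0:
            raise ValueError("skip_edge_fraction must lie in [0, 1)")
        if self.n_responsive_drugs > self.n_drugs:
            raise ValueError("more responsive drugs than drugs")


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Single-rooted term tree with optional level-skipping edges.

    Each edge from a term at level >= 2 to its parent is rewired, with
    probability ``skip_edge_fraction``, to a random strictly higher ancestor
    — the rewired edge then spans more than one layer and forces
    :func:`~ontovnn.ontology.layerize` to insert virtual nodes.  Identical
    seeds produce identical graphs.
    """
    rng = np.random.default_rng(spec.seed)
    root = "T0"
    levels: list[list[str]] = [[root]]
    counter = 1
    parent_of: dict[str, str] = {}
    for level in range(1, spec.depth + 1):
        current: list[str] = []
        for parent in levels[level - 1]:
            for _ in range(spec.branching):
                term = f"T{counter}"
                counter += 1
                parent_of[term] = parent
                current.append(term)
        levels.append(current)
    if spec.skip_edge_fraction > 0 and spec.depth < 2:
        raise ValueError("skip edges require depth >= 2")

    edges: list[tuple[str, str, str]] = []
    for level in range(1, spec.depth + 1):
        for term in levels[level]:
            parent = parent_of[term]
            if level >= 2 and rng.random() < spec.skip_edge_fraction:
                # ancestors strictly above the direct parent (levels 0..level-2)
                ancestors = []
                node = parent
                while node in parent_of:
                    node = parent_of[node]
                    ancestors.append(node)
                if not ancestors:
                    ancestors = [root]
                parent = ancestors[rng.integers(len(ancestors))]
            edges.append((parent, term, "default"))

    annotations: dict[str, set[str]] = {}
    gene_id = 0
    for term in levels[-1]:
        annotations[term] = {
            f"g{gene_id + i:04d}" for i in range(spec.genes_per_bottom_term)
        }
        gene_id += spec.genes_per_bottom_term
    return OntologyGraph(terms=set().union(*levels), edges=edges, annotations=annotations)


@dataclass
class SyntheticCohort:
    features: CellFeatureMatrix
    fingerprints: dict[str, FingerprintVector]
    pairs: ResponsePairSet
    moa_annotations: pd.DataFrame  # (drug, term), pre-closure
    causal_term_of: dict[str, str]
    true_signal: dict[str, np.ndarray] = field(default_factory=dict)  # term -> per-cell z


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(spec: FixtureSpec, graph: OntologyGraph) -> SyntheticCohort:
    """Cohort with a planted per-term response mechanism.

    Features are i.i.d. Gamma(2, 1) per gene (expression-like, nonnegative).
    Each responsive drug is assigned a causal bottom term; its response is
    ``1 - effect_size * sigmoid(z)`` plus Gaussian noise, where ``z`` is the
    cohort-standardized mean feature of the causal term's genes (standardized
    so the sigmoid is exercised away from saturation).  Non-responsive pairs
    are ``1 + noise``.  Responsive drugs are annotated to their causal term.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = graph.genes()
    cells = [f"C{i:04d}" for i in range(spec.n_cells)]
    drugs = [f"D{i:03d}" for i in range(spec.n_drugs)]

    values = rng.gamma(shape=2.0, scale=1.0, size=(spec.n_cells, len(genes)))
    features = CellFeatureMatrix(values=values, cells=cells, genes=genes,
                                 modality="expression")

    fingerprints = {
        d: FingerprintVector(bits=(rng.random(spec.fingerprint_bits) < 0.1).astype(np.uint8),
                             drug_id=d)
        for d in drugs
    }

    annotated = sorted(t for t, gs in graph.annotations.items() if gs)
    if spec.n_causal_terms > len(annotated):
        raise ValueError("not enough gene-annotated terms for the causal assignment")
    causal_terms = list(rng.choice(annotated, size=spec.n_causal_terms, replace=False))
    for t in causal_terms:
        if not graph.annotations.get(t):
            raise ValueError(f"causal term {t} has no genes")

    gene_idx = {g: i for i, g in enumerate(genes)}
    z_of: dict[str, np.ndarray] = {}
    for t in causal_terms:
        cols = [gene_idx[g] for g in sorted(graph.annotations[t])]
        m = values[:, cols].mean(axis=1)
        sd = m.std()
        z_of[t] = (m - m.mean()) / (sd if sd > 0 else 1.0)

    causal_term_of = {
        drugs[i]: causal_terms[i % spec.n_causal_terms]
        for i in range(spec.n_responsive_drugs)
    }

    records = []
    for d in drugs:
        if d in causal_term_of:
            base = 1.0 - spec.effect_size * _sigmoid(z_of[causal_term_of[d]])
        else:
            base = np.ones(spec.n_cells)
        noise = rng.normal(0.0, spec.noise_sd, size=spec.n_cells) if spec.noise_sd > 0 else 0.0
        resp = base + noise
        for c, r in zip(cells, resp):
            records.append((c, d, float(r), "synthetic"))
    responses = pd.DataFrame(records, columns=["cell", "drug", "response", "study"])
    pairs = assemble_pairs(responses, features, fingerprints)

    moa = pd.DataFrame(
        sorted(causal_term_of.items()), columns=["drug", "term"]
    )
    return SyntheticCohort(
        features=features,
        fingerprints=fingerprints,
        pairs=pairs,
        moa_annotations=moa,
        causal_term_of=causal_term_of,
        true_signal=z_of,
    )


@dataclass
class GeneratedCurve:
    curve: DoseResponseCurve
    true_params: FourPLParams
    true_audrc2: AUDRCValue


def generate_dose_response(
    spec: FixtureSpec,
    audrc_targets=None,
    n_curves: int = 10,
) -> list[GeneratedCurve]:
    """4PL curves with known parameters and recorded ground-truth AUDRC2.

    If ``audrc_targets`` is given, one curve per target is built with
    upper=1, lower=0, slope 2 and the EC50 placed so the standardized area
    approximates the target (the recorded ground truth is the exact area of
    the true parameters, obtained by quadrature, not the requested target).
    Otherwise ``n_curves`` random curves are drawn.  Viability noise of sd
    ``dose_noise_sd`` is added when nonzero.
    """
    rng = np.random.default_rng(spec.seed + 2)
    t0, t1 = np.log10(spec.dose_cmin), np.log10(spec.dose_cmax)
    doses = np.logspace(t0, t1, spec.dose_points)

    param_sets: list[FourPLParams] = []
    if audrc_targets is not None:
        for a in audrc_targets:
            log_ec50 = t0 + float(a) * (t1 - t0)
            param_sets.append(FourPLParams(1.0, 0.0, 10.0**log_ec50, 2.0))
    else:
        for _ in range(n_curves):
            log_ec50 = rng.uniform(t0 + 1, t1 - 1)
            slope = rng.uniform(0.5, 3.0)
            lower = rng.uniform(0.0, 0.3)
            param_sets.append(FourPLParams(1.0, lower, 10.0**log_ec50, slope))

    out: list[GeneratedCurve] = []
    for i, p in enumerate(param_sets):
        v = p.predict(doses)
        if spec.dose_noise_sd > 0:
            v = v + rng.normal(0.0, spec.dose_noise_sd, size=v.shape)
        curve = DoseResponseCurve(
            concentrations=doses.copy(), viabilities=v, drug_id=f"D{i:03d}",
            cell_id="C0000", study="synthetic",
        )
        out.append(GeneratedCurve(curve=curve, true_params=p,
                                  true_audrc2=audrc_standardized(
                                      p, spec.dose_cmin, spec.dose_cmax)))
    return out
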