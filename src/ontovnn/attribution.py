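"""DeepLIFT attribution of the VNN branch against a reference activation.

DeepLIFT explains a prediction by comparing every neuron's activation with
its activation on a *reference* input and backpropagating multipliers so that
the contributions at any layer sum to the output difference
(summation-to-delta).  Here the reference is the per-gene median of the cell
feature matrix on the cell side and the fingerprint of glucose on the drug
side — the drug's effect is contrasted with a cellular-beneficial substance.

Rules used: the linear rule through affine layers (sparse/dense weights and
evaluation-mode batch normalization, which folds to an affine map), and the
Rescale rule through the hyperbolic tangent, falling back to the local
gradient when the input difference is numerically zero.  Dropout is inactive
(evaluation mode).  Scores are produced for every VNN node neuron and every
input gene; drug-side input scores are computed and stored but the bit-level
fingerprint scores are not biologically interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CellFeatureMatrix, FingerprintVector
from .sparse_vnn import (
    BatchNorm,
    DenseLinear,
    Dropout,
    Identity,
    SparseLinear,
    SparseVNNModel,
    Tanh,
)

__all__ = [
    "ReferenceInput",
    "AttributionTensor",
    "build_reference",
    "deeplift_vnn",
    "gene_attributions",
    "completeness_residual",
]

#: below this |delta input|, the Rescale ratio falls back to the gradient
RESCALE_EPS = 1e-9


@dataclass
class ReferenceInput:
    """Reference activations: per-gene median cell + glucose fingerprint."""

    cell: np.ndarray
    drug: np.ndarray

    def __post_init__(self) -> None:
        self.cell = np.asarray(self.cell, dtype=float).ravel()
        self.drug = np.asarray(self.drug, dtype=float).ravel()


@dataclass
class AttributionTensor:
    """DeepLIFT scores for one drug across a batch of cell lines.

    ``node_scores`` has shape (n_cells, n_nodes, k) over all VNN nodes of all
    layers (real terms and virtual nodes, flagged by ``is_virtual``);
    ``gene_scores`` has shape (n_cells, n_genes).  Scores are exactly zero
    when the input equals the reference.
    """

    drug_id: str
    cells: list[str]
    nodes: list[str]
    node_layer: np.ndarray  # hierarchy layer of each node
    is_virtual: np.ndarray
    node_scores: np.ndarray  # (n_cells, n_nodes, k)
    gene_scores: np.ndarray  # (n_cells, n_genes)
    drug_scores: np.ndarray  # (n_cells, n_fp_bits)
    genes: list[str]


def build_reference(features: CellFeatureMatrix, glucose_fp: FingerprintVector) -> ReferenceInput:
    """Column-wise median of the cell features; fingerprint passthrough."""
    if features.values.shape[0] < 1:
        raise ValueError("reference requires at least one cell line")
    return ReferenceInput(
        cell=np.median(features.values, axis=0),
        drug=glucose_fp.bits.astype(float),
    )


# ---------------------------------------------------------------------------
# Multiplier backpropagation
# ---------------------------------------------------------------------------


def _forward_capture(layers, x: np.ndarray) -> list[np.ndarray]:
    """Evaluation-mode forward pass keeping every interface vector.

    Returns ``acts`` with ``len(layers) + 1`` entries; ``acts[i]`` is the
    input of ``layers[i]`` and ``acts[-1]`` the stack output.
    """
    acts = [x]
    for layer in layers:
        x = layer.forward(x, train=False)
        acts.append(x)
    return acts


def _layer_multiplier(layer, m: np.ndarray, a_in, r_in, a_out, r_out) -> np.ndarray:
    """Backpropagate multipliers through one elementary layer."""
    if isinstance(layer, (DenseLinear, SparseLinear)):
        return m @ layer.W  # linear rule; the bias drops out of the delta
    if isinstance(layer, BatchNorm):
        return m * layer.eval_scale()  # eval-mode norm folds to an affine map
    if isinstance(layer, Tanh):
        dz = a_in - r_in
        dy = a_out - r_out
        grad = 1.0 - np.tanh(a_in) ** 2
        ratio = np.where(np.abs(dz) > RESCALE_EPS, dy / np.where(dz == 0, 1.0, dz), grad)
        return m * ratio
    if isinstance(layer, (Identity, Dropout)):
        return m
    raise TypeError(f"no DeepLIFT rule for layer type {type(layer).__name__}")


def _backprop_stack(layers, acts, refs, m_out: np.ndarray) -> list[np.ndarray]:
    """Multipliers at every interface of a layer stack, output first seeded."""
    ms = [None] * (len(layers) + 1)
    ms[-1] = m_out
    for i in range(len(layers) - 1, -1, -1):
        ms[i] = _layer_multiplier(
            layers[i], ms[i + 1], acts[i], refs[i], acts[i + 1], refs[i + 1]
        )
    return ms


def _run_deeplift(model: SparseVNNModel, cell_X: np.ndarray, drug_X: np.ndarray,
                  reference: ReferenceInput):
    """Forward input and reference, backpropagate multipliers through both
    branches; returns per-interface (multiplier, delta) lists and the output
    delta."""
    g = len(model.hierarchy.genes)
    if reference.cell.shape[0] != g or reference.drug.shape[0] != model.config.drug_input_dim:
        raise ValueError("reference shape does not match the model inputs")
    cell_X = np.atleast_2d(np.asarray(cell_X, dtype=float))
    drug_X = np.atleast_2d(np.asarray(drug_X, dtype=float))
    if drug_X.shape[0] == 1 and cell_X.shape[0] > 1:
        drug_X = np.repeat(drug_X, cell_X.shape[0], axis=0)

    acts_v = _forward_capture(model.vnn_layers, cell_X)
    acts_d = _forward_capture(model.drug_layers, drug_X)
    concat = np.concatenate([acts_v[-1], acts_d[-1]], axis=1)
    acts_h = _forward_capture(model.head_layers, concat)

    refs_v = _forward_capture(model.vnn_layers, reference.cell[None, :])
    refs_d = _forward_capture(model.drug_layers, reference.drug[None, :])
    rconcat = np.concatenate([refs_v[-1], refs_d[-1]], axis=1)
    refs_h = _forward_capture(model.head_layers, rconcat)

    ms_h = _backprop_stack(model.head_layers, acts_h, refs_h, np.ones_like(acts_h[-1]))
    w = acts_v[-1].shape[1]
    ms_v = _backprop_stack(model.vnn_layers, acts_v, refs_v, ms_h[0][:, :w])
    ms_d = _backprop_stack(model.drug_layers, acts_d, refs_d, ms_h[0][:, w:])

    delta_out = (acts_h[-1] - refs_h[-1])[:, 0]
    return (acts_v, refs_v, ms_v), (acts_d, refs_d, ms_d), (acts_h, refs_h, ms_h), delta_out


def deeplift_vnn(
    model: SparseVNNModel,
    cell_X: np.ndarray,
    drug_fp: np.ndarray,
    reference: ReferenceInput,
    drug_id: str = "",
    cells: list[str] | None = None,
) -> AttributionTensor:
    """Attribution scores of every VNN neuron and gene for one drug.

    ``cell_X`` is a (n_cells, genes) batch; ``drug_fp`` a single fingerprint
    applied to every cell.  Scores target the scalar output.
    """
    (acts_v, refs_v, ms_v), (acts_d, refs_d, ms_d), _, _ = _run_deeplift(
        model, cell_X, np.asarray(drug_fp, dtype=float)[None, :], reference
    )
    n = acts_v[0].shape[0]
    k = model.config.k

    nodes: list[str] = []
    layers: list[int] = []
    virt: list[bool] = []
    blocks: list[np.ndarray] = []
    for pos, s in model.vnn_interfaces:
        order = model.connectivity.node_order[s - 1]
        contrib = ms_v[pos] * (acts_v[pos] - refs_v[pos])  # (n, k*p)
        blocks.append(contrib.reshape(n, len(order), k))
        nodes.extend(order)
        layers.extend([s] * len(order))
        virt.extend(node in model.hierarchy.virtual_nodes for node in order)

    gene_scores = ms_v[0] * (acts_v[0] - refs_v[0])
    drug_scores = ms_d[0] * (acts_d[0] - refs_d[0])
    return AttributionTensor(
        drug_id=drug_id,
        cells=list(cells) if cells is not None else [str(i) for i in range(n)],
        nodes=nodes,
        node_layer=np.asarray(layers),
        is_virtual=np.asarray(virt),
        node_scores=np.concatenate(blocks, axis=1),
        gene_scores=gene_scores,
        drug_scores=drug_scores,
        genes=list(model.hierarchy.genes),
    )


def gene_attributions(
    model: SparseVNNModel,
    features: CellFeatureMatrix,
    fingerprints: dict[str, FingerprintVector],
    reference: ReferenceInput,
) -> pd.DataFrame:
    """Genes x drugs score matrix: per-drug sum of gene scores over cell lines.

    A gene disconnected from every term receives exactly zero for all drugs
    (no multiplier path reaches it).
    """
    cols = {}
    for drug_id in sorted(fingerprints):
        tensor = deeplift_vnn(
            model, features.values, fingerprints[drug_id].bits, reference, drug_id=drug_id
        )
        cols[drug_id] = tensor.gene_scores.sum(axis=0)
    return pd.DataFrame(cols, index=list(model.hierarchy.genes))


def completeness_residual(
    model: SparseVNNModel,
    cell_X: np.ndarray,
    drug_X: np.ndarray,
    reference: ReferenceInput,
) -> float:
    """Largest summation-to-delta violation over every layer cut.

    For every interface of the head stack, and for every (VNN interface,
    drug-branch input) and (VNN input, drug interface) cut, the summed
    contributions must equal the output difference.  Returns the maximum
    absolute residual across all cuts and samples.
    """
    (acts_v, refs_v, ms_v), (acts_d, refs_d, ms_d), (acts_h, refs_h, ms_h), delta = (
        _run_deeplift(model, cell_X, drug_X, reference)
    )

    def sums(acts, refs, ms):
        return [
            (m * (a - r)).sum(axis=1) for m, a, r in zip(ms, acts, refs)
        ]

    sv, sd, sh = sums(acts_v, refs_v, ms_v), sums(acts_d, refs_d, ms_d), sums(
        acts_h, refs_h, ms_h
    )
    residuals = [np.abs(s - delta) for s in sh]
    residuals += [np.abs(p + sd[0] - delta) for p in sv]
    residuals += [np.abs(sv[0] + q - delta) for q in sd]
    return float(max(r.max() for r in residuals))
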