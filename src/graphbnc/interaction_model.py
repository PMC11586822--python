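"""Pairwise interaction-energy estimation with sum-aggregated supervision.

Ligand-residue pairs within a formation distance (default 10 A between a
ligand head centroid and a CA) form the rows of a batch; the training
label is the *configuration-level* Coulomb + van der Waals interaction
energy.  A small feed-forward network (hidden layers 128/64/32, ReLU)
predicts a per-pair (coulomb, vdw) contribution; its training objective
is the mean absolute error between the sum of per-pair contributions and
the configuration label.  Five networks are trained on the five
cross-validation folds and predictions are averaged over them.

Predicted pair energies are rescaled so the strongest (most negative)
interaction maps to 1.0 and the median to 0; this scaled strength (phi)
is what the placement stage consumes.

The network is implemented directly on numpy (Adam optimiser, seeded
He initialisation); inputs are min-max scaled to [0,1] and outputs by a
symmetric max-abs factor to [-1,1], which keeps per-pair contributions
additive over a configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

from .cluster_features import pair_feature_matrix

logger = logging.getLogger(__name__)

DEFAULT_FORMATION_DISTANCE = 10.0
DEFAULT_HIDDEN = (128, 64, 32)
DEFAULT_EPOCHS = 150
DEFAULT_LR = 1e-3
DEFAULT_BATCH_SIZE = 32
DEFAULT_FOLDS = 5
DEFAULT_MIN_UPDATES = 15000


@dataclass
class PairBatch:
    """Ligand-residue pairs of one configuration with its energy labels."""

    configuration_id: int
    features: np.ndarray        # (P, D)
    e_coul: float = 0.0
    e_vdw: float = 0.0
    pair_ids: np.ndarray | None = None  # (P,) indices ligand*n_residues + node
    distances: np.ndarray | None = None

    @property
    def label(self) -> float:
        return self.e_coul + self.e_vdw

    def __len__(self):
        return len(self.features)


def form_pairs(protein_graph, cluster, pose=None,
               formation_distance: float = DEFAULT_FORMATION_DISTANCE,
               feature_matrix: np.ndarray | None = None,
               configuration_id: int = 0,
               e_coul: float = 0.0, e_vdw: float = 0.0) -> PairBatch:
    """All (ligand head, CA) pairs within the formation distance.

    ``feature_matrix`` may carry the precomputed (L*N, D) pair features
    (ligand-major order) to avoid recomputation across poses.
    """
    heads = cluster.head_centroids
    if pose is not None:
        heads = pose.apply(heads)
    ca = protein_graph.coarse.ca_coords
    d = np.linalg.norm(heads[:, None, :] - ca[None, :, :], axis=2)  # (L, N)
    lig_idx, node_idx = np.nonzero(d <= formation_distance)
    ids = lig_idx * len(ca) + node_idx
    if feature_matrix is None:
        feature_matrix = pair_feature_matrix(protein_graph, cluster)
    return PairBatch(configuration_id=configuration_id,
                     features=feature_matrix[ids],
                     e_coul=e_coul, e_vdw=e_vdw,
                     pair_ids=ids, distances=d[lig_idx, node_idx])


# ---------------------------------------------------------------------------
# Dense network on numpy


class _MLP:
    """Plain dense ReLU network with Adam, used per CV fold."""

    def __init__(self, dims, rng: np.random.Generator):
        self.W = [rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._adam = [[np.zeros_like(p), np.zeros_like(p)]
                      for p in self.W + self.b]
        self._t = 0

    def forward(self, X, cache=False):
        h = X
        acts = [X]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = np.maximum(z, 0.0) if i < len(self.W) - 1 else z
            acts.append(h)
        if cache:
            self._acts = acts
        return h

    def backward(self, dOut):
        grads_W, grads_b = [], []
        delta = dOut
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = self._acts[i]
            grads_W.append(a_prev.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W[i].T) * (self._acts[i] > 0)
        return grads_W[::-1], grads_b[::-1]

    def adam_step(self, grads_W, grads_b, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        params = self.W + self.b
        grads = grads_W + grads_b
        for p, g, mv in zip(params, grads, self._adam):
            m, v = mv
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** self._t)
            vhat = v / (1 - beta2 ** self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class EnsembleModel:
    """Five-fold ensemble with its input/output scalers."""

    folds: list
    input_lo: np.ndarray
    input_span: np.ndarray  # 0 marks a constant feature (maps to 0)
    output_scale: float     # scaled = physical * output_scale
    hidden: tuple = DEFAULT_HIDDEN
    seed: int = 0
    fold_assignment: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def scale_inputs(self, X):
        span = np.where(self.input_span > 0, self.input_span, np.inf)
        return (X - self.input_lo) / span

    def fold_outputs(self, X):
        """(n_folds, P, 2) per-pair physical-unit predictions per fold."""
        Xs = self.scale_inputs(np.atleast_2d(X))
        return np.stack([f.forward(Xs) for f in self.folds]) / self.output_scale


def _fit_input_scaler(X):
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        warnings.warn(f"{int((span == 0).sum())} constant input feature(s) map to 0")
    return lo, span


def _train_one_fold(batches, dims, rng, epochs, lr, batch_size, aux_loss):
    net = _MLP(dims, rng)
    n = len(batches)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, batch_size):
            chunk = [batches[i] for i in order[start:start + batch_size]]
            X = np.vstack([b.features for b in chunk if len(b)])
            seg = np.concatenate([[i] * len(b) for i, b in enumerate(chunk)
                                  if len(b)]) if len(X) else np.zeros(0, int)
            y = np.array([b.label for b in chunk])
            yc = np.array([b.e_coul for b in chunk])
            yv = np.array([b.e_vdw for b in chunk])
            if len(X) == 0:
                continue
            out = net.forward(X, cache=True)  # (P, 2) scaled units
            S = np.zeros((len(chunk), 2))
            np.add.at(S, seg, out)
            err = S.sum(axis=1) - y
            loss = np.abs(err).mean()
            dS = np.zeros_like(S)
            dS += (np.sign(err) / len(chunk))[:, None]
            if aux_loss:
                loss += (np.abs(S[:, 0] - yc).mean() + np.abs(S[:, 1] - yv).mean())
                dS[:, 0] += np.sign(S[:, 0] - yc) / len(chunk)
                dS[:, 1] += np.sign(S[:, 1] - yv) / len(chunk)
            dOut = dS[seg]
            gW, gb = net.backward(dOut)
            net.adam_step(gW, gb, lr)
            ep_loss += loss * len(chunk) / n
        losses.append(ep_loss)
    return net, losses


def train(batches: list, seed: int = 0, epochs: int = DEFAULT_EPOCHS,
          lr: float = DEFAULT_LR, batch_size: int = DEFAULT_BATCH_SIZE,
          n_folds: int = DEFAULT_FOLDS, hidden=DEFAULT_HIDDEN,
          aux_loss: bool = False,
          min_updates: int = DEFAULT_MIN_UPDATES) -> EnsembleModel:
    """Train the five-fold ensemble on configuration-labelled pair batches.

    Each fold trains on a distinct 80% of the configurations; the loss is
    the MAE between the summed per-pair (coulomb + vdw) prediction and the
    configuration label.  One master seed drives fold splits, weight
    initialisation and batch shuffling.

    ``epochs`` is the overfitting cap for corpus-scale data; because an
    epoch over a small corpus contains only a handful of minibatches, the
    number of passes is raised so that each fold performs at least
    ``min_updates`` optimiser updates (set ``min_updates=0`` to disable).
    """
    if len(batches) < n_folds:
        raise ValueError(f"need at least {n_folds} configurations, got {len(batches)}")
    X_all = np.vstack([b.features for b in batches if len(b)])
    lo, span = _fit_input_scaler(X_all)
    labels = np.array([b.label for b in batches])
    max_abs = np.abs(labels).max()
    output_scale = 1.0 / max_abs if max_abs > 0 else 1.0

    span_safe = np.where(span > 0, span, np.inf)
    scaled = [PairBatch(b.configuration_id,
                        (b.features - lo) / span_safe,
                        b.e_coul * output_scale, b.e_vdw * output_scale,
                        b.pair_ids, b.distances)
              for b in batches]

    dims = [X_all.shape[1], *hidden, 2]
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    master = np.random.SeedSequence(seed)
    fold_seeds = master.spawn(n_folds)
    folds, assignment, history = [], {}, []
    for f, (train_idx, val_idx) in enumerate(kf.split(scaled)):
        rng = np.random.default_rng(fold_seeds[f])
        updates_per_epoch = max(1, int(np.ceil(len(train_idx) / batch_size)))
        n_epochs = max(epochs, int(np.ceil(min_updates / updates_per_epoch)))
        net, losses = _train_one_fold([scaled[i] for i in train_idx], dims, rng,
                                      n_epochs, lr, batch_size, aux_loss)
        folds.append(net)
        assignment[f] = {"train": train_idx.tolist(), "val": val_idx.tolist()}
        history.append(losses)
        logger.info("fold %d: final training MAE %.4f (scaled units)", f, losses[-1])
    return EnsembleModel(folds=folds, input_lo=lo, input_span=span,
                         output_scale=output_scale, hidden=tuple(hidden),
                         seed=seed, fold_assignment=assignment, history=history)


def predict(model: EnsembleModel, batch: PairBatch):
    """Ensemble per-pair (coulomb, vdw) energies and the configuration total.

    Returns ``(per_pair, total)`` in the physical units of the training
    labels; an empty batch yields an empty array and total 0.
    """
    if len(batch) == 0:
        return np.zeros((0, 2)), 0.0
    if batch.features.shape[1] != len(model.input_lo):
        raise ValueError("feature dimension mismatch with trained model")
    per_pair = model.fold_outputs(batch.features).mean(axis=0)
    return per_pair, float(per_pair.sum())


def predict_pair_energies(model: EnsembleModel, protein_graph, cluster) -> np.ndarray:
    """(n_ligands, n_residues) total predicted energy for every possible pair."""
    feats = pair_feature_matrix(protein_graph, cluster)
    per_pair = model.fold_outputs(feats).mean(axis=0).sum(axis=1)
    return per_pair.reshape(cluster.n_ligands, len(protein_graph))


# ---------------------------------------------------------------------------
# Linear rescaling to interaction strengths


@dataclass
class ScaledInteractionTable:
    """Raw pair energies and their scaled strengths phi.

    phi is affine in energy with phi(E_min) = 1 (strongest interaction)
    and phi(median) = 0.
    """

    energies: np.ndarray
    phi: np.ndarray


def scale_interactions(energies: np.ndarray) -> ScaledInteractionTable:
    """phi(E) = (median - E) / (median - E_min); degenerate lists give 0."""
    energies = np.asarray(energies, dtype=float)
    med = np.median(energies)
    e_min = energies.min()
    if med - e_min <= 0:
        warnings.warn("all energies equal; scaled interactions set to 0")
        return ScaledInteractionTable(energies, np.zeros_like(energies))
    return ScaledInteractionTable(energies, (med - energies) / (med - e_min))


# ---------------------------------------------------------------------------
# Cross-validation report


def evaluate_cv(model: EnsembleModel, batches: list) -> dict:
    """Held-out RMSE of summed-energy predictions and inter-fold spread.

    ``rmse``: root-mean-square error of the configuration totals;
    ``mean_fold_std``: mean over pairs of the standard deviation of the
    five fold predictions (ensemble agreement).
    """
    totals, labels, stds = [], [], []
    for b in batches:
        per_pair, total = predict(model, b)
        totals.append(total)
        labels.append(b.label)
        if len(b):
            fold_pred = model.fold_outputs(b.features).sum(axis=2)  # (F, P)
            stds.append(fold_pred.std(axis=0).mean())
    totals = np.array(totals)
    labels = np.array(labels)
    rmse = float(np.sqrt(np.mean((totals - labels) ** 2)))
    return {"rmse": rmse,
            "mean_fold_std": float(np.mean(stds)) if stds else 0.0,
            "label_std": float(labels.std()),
            "n_configurations": len(batches)}


# ---------------------------------------------------------------------------
# Checkpointing


def save_model(model: EnsembleModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"hidden": list(model.hidden), "seed": model.seed,
            "output_scale": model.output_scale, "n_folds": len(model.folds),
            "fold_assignment": model.fold_assignment}
    (directory / "model.json").write_text(json.dumps(meta, indent=1))
    arrays = {"input_lo": model.input_lo, "input_span": model.input_span}
    for f, net in enumerate(model.folds):
        for i, (W, b) in enumerate(zip(net.W, net.b)):
            arrays[f"fold{f}_W{i}"] = W
            arrays[f"fold{f}_b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory) -> EnsembleModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    data = np.load(directory / "weights.npz")
    folds = []
    for f in range(meta["n_folds"]):
        net = _MLP([1, 1], np.random.default_rng(0))
        net.W, net.b = [], []
        i = 0
        while f"fold{f}_W{i}" in data:
            net.W.append(data[f"fold{f}_W{i}"])
            net.b.append(data[f"fold{f}_b{i}"])
            i += 1
        folds.append(net)
    return EnsembleModel(folds=folds, input_lo=data["input_lo"],
                         input_span=data["input_span"],
                         output_scale=float(meta["output_scale"]),
                         hidden=tuple(meta["hidden"]), seed=meta["seed"],
                         fold_assignment=meta.get("fold_assignment", {}))
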