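"""Graph neural predictor over the influence pathway, in pure numpy.

Each country-year row becomes one graph instance: nodes are the 37 catalog
variables, the node feature is that variable's normalized value (outcome
nodes are masked to zero so no target information leaks in), and edges are
the pathway edges. Two rounds of edge-directed message passing with tanh
aggregation propagate information strictly along the DAG, so a variable can
only influence the prediction at a cause node if a directed path leads to
it. Predictions are read out at the five cause nodes.

Forward pass, for node states ``h`` of width ``d``::

    h0[v]   = tanh(x[v] * W_x[v] + E[v])                   node embedding
    m[v]    = sum over parents u of h[u]                   directed messages
    h'[v]   = tanh(h[v] @ W_self + m[v] @ W_msg + b)       per round
    yhat[c] = h2[c] @ r + b_out[c]                         cause readout

Training is full-batch Adam on the mean squared error over the five causes,
with early stopping on a validation fold carved from the training rows.
Gradients are computed by hand (reverse-mode through the three layers);
everything runs in float32.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import CAUSES, TOTAL_BURDEN, PathwayGraph

_F = np.float32


@dataclass
class GraphBatch:
    """A batch of row-graphs sharing one edge structure."""

    node_features: np.ndarray  # (n_rows, n_nodes), outcome nodes masked to 0
    adjacency: np.ndarray      # (n_nodes, n_nodes), A[u, v] = 1 iff edge u -> v
    node_order: list[str]
    cause_index: np.ndarray    # positions of the 5 cause nodes in node_order

    @property
    def n_rows(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def take(self, idx: np.ndarray) -> "GraphBatch":
        return GraphBatch(self.node_features[idx], self.adjacency,
                          self.node_order, self.cause_index)


def build_graph_batch(pathway: PathwayGraph, rows: pd.DataFrame) -> GraphBatch:
    """One graph instance per row of ``rows`` (columns = catalog variables).

    All instances share the pathway's edges and differ only in node
    features; the cause and total-burden node features are masked to zero at
    both fit and prediction time.
    """
    node_order = pathway.catalog.names
    missing = [v for v in node_order if v not in rows.columns]
    if missing:
        raise ValueError(f"rows lack catalog variables: {missing}")
    x = rows[node_order].to_numpy(dtype=_F).copy()
    if np.isnan(x).any():
        raise ValueError("rows contain missing values")
    idx = {name: i for i, name in enumerate(node_order)}
    for name in list(CAUSES) + [TOTAL_BURDEN]:
        x[:, idx[name]] = 0.0
    n = len(node_order)
    adj = np.zeros((n, n), dtype=_F)
    for u, v in pathway.edges:
        adj[idx[u], idx[v]] = 1.0
    cause_index = np.array([idx[c] for c in CAUSES])
    return GraphBatch(x, adj, node_order, cause_index)


def _messages(A: np.ndarray, h: np.ndarray) -> np.ndarray:
    # m[n, v] = sum_u A[u, v] h[n, u]
    return np.tensordot(h, A, axes=([1], [0])).transpose(0, 2, 1)


class GNNRegressor:
    """Message-passing regressor from the 31 inputs to the 5 causes.

    Parameters
    ----------
    hidden : node state width (default 32).
    rounds : message-passing rounds (default 2; the readout then sees each
        cause's parents and grandparents, never non-ancestors).
    lr, max_epochs, patience : full-batch Adam schedule with early stopping
        on a validation fold of ``val_fraction`` of the training rows.
    """

    def __init__(
        self,
        pathway: PathwayGraph,
        hidden: int = 32,
        rounds: int = 2,
        lr: float = 0.01,
        max_epochs: int = 1000,
        patience: int = 100,
        restarts: int = 3,
        val_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.pathway = pathway
        self.hidden = hidden
        self.rounds = rounds
        self.lr = lr
        self.max_epochs = max_epochs
        self.patience = patience
        self.restarts = restarts
        self.val_fraction = val_fraction
        self.seed = seed
        self.params_: dict[str, np.ndarray] | None = None
        self.n_epochs_: int | None = None

    # -- parameter plumbing -------------------------------------------------
    def _init_params(self, n_nodes: int, y_mean: np.ndarray,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
        d = self.hidden
        scale = 1.0 / np.sqrt(d)
        p = {
            "E": rng.normal(0, 0.5, size=(n_nodes, d)).astype(_F),
            "W_x": rng.normal(0, 1.0, size=(n_nodes, d)).astype(_F),
            "r": rng.normal(0, scale, size=d).astype(_F),
            "b_out": y_mean.astype(_F).copy(),
        }
        for t in range(self.rounds):
            p[f"W_self{t}"] = rng.normal(0, scale, size=(d, d)).astype(_F)
            p[f"W_msg{t}"] = rng.normal(0, scale, size=(d, d)).astype(_F)
            p[f"b{t}"] = np.zeros(d, dtype=_F)
        return p

    # -- forward / backward -------------------------------------------------
    def _forward(self, p: dict, batch: GraphBatch, cache: bool = False):
        x, A = batch.node_features, batch.adjacency
        h = np.tanh(x[:, :, None] * p["W_x"][None, :, :] + p["E"][None, :, :])
        hs, ms = [h], []
        for t in range(self.rounds):
            m = _messages(A, h)
            pre = h @ p[f"W_self{t}"] + m @ p[f"W_msg{t}"] + p[f"b{t}"]
            h = np.tanh(pre)
            if cache:
                ms.append(m)
                hs.append(h)
        yhat = h[:, batch.cause_index, :] @ p["r"] + p["b_out"]
        if cache:
            return yhat, hs, ms
        return yhat

    def _backward(self, p: dict, batch: GraphBatch, y: np.ndarray):
        yhat, hs, ms = self._forward(p, batch, cache=True)
        n = batch.n_rows
        A = batch.adjacency
        g = {}
        dy = (2.0 * (yhat - y) / (n * y.shape[1])).astype(_F)
        h_final = hs[-1]
        g["r"] = np.einsum("nc,ncd->d", dy, h_final[:, batch.cause_index, :])
        g["b_out"] = dy.sum(axis=0)
        dh = np.zeros_like(h_final)
        dh[:, batch.cause_index, :] = dy[:, :, None] * p["r"][None, None, :]
        for t in reversed(range(self.rounds)):
            h_prev, m, h_cur = hs[t], ms[t], hs[t + 1]
            dpre = dh * (1.0 - h_cur**2)
            flat_prev = h_prev.reshape(-1, self.hidden)
            flat_m = m.reshape(-1, self.hidden)
            flat_dpre = dpre.reshape(-1, self.hidden)
            g[f"W_self{t}"] = flat_prev.T @ flat_dpre
            g[f"W_msg{t}"] = flat_m.T @ flat_dpre
            g[f"b{t}"] = flat_dpre.sum(axis=0)
            dm = dpre @ p[f"W_msg{t}"].T
            dh = dpre @ p[f"W_self{t}"].T
            # back through m[n, v] = sum_u A[u, v] h_prev[n, u]
            dh += np.tensordot(dm, A, axes=([1], [1])).transpose(0, 2, 1)
        h0 = hs[0]
        dpre0 = dh * (1.0 - h0**2)
        g["W_x"] = np.einsum("nv,nvd->vd", batch.node_features, dpre0)
        g["E"] = dpre0.sum(axis=0)
        loss = float(np.mean((yhat - y) ** 2))
        return loss, g

    # -- training -----------------------------------------------------------
    def fit(self, batch: GraphBatch, y: np.ndarray) -> "GNNRegressor":
        """Train with early stopping; an optimization run that fails to beat
        the mean predictor on the validation fold (a rare bad-initialization
        mode) is restarted with a fresh init, up to ``restarts`` times,
        deterministically from the seed."""
        y = np.asarray(y, dtype=_F)
        rng = np.random.default_rng(self.seed)
        n = batch.n_rows
        n_val = max(1, int(round(n * self.val_fraction)))
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        fit_batch, val_batch = batch.take(fit_idx), batch.take(val_idx)
        y_fit, y_val = y[fit_idx], y[val_idx]
        collapse_level = float(np.mean((y_val - y_fit.mean(axis=0)) ** 2))
        for attempt in range(1 + self.restarts):
            best_val = self._train_once(batch, fit_batch, val_batch, y_fit, y_val, rng)
            if best_val < 0.95 * collapse_level or collapse_level == 0:
                break
        return self

    def _train_once(self, batch, fit_batch, val_batch, y_fit, y_val,
                    rng: np.random.Generator) -> float:
        p = self._init_params(len(batch.node_order), y_fit.mean(axis=0), rng)
        m1 = {k: np.zeros_like(v) for k, v in p.items()}
        m2 = {k: np.zeros_like(v) for k, v in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_val, best_p, stale = np.inf, {k: v.copy() for k, v in p.items()}, 0
        for epoch in range(1, self.max_epochs + 1):
            _, g = self._backward(p, fit_batch, y_fit)
            for k in p:
                m1[k] = beta1 * m1[k] + (1 - beta1) * g[k]
                m2[k] = beta2 * m2[k] + (1 - beta2) * g[k] ** 2
                mhat = m1[k] / (1 - beta1**epoch)
                vhat = m2[k] / (1 - beta2**epoch)
                p[k] -= (self.lr * mhat / (np.sqrt(vhat) + eps)).astype(_F)
            val_pred = self._forward(p, val_batch)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            if val_loss < best_val * (1.0 - 1e-5):
                best_val, stale = val_loss, 0
                best_p = {k: v.copy() for k, v in p.items()}
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.params_ = best_p
        self.n_epochs_ = epoch
        return best_val

    def predict(self, batch: GraphBatch) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("GNNRegressor is not fitted")
        return np.asarray(self._forward(self.params_, batch), dtype=float)
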