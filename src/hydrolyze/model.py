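"""Gated graph-convolution network over union reaction graphs.

The network operates on the reaction heterograph: atom nodes, bond nodes
(the union of reactant and product bond sets) and one global node per
reaction. Messages flow bond -> atom -> global each layer, every update is
gated by a learned sigmoid and added residually, so a layer with zero
message weights is the identity. After the convolution stack, atom and
bond nodes are pooled with one of {set2set, weighted_mean, self_attention,
mean} and concatenated with the global embedding before a dense regression
head predicts the hydrolysis free energy in kcal/mol.

Frozen per-layer update equations (d = embedding size, [.] = concat):

    bond b=(u,v):  z_b = [h_u + h_v, h_b, h_g]
                   h_b <- h_b + sigmoid(z_b W_b^g) * tanh(z_b W_b^m)
    atom a:        z_a = [mean_{b : a in b} h_b, h_a, h_g]
                   h_a <- h_a + sigmoid(z_a W_a^g) * tanh(z_a W_a^m)
    global g:      z_g = [mean_a h_a, mean_b h_b, h_g]
                   h_g <- h_g + sigmoid(z_g W_g^g) * tanh(z_g W_g^m)
"""

from __future__ import annotations

import copy
import dataclasses
import json
import pathlib
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from . import autograd as ag
from .autograd import Tensor
from .molgraph import Featurizer
from .reaction_graph import BOND_PRESENCE, ReactionGraph, build_reaction_graph
from .templates import HydrolysisReaction

POOLING_METHODS = ("set2set", "weighted_mean", "self_attention", "mean")

#: absolute-error histogram edges (kcal/mol)
ERROR_BINS = ("<2", "2-5", "5-10", ">10")


class TrainingError(RuntimeError):
    pass


class SchemaMismatchError(ValueError):
    pass


@dataclasses.dataclass
class ModelConfig:
    embedding_size: int = 64
    n_conv_layers: int = 3
    pooling: str = "set2set"
    head_sizes: tuple[int, ...] = (64,)
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 30
    seed: int = 0
    loss: str = "mse"
    set2set_steps: int = 3
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.pooling not in POOLING_METHODS:
            raise ValueError(
                f"pooling {self.pooling!r} not in {POOLING_METHODS}")
        if not (2 <= self.n_conv_layers <= 4):
            raise ValueError("n_conv_layers must be in 2..4")
        for name in ("embedding_size", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(h <= 0 for h in self.head_sizes):
            raise ValueError("head sizes must be positive")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        self.head_sizes = tuple(self.head_sizes)


@dataclasses.dataclass
class EvalReport:
    mae: float
    rmse: float
    r2: float
    sign_accuracy: float  # percent
    per_fg_mae: dict[str, float]
    error_bins: dict[str, int]
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"functional group": fg, "MAE (kcal/mol)": v}
                for fg, v in self.per_fg_mae.items()]
        rows.append({"functional group": "overall average",
                     "MAE (kcal/mol)": self.mae})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# batching
# --------------------------------------------------------------------------

@dataclasses.dataclass
class Batch:
    atom_x: np.ndarray
    atom_seg: np.ndarray
    bond_x: np.ndarray
    bond_seg: np.ndarray
    incidence: np.ndarray      # (2*NB,) atom index of each bond endpoint
    atom_deg: np.ndarray       # (NA,1) incident-bond counts, clipped >= 1
    global_x: np.ndarray
    pool_perm: np.ndarray      # permutation sorting [atoms; bonds] by graph
    pool_seg: np.ndarray       # sorted segment ids of pooled nodes
    y: Optional[np.ndarray]
    fg_ids: list[str]
    n_graphs: int


def collate(graphs: Sequence[ReactionGraph]) -> Batch:
    atom_x, bond_x, atom_seg, bond_seg, incidence = [], [], [], [], []
    global_x, y, fg_ids = [], [], []
    atom_off = 0
    for gi, g in enumerate(graphs):
        atom_x.append(g.atom_diff)
        bond_x.append(np.concatenate([g.bond_diff, g.bond_flag_onehot()],
                                     axis=1))
        atom_seg.append(np.full(g.n_atoms, gi))
        bond_seg.append(np.full(g.n_bonds, gi))
        incidence.append(g.bond_atoms + atom_off)
        global_x.append(np.concatenate([g.global_static, g.global_diff]))
        fg_ids.append(g.fg_id)
        if g.dG_label is not None:
            y.append(g.dG_label)
        atom_off += g.n_atoms
    atom_seg = np.concatenate(atom_seg)
    bond_seg = np.concatenate(bond_seg)
    bond_atoms = np.concatenate(incidence)
    inc = np.concatenate([bond_atoms[:, 0], bond_atoms[:, 1]])
    na = atom_off
    deg = np.bincount(inc, minlength=na).astype(np.float64)
    node_seg = np.concatenate([atom_seg, bond_seg])
    perm = np.argsort(node_seg, kind="stable")
    return Batch(
        atom_x=np.concatenate(atom_x),
        atom_seg=atom_seg,
        bond_x=np.concatenate(bond_x),
        bond_seg=bond_seg,
        incidence=inc,
        atom_deg=np.maximum(deg, 1.0)[:, None],
        global_x=np.stack(global_x),
        pool_perm=perm,
        pool_seg=node_seg[perm],
        y=np.asarray(y)[:, None] if len(y) == len(graphs) else None,
        fg_ids=fg_ids,
        n_graphs=len(graphs),
    )


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

def _linear(params, name, x: Tensor) -> Tensor:
    return x @ params[f"{name}_W"] + params[f"{name}_b"]


def init_params(config: ModelConfig, atom_dim: int, bond_dim: int,
                global_dim: int, rng: np.random.Generator) -> dict[str, Tensor]:
    d = config.embedding_size
    p: dict[str, Tensor] = {}

    def lin(name, nin, nout):
        p[f"{name}_W"] = ag.parameter(rng, (nin, nout))
        p[f"{name}_b"] = ag.parameter(rng, (1, nout), scale="zeros")

    lin("proj_atom", atom_dim, d)
    lin("proj_bond", bond_dim + len(BOND_PRESENCE), d)
    lin("proj_global", global_dim, d)
    for layer in range(config.n_conv_layers):
        for part in ("bond", "atom", "global"):
            lin(f"conv{layer}_{part}_gate", 3 * d, d)
            lin(f"conv{layer}_{part}_msg", 3 * d, d)
    if config.pooling == "weighted_mean":
        lin("pool_w", d, 1)
    elif config.pooling == "self_attention":
        lin("pool_att", d, d)
        lin("pool_score", d, 1)
    elif config.pooling == "set2set":
        for gate in ("i", "f", "o", "c"):
            lin(f"s2s_x{gate}", 2 * d, d)
            p[f"s2s_h{gate}_W"] = ag.parameter(rng, (d, d))
    pooled = 2 * d if config.pooling == "set2set" else d
    sizes = (pooled + d,) + config.head_sizes + (1,)
    for i, (nin, nout) in enumerate(zip(sizes[:-1], sizes[1:])):
        lin(f"head{i}", nin, nout)
    return p


def gated_conv_forward(params: dict[str, Tensor], layer: int, batch: Batch,
                       h_a: Tensor, h_b: Tensor, h_g: Tensor
                       ) -> tuple[Tensor, Tensor, Tensor]:
    """One gated update of bond, atom and global embeddings (residual)."""
    nb = batch.bond_x.shape[0]
    na = batch.atom_x.shape[0]
    ng = batch.n_graphs

    def gated(name, z, h):
        gate = _linear(params, f"{name}_gate", z).sigmoid()
        msg = _linear(params, f"{name}_msg", z).tanh()
        return h + gate * msg

    hu = ag.gather_rows(h_a, batch.incidence[:nb])
    hv = ag.gather_rows(h_a, batch.incidence[nb:])
    z_b = ag.concat([hu + hv, h_b, ag.gather_rows(h_g, batch.bond_seg)])
    h_b = gated(f"conv{layer}_bond", z_b, h_b)

    agg = segment_incident_mean(h_b, batch, na)
    z_a = ag.concat([agg, h_a, ag.gather_rows(h_g, batch.atom_seg)])
    h_a = gated(f"conv{layer}_atom", z_a, h_a)

    z_g = ag.concat([ag.segment_mean(h_a, batch.atom_seg, ng),
                     ag.segment_mean(h_b, batch.bond_seg, ng), h_g])
    h_g = gated(f"conv{layer}_global", z_g, h_g)
    return h_a, h_b, h_g


def segment_incident_mean(h_b: Tensor, batch: Batch, n_atoms: int) -> Tensor:
    """Mean of incident bond embeddings per atom."""
    both = ag.vstack([h_b, h_b])
    s = ag.segment_sum(both, batch.incidence, n_atoms)
    return s * Tensor(1.0 / batch.atom_deg)


def pool(params: dict[str, Tensor], config: ModelConfig, batch: Batch,
         h_a: Tensor, h_b: Tensor) -> Tensor:
    """Permutation-invariant readout over the atom+bond node set."""
    nodes = ag.gather_rows(ag.vstack([h_a, h_b]), batch.pool_perm)
    seg, ng = batch.pool_seg, batch.n_graphs
    method = config.pooling
    if method == "mean":
        return ag.segment_mean(nodes, seg, ng)
    if method == "weighted_mean":
        w = _linear(params, "pool_w", nodes).sigmoid()
        num = ag.segment_sum(w * nodes, seg, ng)
        den = ag.segment_sum(w, seg, ng)
        return num / den
    if method == "self_attention":
        e = _linear(params, "pool_score",
                    _linear(params, "pool_att", nodes).tanh())
        alpha = ag.segment_softmax(e, seg, ng)
        return ag.segment_sum(alpha * nodes, seg, ng)
    # set2set: LSTM-driven iterative attention
    d = config.embedding_size
    q = Tensor(np.zeros((ng, d)))
    c = Tensor(np.zeros((ng, d)))
    qstar = Tensor(np.zeros((ng, 2 * d)))
    for _ in range(config.set2set_steps):
        i = (_linear(params, "s2s_xi", qstar) + q @ params["s2s_hi_W"]).sigmoid()
        f = (_linear(params, "s2s_xf", qstar) + q @ params["s2s_hf_W"]).sigmoid()
        o = (_linear(params, "s2s_xo", qstar) + q @ params["s2s_ho_W"]).sigmoid()
        u = (_linear(params, "s2s_xc", qstar) + q @ params["s2s_hc_W"]).tanh()
        c = f * c + i * u
        q = o * c.tanh()
        e = (nodes * ag.gather_rows(q, seg)).sum(axis=1, keepdims=True)
        alpha = ag.segment_softmax(e, seg, ng)
        r = ag.segment_sum(alpha * nodes, seg, ng)
        qstar = ag.concat([q, r])
    return qstar


def forward(params: dict[str, Tensor], config: ModelConfig,
            batch: Batch) -> Tensor:
    h_a = _linear(params, "proj_atom", Tensor(batch.atom_x))
    h_b = _linear(params, "proj_bond", Tensor(batch.bond_x))
    h_g = _linear(params, "proj_global", Tensor(batch.global_x))
    for layer in range(config.n_conv_layers):
        h_a, h_b, h_g = gated_conv_forward(params, layer, batch, h_a, h_b, h_g)
    h = ag.concat([pool(params, config, batch, h_a, h_b), h_g])
    n_head = len(config.head_sizes) + 1
    for i in range(n_head):
        h = _linear(params, f"head{i}", h)
        if i < n_head - 1:
            h = h.relu()
    return h


# --------------------------------------------------------------------------
# trained model
# --------------------------------------------------------------------------

def feature_stats(batch: Batch) -> dict[str, np.ndarray]:
    """Per-dimension input scales (and a center for the global block).

    Atom/bond difference features are scaled but not centered so that a
    zero vector keeps meaning "no change / absent side"; the global block
    holds raw counts and molecular weights and is centered as well.
    """

    def scale(x):
        return np.maximum(x.std(axis=0), 1e-3) if len(x) else np.ones(x.shape[1])

    return {
        "atom_scale": scale(batch.atom_x),
        "bond_scale": scale(batch.bond_x),
        "global_center": batch.global_x.mean(axis=0),
        "global_scale": scale(batch.global_x),
    }


def scale_batch(batch: Batch, stats: dict[str, np.ndarray]) -> Batch:
    return dataclasses.replace(
        batch,
        atom_x=batch.atom_x / stats["atom_scale"],
        bond_x=batch.bond_x / stats["bond_scale"],
        global_x=(batch.global_x - stats["global_center"])
        / stats["global_scale"],
    )


@dataclasses.dataclass
class TrainedModel:
    params: dict[str, Tensor]
    config: ModelConfig
    feature_schema: str
    fg_catalog: tuple[str, ...]
    atom_dim: int
    bond_dim: int
    global_dim: int
    y_mean: float
    y_std: float
    history: list[dict]
    x_stats: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def featurizer(self) -> Featurizer:
        return Featurizer(self.fg_catalog)

    def _check(self, batch: Batch) -> None:
        if batch.atom_x.shape[1] != self.atom_dim or \
                batch.bond_x.shape[1] != self.bond_dim + len(BOND_PRESENCE) or \
                batch.global_x.shape[1] != self.global_dim:
            raise SchemaMismatchError(
                "feature dimensions do not match the trained schema "
                f"({self.feature_schema})")

    def predict_batch(self, graphs: Sequence[ReactionGraph]) -> np.ndarray:
        if not len(graphs):
            return np.zeros(0)
        for g in graphs:
            if g.atom_diff.shape[1] != self.atom_dim:
                raise SchemaMismatchError(
                    f"graph atom feature dim {g.atom_diff.shape[1]} != "
                    f"model {self.atom_dim}")
        batch = collate(graphs)
        self._check(batch)
        if self.x_stats:
            batch = scale_batch(batch, self.x_stats)
        out = forward(self.params, self.config, batch)
        return (out.data[:, 0] * self.y_std) + self.y_mean

    def save(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        meta = {
            "config": dataclasses.asdict(self.config),
            "feature_schema": self.feature_schema,
            "fg_catalog": list(self.fg_catalog),
            "atom_dim": self.atom_dim,
            "bond_dim": self.bond_dim,
            "global_dim": self.global_dim,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "history": self.history,
        }
        arrays = {f"p_{k}": v.data for k, v in self.params.items()}
        arrays.update({f"s_{k}": v for k, v in self.x_stats.items()})
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg = dict(meta["config"])
        cfg["head_sizes"] = tuple(cfg["head_sizes"])
        params = {k[2:]: Tensor(data[k], requires_grad=True)
                  for k in data.files if k.startswith("p_")}
        stats = {k[2:]: data[k] for k in data.files if k.startswith("s_")}
        return cls(params=params, config=ModelConfig(**cfg), x_stats=stats,
                   feature_schema=meta["feature_schema"],
                   fg_catalog=tuple(meta["fg_catalog"]),
                   atom_dim=meta["atom_dim"], bond_dim=meta["bond_dim"],
                   global_dim=meta["global_dim"],
                   y_mean=meta["y_mean"], y_std=meta["y_std"],
                   history=meta["history"])


def predict_dg(model: TrainedModel,
               rxn: Union[HydrolysisReaction, ReactionGraph]) -> float:
    """Predicted hydrolysis free energy (kcal/mol) for one reaction."""
    if isinstance(rxn, HydrolysisReaction):
        rxn = build_reaction_graph(rxn, model.featurizer())
    return float(model.predict_batch([rxn])[0])


# --------------------------------------------------------------------------
# training / evaluation
# --------------------------------------------------------------------------

def _loss(pred: Tensor, y: np.ndarray, kind: str) -> Tensor:
    diff = pred - Tensor(y)
    return (diff ** 2).mean() if kind == "mse" else diff.abs().mean()


def train(graphs: Sequence[ReactionGraph], config: ModelConfig,
          featurizer: Featurizer,
          val_graphs: Optional[Sequence[ReactionGraph]] = None,
          log=None) -> TrainedModel:
    """Train on labeled reaction graphs; returns the best-validation model.

    The split, initialization and batch order are all driven by
    ``config.seed``, so the loss history is bit-reproducible.
    """
    graphs = [g for g in graphs if g.dG_label is not None]
    if not graphs:
        raise TrainingError("empty labeled dataset")
    rng = np.random.default_rng(config.seed)

    if val_graphs is None:
        idx = rng.permutation(len(graphs))
        n_val = max(1, int(round(config.val_fraction * len(graphs)))) \
            if len(graphs) > 1 else 0
        val_graphs = [graphs[i] for i in idx[:n_val]]
        train_graphs = [graphs[i] for i in idx[n_val:]]
    else:
        train_graphs = list(graphs)
        val_graphs = list(val_graphs)

    y_train = np.array([g.dG_label for g in train_graphs])
    y_mean = float(y_train.mean())
    y_std = float(y_train.std()) or 1.0

    def std_graphs(gs):
        out = []
        for g in gs:
            g2 = dataclasses.replace(g, dG_label=(g.dG_label - y_mean) / y_std)
            out.append(g2)
        return out

    train_s = std_graphs(train_graphs)
    val_s = std_graphs(val_graphs)

    full = collate(train_s)
    stats = feature_stats(full)
    val_batch = scale_batch(collate(val_s), stats) if val_s else None

    atom_dim = full.atom_x.shape[1]
    bond_dim = full.bond_x.shape[1] - len(BOND_PRESENCE)
    global_dim = full.global_x.shape[1]
    params = init_params(config, atom_dim, bond_dim, global_dim, rng)
    opt = ag.Adam(params, lr=config.learning_rate)

    history: list[dict] = []
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_s))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            chunk = [train_s[i] for i in order[lo:lo + config.batch_size]]
            batch = scale_batch(collate(chunk), stats)
            pred = forward(params, config, batch)
            loss = _loss(pred, batch.y, config.loss)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        if val_batch is not None:
            vpred = forward(params, config, val_batch)
            val_loss = float(_loss(vpred, val_batch.y, config.loss).data)
        else:
            val_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if log is not None:
            log(f"epoch {epoch:4d}  train {train_loss:.5f}  val {val_loss:.5f}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: copy.deepcopy(v.data) for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_params is not None:
        for k, p in params.items():
            p.data = best_params[k]
    return TrainedModel(
        params=params, config=config,
        feature_schema=featurizer.schema_version,
        fg_catalog=tuple(featurizer.fg_catalog),
        atom_dim=atom_dim, bond_dim=bond_dim, global_dim=global_dim,
        y_mean=y_mean, y_std=y_std, history=history, x_stats=stats)


def evaluate(model: TrainedModel,
             graphs: Sequence[ReactionGraph]) -> EvalReport:
    """Standard regression metrics plus endergonic/exergonic classification
    and the per-functional-group MAE table."""
    graphs = [g for g in graphs if g.dG_label is not None]
    y = np.array([g.dG_label for g in graphs])
    pred = model.predict_batch(graphs)
    err = np.abs(pred - y)
    mae = float(mean_absolute_error(y, pred))
    rmse = float(np.sqrt(mean_squared_error(y, pred)))
    r2 = float(r2_score(y, pred))
    sign_acc = float(100.0 * np.mean((pred > 0) == (y > 0)))
    fg = pd.Series([g.fg_id for g in graphs])
    per_fg = {k: float(v)
              for k, v in pd.Series(err).groupby(fg).mean().items()}
    bins = {
        "<2": int(np.sum(err < 2)),
        "2-5": int(np.sum((err >= 2) & (err < 5))),
        "5-10": int(np.sum((err >= 5) & (err < 10))),
        ">10": int(np.sum(err >= 10)),
    }
    return EvalReport(mae=mae, rmse=rmse, r2=r2, sign_accuracy=sign_acc,
                      per_fg_mae=per_fg, error_bins=bins, n=len(graphs))
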