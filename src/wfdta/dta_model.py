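"""Hybrid graph-convolution + 1D-convolution binding-affinity regressors.

A drug branch (one of four graph-network kinds) embeds the molecular graph
into a 128-dim vector; a protein branch runs a 1D convolution over the
word-frequency peptide vector and maps it to a matching embedding.  The two
embeddings are concatenated and passed through fully connected layers of
512 and 128 units to a single affinity output.  Training minimizes mean
squared error with Adam.

Drug branch kinds:

* ``gcn`` — three graph-convolution+ReLU units with output channels
  78, 156, 312, global max pooling, a 1024-unit dense layer, 128-dim out.
* ``gin`` — five graph-isomorphism units whose MLPs are two 32-wide linear
  maps, global sum pooling, 128-dim out.
* ``gat`` — attention layers of 78 channels x 10 heads then 128 channels x
  1 head, global max pooling, 128-dim out.
* ``gat_gcn`` — a 78-channel 10-head attention layer into a 780-channel
  graph convolution, concatenated max+mean pooling, a 1500-unit dense
  layer, 128-dim out.

Labels are z-scored on the training set inside the trainer and restored to
original units at prediction time; this keeps the optimization scale-free
across pKd- and KIBA-valued datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from .affinity_data import AffinityDataset
from .drug_graph import FEATURE_DIM, MolecularGraph, graphs_from_table
from .protein_encoding import CorpusWeights, WordFrequencyEncoder
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import (
    Adam,
    Conv1d,
    GATConv,
    GCNConv,
    GINConv,
    Linear,
    Module,
    normalized_adjacency,
    plain_adjacency,
)

BRANCH_KINDS = ("gcn", "gin", "gat", "gat_gcn")


@dataclass
class ModelConfig:
    branch_kind: str = "gcn"
    protein_input_dim: int = 625  # 25**n
    embed_dim: int = 128
    protein_embed_dim: int = 128  # 256 reproduces the wider protein-head variant
    conv_filters: int = 32
    conv_kernel: int = 8
    batch_size: int = 512
    learning_rate: float = 5e-5
    epochs: int = 30
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.branch_kind not in BRANCH_KINDS:
            raise ValueError(
                f"unknown branch kind {self.branch_kind!r}; valid kinds: {BRANCH_KINDS}"
            )
        for name in ("protein_input_dim", "embed_dim", "protein_embed_dim",
                     "conv_filters", "conv_kernel", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss, in original label units."""

    train_mse: list[float] = field(default_factory=list)


class GraphBatch:
    """Block-diagonal batch of molecular graphs."""

    def __init__(self, graphs: list[MolecularGraph]):
        feats, srcs, dsts, batch_idx = [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            feats.append(g.node_features)
            src, dst = g.edge_arrays()
            srcs.append(src + offset)
            dsts.append(dst + offset)
            batch_idx.append(np.full(g.num_atoms, gi, dtype=np.int64))
            offset += g.num_atoms
        self.node_features = np.vstack(feats)
        self.edge_src = np.concatenate(srcs)
        self.edge_dst = np.concatenate(dsts)
        self.batch_index = np.concatenate(batch_idx)
        self.num_nodes = offset
        self.num_graphs = len(graphs)
        self._adj_norm: sparse.csr_matrix | None = None
        self._adj: sparse.csr_matrix | None = None

    @property
    def adj_norm(self) -> sparse.csr_matrix:
        if self._adj_norm is None:
            self._adj_norm = normalized_adjacency(self.edge_src, self.edge_dst, self.num_nodes)
        return self._adj_norm

    @property
    def adj(self) -> sparse.csr_matrix:
        if self._adj is None:
            self._adj = plain_adjacency(self.edge_src, self.edge_dst, self.num_nodes)
        return self._adj


class GCNBranch(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.conv1 = GCNConv(FEATURE_DIM, 78, rng)
        self.conv2 = GCNConv(78, 156, rng)
        self.conv3 = GCNConv(156, 312, rng)
        self.fc = Linear(312, 1024, rng)
        self.out = Linear(1024, cfg.embed_dim, rng)
        self.dropout = cfg.dropout

    def __call__(self, batch: GraphBatch, *, training: bool, rng: np.random.Generator) -> Tensor:
        x = Tensor(batch.node_features)
        x = ad.relu(self.conv1(x, batch.adj_norm))
        x = ad.relu(self.conv2(x, batch.adj_norm))
        x = ad.relu(self.conv3(x, batch.adj_norm))
        pooled = ad.segment_max(x, batch.batch_index, batch.num_graphs)
        h = ad.dropout(ad.relu(self.fc(pooled)), self.dropout, rng, training)
        return self.out(h)


class GINBranch(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, hidden: int = 32, units: int = 5):
        dims = [FEATURE_DIM] + [hidden] * units
        self.convs = [GINConv(dims[i], hidden, rng) for i in range(units)]
        self.out = Linear(hidden, cfg.embed_dim, rng)

    def __call__(self, batch: GraphBatch, *, training: bool, rng: np.random.Generator) -> Tensor:
        x = Tensor(batch.node_features)
        for conv in self.convs:
            x = ad.relu(conv(x, batch.adj))
        pooled = ad.segment_sum(x, batch.batch_index, batch.num_graphs)
        return self.out(pooled)


class GATBranch(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.gat1 = GATConv(FEATURE_DIM, 78, heads=10, rng=rng)
        self.gat2 = GATConv(78 * 10, 128, heads=1, rng=rng)
        self.out = Linear(128, cfg.embed_dim, rng)

    def __call__(self, batch: GraphBatch, *, training: bool, rng: np.random.Generator) -> Tensor:
        x = Tensor(batch.node_features)
        x = ad.relu(self.gat1(x, batch.edge_src, batch.edge_dst, batch.num_nodes))
        x = ad.relu(self.gat2(x, batch.edge_src, batch.edge_dst, batch.num_nodes))
        pooled = ad.segment_max(x, batch.batch_index, batch.num_graphs)
        return self.out(pooled)


class GATGCNBranch(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.gat = GATConv(FEATURE_DIM, 78, heads=10, rng=rng)
        self.gcn = GCNConv(780, 780, rng)
        self.fc = Linear(2 * 780, 1500, rng)
        self.out = Linear(1500, cfg.embed_dim, rng)
        self.dropout = cfg.dropout

    def __call__(self, batch: GraphBatch, *, training: bool, rng: np.random.Generator) -> Tensor:
        x = Tensor(batch.node_features)
        x = ad.relu(self.gat(x, batch.edge_src, batch.edge_dst, batch.num_nodes))
        x = ad.relu(self.gcn(x, batch.adj_norm))
        pooled = ad.concat(
            [
                ad.segment_max(x, batch.batch_index, batch.num_graphs),
                ad.segment_mean(x, batch.batch_index, batch.num_graphs),
            ],
            axis=1,
        )
        h = ad.dropout(ad.relu(self.fc(pooled)), self.dropout, rng, training)
        return self.out(h)


_BRANCHES = {"gcn": GCNBranch, "gin": GINBranch, "gat": GATBranch, "gat_gcn": GATGCNBranch}


def build_drug_branch(kind: str, cfg: ModelConfig, rng: np.random.Generator) -> Module:
    if kind not in _BRANCHES:
        raise ValueError(f"unknown branch kind {kind!r}; valid kinds: {BRANCH_KINDS}")
    return _BRANCHES[kind](cfg, rng)


class ProteinBranch(Module):
    """1D convolution over the word-frequency vector, dense map to the embedding."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.input_dim = cfg.protein_input_dim
        self.conv = Conv1d(cfg.conv_kernel, cfg.conv_filters, rng)
        self.out = Linear(self.conv.out_dim(cfg.protein_input_dim), cfg.protein_embed_dim, rng)

    def __call__(self, vectors: np.ndarray) -> Tensor:
        if vectors.ndim != 2 or vectors.shape[1] != self.input_dim:
            raise ValueError(
                f"protein vectors must be (batch, {self.input_dim}); got {vectors.shape}"
            )
        return self.out(ad.relu(self.conv(vectors)))


class DTAModel(Module):
    """(molecular graph, protein vector) -> scalar affinity."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng([config.seed, 0])
        self.drug_branch = build_drug_branch(config.branch_kind, config, rng)
        self.protein_branch = ProteinBranch(config, rng)
        fused = config.embed_dim + config.protein_embed_dim
        self.fc1 = Linear(fused, 512, rng)
        self.fc2 = Linear(512, 128, rng)
        self.head = Linear(128, 1, rng)
        # label standardization fitted by train()
        self.y_mean = 0.0
        self.y_std = 1.0

    def forward(
        self,
        batch: GraphBatch,
        protein_vectors: np.ndarray,
        *,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Scaled-space predictions of shape (batch, 1)."""
        rng = rng or np.random.default_rng(0)
        drug = self.drug_branch(batch, training=training, rng=rng)
        prot = self.protein_branch(protein_vectors)
        h = ad.concat([drug, prot], axis=1)
        p = self.config.dropout
        h = ad.dropout(ad.relu(self.fc1(h)), p, rng, training)
        h = ad.dropout(ad.relu(self.fc2(h)), p, rng, training)
        return self.head(h)


@dataclass
class FeaturizedPairs:
    """Featurized (drug graph, protein vector, affinity) records."""

    graphs: list[MolecularGraph]  # unique drugs
    drug_index: np.ndarray  # per record -> graphs
    protein_vectors: np.ndarray  # unique proteins x 25**n
    protein_index: np.ndarray  # per record -> rows
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "FeaturizedPairs":
        return FeaturizedPairs(
            graphs=self.graphs,
            drug_index=self.drug_index[idx],
            protein_vectors=self.protein_vectors,
            protein_index=self.protein_index[idx],
            y=self.y[idx],
        )

    def batch_inputs(self, idx: np.ndarray) -> tuple[GraphBatch, np.ndarray]:
        graphs = [self.graphs[i] for i in self.drug_index[idx]]
        return GraphBatch(graphs), self.protein_vectors[self.protein_index[idx]]


class PairFeaturizer:
    """Fits the protein encoder on training data; featurizes any dataset.

    The word-frequency weights are learned from the training proteins only
    and reused for held-out sequences; drug graphs depend on no fitted
    state.
    """

    def __init__(self, n: int = 2, *, rank_mode: str = "bonds_plus_h", **encoder_kwargs):
        self.encoder = WordFrequencyEncoder(n=n, **encoder_kwargs)
        self.rank_mode = rank_mode

    @property
    def protein_dim(self) -> int:
        return self.encoder.dim

    def fit(self, train: AffinityDataset) -> "PairFeaturizer":
        self.encoder.fit(train.proteins())
        return self

    def transform(self, ds: AffinityDataset) -> FeaturizedPairs:
        if self.encoder.weights_ is None:
            raise RuntimeError("featurizer must be fitted on the training set first")
        drugs = ds.drugs()
        graphs, report = graphs_from_table(drugs, rank_mode=self.rank_mode)
        if not report.ok:
            raise ValueError(f"unparseable drugs: {report.failures}")
        drug_pos = {d_id: i for i, (d_id, _) in enumerate(drugs)}
        proteins = ds.proteins()
        vectors = self.encoder.transform(proteins).to_numpy()
        prot_pos = {p.id: i for i, p in enumerate(proteins)}
        return FeaturizedPairs(
            graphs=graphs,
            drug_index=np.array([drug_pos[r.drug_id] for r in ds.records], dtype=np.int64),
            protein_vectors=vectors,
            protein_index=np.array([prot_pos[r.protein_id] for r in ds.records], dtype=np.int64),
            y=ds.affinities,
        )


def train(
    model: DTAModel, data: FeaturizedPairs, config: ModelConfig | None = None
) -> tuple[DTAModel, TrainingHistory]:
    """Mini-batch Adam training on MSE; returns the model and loss history.

    Reproducible under the config seed; aborts with a diagnostic on
    non-finite loss.  ``epochs=0`` returns the untrained model with an
    empty history.
    """
    config = config or model.config
    if len(data) == 0:
        raise ValueError("training set is empty")
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history

    model.y_mean = float(data.y.mean())
    model.y_std = float(data.y.std()) or 1.0
    y_scaled = (data.y - model.y_mean) / model.y_std

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng([config.seed, 1])
    dropout_rng = np.random.default_rng([config.seed, 2])
    n = len(data)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch, prot = data.batch_inputs(idx)
            pred = model.forward(batch, prot, training=True, rng=dropout_rng)
            target = Tensor(y_scaled[idx][:, None])
            loss = ad.mean((pred - target) * (pred - target))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch start {start}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_mse.append(epoch_loss / n * model.y_std**2)
    return model, history


def predict(model: DTAModel, data: FeaturizedPairs, batch_size: int | None = None) -> np.ndarray:
    """Order-preserving predictions in original label units."""
    batch_size = batch_size or model.config.batch_size
    n = len(data)
    out = np.empty(n)
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        batch, prot = data.batch_inputs(idx)
        pred = model.forward(batch, prot, training=False)
        out[idx] = pred.data.ravel() * model.y_std + model.y_mean
    return out


def save_checkpoint(path, model: DTAModel, featurizer: PairFeaturizer) -> None:
    """Persist model parameters, config, label scaling and encoder weights."""
    weights = featurizer.encoder.weights_
    if weights is None:
        raise ValueError("featurizer is unfitted; nothing to save")
    params = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {
        "config": asdict(model.config),
        "y_mean": model.y_mean,
        "y_std": model.y_std,
        "encoder_n": weights.n,
        "encoder_N": weights.n_sequences,
        "rank_mode": featurizer.rank_mode,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        encoder_counts=weights.counts,
        **params,
    )


def load_checkpoint(path) -> tuple[DTAModel, PairFeaturizer]:
    with np.load(path) as blob:
        meta = json.loads(bytes(blob["meta"]).decode())
        config = ModelConfig(**meta["config"])
        model = DTAModel(config)
        params = model.parameters()
        for i, p in enumerate(params):
            saved = blob[f"param_{i}"]
            if saved.shape != p.data.shape:
                raise ValueError("checkpoint does not match the model architecture")
            p.data = saved.copy()
        model.y_mean = meta["y_mean"]
        model.y_std = meta["y_std"]
        featurizer = PairFeaturizer(n=meta["encoder_n"], rank_mode=meta["rank_mode"])
        featurizer.encoder.weights_ = CorpusWeights(
            n=meta["encoder_n"],
            n_sequences=meta["encoder_N"],
            counts=blob["encoder_counts"].copy(),
        )
    return model, featurizer
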