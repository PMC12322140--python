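"""Attention-based multiple instance learning over multimodal embedding bags.

A *bag* is one patient's set of instance embeddings — tiles sampled from a
whole-slide image and/or from multi-stain tissue-microarray cores, already
encoded to fixed-dimension vectors — with a bag-level label.  The model is
a gated-attention pooling network (two-layer tanh x sigmoid gate, hidden
size 32 by default): per-instance attention weights are softmax-normalized,
the bag representation is the attention-weighted sum of instance
embeddings, and a linear head produces the bag score.  Training minimizes
the bag-level cross-entropy plus a clustering term: the top-k most and
bottom-k least attended instances receive pseudo-labels (bag label and 0
respectively) and a separate instance classifier is fitted to them with
binary cross-entropy, encouraging attention to concentrate on instances
that separate the classes.  Gradients are derived analytically and
optimized with Adam; everything is plain numpy and reproducible by seed.

Attention weights double as the interpretability signal: per-source
aggregation of the weights shows which modality (WSI vs. each TMA stain)
the model relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._utils import child_rng, child_seed
from .predict import OutcomeLabels, THREE_YEARS
from .records import Cohort

__all__ = [
    "Bag",
    "BagConfig",
    "MILParams",
    "MILModel",
    "MILEnsemble",
    "AttentionResult",
    "TMA_STAINS",
    "make_bags",
    "mil_survival_labels",
    "train_mil",
    "attend",
    "predict_bags",
    "modality_attention_summary",
]

TMA_STAINS = ("TMA:CD163", "TMA:CD3", "TMA:CD56", "TMA:CD68", "TMA:CD8",
              "TMA:HE", "TMA:MHC1", "TMA:PDL1")


@dataclass
class Bag:
    """One patient's instance embeddings with per-instance source tags."""

    patient_id: str
    instances: np.ndarray            # (n_instances, d)
    source_tags: list[str]
    label: int | None = None
    informative: np.ndarray | None = None  # planted ground truth, if known

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=float)
        if self.instances.ndim != 2 or self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance embedding")
        if len(self.source_tags) != self.instances.shape[0]:
            raise ValueError("source_tags must align with instances")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


@dataclass
class BagConfig:
    """Bag-assembly parameters (defaults echo the study protocol: 32 tiles
    per TMA core, two cores per stain, eight stains)."""

    sources: tuple[str, ...] = ("WSI",)
    wsi_instances: int = 64
    tma_tiles_per_core: int = 32
    tma_cores: int = 2
    seed: int = 0


def make_bags(cohort: Cohort, embed_source, config: BagConfig,
              labels: dict[str, int] | None = None) -> list[Bag]:
    """Assemble per-patient bags from an embedding source.

    ``embed_source`` must provide ``instances(patient_id, source_tag, n)``
    returning (embeddings, informative_mask); labels default to
    ``embed_source.labels``.  Patients whose bags would be empty are skipped.
    """
    labels = labels if labels is not None else getattr(embed_source, "labels", {})
    bags = []
    for rec in cohort:
        pid = rec.patient_id
        emb_parts, tags, info_parts = [], [], []
        for src in config.sources:
            n = config.wsi_instances if src == "WSI" \
                else config.tma_tiles_per_core * config.tma_cores
            if n <= 0:
                continue
            emb, informative = embed_source.instances(pid, src, n)
            emb_parts.append(emb)
            info_parts.append(informative)
            tags.extend([src] * n)
        if not emb_parts:
            continue
        bags.append(Bag(patient_id=pid,
                        instances=np.vstack(emb_parts),
                        source_tags=tags,
                        label=labels.get(pid),
                        informative=np.concatenate(info_parts)))
    return bags


def mil_survival_labels(cohort: Cohort) -> OutcomeLabels:
    """3-year survival-status labels for bag-level training.

    Deceased within 1095 days -> positive (deceased class); deceased later
    than 1095 days -> force-labeled negative (alive at 3 years); alive with
    at least 1095 days of follow-up -> negative; alive with shorter
    follow-up -> excluded (status at 3 years unknown).
    """
    states: dict[str, str] = {}
    reasons: dict[str, str] = {}
    for rec in cohort:
        pid = rec.patient_id
        if rec.death_days is not None:
            states[pid] = "positive" if rec.death_days <= THREE_YEARS else "negative"
        elif rec.followup_days >= THREE_YEARS:
            states[pid] = "negative"
        else:
            states[pid] = "excluded"
            reasons[pid] = "alive with under 3 years of follow-up"
    return OutcomeLabels("mil_survival", states, reasons)


@dataclass
class MILParams:
    """Training hyperparameters for the gated-attention network.

    ``restarts > 1`` trains independently initialized networks on the same
    bags and averages their scores and attention weights (a small ensemble
    that damps the variance of per-bag stochastic optimization).
    """

    epochs: int = 60
    lr: float = 3e-3
    clustering_loss_weight: float = 0.3
    topk: int = 8
    hidden: int = 32
    n_classes: int = 2
    restarts: int = 3
    seed: int = 0


@dataclass
class MILModel:
    """Gated-attention MIL network weights plus training traces."""

    V: np.ndarray            # (d, H) tanh branch
    U: np.ndarray            # (d, H) sigmoid gate branch
    w: np.ndarray            # (H,)  attention projection
    C: np.ndarray            # (d, K) bag classifier (K=1: binary sigmoid)
    b: np.ndarray            # (K,)
    u_inst: np.ndarray       # (d,)  instance pseudo-label head
    b_inst: float
    loss_trace: list[float] = dc_field(default_factory=list)
    bag_loss_trace: list[float] = dc_field(default_factory=list)
    inst_loss_trace: list[float] = dc_field(default_factory=list)

    @property
    def embed_dim(self) -> int:
        return self.V.shape[0]

    @property
    def n_logits(self) -> int:
        return self.C.shape[1]


@dataclass
class AttentionResult:
    """Per-instance attention, bag-level score and per-source aggregates."""

    weights: np.ndarray
    bag_score: float                  # positive-class probability (binary)
    class_probs: np.ndarray
    source_weight_sums: dict[str, float]

    def top_k(self, k: int) -> np.ndarray:
        """Indices of the k most-attended instances; ties break to the
        lowest index (stable sort on descending weight)."""
        order = np.argsort(-self.weights, kind="stable")
        return order[:k]


def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))


def _forward(model: MILModel, h: np.ndarray):
    """Attention forward pass; returns (a, z, logits, cache)."""
    p = np.tanh(h @ model.V)
    q = _sigmoid(h @ model.U)
    g = p * q
    e = g @ model.w
    e = e - e.max()
    ex = np.exp(e)
    a = ex / ex.sum()
    z = a @ h
    logits = z @ model.C + model.b
    return a, z, logits, (p, q, g)


def _bag_loss_grad(logits: np.ndarray, y: int, n_classes: int):
    """Cross-entropy loss and d(loss)/d(logits)."""
    if logits.size == 1:  # binary with a single sigmoid logit
        s = float(logits[0])
        loss = max(s, 0.0) - s * y + np.log1p(np.exp(-abs(s)))
        grad = np.array([float(_sigmoid(np.array(s))) - y])
        probs = np.array([1.0 - float(_sigmoid(np.array(s))), float(_sigmoid(np.array(s)))])
    else:
        m = logits - logits.max()
        ex = np.exp(m)
        probs = ex / ex.sum()
        loss = -float(np.log(max(probs[y], 1e-12)))
        grad = probs.copy()
        grad[y] -= 1.0
    return float(loss), grad, probs


@dataclass
class MILEnsemble:
    """Average of independently initialized gated-attention networks."""

    models: list[MILModel]

    @property
    def embed_dim(self) -> int:
        return self.models[0].embed_dim

    @property
    def n_logits(self) -> int:
        return self.models[0].n_logits

    @property
    def loss_trace(self) -> list[float]:
        return list(np.mean([m.loss_trace for m in self.models], axis=0))

    @property
    def bag_loss_trace(self) -> list[float]:
        return list(np.mean([m.bag_loss_trace for m in self.models], axis=0))

    @property
    def inst_loss_trace(self) -> list[float]:
        return list(np.mean([m.inst_loss_trace for m in self.models], axis=0))


def train_mil(bags: list[Bag], params: MILParams | None = None
              ) -> MILModel | MILEnsemble:
    """Fit the gated-attention MIL model on labeled bags.

    Requires at least two bags per class.  With
    ``clustering_loss_weight == 0`` the objective is exactly the plain
    attention-MIL bag loss (the instance term contributes nothing).
    Returns a single :class:`MILModel` when ``params.restarts == 1``, else
    an averaging :class:`MILEnsemble`.
    """
    params = params or MILParams()
    if params.restarts < 1:
        raise ValueError("restarts must be >= 1")
    if params.restarts > 1:
        models = []
        for r in range(params.restarts):
            sub = MILParams(**{**params.__dict__,
                               "restarts": 1,
                               "seed": child_seed(params.seed, "restart", r)})
            models.append(train_mil(bags, sub))
        return MILEnsemble(models)
    labeled = [bg for bg in bags if bg.label is not None]
    counts: dict[int, int] = {}
    for bg in labeled:
        counts[bg.label] = counts.get(bg.label, 0) + 1
    if len(counts) < 2:
        raise ValueError("training requires bags from at least two classes")
    if min(counts.values()) < 2:
        raise ValueError("training requires at least two bags per class")
    d = labeled[0].instances.shape[1]
    for bg in labeled:
        if bg.instances.shape[1] != d:
            raise ValueError("all bags must share one embedding dimension")

    H = params.hidden
    K = 1 if params.n_classes == 2 else params.n_classes
    rng = child_rng(params.seed, "mil-init")
    model = MILModel(
        V=rng.normal(scale=1.0 / np.sqrt(d), size=(d, H)),
        U=rng.normal(scale=1.0 / np.sqrt(d), size=(d, H)),
        w=rng.normal(scale=1.0 / np.sqrt(H), size=H),
        C=rng.normal(scale=1.0 / np.sqrt(d), size=(d, K)),
        b=np.zeros(K),
        u_inst=rng.normal(scale=1.0 / np.sqrt(d), size=d),
        b_inst=0.0,
    )
    names = ("V", "U", "w", "C", "b", "u_inst", "b_inst")
    m_state = {nm: np.zeros_like(np.asarray(getattr(model, nm), dtype=float)) for nm in names}
    v_state = {nm: np.zeros_like(np.asarray(getattr(model, nm), dtype=float)) for nm in names}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    order_rng = child_rng(params.seed, "mil-order")
    lam = params.clustering_loss_weight

    for _epoch in range(params.epochs):
        order = order_rng.permutation(len(labeled))
        ep_bag, ep_inst = 0.0, 0.0
        for bi in order:
            bag = labeled[bi]
            h = bag.instances
            n = h.shape[0]
            y = int(bag.label)
            a, z, logits, (p, q, g) = _forward(model, h)
            bag_loss, dlogits, _probs = _bag_loss_grad(logits, y, params.n_classes)

            # backprop through the linear head and attention pooling
            gC = np.outer(z, dlogits)
            gb = dlogits
            dz = model.C @ dlogits
            da = h @ dz
            de = a * (da - float(a @ da))          # softmax backward
            gw = g.T @ de
            dg = np.outer(de, model.w)
            dp = dg * q
            dq = dg * p
            gV = h.T @ (dp * (1.0 - p**2))
            gU = h.T @ (dq * q * (1.0 - q))

            # clustering term: BCE on top-k / bottom-k attended instances
            inst_loss = 0.0
            gu = np.zeros_like(model.u_inst)
            gbi = 0.0
            if lam > 0:
                k = min(params.topk, n // 2) or 1
                order_a = np.argsort(-a, kind="stable")
                sel = np.concatenate([order_a[:k], order_a[-k:]])
                pseudo = np.concatenate([np.full(k, float(min(y, 1))), np.zeros(k)])
                hs = h[sel]
                s_inst = hs @ model.u_inst + model.b_inst
                pr = _sigmoid(s_inst)
                inst_loss = float(np.mean(
                    np.maximum(s_inst, 0) - s_inst * pseudo + np.log1p(np.exp(-np.abs(s_inst)))))
                dinst = (pr - pseudo) / sel.size
                gu = hs.T @ dinst
                gbi = float(dinst.sum())

            grads = {"V": gV, "U": gU, "w": gw, "C": gC, "b": gb,
                     "u_inst": lam * gu, "b_inst": lam * gbi}
            step += 1
            for nm in names:
                gcur = np.asarray(grads[nm], dtype=float)
                m_state[nm] = beta1 * m_state[nm] + (1 - beta1) * gcur
                v_state[nm] = beta2 * v_state[nm] + (1 - beta2) * gcur**2
                mhat = m_state[nm] / (1 - beta1**step)
                vhat = v_state[nm] / (1 - beta2**step)
                upd = params.lr * mhat / (np.sqrt(vhat) + eps)
                if nm == "b_inst":
                    model.b_inst = float(model.b_inst - upd)
                else:
                    setattr(model, nm, getattr(model, nm) - upd)
            ep_bag += bag_loss
            ep_inst += inst_loss
        nb = len(labeled)
        model.bag_loss_trace.append(ep_bag / nb)
        model.inst_loss_trace.append(ep_inst / nb)
        model.loss_trace.append((ep_bag + lam * ep_inst) / nb)
    return model


def attend(model: MILModel | MILEnsemble, bag: Bag) -> AttentionResult:
    """Attention weights (sum to 1), bag score and per-source weight sums.

    For an ensemble, weights and class probabilities are the average over
    member networks (the average of softmax weight vectors still sums to 1).
    """
    if bag.instances.shape[1] != model.embed_dim:
        raise ValueError(f"bag dimension {bag.instances.shape[1]} does not match "
                         f"model dimension {model.embed_dim}")
    members = model.models if isinstance(model, MILEnsemble) else [model]
    # canonicalize instance order so attention is exactly permutation-
    # equivariant (floating-point summation is order-dependent otherwise)
    h = bag.instances
    order = np.lexsort(h.T[::-1])
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    ws, ps = [], []
    for mem in members:
        a_sorted, _z, logits, _ = _forward(mem, h[order])
        a = a_sorted[inv]
        _loss, _grad, probs = _bag_loss_grad(logits, 0,
                                             mem.n_logits if mem.n_logits > 1 else 2)
        ws.append(a)
        ps.append(probs)
    a = np.mean(ws, axis=0)
    probs = np.mean(ps, axis=0)
    score = float(probs[1]) if probs.size == 2 else float(probs.max())
    sums: dict[str, float] = {}
    for tag, wt in zip(bag.source_tags, a):
        sums[tag] = sums.get(tag, 0.0) + float(wt)
    return AttentionResult(weights=a, bag_score=score, class_probs=probs,
                           source_weight_sums=sums)


def predict_bags(model: MILModel | MILEnsemble, bags: list[Bag]) -> np.ndarray:
    """Positive-class bag scores (binary) or max-class probability."""
    return np.array([attend(model, bg).bag_score for bg in bags])


def modality_attention_summary(model: MILModel, bags: list[Bag],
                               n_bins: int = 20) -> dict[str, dict]:
    """Per-source attention distributions over all instances of all bags.

    Weights are reported as produced by the softmax (not renormalized per
    source); per bag, the per-source sums therefore partition 1.
    """
    per_source: dict[str, list[float]] = {}
    for bag in bags:
        res = attend(model, bag)
        for tag, wt in zip(bag.source_tags, res.weights):
            per_source.setdefault(tag, []).append(float(wt))
    top = max((max(v) for v in per_source.values()), default=1.0)
    out = {}
    for tag, vals in sorted(per_source.items()):
        arr = np.asarray(vals)
        counts, edges = np.histogram(arr, bins=n_bins, range=(0.0, top))
        out[tag] = {"mean": float(arr.mean()), "n_instances": int(arr.size),
                    "hist_counts": counts, "hist_edges": edges}
    return out
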