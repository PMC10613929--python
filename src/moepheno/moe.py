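"""Outcomes-driven deep mixture of experts.

Architecture
------------
A *selector network* (multilayer perceptron) sees only presentation-tier
features and emits (i) a softmax gate vector over the K experts — the soft
phenotype membership — and (ii) optionally an initial pre-treatment risk
estimate.  Each *expert network* sees the selector's final hidden layer
(pass-through) concatenated with the treatment-tier features and emits an
outcome probability.  The model prediction is the gate-weighted vote
``yhat = sum_k g_k p_k``.

Training minimizes binary cross-entropy of the vote plus an L2 penalty on the
gate vector, ``lambda * mean_rows sum_k g_k^2``.  The penalty is smallest
(``lambda/K``) at uniform gates and largest (``lambda``) at one-hot gates, so
it pushes against the single-expert collapse seen in under-regularized
mixtures while large values flatten the gates entirely.

Everything is plain NumPy with hand-written backpropagation and an Adam
optimizer; gradient correctness is covered by finite-difference tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .schema import CohortSchema, CohortTable

__all__ = [
    "MoEConfig",
    "MoEModel",
    "MoEPrediction",
    "SIZE_PRESETS",
    "impute_missing",
    "fit_preprocessing",
    "apply_preprocessing",
    "build_moe",
    "moe_forward",
    "predict_table",
    "gating_penalty",
    "training_loss",
    "train_moe",
    "assign_clusters",
    "save_model",
    "load_model",
]

#: hidden-layer widths (selector, expert) per size preset: the large preset is
#: three 50-unit layers everywhere, mid is two 24-unit layers, and small keeps
#: the mid-sized selector but reduces each expert to a single prediction layer.
SIZE_PRESETS: dict[str, tuple[list[int], list[int]]] = {
    "large": ([50, 50, 50], [50, 50, 50]),
    "mid": ([24, 24], [24, 24]),
    "small": ([24, 24], []),
}

CONNECTION_VARIANTS = ("standard", "later_hidden", "no_hidden")
MAX_EXPERTS = 10  # interpretability cap; also sidesteps the shrinking-batch problem

_EPS = 1e-7


@dataclass
class MoEConfig:
    n_experts: int = 5
    size_preset: str = "small"
    connection_variant: str = "standard"
    initial_risk: bool = True
    gating_l2: float = 0.01
    penalty_on: str = "gates"  # "gates" (post-softmax, default) or "scores"
    aux_weight: float = 0.1  # weight of the initial-risk auxiliary loss
    epochs: int = 150
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 10
    standardize: bool = True
    gate_init: str = "kmeans"  # "kmeans" (pretrained gate) or "random"
    pretrain_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_experts <= MAX_EXPERTS:
            raise ValueError(f"n_experts must lie in [2, {MAX_EXPERTS}]")
        if self.size_preset not in SIZE_PRESETS:
            raise ValueError(f"unknown size preset {self.size_preset!r}")
        if self.connection_variant not in CONNECTION_VARIANTS:
            raise ValueError(f"unknown connection variant {self.connection_variant!r}")
        if self.gating_l2 < 0:
            raise ValueError("gating_l2 must be nonnegative")
        if self.penalty_on not in ("gates", "scores"):
            raise ValueError("penalty_on must be 'gates' or 'scores'")
        if self.gate_init not in ("kmeans", "random"):
            raise ValueError("gate_init must be 'kmeans' or 'random'")


@dataclass
class MoEPrediction:
    """Per-row gates (n,K), expert risks (n,K), weighted-vote risk (n,), and
    the optional pre-treatment initial risk (n,)."""

    gates: np.ndarray
    expert_risks: np.ndarray
    final_risk: np.ndarray
    initial_risk: Optional[np.ndarray] = None


@dataclass
class MoEModel:
    """Opaque model handle: parameter dict + config + schema + preprocessing
    statistics (imputation means and z-scoring moments, learned on the
    training split only)."""

    config: MoEConfig
    schema: CohortSchema
    params: dict[str, np.ndarray]
    stats: Optional[dict] = None


# --- imputation and scaling ------------------------------------------------


def impute_missing(
    table: CohortTable, schema: Optional[CohortSchema] = None, means: Optional[pd.Series] = None
) -> tuple[CohortTable, pd.Series]:
    """Fill missing feature cells: binary -> 0 ("no"), continuous -> column mean.

    ``means`` holds the continuous-column means to reuse (e.g. train-split
    statistics applied to a test split); when absent they are computed from
    ``table`` and returned for reuse.
    """
    schema = schema or table.schema
    df = table.features.copy()
    if table.missing_mask is not None:
        df = df.mask(table.missing_mask.to_numpy())
    if means is None:
        cont = schema.names(kind="continuous")
        means = df[cont].mean()
        if means.isna().any():
            bad = list(means.index[means.isna()])
            raise ValueError(f"columns entirely missing, no stored mean: {bad}")
    for f in schema.features:
        col = df[f.name]
        if not col.isna().any():
            continue
        if f.kind == "binary":
            df[f.name] = col.fillna(0.0)
        else:
            if f.name not in means.index or pd.isna(means[f.name]):
                raise ValueError(f"column {f.name!r} entirely missing and no stored mean")
            df[f.name] = col.fillna(means[f.name])
    out = CohortTable(
        features=df,
        outcome=table.outcome,
        schema=schema,
        latent_labels=table.latent_labels,
        missing_mask=None,
    )
    return out, means


def fit_preprocessing(table: CohortTable, schema: Optional[CohortSchema] = None, standardize: bool = True) -> dict:
    """Learn imputation means and (optionally) z-scoring moments of the
    continuous columns from a training split."""
    schema = schema or table.schema
    imputed, means = impute_missing(table, schema)
    stats: dict = {"impute_means": means, "standardize": standardize, "mu": {}, "sd": {}}
    if standardize:
        for name in schema.names(kind="continuous"):
            col = imputed.features[name].to_numpy(dtype=float)
            sd = float(col.std())
            stats["mu"][name] = float(col.mean())
            stats["sd"][name] = sd if sd > 1e-12 else 1.0
    return stats


def apply_preprocessing(table: CohortTable, stats: dict, schema: Optional[CohortSchema] = None) -> CohortTable:
    schema = schema or table.schema
    imputed, _ = impute_missing(table, schema, means=stats["impute_means"])
    if stats.get("standardize"):
        df = imputed.features
        for name, mu in stats["mu"].items():
            df[name] = (df[name] - mu) / stats["sd"][name]
    return imputed


# --- parameter construction ------------------------------------------------


def _layer_dims(config: MoEConfig, schema: CohortSchema) -> dict:
    dp, dt = len(schema.presentation), len(schema.treatment)
    sel_hidden, exp_hidden = SIZE_PRESETS[config.size_preset]
    variant = config.connection_variant
    if variant == "standard":
        exp_in = sel_hidden[-1] + dt
        out_extra = 0
    elif variant == "no_hidden":
        exp_in = dp + dt
        out_extra = 0
    else:  # later_hidden: experts consume treatment data; the selector's
        # *first* hidden layer is injected right before the prediction layer
        exp_in = dt
        out_extra = sel_hidden[0]
    return {
        "dp": dp,
        "dt": dt,
        "sel_hidden": sel_hidden,
        "exp_hidden": exp_hidden,
        "exp_in": exp_in,
        "out_extra": out_extra,
    }


def build_moe(config: MoEConfig, schema: CohortSchema) -> MoEModel:
    """Initialize an MoE with seeded He/Xavier weights for the given schema."""
    if not schema.presentation or not schema.treatment:
        raise ValueError("schema needs at least one presentation and one treatment feature")
    dims = _layer_dims(config, schema)
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}

    def he(fan_in: int, fan_out: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))

    def xavier(fan_in: int, fan_out: int) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out))

    prev = dims["dp"]
    for i, w in enumerate(dims["sel_hidden"]):
        params[f"sel{i}_W"], params[f"sel{i}_b"] = he(prev, w), np.zeros(w)
        prev = w
    params["gate_W"], params["gate_b"] = xavier(prev, config.n_experts), np.zeros(config.n_experts)
    if config.initial_risk:
        params["risk_W"], params["risk_b"] = xavier(prev, 1), np.zeros(1)
    for k in range(config.n_experts):
        prev_e = dims["exp_in"]
        for i, w in enumerate(dims["exp_hidden"]):
            params[f"e{k}_{i}_W"], params[f"e{k}_{i}_b"] = he(prev_e, w), np.zeros(w)
            prev_e = w
        params[f"e{k}_out_W"] = xavier(prev_e + dims["out_extra"], 1)
        params[f"e{k}_out_b"] = np.zeros(1)
    return MoEModel(config=config, schema=schema, params=params)


# --- forward / backward ----------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(model: MoEModel, Xp: np.ndarray, Xt: np.ndarray) -> dict:
    cfg, params = model.config, model.params
    dims = _layer_dims(cfg, model.schema)
    K = cfg.n_experts
    n_sel = len(dims["sel_hidden"])
    cache: dict = {"Xp": Xp, "Xt": Xt}

    h = Xp
    sel_z, sel_h = [], []
    for i in range(n_sel):
        z = h @ params[f"sel{i}_W"] + params[f"sel{i}_b"]
        h = np.maximum(z, 0.0)
        sel_z.append(z)
        sel_h.append(h)
    cache["sel_z"], cache["sel_h"] = sel_z, sel_h

    s = sel_h[-1] @ params["gate_W"] + params["gate_b"]
    g = _softmax(s)
    cache["scores"], cache["gates"] = s, g
    if cfg.initial_risk:
        ar = sel_h[-1] @ params["risk_W"] + params["risk_b"]
        cache["risk_a"] = ar
        cache["r0"] = _sigmoid(ar)[:, 0]

    variant = cfg.connection_variant
    if variant == "standard":
        exp_base = np.hstack([sel_h[-1], Xt])
    elif variant == "no_hidden":
        exp_base = np.hstack([Xp, Xt])
    else:
        exp_base = Xt
    cache["exp_base"] = exp_base

    P = np.empty((Xp.shape[0], K))
    cache["exp"] = []
    n_exp = len(dims["exp_hidden"])
    for k in range(K):
        u = exp_base
        ez, eh = [], []
        for i in range(n_exp):
            z = u @ params[f"e{k}_{i}_W"] + params[f"e{k}_{i}_b"]
            u = np.maximum(z, 0.0)
            ez.append(z)
            eh.append(u)
        if variant == "later_hidden":
            u = np.hstack([u, sel_h[0]])
        a = u @ params[f"e{k}_out_W"] + params[f"e{k}_out_b"]
        p = _sigmoid(a)[:, 0]
        P[:, k] = p
        cache["exp"].append({"z": ez, "h": eh, "out_in": u, "a": a, "p": p})
    cache["P"] = P
    cache["yhat"] = (g * P).sum(axis=1)
    return cache


def _backward(model: MoEModel, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of `training_loss` w.r.t. every parameter, for one batch."""
    cfg, params = model.config, model.params
    dims = _layer_dims(cfg, model.schema)
    K, lam = cfg.n_experts, cfg.gating_l2
    n = len(y)
    g, P = cache["gates"], cache["P"]
    yhat = np.clip(cache["yhat"], _EPS, 1 - _EPS)
    grads: dict[str, np.ndarray] = {}

    dyhat = (yhat - y) / (yhat * (1 - yhat)) / n
    dP = dyhat[:, None] * g
    dg = dyhat[:, None] * P
    if lam > 0 and cfg.penalty_on == "gates":
        dg = dg + 2.0 * lam * g / n

    n_sel = len(dims["sel_hidden"])
    dH = [np.zeros_like(h) for h in cache["sel_h"]]

    # experts
    n_exp = len(dims["exp_hidden"])
    variant = cfg.connection_variant
    d_exp_base = np.zeros_like(cache["exp_base"])
    for k in range(K):
        ek = cache["exp"][k]
        p = ek["p"]
        da = (dP[:, k] * p * (1 - p))[:, None]
        grads[f"e{k}_out_W"] = ek["out_in"].T @ da
        grads[f"e{k}_out_b"] = da.sum(axis=0)
        du = da @ params[f"e{k}_out_W"].T
        if variant == "later_hidden":
            split = du.shape[1] - dims["out_extra"]
            dH[0] += du[:, split:]
            du = du[:, :split]
        for i in range(n_exp - 1, -1, -1):
            dz = du * (ek["z"][i] > 0)
            prev = ek["h"][i - 1] if i > 0 else cache["exp_base"]
            grads[f"e{k}_{i}_W"] = prev.T @ dz
            grads[f"e{k}_{i}_b"] = dz.sum(axis=0)
            du = dz @ params[f"e{k}_{i}_W"].T
        d_exp_base += du
    if variant == "standard":
        dH[-1] += d_exp_base[:, : dims["sel_hidden"][-1]]
    # no_hidden / later_hidden: raw-feature gradients are discarded

    # gating layer (softmax backward), optional score-space penalty
    ds = g * (dg - (dg * g).sum(axis=1, keepdims=True))
    if lam > 0 and cfg.penalty_on == "scores":
        ds = ds + 2.0 * lam * cache["scores"] / n
    grads["gate_W"] = cache["sel_h"][-1].T @ ds
    grads["gate_b"] = ds.sum(axis=0)
    dH[-1] += ds @ params["gate_W"].T

    if cfg.initial_risk:
        r0 = cache["r0"]
        dar = (cfg.aux_weight * (r0 - y) / n)[:, None]
        grads["risk_W"] = cache["sel_h"][-1].T @ dar
        grads["risk_b"] = dar.sum(axis=0)
        dH[-1] += dar @ params["risk_W"].T

    # selector stack
    dh = dH[-1]
    for i in range(n_sel - 1, -1, -1):
        dz = dh * (cache["sel_z"][i] > 0)
        prev = cache["sel_h"][i - 1] if i > 0 else cache["Xp"]
        grads[f"sel{i}_W"] = prev.T @ dz
        grads[f"sel{i}_b"] = dz.sum(axis=0)
        if i > 0:
            dh = dz @ params[f"sel{i}_W"].T + dH[i - 1]
    return grads


def moe_forward(model: MoEModel, presentation_rows: np.ndarray, treatment_rows: np.ndarray) -> MoEPrediction:
    """Run the model on already-imputed, already-scaled feature matrices."""
    Xp = np.atleast_2d(np.asarray(presentation_rows, dtype=float))
    Xt = np.atleast_2d(np.asarray(treatment_rows, dtype=float))
    dims = _layer_dims(model.config, model.schema)
    if Xp.shape[1] != dims["dp"] or Xt.shape[1] != dims["dt"]:
        raise ValueError("row dimensions do not match schema tiers")
    cache = _forward(model, Xp, Xt)
    return MoEPrediction(
        gates=cache["gates"],
        expert_risks=cache["P"],
        final_risk=cache["yhat"],
        initial_risk=cache.get("r0"),
    )


def predict_table(model: MoEModel, table: CohortTable) -> MoEPrediction:
    """Preprocess a cohort with the model's stored statistics and predict."""
    if model.stats is None:
        raise ValueError("model has no preprocessing statistics; train it first")
    prepped = apply_preprocessing(table, model.stats, model.schema)
    return moe_forward(model, prepped.presentation_matrix(), prepped.treatment_matrix())


# --- losses ----------------------------------------------------------------


def gating_penalty(gates: np.ndarray, lam: float) -> float:
    """``lam * mean_rows sum_k g_k^2`` — lam at one-hot gates, lam/K at uniform."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    g = np.atleast_2d(np.asarray(gates, dtype=float))
    return float(lam * (g**2).sum(axis=1).mean())


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def training_loss(y: np.ndarray, prediction: MoEPrediction, lam: float, aux_weight: float = 0.1) -> float:
    """Cross-entropy of the weighted vote + gate penalty (+ auxiliary
    cross-entropy of the selector's initial risk, if present)."""
    y = np.asarray(y, dtype=float)
    loss = _bce(y, prediction.final_risk) + gating_penalty(prediction.gates, lam)
    if prediction.initial_risk is not None:
        loss += aux_weight * _bce(y, prediction.initial_risk)
    return loss


# --- training --------------------------------------------------------------


def _pretrain_gate(model: MoEModel, Xp: np.ndarray, cfg: MoEConfig) -> None:
    """Warm-start the selector's gate toward a k-means partition of the
    presentation features.

    The joint gating objective is multi-modal; cold-started runs can settle
    in optima where planted subgroups are split or merged across experts.
    Pretraining the selector to reproduce an unsupervised k-means partition
    (the classic initialization for mixture models) starts the experts
    specialized, after which joint outcome-driven training refines both the
    partition and the risk estimates.  Expert parameters are untouched.
    """
    from sklearn.cluster import KMeans

    km = KMeans(cfg.n_experts, n_init=4, random_state=cfg.seed % (2**31)).fit(Xp)
    onehot = np.eye(cfg.n_experts)[km.labels_]
    params = model.params
    keys = [k for k in params if k.startswith("sel") or k.startswith("gate")]
    m = {k: np.zeros_like(params[k]) for k in keys}
    v = {k: np.zeros_like(params[k]) for k in keys}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(Xp)
    rng = np.random.default_rng(cfg.seed + 2)
    n_sel = sum(1 for k in params if k.endswith("_W") and k.startswith("sel"))
    for _ in range(cfg.pretrain_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            ix = perm[start : start + cfg.batch_size]
            X = Xp[ix]
            h, zs, hs = X, [], []
            for i in range(n_sel):
                z = h @ params[f"sel{i}_W"] + params[f"sel{i}_b"]
                h = np.maximum(z, 0.0)
                zs.append(z)
                hs.append(h)
            g = _softmax(h @ params["gate_W"] + params["gate_b"])
            ds = (g - onehot[ix]) / len(ix)  # CE-through-softmax gradient
            grads = {"gate_W": hs[-1].T @ ds, "gate_b": ds.sum(axis=0)}
            dh = ds @ params["gate_W"].T
            for i in range(n_sel - 1, -1, -1):
                dz = dh * (zs[i] > 0)
                prev = hs[i - 1] if i > 0 else X
                grads[f"sel{i}_W"] = prev.T @ dz
                grads[f"sel{i}_b"] = dz.sum(axis=0)
                dh = dz @ params[f"sel{i}_W"].T
            step += 1
            for key, gr in grads.items():
                m[key] = b1 * m[key] + (1 - b1) * gr
                v[key] = b2 * v[key] + (1 - b2) * gr**2
                params[key] -= cfg.learning_rate * (m[key] / (1 - b1**step)) / (
                    np.sqrt(v[key] / (1 - b2**step)) + eps
                )


def train_moe(
    model: MoEModel,
    train_table: CohortTable,
    val_table: CohortTable,
    config: Optional[MoEConfig] = None,
) -> tuple[MoEModel, dict]:
    """Fit by Adam on minibatches with early stopping on validation loss.

    Preprocessing statistics (imputation means, z-scoring moments) are fit on
    the training split only and stored on the returned model.  Deterministic
    for a fixed config seed.
    """
    cfg = config or model.config
    if val_table.n == 0:
        raise ValueError("validation set is empty")
    stats = fit_preprocessing(train_table, model.schema, standardize=cfg.standardize)
    model.stats = stats
    tr = apply_preprocessing(train_table, stats, model.schema)
    va = apply_preprocessing(val_table, stats, model.schema)
    Xp, Xt, y = tr.presentation_matrix(), tr.treatment_matrix(), tr.outcome.astype(float)
    Vp, Vt, vy = va.presentation_matrix(), va.treatment_matrix(), va.outcome.astype(float)

    if cfg.gate_init == "kmeans":
        _pretrain_gate(model, Xp, cfg)

    rng = np.random.default_rng(cfg.seed + 1)
    params = model.params
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(y)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val, best_params, since_best = np.inf, {k: p.copy() for k, p in params.items()}, 0

    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            cache = _forward(model, Xp[idx], Xt[idx])
            grads = _backward(model, cache, y[idx])
            step += 1
            for key, gr in grads.items():
                m[key] = b1 * m[key] + (1 - b1) * gr
                v[key] = b2 * v[key] + (1 - b2) * gr**2
                mh = m[key] / (1 - b1**step)
                vh = v[key] / (1 - b2**step)
                params[key] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            pred = MoEPrediction(
                gates=cache["gates"], expert_risks=cache["P"], final_risk=cache["yhat"],
                initial_risk=cache.get("r0"),
            )
            ep_loss += training_loss(y[idx], pred, cfg.gating_l2, cfg.aux_weight) * len(idx)
        history["train_loss"].append(ep_loss / n)

        vpred = moe_forward(model, Vp, Vt)
        vloss = training_loss(vy, vpred, cfg.gating_l2, cfg.aux_weight)
        history["val_loss"].append(vloss)
        if vloss < best_val - 1e-6:
            best_val, since_best = vloss, 0
            best_params = {k: p.copy() for k, p in params.items()}
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.params = best_params
    history["best_val_loss"] = best_val
    history["epochs_run"] = len(history["train_loss"])
    return model, history


def assign_clusters(prediction: MoEPrediction) -> tuple[np.ndarray, np.ndarray]:
    """Hard phenotype label (argmax gate; ties -> lowest index) and the soft
    membership (the gate vector itself)."""
    return prediction.gates.argmax(axis=1), prediction.gates


# --- persistence -----------------------------------------------------------


def save_model(model: MoEModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "params.npz", **model.params)
    meta = {
        "config": asdict(model.config),
        "schema": {
            "outcome": model.schema.outcome,
            "features": [[f.name, f.kind, f.tier] for f in model.schema.features],
        },
    }
    if model.stats is not None:
        meta["stats"] = {
            "impute_means": {k: float(v) for k, v in model.stats["impute_means"].items()},
            "standardize": model.stats["standardize"],
            "mu": model.stats["mu"],
            "sd": model.stats["sd"],
        }
    (path / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> MoEModel:
    from .schema import FeatureSpec

    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    schema = CohortSchema(
        features=tuple(FeatureSpec(*row) for row in meta["schema"]["features"]),
        outcome=meta["schema"]["outcome"],
    )
    config = MoEConfig(**meta["config"])
    with np.load(path / "params.npz") as z:
        params = {k: z[k] for k in z.files}
    stats = None
    if "stats" in meta:
        stats = {
            "impute_means": pd.Series(meta["stats"]["impute_means"]),
            "standardize": meta["stats"]["standardize"],
            "mu": meta["stats"]["mu"],
            "sd": meta["stats"]["sd"],
        }
    return MoEModel(config=config, schema=schema, params=params, stats=stats)
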