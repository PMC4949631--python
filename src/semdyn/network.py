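"""Recurrent attractor network over semantic features, with staged input.

The model maps an abstract binary word form onto a distributed semantic
representation: an input layer (30 nodes by default) feeds a recurrently
connected semantic layer with one node per feature in the norms.  Spoken
input is emulated by revealing the word-form pattern incrementally, one
input node per time-tick, for ``t_input`` ticks; semantic activation then
continues to evolve until ``t_total`` ticks (30 and 50 by default).

Each semantic node ``n`` integrates its external input over time,

    x_n(t) = c * e_n(t) + (1 - c) * x_n(t - 1)

where ``e_n(t)`` is the weighted sum of incoming activation (input layer,
recurrent connections, and a bias) and the integration rate ``c`` in (0, 1]
sets how quickly a node tracks changes in its input.  Activation is the
logistic of the integrated input.  Training minimises the cross-entropy
between activations and the binary feature targets summed over *all* ticks,
by backpropagation through the unrolled recurrence (including the
c-weighted averaging), so the network is pressed to activate the correct
features as early as the accumulating input allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .norms import PropertyNorms

__all__ = [
    "NetworkConfig",
    "ActivationTrajectory",
    "SemanticAttractorNet",
    "AttractorNetResults",
    "init_model",
    "forward_pass",
    "cross_entropy_loss",
    "train",
    "evaluate",
    "run_grid",
]

_EPS = 1e-7


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyperparameters.

    ``c`` is the integration-rate parameter; the values studied are
    0.16, 0.2 and 0.24.  ``init_act_range`` bounds the random initial
    integrated inputs (so initial activations start near the logistic
    midpoint and are quickly washed out), ``init_weight_range`` the random
    initial weights.  ``input_baseline`` is the value unrevealed input
    nodes take before their reveal tick (0 = silence; 0.5 emulates fully
    uncommitted evidence).
    """

    n_input: int = 30
    n_semantic: int = 100
    t_input: int = 30
    t_total: int = 50
    c: float = 0.2
    lr: float = 0.01
    epochs: int = 2000
    momentum: float = 0.9
    init_act_range: tuple[float, float] = (0.0, 0.1)
    init_weight_range: tuple[float, float] = (0.0, 0.05)
    input_baseline: float = 0.0
    frequency_weighted_targets: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.c <= 1.0):
            raise ValueError(f"c must be in (0, 1], got {self.c}")
        if self.t_input > self.t_total:
            raise ValueError("t_input cannot exceed t_total")
        if min(self.n_input, self.n_semantic, self.t_total) < 1:
            raise ValueError("sizes must be positive")
        if self.epochs < 0 or self.lr <= 0:
            raise ValueError("epochs must be >= 0 and lr > 0")


@dataclass
class ActivationTrajectory:
    """Per-item, per-feature, per-tick semantic activations in [0, 1].

    ``values`` has shape (n_items, n_semantic, t_total); tick ``t`` (1-based)
    is stored at index ``t - 1``.
    """

    values: np.ndarray
    item_ids: list[str]
    feature_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 3:
            raise ValueError("trajectory must be (items, features, ticks)")
        if v.shape[0] != len(self.item_ids) or v.shape[1] != len(self.feature_ids):
            raise ValueError("trajectory dimensions do not match labels")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("activations must lie in [0, 1]")
        self.values = v

    @property
    def n_ticks(self) -> int:
        return self.values.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (item, feature, tick, activation) table."""
        n_i, n_f, n_t = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.item_ids, self.feature_ids, range(1, n_t + 1)],
            names=["item", "feature", "tick"],
        )
        df = pd.DataFrame({"activation": self.values.reshape(-1)}, index=idx)
        return df.reset_index()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _input_at(wordforms: np.ndarray, t: int, cfg: NetworkConfig) -> np.ndarray:
    """Input-layer values at tick t: nodes 1..min(t, t_input) revealed."""
    n_revealed = min(t, cfg.t_input)
    u = np.full_like(wordforms, cfg.input_baseline)
    u[:, :n_revealed] = wordforms[:, :n_revealed]
    return u


def _init_params(cfg: NetworkConfig, rng: np.random.Generator) -> dict:
    lo, hi = cfg.init_weight_range
    return {
        "W_in": rng.uniform(lo, hi, size=(cfg.n_input, cfg.n_semantic)),
        "W_rec": rng.uniform(lo, hi, size=(cfg.n_semantic, cfg.n_semantic)),
        "b": rng.uniform(lo, hi, size=cfg.n_semantic),
    }


def _init_state(cfg: NetworkConfig, n_items: int, rng: np.random.Generator):
    lo, hi = cfg.init_act_range
    return rng.uniform(lo, hi, size=(n_items, cfg.n_semantic))


def _forward(params, wordforms, cfg: NetworkConfig, x0):
    """Run the recurrence; returns activations (T+1, items, nodes) with the
    initial state at index 0, and integrated inputs likewise."""
    n_items = wordforms.shape[0]
    T = cfg.t_total
    xs = np.empty((T + 1, n_items, cfg.n_semantic))
    acts = np.empty_like(xs)
    xs[0] = x0
    acts[0] = _sigmoid(x0)
    for t in range(1, T + 1):
        u = _input_at(wordforms, t, cfg)
        e = u @ params["W_in"] + acts[t - 1] @ params["W_rec"] + params["b"]
        xs[t] = cfg.c * e + (1.0 - cfg.c) * xs[t - 1]
        acts[t] = _sigmoid(xs[t])
    return acts, xs


def cross_entropy_loss(trajectory, targets: np.ndarray) -> float:
    """Cross-entropy between activations and binary targets, summed over
    all items, semantic nodes and ticks, with epsilon clipping at 1e-7."""
    if isinstance(trajectory, ActivationTrajectory):
        a = trajectory.values.transpose(2, 0, 1)  # (T, items, nodes)
    else:
        a = np.asarray(trajectory, float)
    y = np.asarray(targets, float)
    if a.shape[-1] != y.shape[-1] or a.shape[-2] != y.shape[0]:
        raise ValueError(
            f"trajectory {a.shape} incompatible with targets {y.shape}"
        )
    ac = np.clip(a, _EPS, 1.0 - _EPS)
    return float(-(y * np.log(ac) + (1.0 - y) * np.log(1.0 - ac)).sum())


def _loss_and_grads(params, wordforms, targets, cfg: NetworkConfig, x0):
    """Full-batch loss (mean over items, summed over nodes and ticks) and
    analytic gradients via backpropagation through the unrolled graph."""
    n_items = wordforms.shape[0]
    acts, xs = _forward(params, wordforms, cfg, x0)
    T = cfg.t_total
    y = targets

    ac = np.clip(acts[1:], _EPS, 1.0 - _EPS)
    loss = float(-(y * np.log(ac) + (1.0 - y) * np.log(1.0 - ac)).sum()) / n_items

    gW_in = np.zeros_like(params["W_in"])
    gW_rec = np.zeros_like(params["W_rec"])
    gb = np.zeros_like(params["b"])
    delta_x_next = np.zeros((n_items, cfg.n_semantic))
    delta_e_next = np.zeros_like(delta_x_next)
    for t in range(T, 0, -1):
        a_t = acts[t]
        a_clip = np.clip(a_t, _EPS, 1.0 - _EPS)
        dL_da = (a_clip - y) / (a_clip * (1.0 - a_clip))
        dL_da *= (a_t > _EPS) & (a_t < 1.0 - _EPS)
        # recurrent path: a(t) feeds e(t+1)
        dL_da += delta_e_next @ params["W_rec"].T
        delta_x = dL_da * a_t * (1.0 - a_t) + (1.0 - cfg.c) * delta_x_next
        delta_e = cfg.c * delta_x
        u = _input_at(wordforms, t, cfg)
        gW_in += u.T @ delta_e
        gW_rec += acts[t - 1].T @ delta_e
        gb += delta_e.sum(axis=0)
        delta_x_next = delta_x
        delta_e_next = delta_e
    scale = 1.0 / n_items
    return loss, {"W_in": gW_in * scale, "W_rec": gW_rec * scale, "b": gb * scale}


@dataclass
class AttractorNetResults:
    """Learned weights plus training diagnostics.

    Fields
    ------
    params : dict with ``W_in`` (n_input x n_semantic), ``W_rec``
        (n_semantic x n_semantic) and ``b`` (n_semantic,).
    loss_history : per-epoch mean-per-item cross-entropy (length = epochs).
    """

    params: dict
    config: NetworkConfig
    loss_history: np.ndarray
    item_ids: list[str]
    feature_ids: list[str]
    wordforms: np.ndarray = field(repr=False)
    targets: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    def forward(self, wordforms: np.ndarray | None = None, seed: int = 0,
                x0: np.ndarray | None = None) -> ActivationTrajectory:
        """Single deterministic forward pass with seeded random initial state."""
        wf = self.wordforms if wordforms is None else np.asarray(wordforms, float)
        if wf.shape[1] != self.config.n_input:
            raise ValueError(
                f"wordform length {wf.shape[1]} != n_input {self.config.n_input}"
            )
        if x0 is None:
            x0 = _init_state(self.config, wf.shape[0], np.random.default_rng(seed))
        acts, _ = _forward(self.params, wf, self.config, x0)
        items = self.item_ids if wordforms is None else [
            f"item{i}" for i in range(wf.shape[0])
        ]
        return ActivationTrajectory(
            acts[1:].transpose(1, 2, 0), items, self.feature_ids,
            meta={**self.meta, "seed": seed},
        )

    def evaluate(self, runs: int = 5, seed: int = 0,
                 wordforms: np.ndarray | None = None) -> ActivationTrajectory:
        """Mean trajectory over ``runs`` forward passes with independently
        randomized initial activations (weights fixed)."""
        if runs < 1:
            raise ValueError("runs must be >= 1")
        child = np.random.SeedSequence(seed).spawn(runs)
        total = None
        traj = None
        for ss in child:
            rng = np.random.default_rng(ss)
            wf = self.wordforms if wordforms is None else np.asarray(wordforms, float)
            x0 = _init_state(self.config, wf.shape[0], rng)
            traj = self.forward(wordforms, x0=x0)
            total = traj.values if total is None else total + traj.values
        out = total / runs
        return ActivationTrajectory(
            out, traj.item_ids, traj.feature_ids,
            meta={**self.meta, "runs": runs, "eval_seed": seed},
        )

    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1]) if len(self.loss_history) else float("nan")

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Semantic attractor network",
            "=" * 44,
            f"input nodes          {cfg.n_input}",
            f"semantic nodes       {cfg.n_semantic}",
            f"ticks (input/total)  {cfg.t_input}/{cfg.t_total}",
            f"integration rate c   {cfg.c}",
            f"items                {len(self.item_ids)}",
            f"epochs               {len(self.loss_history)}",
        ]
        if len(self.loss_history):
            lines.append(f"initial loss/item    {self.loss_history[0]:.3f}")
            lines.append(f"final loss/item      {self.loss_history[-1]:.3f}")
        return "\n".join(lines)


class SemanticAttractorNet:
    """Model object: word-form inputs, feature targets and a configuration.

    ``fit`` trains the network by full-batch gradient descent with momentum
    on the all-tick cross-entropy and returns an
    :class:`AttractorNetResults`.
    """

    def __init__(
        self,
        targets: np.ndarray,
        wordforms: np.ndarray,
        config: NetworkConfig | None = None,
        item_ids: list[str] | None = None,
        feature_ids: list[str] | None = None,
    ) -> None:
        targets = np.asarray(targets, float)
        wordforms = np.asarray(wordforms, float)
        if targets.shape[0] != wordforms.shape[0]:
            raise ValueError("one wordform per item required")
        config = config or NetworkConfig(
            n_input=wordforms.shape[1], n_semantic=targets.shape[1]
        )
        if config.n_semantic != targets.shape[1]:
            raise ValueError(
                f"config.n_semantic {config.n_semantic} != target width "
                f"{targets.shape[1]}"
            )
        if config.n_input != wordforms.shape[1]:
            raise ValueError(
                f"config.n_input {config.n_input} != wordform length "
                f"{wordforms.shape[1]}"
            )
        self.targets = targets
        self.wordforms = wordforms
        self.config = config
        self.item_ids = item_ids or [f"item{i}" for i in range(targets.shape[0])]
        self.feature_ids = feature_ids or [f"f{j}" for j in range(targets.shape[1])]

    @classmethod
    def from_norms(
        cls,
        norms: PropertyNorms,
        wordforms: np.ndarray,
        config: NetworkConfig | None = None,
        **overrides,
    ) -> "SemanticAttractorNet":
        """Build the model from a property-norm set: one semantic node per
        feature, binary presence targets (frequency-weighted via config)."""
        freq_weighted = (config or NetworkConfig()).frequency_weighted_targets
        tmat = norms.target_matrix(frequency_weighted=freq_weighted)
        wordforms = np.asarray(wordforms, float)
        if wordforms.shape[0] != tmat.shape[0]:
            raise ValueError(
                f"{tmat.shape[0]} concepts but {wordforms.shape[0]} wordforms"
            )
        base = config or NetworkConfig()
        cfg = replace(
            base,
            n_input=wordforms.shape[1],
            n_semantic=tmat.shape[1],
            **overrides,
        )
        return cls(
            tmat.to_numpy(), wordforms, cfg,
            item_ids=list(tmat.index), feature_ids=list(tmat.columns),
        )

    def init_results(self, meta: dict | None = None) -> AttractorNetResults:
        """Freshly initialized (untrained) weights under the config seed."""
        rng = np.random.default_rng(self.config.seed)
        return AttractorNetResults(
            params=_init_params(self.config, rng),
            config=self.config,
            loss_history=np.empty(0),
            item_ids=self.item_ids,
            feature_ids=self.feature_ids,
            wordforms=self.wordforms,
            targets=self.targets,
            meta=meta or {},
        )

    def fit(self, callback=None, meta: dict | None = None) -> AttractorNetResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = _init_params(cfg, rng)
        velocity = {k: np.zeros_like(v) for k, v in params.items()}
        history = np.empty(cfg.epochs)
        n_items = self.wordforms.shape[0]
        for epoch in range(cfg.epochs):
            x0 = _init_state(cfg, n_items, rng)
            loss, grads = _loss_and_grads(
                params, self.wordforms, self.targets, cfg, x0
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss = {loss}"
                )
            history[epoch] = loss
            for k in params:
                velocity[k] = cfg.momentum * velocity[k] - cfg.lr * grads[k]
                params[k] = params[k] + velocity[k]
            if callback is not None:
                callback(epoch, loss)
        return AttractorNetResults(
            params=params,
            config=cfg,
            loss_history=history,
            item_ids=self.item_ids,
            feature_ids=self.feature_ids,
            wordforms=self.wordforms,
            targets=self.targets,
            meta=meta or {},
        )


# ---------------------------------------------------------------------------
# functional wrappers

def init_model(cfg: NetworkConfig) -> AttractorNetResults:
    """Untrained model with weights drawn uniformly from init_weight_range."""
    dummy_targets = np.zeros((1, cfg.n_semantic))
    dummy_wf = np.zeros((1, cfg.n_input))
    return SemanticAttractorNet(dummy_targets, dummy_wf, cfg).init_results()


def forward_pass(results: AttractorNetResults, wordform: np.ndarray,
                 seed: int = 0) -> ActivationTrajectory:
    """Single-item forward pass through a (trained) model."""
    wordform = np.atleast_2d(np.asarray(wordform, float))
    return results.forward(wordform, seed=seed)


def train(
    norms: PropertyNorms,
    wordforms: np.ndarray,
    cfg: NetworkConfig | None = None,
) -> AttractorNetResults:
    return SemanticAttractorNet.from_norms(norms, wordforms, cfg).fit()


def evaluate(results: AttractorNetResults, runs: int = 5,
             seed: int = 0) -> ActivationTrajectory:
    return results.evaluate(runs=runs, seed=seed)


def run_grid(
    norms: PropertyNorms,
    n_pattern_sets: int = 3,
    c_values: tuple[float, ...] = (0.16, 0.2, 0.24),
    base_seed: int = 0,
    cfg: NetworkConfig | None = None,
    eval_runs: int = 5,
    dry_run: bool = False,
):
    """Train one model per (pattern set x integration rate c).

    Every cell derives its own seed deterministically from ``base_seed``.
    With ``dry_run`` the (pattern_set, c, seed) combinations are enumerated
    without training.  Returns a list of dicts with keys ``pattern_set``,
    ``c``, ``seed`` and, unless dry-run, ``results`` and ``trajectory``
    (the run-averaged evaluation).
    """
    base = cfg or NetworkConfig()
    out = []
    for i in range(n_pattern_sets):
        for j, c in enumerate(c_values):
            ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(i, j))
            seed = int(ss.generate_state(1)[0] % (2**31))
            cell = {"pattern_set": i, "c": float(c), "seed": seed}
            if not dry_run:
                wf = _grid_wordforms(norms, base.n_input, base_seed, i)
                model = SemanticAttractorNet.from_norms(
                    norms, wf, base, c=float(c), seed=seed
                )
                res = model.fit(meta=dict(cell))
                cell["results"] = res
                cell["trajectory"] = res.evaluate(runs=eval_runs, seed=seed)
            out.append(cell)
    return out


def _grid_wordforms(norms, n_input, base_seed, pattern_set):
    from .synth import generate_wordforms

    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(pattern_set, 999))
    seed = int(ss.generate_state(1)[0] % (2**31))
    return generate_wordforms(len(norms.concepts), n_input=n_input, seed=seed)
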