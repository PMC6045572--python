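"""Semantic attractor network: recurrent dynamics and training.

The network is a single, fully recurrently connected layer of sigmoid
"semantic feature" nodes driven by a static visual input vector.  At each
discrete time-tick every node receives an external input (a weighted sum
of the input units and of the other semantic nodes' activations at the
previous tick, plus a bias), integrates it with its previous total input
through a leak parameter ``c``, and passes the result through a logistic
sigmoid:

    e_n(t) = sum_i w_ni * a_i(t-1) + b_n
    x_n(t) = c * e_n(t) + (1 - c) * x_n(t-1)
    a_n(t) = 1 / (1 + exp(-x_n(t)))

Training is continuous recurrent backpropagation through time: the
cross-entropy between activations and the binary feature target is
accumulated at every tick from ``t_err`` onward and minimised by batch
gradient descent with momentum.  A run is declared converged when a
criterion fraction of the target (value-1) features reaches a criterion
activation level at the final tick.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AttractorNetwork",
    "AttractorState",
    "Trajectory",
    "TrainHistory",
    "init_network",
    "step_dynamics",
    "run_ticks",
    "train_bptt",
    "stage_activations",
    "external_input_to_feature",
]

_ACT_CLIP = 1e-7  # cross-entropy clipping for numerical safety


@dataclass
class AttractorNetwork:
    """Weights and hyperparameters of the attractor layer.

    Attributes
    ----------
    W_in : ndarray of shape (semantic_dim, input_dim)
        Feed-forward weights from visual input units to semantic nodes.
    W_rec : ndarray of shape (semantic_dim, semantic_dim)
        Lateral recurrent weights between semantic nodes.
    b : ndarray of shape (semantic_dim,)
        Per-node bias.
    c : float
        Integration constant in (0, 1]; how strongly the current external
        input dominates over the previous total input.
    n_ticks : int
        Number of time-ticks T (tick 1 is the random initialisation).
    a0 : ndarray of shape (semantic_dim,)
        Tick-1 activation template shared by all items.
    self_connections : bool
        If False (default) the diagonal of ``W_rec`` is held at zero.
    """

    W_in: np.ndarray
    W_rec: np.ndarray
    b: np.ndarray
    c: float
    n_ticks: int
    a0: np.ndarray
    self_connections: bool = False

    @property
    def input_dim(self) -> int:
        return self.W_in.shape[1]

    @property
    def semantic_dim(self) -> int:
        return self.W_in.shape[0]

    def validate(self) -> None:
        if not (0.0 < self.c <= 1.0):
            raise ValueError(f"integration constant c must be in (0, 1], got {self.c}")
        if self.n_ticks < 2:
            raise ValueError(f"n_ticks must be >= 2, got {self.n_ticks}")
        for name in ("W_in", "W_rec", "b", "a0"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        if not self.self_connections and np.any(np.diag(self.W_rec) != 0.0):
            raise ValueError("self-connections disabled but W_rec diagonal nonzero")


@dataclass
class AttractorState:
    """Per-node state at one tick: total input x, activation a, external input e."""

    x: np.ndarray
    a: np.ndarray
    e: np.ndarray
    tick: int


@dataclass
class Trajectory:
    """Per-tick activations for a batch of items.

    ``acts`` has shape (n_ticks, n_items, semantic_dim); ``acts[0]`` is the
    tick-1 initialisation template broadcast over items.
    """

    acts: np.ndarray
    items: list[str] | None = None

    @property
    def n_ticks(self) -> int:
        return self.acts.shape[0]

    def at_tick(self, tick: int) -> np.ndarray:
        """Activations at 1-based tick ``tick`` (items x semantic nodes)."""
        if not (1 <= tick <= self.n_ticks):
            raise ValueError(f"tick must be in 1..{self.n_ticks}, got {tick}")
        return self.acts[tick - 1]


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    criterion_frac: list[float] = field(default_factory=list)
    converged: bool = False
    epochs_run: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # stable piecewise form: never exponentiates a large positive argument
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _logit(a: np.ndarray) -> np.ndarray:
    a = np.clip(a, _ACT_CLIP, 1.0 - _ACT_CLIP)
    return np.log(a / (1.0 - a))


def init_network(
    input_dim: int,
    semantic_dim: int,
    c: float = 0.25,
    n_ticks: int = 20,
    seed: int | np.random.SeedSequence | None = 0,
    self_connections: bool = False,
) -> AttractorNetwork:
    """Randomly initialise a network.

    Connection weights (input, recurrent, bias) are drawn Uniform(0, 0.05)
    and the tick-1 activation template Uniform(0, 0.10), reproducibly from
    ``seed``.
    """
    if input_dim < 1 or semantic_dim < 1:
        raise ValueError("input_dim and semantic_dim must be >= 1")
    if not (0.0 < c <= 1.0):
        raise ValueError(f"integration constant c must be in (0, 1], got {c}")
    if n_ticks < 2:
        raise ValueError(f"n_ticks must be >= 2, got {n_ticks}")
    rng = np.random.default_rng(seed)
    W_in = rng.uniform(0.0, 0.05, size=(semantic_dim, input_dim))
    W_rec = rng.uniform(0.0, 0.05, size=(semantic_dim, semantic_dim))
    b = rng.uniform(0.0, 0.05, size=semantic_dim)
    a0 = rng.uniform(0.0, 0.10, size=semantic_dim)
    if not self_connections:
        np.fill_diagonal(W_rec, 0.0)
    net = AttractorNetwork(
        W_in=W_in, W_rec=W_rec, b=b, c=float(c), n_ticks=int(n_ticks),
        a0=a0, self_connections=self_connections,
    )
    net.validate()
    return net


def step_dynamics(
    net: AttractorNetwork, state: AttractorState, input_vector: np.ndarray
) -> AttractorState:
    """Advance the dynamics one tick for a single item."""
    input_vector = np.asarray(input_vector, dtype=float)
    if input_vector.shape != (net.input_dim,):
        raise ValueError(
            f"input_vector must have length {net.input_dim}, got {input_vector.shape}"
        )
    if not np.all(np.isfinite(input_vector)):
        raise ValueError("non-finite input_vector")
    e = net.W_in @ input_vector + net.W_rec @ state.a + net.b
    x = net.c * e + (1.0 - net.c) * state.x
    a = _sigmoid(x)
    return AttractorState(x=x, a=a, e=e, tick=state.tick + 1)


def initial_state(net: AttractorNetwork) -> AttractorState:
    """Tick-1 state: the activation template, with x its logit preimage."""
    a = net.a0.copy()
    return AttractorState(x=_logit(a), a=a, e=np.zeros_like(a), tick=1)


def run_ticks(
    net: AttractorNetwork, input_matrix: np.ndarray, n_ticks: int | None = None
) -> Trajectory:
    """Run the dynamics for all items with the input clamped constant.

    Returns the full per-tick activation tensor; tick 1 is the
    initialisation template.
    """
    X = np.atleast_2d(np.asarray(input_matrix, dtype=float))
    if X.shape[1] != net.input_dim:
        raise ValueError(f"input has {X.shape[1]} columns, expected {net.input_dim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input matrix")
    T = net.n_ticks if n_ticks is None else int(n_ticks)
    n_items = X.shape[0]
    acts = np.empty((T, n_items, net.semantic_dim))
    a = np.broadcast_to(net.a0, (n_items, net.semantic_dim)).copy()
    x = _logit(a)
    acts[0] = a
    drive = X @ net.W_in.T + net.b  # constant across ticks
    for t in range(1, T):
        e = a @ net.W_rec.T + drive
        x = net.c * e + (1.0 - net.c) * x
        a = _sigmoid(x)
        acts[t] = a
    return Trajectory(acts=acts)


def _cross_entropy(a: np.ndarray, y: np.ndarray) -> float:
    ac = np.clip(a, _ACT_CLIP, 1.0 - _ACT_CLIP)
    return float(-np.mean(np.sum(y * np.log(ac) + (1 - y) * np.log(1 - ac), axis=-1)))


def bptt_loss_and_grads(
    net: AttractorNetwork,
    inputs: np.ndarray,
    targets: np.ndarray,
    t_err: int = 2,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy over ticks ``t_err``..T and its analytic gradients.

    The loss is averaged over items and summed over semantic nodes and
    ticks.  Gradients are backpropagated through the recurrence: a node's
    total input at tick t influences the loss directly through a(t), through
    the lateral input to every node at t+1, and through the (1-c) leak into
    x(t+1).
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    n_items = X.shape[0]
    T = net.n_ticks
    c = net.c

    acts = np.empty((T, n_items, net.semantic_dim))
    xs = np.empty_like(acts)
    a = np.broadcast_to(net.a0, (n_items, net.semantic_dim)).copy()
    x = _logit(a)
    acts[0], xs[0] = a, x
    drive = X @ net.W_in.T + net.b
    for t in range(1, T):
        x = c * (a @ net.W_rec.T + drive) + (1.0 - c) * x
        a = _sigmoid(x)
        acts[t], xs[t] = a, x

    loss = sum(_cross_entropy(acts[t], Y) for t in range(t_err - 1, T))

    gW_in = np.zeros_like(net.W_in)
    gW_rec = np.zeros_like(net.W_rec)
    gb = np.zeros_like(net.b)
    g_x_next = np.zeros((n_items, net.semantic_dim))  # dL/dx(t+1)
    for t in range(T - 1, 0, -1):  # 0-based tick index t (tick t+1), down to tick 2
        g_a = (c * g_x_next) @ net.W_rec  # via lateral input at the next tick
        g_x = g_a * acts[t] * (1.0 - acts[t]) + (1.0 - c) * g_x_next
        if t >= t_err - 1:
            g_x = g_x + (acts[t] - Y) / n_items  # sigmoid + cross-entropy shortcut
        gW_in += c * (g_x.T @ X)
        gW_rec += c * (g_x.T @ acts[t - 1])
        gb += c * g_x.sum(axis=0)
        g_x_next = g_x
    if not net.self_connections:
        np.fill_diagonal(gW_rec, 0.0)
    return loss, {"W_in": gW_in, "W_rec": gW_rec, "b": gb}


def criterion_fraction(
    final_acts: np.ndarray, targets: np.ndarray, level: float = 0.70
) -> float:
    """Fraction of target (value-1) features whose activation reaches ``level``."""
    Y = np.asarray(targets) > 0
    n_target = int(Y.sum())
    if n_target == 0:
        raise ValueError("targets contain no value-1 features")
    return float(np.sum(final_acts[Y] >= level) / n_target)


def train_bptt(
    net: AttractorNetwork,
    inputs: np.ndarray,
    targets: np.ndarray,
    lr: float = 0.01,
    max_epochs: int = 2000,
    criterion_frac: float = 0.95,
    criterion_level: float = 0.70,
    momentum: float = 0.9,
    t_err: int = 2,
    check_every: int = 1,
) -> tuple[AttractorNetwork, int, TrainHistory]:
    """Train by batch gradient descent on the per-tick cross-entropy.

    Stops at the first epoch where the fraction of target features with
    final-tick activation >= ``criterion_level`` reaches ``criterion_frac``,
    or after ``max_epochs``.  Returns (trained network, epochs run, history);
    ``history.converged`` records whether the criterion was met.
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("inputs and targets must have the same item count")
    if not (0.0 < criterion_frac <= 1.0):
        raise ValueError("criterion_frac must be in (0, 1]")
    if not (0.0 < criterion_level < 1.0):
        raise ValueError("criterion_level must be in (0, 1)")
    if not (2 <= t_err <= net.n_ticks):
        raise ValueError(f"t_err must be in 2..{net.n_ticks}")

    net = replace(
        net, W_in=net.W_in.copy(), W_rec=net.W_rec.copy(), b=net.b.copy(),
        a0=net.a0.copy(),
    )
    vel = {k: np.zeros_like(getattr(net, k)) for k in ("W_in", "W_rec", "b")}
    hist = TrainHistory()
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        loss, grads = bptt_loss_and_grads(net, X, Y, t_err=t_err)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss!r}; "
                "reduce the learning rate"
            )
        for k in vel:
            vel[k] = momentum * vel[k] - lr * grads[k]
            getattr(net, k).__iadd__(vel[k])
        if not net.self_connections:
            np.fill_diagonal(net.W_rec, 0.0)
        hist.loss.append(loss)
        if epoch % check_every == 0 or epoch == max_epochs:
            final = run_ticks(net, X).at_tick(net.n_ticks)
            frac = criterion_fraction(final, Y, level=criterion_level)
        else:
            frac = hist.criterion_frac[-1] if hist.criterion_frac else 0.0
        hist.criterion_frac.append(frac)
        if frac >= criterion_frac:
            hist.converged = True
            break
    hist.epochs_run = epoch
    return net, epoch, hist


def stage_activations(net: AttractorNetwork, inputs: np.ndarray, tick: int):
    """Item x semantic-node activations at one tick as a StageRepresentation.

    Tick 1 is the random initialisation template, identical for every item,
    and is excluded from stage analyses.
    """
    from .syndata import StageRepresentation

    if tick == 1:
        raise ValueError(
            "tick 1 is the random initialisation and carries no item "
            "information; stages start at tick 2"
        )
    if not (2 <= tick <= net.n_ticks):
        raise ValueError(f"tick must be in 2..{net.n_ticks}, got {tick}")
    traj = run_ticks(net, inputs)
    return StageRepresentation(
        stage_id=f"semantic_tick{tick}",
        items=[f"item{i}" for i in range(np.atleast_2d(inputs).shape[0])],
        matrix=traj.at_tick(tick).copy(),
    )


def external_input_to_feature(
    net: AttractorNetwork, input_matrix: np.ndarray, feature_index: int
) -> np.ndarray:
    """Per-item feed-forward external input to one semantic feature node.

    Only the input-layer term W_in . input + b is included; the lateral
    recurrent contribution is excluded, so this ranks items by how strongly
    the visual input alone drives the feature.
    """
    X = np.atleast_2d(np.asarray(input_matrix, dtype=float))
    if not (0 <= feature_index < net.semantic_dim):
        raise KeyError(f"unknown feature index {feature_index}")
    return X @ net.W_in[feature_index] + net.b[feature_index]
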