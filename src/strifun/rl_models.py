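"""Q-learning model family for the restless two-armed bandit.

The base model carries a learning rate alpha and softmax inverse temperature
beta.  Five optional extensions can be switched on in any combination:

* ``neg_alpha`` — separate learning rate for no-reward (r=0) feedback;
* ``effector_bias`` — fixed additive utility offset toward the hand response;
* ``lapse`` — choice probabilities compressed into [eps, 1-eps];
* ``decay`` — unsampled (stimulus, action) pairs relax geometrically back to
  the neutral value 0.5 with per-trial rate d;
* ``perseverance`` — additive utility bonus for repeating the previous
  action taken for the *same* stimulus, irrespective of value.

Action values update only for the chosen pair: Q <- Q + alpha * (r - Q),
with the reward prediction error delta = r - Q.  Bias and perseverance enter
the softmax as additive utility offsets (not multiplied by beta), so their
magnitudes are comparable across subjects with different beta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _engine
from .bandit_task import (NO_ACTION, NO_REWARD, BehavioralSession,
                          RewardWalkSet, TrialSequence, sample_outcome)

FLAG_NAMES = ("neg_alpha", "effector_bias", "lapse", "decay", "perseverance")
HAND, FOOT = 0, 1


@dataclass(frozen=True)
class ModelSpec:
    """Which optional parameters are active; any subset is a valid model."""

    neg_alpha: bool = False
    effector_bias: bool = False
    lapse: bool = False
    decay: bool = False
    perseverance: bool = False

    @classmethod
    def from_string(cls, flags: str) -> "ModelSpec":
        """Parse a comma-separated flag string, e.g. ``"neg_alpha,decay"``."""
        parts = [p.strip() for p in flags.split(",") if p.strip()]
        unknown = set(parts) - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"unknown model flags: {sorted(unknown)}; "
                             f"valid flags: {FLAG_NAMES}")
        return cls(**{name: name in parts for name in FLAG_NAMES})

    def to_string(self) -> str:
        active = [n for n in FLAG_NAMES if getattr(self, n)]
        return ",".join(active) if active else "base"

    @property
    def param_names(self) -> tuple:
        names = ["alpha_pos"]
        if self.neg_alpha:
            names.append("alpha_neg")
        names.append("beta")
        if self.effector_bias:
            names.append("bias")
        if self.lapse:
            names.append("lapse")
        if self.decay:
            names.append("decay")
        if self.perseverance:
            names.append("perseverance")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __str__(self) -> str:
        return self.to_string()


# -- bijections between natural parameter space and the unconstrained space
#    used by the population Gaussian: logit for (0,1) rates, scaled logit
#    for the lapse (0, 0.5), log for beta, identity for signed offsets.

def _logit(p):
    return np.log(p) - np.log1p(-p)


def _sigmoid(x):
    return expit(x)


_TO_UNCONSTRAINED = {
    "alpha_pos": _logit,
    "alpha_neg": _logit,
    "beta": np.log,
    "bias": lambda v: v,
    "lapse": lambda e: _logit(2.0 * e),
    "decay": _logit,
    "perseverance": lambda v: v,
}

_FROM_UNCONSTRAINED = {
    "alpha_pos": _sigmoid,
    "alpha_neg": _sigmoid,
    "beta": np.exp,
    "bias": lambda x: x,
    "lapse": lambda x: 0.5 * _sigmoid(x),
    "decay": _sigmoid,
    "perseverance": lambda x: x,
}


@dataclass
class RLParams:
    """Natural-space parameter values; inactive parameters sit at neutral."""

    alpha_pos: float
    beta: float
    alpha_neg: float | None = None
    bias: float = 0.0
    lapse: float = 0.0
    decay: float = 0.0
    perseverance: float = 0.0

    def effective_alpha_neg(self, spec: ModelSpec) -> float:
        if spec.neg_alpha:
            if self.alpha_neg is None:
                raise ValueError("spec has neg_alpha but alpha_neg unset")
            return self.alpha_neg
        return self.alpha_pos

    def value(self, name: str, spec: ModelSpec) -> float:
        if name == "alpha_neg":
            return self.effective_alpha_neg(spec)
        return getattr(self, name)

    def to_transformed(self, spec: ModelSpec) -> np.ndarray:
        return np.array([_TO_UNCONSTRAINED[n](self.value(n, spec))
                         for n in spec.param_names])

    @classmethod
    def from_transformed(cls, x, spec: ModelSpec) -> "RLParams":
        vals = {n: float(_FROM_UNCONSTRAINED[n](xi))
                for n, xi in zip(spec.param_names, np.asarray(x, dtype=float))}
        return cls(alpha_pos=vals["alpha_pos"], beta=vals["beta"],
                   alpha_neg=vals.get("alpha_neg"),
                   bias=vals.get("bias", 0.0), lapse=vals.get("lapse", 0.0),
                   decay=vals.get("decay", 0.0),
                   perseverance=vals.get("perseverance", 0.0))

    def to_row(self, spec: ModelSpec) -> np.ndarray:
        """Full 7-element natural-space row for the compiled kernels."""
        return np.array([self.alpha_pos, self.effective_alpha_neg(spec),
                         self.beta, self.bias, self.lapse, self.decay,
                         self.perseverance], dtype=float)

    def to_json(self, spec: ModelSpec) -> str:
        d = {"model": spec.to_string(),
             "natural": {n: self.value(n, spec) for n in spec.param_names},
             "transformed": dict(zip(spec.param_names,
                                     self.to_transformed(spec).tolist()))}
        return json.dumps(d, indent=2)


def transformed_to_rows(X: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Vectorized map from [K, P] unconstrained vectors to [K, 7] rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = dict(zip(spec.param_names, X.T))
    rows = np.zeros((X.shape[0], 7))
    rows[:, 0] = _sigmoid(cols["alpha_pos"])
    rows[:, 1] = _sigmoid(cols["alpha_neg"]) if spec.neg_alpha else rows[:, 0]
    rows[:, 2] = np.exp(np.clip(cols["beta"], -50.0, 50.0))
    if spec.effector_bias:
        rows[:, 3] = cols["bias"]
    if spec.lapse:
        rows[:, 4] = 0.5 * _sigmoid(cols["lapse"])
    if spec.decay:
        rows[:, 5] = _sigmoid(cols["decay"])
    if spec.perseverance:
        rows[:, 6] = cols["perseverance"]
    return rows


# ---------------------------------------------------------------------------
# value table and trial-level operations
# ---------------------------------------------------------------------------

@dataclass
class QTable:
    """2 stimuli x 2 actions action values plus per-stimulus last action."""

    q: np.ndarray = field(default_factory=lambda: np.full((2, 2), 0.5))
    last_action: np.ndarray = field(
        default_factory=lambda: np.full(2, NO_ACTION, dtype=np.int64))

    def copy(self) -> "QTable":
        return QTable(q=self.q.copy(), last_action=self.last_action.copy())


@dataclass
class UpdateResult:
    q: QTable
    rpe: float | None


def initial_q() -> QTable:
    """All four values at the neutral point 0.5, no action history."""
    return QTable()


def action_probabilities(q: QTable, stimulus: int, params: RLParams,
                         spec: ModelSpec) -> np.ndarray:
    """Softmax choice probabilities over (hand, foot) for one stimulus."""
    u = params.beta * q.q[stimulus].astype(float)
    if spec.effector_bias:
        u[HAND] += params.bias
    last = q.last_action[stimulus]
    if spec.perseverance and last != NO_ACTION:
        u[last] += params.perseverance
    u -= u.max()
    p = np.exp(u)
    p /= p.sum()
    if spec.lapse:
        p = params.lapse + (1.0 - 2.0 * params.lapse) * p
    return p


def _decay_toward_neutral(q: np.ndarray, d: float, skip=None) -> None:
    for si in range(2):
        for ai in range(2):
            if skip is not None and (si, ai) == skip:
                continue
            q[si, ai] += d * (0.5 - q[si, ai])


def apply_update(q: QTable, stimulus: int, action, reward, params: RLParams,
                 spec: ModelSpec) -> UpdateResult:
    """One trial's learning update; returns the new table and the RPE.

    ``action`` may be None (or -1) for abort/missed trials, in which case no
    prediction error is produced and, if decay is active, all four values
    relax toward 0.5.
    """
    new = q.copy()
    if action is None or action == NO_ACTION:
        if spec.decay:
            _decay_toward_neutral(new.q, params.decay)
        return UpdateResult(q=new, rpe=None)
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    rpe = float(reward) - float(new.q[stimulus, action])
    alpha = params.alpha_pos if reward == 1 else params.effective_alpha_neg(spec)
    new.q[stimulus, action] += alpha * rpe
    if spec.decay:
        _decay_toward_neutral(new.q, params.decay, skip=(stimulus, action))
    new.last_action[stimulus] = action
    return UpdateResult(q=new, rpe=rpe)


def session_nll(session: BehavioralSession, params: RLParams,
                spec: ModelSpec) -> float:
    """Negative log-likelihood (nats) of the recorded choices.

    Replays the session in trial order; only response trials with a recorded
    action contribute -log p(chosen action).  Abort and missed trials
    contribute decay only.
    """
    stim, act, rew = session.arrays()
    row = params.to_row(spec)
    return float(_engine.session_nll_core(stim, act, rew, *row))


def simulate_session(walks: RewardWalkSet, sequence: TrialSequence,
                     params: RLParams, spec: ModelSpec, seed=None,
                     miss_prob: float = 0.0, subject: str = "sub-01",
                     session: str = "ses-1") -> BehavioralSession:
    """Generate behavior from the model on a given schedule and walk set.

    On response trials the action is drawn from the softmax policy and the
    reward from the walk; with probability ``miss_prob`` the trial is marked
    missed (action=none).  Abort and missed trials apply decay only.
    """
    if walks.n_trials < sequence.n_trials:
        raise ValueError("walks shorter than the trial sequence")
    rng = np.random.default_rng(seed)
    q = initial_q()
    n = sequence.n_trials
    action = np.full(n, NO_ACTION, dtype=np.int64)
    reward = np.full(n, NO_REWARD, dtype=np.int64)
    for t in range(n):
        s = int(sequence.stimulus[t])
        if sequence.kind[t] == 1 and rng.random() >= miss_prob:
            p = action_probabilities(q, s, params, spec)
            a = int(rng.random() < p[FOOT])
            r = sample_outcome(walks, t, s, a, rng)
            action[t] = a
            reward[t] = r
            q = apply_update(q, s, a, r, params, spec).q
        else:
            q = apply_update(q, s, None, None, params, spec).q
    return BehavioralSession(stimulus=sequence.stimulus.copy(),
                             kind=sequence.kind.copy(), action=action,
                             reward=reward, subject=subject, session=session)
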