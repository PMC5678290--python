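"""Restless two-armed-bandit task: reward walks, trial sequences, sessions.

The task presents one of two slot machines (red/blue) per trial; on half the
trials (response trials) the subject chooses between a hand and a foot
response and receives binary feedback, on the other half (abort trials) the
trial is cancelled before the go cue.  Reward probabilities for the four
(stimulus, action) pairs drift as bounded Gaussian random walks, forcing
continual learning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

STIMULI = ("red", "blue")
KINDS = ("abort", "response")
ACTIONS = ("hand", "foot")
NO_ACTION = -1
NO_REWARD = -1

WALK_COLUMNS = ("p_s1a1", "p_s1a2", "p_s2a1", "p_s2a2")


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


# ---------------------------------------------------------------------------
# reward probability walks
# ---------------------------------------------------------------------------

@dataclass
class RewardWalkSet:
    """Per-trial reward probabilities p_t(r | s_i, a_j) for 2x2 (s, a) pairs.

    ``probs`` has shape [n_trials, 4] with columns ordered
    (s1,a1), (s1,a2), (s2,a1), (s2,a2); entry (t, 2*s + a) is the reward
    probability of action ``a`` for stimulus ``s`` on trial ``t``.
    """

    probs: np.ndarray
    step_scale: float = 0.01
    lower: float = 0.15
    upper: float = 0.85
    mean_lo: float = 0.4
    mean_hi: float = 0.6

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, t: int, stimulus: int, action: int) -> float:
        if not 0 <= t < self.n_trials:
            raise IndexError(f"trial {t} outside walk of length {self.n_trials}")
        return float(self.probs[t, 2 * stimulus + action])

    def with_assignment(self, pair_swap: bool,
                        action_swap) -> "RewardWalkSet":
        """Re-assign walk pairs to stimuli and walks to actions.

        The same underlying walks serve every subject, but which pair maps
        to which slot machine (``pair_swap``) and which walk of a pair maps
        to which action (``action_swap``, one flag per stimulus) are
        randomized per participant, matching volatility while decorrelating
        the environment across subjects.
        """
        cols = []
        for s in range(2):
            src_pair = 1 - s if pair_swap else s
            for a in range(2):
                src_a = 1 - a if action_swap[s] else a
                cols.append(2 * src_pair + src_a)
        return dataclasses.replace(self, probs=self.probs[:, cols])

    def max_pairwise_corr(self) -> float:
        c = np.corrcoef(self.probs.T)
        return float(np.max(np.abs(c[np.triu_indices(4, k=1)])))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(WALK_COLUMNS))
        df.insert(0, "trial", np.arange(self.n_trials))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RewardWalkSet":
        df = pd.read_csv(path)
        return cls(probs=df[list(WALK_COLUMNS)].to_numpy(dtype=float))


def _one_walk(rng, n_trials, sd, lower, upper, init, bounded):
    x = np.empty(n_trials)
    if init is None:
        x[0] = rng.uniform(lower, upper) if bounded else rng.uniform(0.0, 1.0)
    else:
        x[0] = init
    if sd == 0.0:
        x[:] = x[0]
        return x
    for t in range(1, n_trials):
        v = x[t - 1] + rng.normal(0.0, sd)
        if bounded:
            # redraw the increment until the walk stays inside the bounds;
            # preserves the per-step Gaussian away from the boundaries
            while not (lower <= v <= upper):
                v = x[t - 1] + rng.normal(0.0, sd)
        x[t] = v
    return x


def generate_walks(n_trials: int = 512,
                   step_scale: float = 0.01,
                   lower: float = 0.15,
                   upper: float = 0.85,
                   mean_lo: float = 0.4,
                   mean_hi: float = 0.6,
                   max_pairwise_corr: float | None = None,
                   seed=None,
                   *,
                   step_is_variance: bool = False,
                   init_values=None,
                   enforce_bounds: bool = True,
                   max_attempts: int = 10_000) -> RewardWalkSet:
    """Generate 4 bounded Gaussian random walks of reward probabilities.

    Each walk starts from U(lower, upper), steps by N(0, step_scale) with
    per-step redraw at the bounds, and is rejected and regenerated until its
    mean falls in [mean_lo, mean_hi].  If ``max_pairwise_corr`` is given the
    whole 4-walk set is resampled until all 6 pairwise Pearson correlations
    are at or below the bound in absolute value.

    ``step_scale`` is a standard deviation by default; pass
    ``step_is_variance=True`` to interpret it as a variance.
    ``enforce_bounds=False`` disables both the [lower, upper] truncation and
    the mean constraint (diagnostic use, e.g. checking the raw step SD).
    """
    if step_scale < 0:
        raise ValueError("step_scale must be nonnegative")
    if enforce_bounds and not (0.0 <= lower < upper <= 1.0):
        raise ValueError("need 0 <= lower < upper <= 1")
    sd = float(np.sqrt(step_scale)) if step_is_variance else float(step_scale)
    rng = np.random.default_rng(seed)
    inits = [None] * 4 if init_values is None else list(init_values)

    for _ in range(max_attempts):
        walks = []
        ok = True
        for j in range(4):
            for _ in range(max_attempts):
                w = _one_walk(rng, n_trials, sd, lower, upper, inits[j],
                              enforce_bounds)
                if not enforce_bounds or mean_lo <= w.mean() <= mean_hi:
                    break
            else:
                raise GenerationError(
                    f"walk {j}: mean constraint [{mean_lo}, {mean_hi}] not met "
                    f"in {max_attempts} attempts (n_trials={n_trials}, "
                    f"sd={sd})")
            walks.append(w)
        probs = np.column_stack(walks)
        if max_pairwise_corr is not None and n_trials > 1:
            c = np.corrcoef(probs.T)
            if np.max(np.abs(c[np.triu_indices(4, k=1)])) > max_pairwise_corr:
                ok = False
        if ok:
            return RewardWalkSet(probs=probs, step_scale=sd, lower=lower,
                                 upper=upper, mean_lo=mean_lo, mean_hi=mean_hi)
    raise GenerationError(
        f"no 4-walk set with max |pairwise corr| <= {max_pairwise_corr} "
        f"found in {max_attempts} attempts")


def sample_outcome(walks: RewardWalkSet, t: int, stimulus: int, action: int,
                   rng) -> int:
    """Bernoulli reward draw with probability p_t(r | stimulus, action)."""
    p = walks.prob(t, stimulus, action)
    return int(rng.random() < p)


# ---------------------------------------------------------------------------
# trial sequences
# ---------------------------------------------------------------------------

@dataclass
class TrialSequence:
    """Per-trial stimulus (0 red / 1 blue) and kind (0 abort / 1 response)."""

    stimulus: np.ndarray
    kind: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.stimulus.shape[0]

    def type_counts(self) -> np.ndarray:
        """Counts of the 4 (stimulus, kind) combinations, in type order."""
        types = 2 * self.stimulus + self.kind
        return np.bincount(types, minlength=4)

    def max_run(self) -> int:
        types = 2 * self.stimulus + self.kind
        return int(_max_run_length(types))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "stimulus": [STIMULI[s] for s in self.stimulus],
            "kind": [KINDS[k] for k in self.kind],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialSequence":
        df = pd.read_csv(path)
        return cls(
            stimulus=np.array([STIMULI.index(s) for s in df["stimulus"]],
                              dtype=np.int64),
            kind=np.array([KINDS.index(k) for k in df["kind"]],
                          dtype=np.int64))


def _max_run_length(a: np.ndarray) -> int:
    if a.size == 0:
        return 0
    change = np.flatnonzero(np.diff(a) != 0)
    run_lengths = np.diff(np.concatenate(([-1], change, [a.size - 1])))
    return int(run_lengths.max())


def generate_trial_sequence(n_per_type: int = 128, max_run: int = 3,
                            seed=None,
                            max_attempts: int = 100_000) -> TrialSequence:
    """Uniform shuffle of 4 x n_per_type trial types, rejecting runs > max_run.

    Rejection over uniformly shuffled sequences yields a uniform draw from
    the set of admissible arrangements.
    """
    if n_per_type < 1 or max_run < 1:
        raise ValueError("n_per_type and max_run must be >= 1")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(4), n_per_type)
    for _ in range(max_attempts):
        types = rng.permutation(base)
        if _max_run_length(types) <= max_run:
            return TrialSequence(stimulus=types // 2, kind=types % 2)
    raise GenerationError(
        f"no arrangement with max run <= {max_run} found in "
        f"{max_attempts} attempts (n_per_type={n_per_type})")


# ---------------------------------------------------------------------------
# behavioral sessions
# ---------------------------------------------------------------------------

@dataclass
class BehavioralSession:
    """Trial-by-trial record of one subject-session.

    Arrays are integer-coded: stimulus 0/1 (red/blue), kind 0/1
    (abort/response), action 0/1/-1 (hand/foot/none), reward 0/1/-1
    (no-reward/reward/NA).  ``rt`` (seconds) is optional and only present
    for real data.  Abort trials and missed response trials carry
    action=-1, reward=-1.
    """

    stimulus: np.ndarray
    kind: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    subject: str = "sub-01"
    session: str = "ses-1"
    rt: np.ndarray | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        n = self.stimulus.shape[0]
        for name in ("kind", "action", "reward"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        no_resp = (self.kind == 0) | (self.action == NO_ACTION)
        if np.any(self.action[self.kind == 0] != NO_ACTION):
            raise ValueError("abort trials must have action=none")
        if np.any(self.reward[no_resp] != NO_REWARD):
            raise ValueError("trials without a response must have reward=NA")
        answered = (self.kind == 1) & (self.action != NO_ACTION)
        if not np.all(np.isin(self.reward[answered], (0, 1))):
            raise ValueError("answered response trials need reward in {0,1}")

    @property
    def n_trials(self) -> int:
        return self.stimulus.shape[0]

    @property
    def n_choices(self) -> int:
        """Number of response trials with a recorded action."""
        return int(np.sum((self.kind == 1) & (self.action != NO_ACTION)))

    @property
    def n_missed(self) -> int:
        return int(np.sum((self.kind == 1) & (self.action == NO_ACTION)))

    def arrays(self):
        """(stimulus, action, reward) int64 views for the likelihood kernels."""
        return (np.ascontiguousarray(self.stimulus, dtype=np.int64),
                np.ascontiguousarray(self.action, dtype=np.int64),
                np.ascontiguousarray(self.reward, dtype=np.int64))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "stimulus": [STIMULI[s] for s in self.stimulus],
            "kind": [KINDS[k] for k in self.kind],
            "action": ["none" if a == NO_ACTION else ACTIONS[a]
                       for a in self.action],
            "reward": [np.nan if r == NO_REWARD else int(r)
                       for r in self.reward],
        })
        if self.rt is not None:
            df["rt"] = self.rt
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject: str = "sub-01",
                   session: str = "ses-1") -> "BehavioralSession":
        action = np.array([NO_ACTION if a == "none" else ACTIONS.index(a)
                           for a in df["action"]], dtype=np.int64)
        reward = np.array([NO_REWARD if pd.isna(r) else int(r)
                           for r in df["reward"]], dtype=np.int64)
        rt = df["rt"].to_numpy(dtype=float) if "rt" in df.columns else None
        return cls(
            stimulus=np.array([STIMULI.index(s) for s in df["stimulus"]],
                              dtype=np.int64),
            kind=np.array([KINDS.index(k) for k in df["kind"]],
                          dtype=np.int64),
            action=action, reward=reward, subject=subject, session=session,
            rt=rt)

    @classmethod
    def read_csv(cls, path, subject: str = "sub-01",
                 session: str = "ses-1") -> "BehavioralSession":
        return cls.from_frame(pd.read_csv(path), subject=subject,
                              session=session)
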