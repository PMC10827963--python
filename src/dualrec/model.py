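"""The dual-recollection multinomial processing tree (MPT) measurement model.

Recognition responses in the conjoint-recognition paradigm are modelled by
one processing tree per (probe question, item class) pair. Branches are
ordered sequences of latent success/failure factors; the probability of a
branch is the product of its factor probabilities and the probability of a
"yes" response in a tree is the sum over its accepting branches.

Latent processes, per target class ``k``:

``RC_k``  context recollection — conscious reinstatement of the contextual
          feature the probe asks about;
``RT_k``  target recollection — vivid reinstatement of the item's own
          presentation;
``F_k``   familiarity — an old-item signal that supports only the
          "either"-question;
``b_q``   response bias — the probability of accepting a non-retrieved
          probe on question ``q``.

For a target whose context is congruent with the probe,
``P(yes) = RC + (1-RC)RT + (1-RC)(1-RT)b``. For an incongruent probe,
successful context recollection is a terminal *reject* and
``P(yes) = (1-RC)[RT + (1-RT)b]``. On the either-question,
``P(yes) = RC + (1-RC)RT + (1-RC)(1-RT)F + (1-RC)(1-RT)(1-F)b``.
Distractors are accepted only through the bias: ``P(yes) = b_q``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .design import DesignSpec

__all__ = [
    "ParameterVector",
    "Branch",
    "MptModel",
    "build_dual_recollection_model",
    "default_sharing_scheme",
    "category_probabilities",
    "check_identifiability",
]

ACCEPT = "accept"
REJECT = "reject"


class ParameterVector(dict):
    """Named probabilities in [0, 1], one per model parameter."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for name, value in self.items():
            v = float(value)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(f"parameter {name!r} = {value} outside [0, 1]")
            self[name] = v

    def as_array(self, order: tuple[str, ...]) -> np.ndarray:
        missing = [p for p in order if p not in self]
        if missing:
            raise KeyError(f"missing parameters: {', '.join(missing)}")
        return np.array([self[p] for p in order], dtype=float)


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: ordered (parameter, success) factors."""

    factors: tuple[tuple[str, bool], ...]
    outcome: str  # ACCEPT or REJECT

    def probability(self, theta: dict[str, float]) -> float:
        p = 1.0
        for name, success in self.factors:
            p *= theta[name] if success else 1.0 - theta[name]
        return p

    def expression(self) -> str:
        if not self.factors:
            return "1"
        return "*".join(name if success else f"(1-{name})" for name, success in self.factors)


class MptModel:
    """A set of processing trees keyed by (probe type, item class)."""

    def __init__(self, trees: dict[tuple[str, str], tuple[Branch, ...]]):
        self.trees = {key: tuple(branches) for key, branches in trees.items()}
        self.categories: tuple[tuple[str, str], ...] = tuple(self.trees)
        names: list[str] = []
        for branches in self.trees.values():
            for br in branches:
                for name, _ in br.factors:
                    if name not in names:
                        names.append(name)
        self.parameter_names: tuple[str, ...] = tuple(names)
        self._compiled = None

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    # -- evaluation ---------------------------------------------------------

    def _compile(self):
        """Matrix layout of the accept branches for vectorised evaluation.

        Branch probabilities are products of theta_p (success factors) and
        1 - theta_p (failure factors); with binary exponent matrices S and F
        every accept-branch probability is prod(1 + S(theta-1)) * prod(1 -
        F theta), and P(yes) is an indicator matmul over branches. Exact at
        the boundaries theta in {0, 1}.
        """
        if self._compiled is None:
            index = {p: i for i, p in enumerate(self.parameter_names)}
            succ, fail, owner = [], [], []
            for c, key in enumerate(self.categories):
                for br in self.trees[key]:
                    if br.outcome != ACCEPT:
                        continue
                    s_row = np.zeros(len(index))
                    f_row = np.zeros(len(index))
                    for name, success in br.factors:
                        (s_row if success else f_row)[index[name]] = 1.0
                    succ.append(s_row)
                    fail.append(f_row)
                    owner.append(c)
            S = np.array(succ)  # (branches, k)
            F = np.array(fail)
            A = np.zeros((len(self.categories), len(owner)))
            A[owner, np.arange(len(owner))] = 1.0
            self._compiled = (S, F, A)
        return self._compiled

    def p_yes(self, theta: np.ndarray) -> np.ndarray:
        """P(yes) per category for parameter values ``theta``.

        ``theta`` has shape ``(..., n_parameters)`` in ``parameter_names``
        order; the result has shape ``(..., n_categories)``.
        """
        S, F, A = self._compile()
        theta = np.asarray(theta, dtype=float)[..., None, :]  # (..., 1, k)
        factors = (1.0 + S * (theta - 1.0)) * (1.0 - F * theta)
        return factors.prod(axis=-1) @ A.T

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "trees": [
                {
                    "probe": probe,
                    "item_class": item_class,
                    "branches": [
                        {"factors": [[n, s] for n, s in br.factors], "outcome": br.outcome}
                        for br in branches
                    ],
                }
                for (probe, item_class), branches in self.trees.items()
            ]
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MptModel":
        trees = {}
        for t in d["trees"]:
            trees[(t["probe"], t["item_class"])] = tuple(
                Branch(tuple((n, bool(s)) for n, s in br["factors"]), br["outcome"])
                for br in t["branches"]
            )
        return cls(trees)

    @classmethod
    def from_json(cls, s: str) -> "MptModel":
        return cls.from_dict(json.loads(s))

    def to_eqn(self) -> str:
        """Plain-text EQN export: one line per branch (tree, category, product)."""
        lines = []
        for (probe, item_class), branches in self.trees.items():
            tree = f"{probe}|{item_class}"
            for br in branches:
                category = "yes" if br.outcome == ACCEPT else "no"
                lines.append(f"{tree} {category} {br.expression()}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def _probe_feature(design: DesignSpec) -> str:
    """Name of the feature the probe questions ask about."""
    levels = {v for v in design.probe_targets.values() if v is not None}
    for cell in design.target_cells:
        for feature, value in cell.feature_values.items():
            if value in levels:
                return feature
    raise ValueError("design's probe targets do not match any target feature")


def default_sharing_scheme(design: DesignSpec) -> dict[tuple[str, str], str]:
    """Map every (probe, item class) pair to its response-bias parameter.

    Defaults mirror the published analyses: in the exp1 neutral arm one bias
    per probe shared across font sizes; in the exp1 reinstated arm biases per
    probe and reinstated font size; in the exp2 neutral arms the two
    colour-question biases are equated; elsewhere one bias per probe.
    """
    scheme: dict[tuple[str, str], str] = {}
    exp, cond = design.experiment_id, design.condition
    for probe in design.probe_types:
        stem = probe.rstrip("?")
        for item_class in design.item_classes:
            if exp == "exp1" and cond == "reinstated":
                size = design.class_features(item_class).get("size", "")
                name = f"b_{stem}_{size}"
            elif exp == "exp2" and cond.endswith("neutral") and design.probe_targets.get(probe) is not None:
                name = "b_colour"
            else:
                name = f"b_{stem}"
            scheme[(probe, item_class)] = name
    return scheme


def _congruent_tree(k: str, b: str) -> tuple[Branch, ...]:
    rc, rt = f"RC_{k}", f"RT_{k}"
    return (
        Branch(((rc, True),), ACCEPT),
        Branch(((rc, False), (rt, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (b, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (b, False)), REJECT),
    )


def _incongruent_tree(k: str, b: str) -> tuple[Branch, ...]:
    # successful context recollection is a terminal reject: the probe's
    # context contradicts the recollected one
    rc, rt = f"RC_{k}", f"RT_{k}"
    return (
        Branch(((rc, True),), REJECT),
        Branch(((rc, False), (rt, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (b, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (b, False)), REJECT),
    )


def _either_tree(k: str, b: str) -> tuple[Branch, ...]:
    rc, rt, f = f"RC_{k}", f"RT_{k}", f"F_{k}"
    return (
        Branch(((rc, True),), ACCEPT),
        Branch(((rc, False), (rt, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (f, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (f, False), (b, True)), ACCEPT),
        Branch(((rc, False), (rt, False), (f, False), (b, False)), REJECT),
    )


def _distractor_tree(b: str) -> tuple[Branch, ...]:
    return (Branch(((b, True),), ACCEPT), Branch(((b, False),), REJECT))


def build_dual_recollection_model(
    design: DesignSpec,
    sharing: dict[tuple[str, str], str] | str = "default",
) -> MptModel:
    """Build the dual-recollection MPT for a conjoint-recognition design.

    Parameters
    ----------
    design
        The item layout; must have target classes, distractor classes and
        probe questions of which exactly one is the either-question.
    sharing
        ``"default"`` for the built-in bias-sharing scheme, or an explicit
        map (probe, item class) -> bias parameter name covering every pair.
    """
    if isinstance(sharing, str):
        if sharing != "default":
            raise ValueError(f"unknown sharing scheme {sharing!r}")
        scheme = default_sharing_scheme(design)
    else:
        scheme = dict(sharing)
        valid = {(q, c) for q in design.probe_types for c in design.item_classes}
        unknown = set(scheme) - valid
        if unknown:
            raise ValueError(f"sharing scheme references unknown (probe, class) slots: {sorted(unknown)}")
        missing = valid - set(scheme)
        if missing:
            raise ValueError(f"sharing scheme missing slots: {sorted(missing)}")

    feature = _probe_feature(design)
    distractor_classes = set(design.distractor_classes)
    trees: dict[tuple[str, str], tuple[Branch, ...]] = {}
    for probe in design.probe_types:
        asked = design.probe_targets.get(probe)
        for item_class in design.item_classes:
            b = scheme[(probe, item_class)]
            if item_class in distractor_classes:
                trees[(probe, item_class)] = _distractor_tree(b)
            elif asked is None:
                trees[(probe, item_class)] = _either_tree(item_class, b)
            elif design.class_features(item_class)[feature] == asked:
                trees[(probe, item_class)] = _congruent_tree(item_class, b)
            else:
                trees[(probe, item_class)] = _incongruent_tree(item_class, b)
    return MptModel(trees)


# ---------------------------------------------------------------------------
# evaluation and diagnostics
# ---------------------------------------------------------------------------


def category_probabilities(model: MptModel, theta: ParameterVector | dict) -> dict[tuple[str, str], float]:
    """P(yes) for every (probe, item class) category under ``theta``."""
    if not isinstance(theta, ParameterVector):
        theta = ParameterVector(theta)
    vec = theta.as_array(model.parameter_names)
    probs = model.p_yes(vec)
    return {key: float(probs[i]) for i, key in enumerate(model.categories)}


def check_identifiability(model: MptModel, n_draws: int = 5, seed: int = 0) -> dict:
    """Local identifiability via the rank of the category-probability Jacobian.

    The Jacobian of the stacked P(yes) vector with respect to the parameters
    is evaluated numerically at ``n_draws`` random interior points; the model
    is locally identifiable when its maximal rank equals the parameter count.
    """
    rng = np.random.default_rng(seed)
    k = model.n_parameters
    h = 1e-6
    best_rank = 0
    for _ in range(n_draws):
        theta = rng.uniform(0.2, 0.8, size=k)
        jac = np.empty((len(model.categories), k))
        for j in range(k):
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            jac[:, j] = (model.p_yes(up) - model.p_yes(dn)) / (2 * h)
        best_rank = max(best_rank, int(np.linalg.matrix_rank(jac, tol=1e-8)))
    return {
        "rank": best_rank,
        "n_parameters": k,
        "n_categories": len(model.categories),
        "identifiable": best_rank == k,
    }
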