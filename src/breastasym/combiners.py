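"""Decision-fusion rules for classifier ensembles.

A *decision profile* for one sample is an L x c row-stochastic matrix: row l
holds base classifier l's soft supports for the c classes.  Fixed rules
(majority vote, max, sum, min, average, product) aggregate the columns
directly.  Trainable rules first learn from training profiles:

* decision templates  -- per-class mean profile T_w; a sample is assigned to
  the class whose template is nearest in (normalized squared) Frobenius
  distance, score_w = 1 - ||DP - T_w||_F^2 / (L*c);
* naive Bayes         -- per-classifier confusion matrices (Laplace-smoothed)
  give P(vote_l | w); score_w proportional to prior_w * prod_l P(vote_l | w);
* Dempster-Shafer     -- the proximity-based evidential combination: template
  row proximities Phi_{w,l} = (1 + ||T_w(l,.) - DP(l,.)||^2)^-1 normalized
  over classes, converted to per-classifier beliefs

      b_l(w) = Phi_{w,l} * K / (1 - Phi_{w,l} * (1 - K)),
      K = prod_{v != w} (1 - Phi_{v,l}),

  multiplied across classifiers and normalized.

All rules break score ties toward the lowest class index and reduce to the
single classifier's decision at L = 1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ContractError

__all__ = [
    "FIXED_RULES",
    "TRAINABLE_RULES",
    "ALL_RULES",
    "DecisionTemplates",
    "combine_fixed",
    "fit_trainable_combiner",
    "apply_trainable_combiner",
    "combine",
]

FIXED_RULES = ("majority", "max", "sum", "min", "average", "product")
TRAINABLE_RULES = ("bayes", "decision_template", "dempster_shafer")
ALL_RULES = FIXED_RULES + TRAINABLE_RULES


def _check_profile(profile: np.ndarray) -> np.ndarray:
    dp = np.asarray(profile, dtype=float)
    if dp.ndim != 2 or dp.shape[0] < 1 or dp.shape[1] < 2:
        raise ContractError(f"decision profile must be L x c with c >= 2, got {dp.shape}")
    if (dp < -1e-9).any() or not np.allclose(dp.sum(axis=1), 1.0, atol=1e-6):
        raise ContractError("decision profile rows must be distributions over classes")
    return dp


@dataclasses.dataclass
class DecisionTemplates:
    """Fitted state for the trainable combiners."""

    templates: np.ndarray  # c x L x c, templates[w] = mean profile of class w
    priors: np.ndarray  # c
    confusion: np.ndarray  # L x c x c, confusion[l][w, v] = count + smoothing
    n_classifiers: int
    n_classes: int


def combine_fixed(profile: np.ndarray, rule: str) -> tuple[int, np.ndarray]:
    """Apply a fixed rule; returns (label index, combined support distribution)."""
    dp = _check_profile(profile)
    if rule not in FIXED_RULES:
        raise ContractError(f"unknown fixed rule {rule!r}")
    if rule == "majority":
        votes = np.argmax(dp, axis=1)
        scores = np.bincount(votes, minlength=dp.shape[1]).astype(float)
    elif rule == "max":
        scores = dp.max(axis=0)
    elif rule in ("sum", "average"):
        scores = dp.sum(axis=0)
    elif rule == "min":
        scores = dp.min(axis=0)
    else:  # product
        scores = dp.prod(axis=0)
    total = scores.sum()
    supports = scores / total if total > 0 else np.full(dp.shape[1], 1.0 / dp.shape[1])
    return int(np.argmax(scores)), supports


def fit_trainable_combiner(
    profiles: Sequence[np.ndarray], labels: Sequence[int], n_classes: int | None = None
) -> DecisionTemplates:
    """Learn decision templates, class priors, and per-classifier confusion
    matrices (with add-one smoothing) from training profiles."""
    if len(profiles) == 0 or len(profiles) != len(labels):
        raise ContractError("need one label per training profile")
    dps = np.asarray([_check_profile(p) for p in profiles])
    y = np.asarray(labels, dtype=int)
    n, L, c = dps.shape
    if n_classes is None:
        n_classes = c
    if n_classes != c:
        raise ContractError(f"profiles have {c} class columns but n_classes={n_classes}")
    present = set(y.tolist())
    if present != set(range(c)):
        raise ContractError(f"every class 0..{c - 1} needs a training profile, got {sorted(present)}")
    templates = np.stack([dps[y == w].mean(axis=0) for w in range(c)])
    priors = np.bincount(y, minlength=c).astype(float) / n
    confusion = np.ones((L, c, c))  # Laplace smoothing: start every cell at 1
    votes = np.argmax(dps, axis=2)  # n x L
    for idx in range(n):
        for l in range(L):
            confusion[l, y[idx], votes[idx, l]] += 1.0
    return DecisionTemplates(
        templates=templates, priors=priors, confusion=confusion, n_classifiers=L, n_classes=c
    )


def apply_trainable_combiner(
    profile: np.ndarray, fitted: DecisionTemplates, rule: str
) -> tuple[int, np.ndarray]:
    """Apply a trained rule; returns (label index, per-class score vector)."""
    dp = _check_profile(profile)
    if rule not in TRAINABLE_RULES:
        raise ContractError(f"unknown trainable rule {rule!r}")
    L, c = dp.shape
    if (L, c) != (fitted.n_classifiers, fitted.n_classes):
        raise ContractError(
            f"profile shape {(L, c)} does not match fitted "
            f"{(fitted.n_classifiers, fitted.n_classes)}"
        )
    if rule == "decision_template":
        scores = np.array(
            [1.0 - ((dp - fitted.templates[w]) ** 2).sum() / (L * c) for w in range(c)]
        )
    elif rule == "bayes":
        votes = np.argmax(dp, axis=1)
        cond = fitted.confusion / fitted.confusion.sum(axis=2, keepdims=True)
        scores = fitted.priors.copy()
        for l in range(L):
            scores = scores * cond[l, :, votes[l]]
    else:  # dempster_shafer
        prox = np.empty((c, L))
        for l in range(L):
            d2 = ((fitted.templates[:, l, :] - dp[l]) ** 2).sum(axis=1)
            phi = 1.0 / (1.0 + d2)
            prox[:, l] = phi / phi.sum()
        scores = np.ones(c)
        for l in range(L):
            for w in range(c):
                others = np.prod(1.0 - np.delete(prox[:, l], w))
                denom = 1.0 - prox[w, l] * (1.0 - others)
                belief = prox[w, l] * others / denom if denom > 0 else 0.0
                scores[w] *= belief
    return int(np.argmax(scores)), scores


def combine(
    profile: np.ndarray, rule: str, fitted: DecisionTemplates | None = None
) -> tuple[int, np.ndarray]:
    """Dispatch to the fixed or trainable rule of that name."""
    if rule in FIXED_RULES:
        return combine_fixed(profile, rule)
    if rule in TRAINABLE_RULES:
        if fitted is None:
            raise ContractError(f"rule {rule!r} requires a fitted DecisionTemplates")
        return apply_trainable_combiner(profile, fitted, rule)
    raise ContractError(f"unknown rule {rule!r}; valid: {ALL_RULES}")
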