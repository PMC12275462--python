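"""Empirical calibration of the parametric rate-shift score.

The signed parametric score of the observed trait is compared against
the scores of permulated null traits.  Significance is summarized by a
two-sided *conditional* p-value: the one-sided plus-one empirical
p-value of the tail containing the observation, divided by that tail's
empirical weight (the fraction of null scores on the observation's side
of the null mean).  For a symmetric null this reduces exactly to
doubling the one-sided p-value; the plus-one form guarantees p > 0.

Adaptive early stopping: with target level alpha and N draws, a
hypothesis can only reach significance if fewer than T = ceil(alpha*N)
null scores are as extreme as the observation.  After each draw we track
the number of null scores at or beyond the observation in *both*
directions; once both counts exceed T the element can no longer reach
p <= alpha under either tail assignment, so the loop stops ("pruned")
and the p-value is computed from the draws so far.  Significance
decisions at level alpha therefore agree exactly with an exhaustive
full-N run, while clearly null elements stop after a handful of draws.

The final convergence score is scorr = -log10(pcorr), signed positive
for deceleration (lam < 1) and negative for acceleration (lam > 1).
Leave-one-out robustness refits the model with each foreground species
removed in turn; the signal is robust only if every reduced fit keeps
the direction of the shift and a nominal LRT p at or below the
configured cutoff.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .likelihood import Alignment, ForegroundSpec, LikelihoodEngine, foreground_branches
from .permulation import NullTrait, PermulationError
from .rate_shift import AltFit, NullFit, fit_alt, fit_null, lrt, signed_score
from .substitution import NeutralModel

__all__ = [
    "CalibrationConfig",
    "NullScoreSet",
    "ConvergenceResult",
    "conditional_two_sided_p",
    "adaptive_calibrate",
    "leave_one_out_robustness",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationConfig:
    alpha: float = 0.05
    n_max: int = 1000
    loo_p_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")

    @property
    def pruning_threshold(self) -> int:
        """Maximum number of extreme null statistics before pruning."""
        return max(1, math.ceil(self.alpha * self.n_max))


@dataclass
class NullScoreSet:
    scores: list[float]
    complete: bool            # ran all N draws (not pruned)
    exhausted_early: bool = False  # stream ended early (rejection failure)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ConvergenceResult:
    pcorr: float
    scorr: float
    lambda_hat: float
    robust: bool | None
    null_set: NullScoreSet


def conditional_two_sided_p(observed: float, nulls) -> float:
    """Two-sided conditional p-value of ``observed`` against null scores.

    The null set is partitioned at its mean; the one-sided plus-one
    p-value of the observation's side is reweighted by that side's
    empirical mass.  Symmetric nulls reduce to doubling.
    """
    s = np.asarray(nulls.scores if isinstance(nulls, NullScoreSet) else nulls,
                   dtype=float)
    n = s.size
    if n == 0:
        raise ValueError("empty null score set")
    m = float(s.mean())
    if observed >= m:
        c = int((s >= observed).sum())
        w = (s >= m).sum() / n
    else:
        c = int((s <= observed).sum())
        w = (s <= m).sum() / n
    p1 = (1 + c) / (n + 1)
    return float(min(1.0, p1 / w))


def adaptive_calibrate(
    scorer: Callable[[frozenset[str]], float],
    observed_fg: ForegroundSpec,
    trait_stream: Iterable[NullTrait],
    config: CalibrationConfig,
    lambda_hat: float,
    *,
    exhaustive: bool = False,
) -> ConvergenceResult:
    """Calibrate one element's score with adaptive early stopping.

    ``scorer`` maps a foreground tip set to its signed parametric score
    and must be deterministic; ``trait_stream`` yields up to
    ``config.n_max`` permulated null traits.  With ``exhaustive=True``
    pruning is disabled and all n_max draws are always consumed.
    """
    observed = scorer(observed_fg.fg_tips)
    T = config.pruning_threshold
    scores: list[float] = []
    n_at_or_above = 0
    n_at_or_below = 0
    pruned = False
    exhausted = False
    stream = iter(trait_stream)
    while len(scores) < config.n_max:
        try:
            trait = next(stream)
        except StopIteration:
            break
        except PermulationError as exc:
            logger.warning("permulation stream ended early: %s", exc)
            exhausted = True
            break
        s = scorer(trait.fg_tips)
        scores.append(s)
        if s >= observed:
            n_at_or_above += 1
        if s <= observed:
            n_at_or_below += 1
        # once both tail counts exceed T, p <= alpha is unreachable for
        # either tail assignment: stop early, decision matches full-N
        if (
            not exhaustive
            and min(n_at_or_above, n_at_or_below) > T
            and len(scores) < config.n_max
        ):
            pruned = True
            break
    if not scores:
        raise PermulationError("no null scores could be computed")
    if exhausted and len(scores) < config.n_max:
        logger.warning(
            "calibrating on %d/%d null draws", len(scores), config.n_max
        )
    null_set = NullScoreSet(scores, complete=not pruned and not exhausted,
                            exhausted_early=exhausted)
    pcorr = conditional_two_sided_p(observed, null_set)
    return ConvergenceResult(
        pcorr=pcorr,
        scorr=signed_score(pcorr, lambda_hat),
        lambda_hat=lambda_hat,
        robust=None,
        null_set=null_set,
    )


def leave_one_out_robustness(
    source: Alignment | LikelihoodEngine,
    model: NeutralModel | None,
    fg: ForegroundSpec,
    *,
    loo_p_threshold: float = 0.05,
    null: NullFit | None = None,
    full_alt: AltFit | None = None,
) -> tuple[bool | None, list[tuple[str, float, float]]]:
    """Refit with each foreground species left out in turn.

    Returns (robust, table) where table rows are (species removed,
    lam_hat, nominal LRT p).  Robust requires every repetition to keep
    the direction of the shift (sign of 1 - lam_hat) and p at or below
    ``loo_p_threshold``.  With a single foreground species robustness is
    undefined (None).
    """
    if len(fg.fg_tips) < 2:
        return None, []
    engine = source if isinstance(source, LikelihoodEngine) else LikelihoodEngine(source, model)
    tree = engine.tree
    if null is None:
        null = fit_null(engine)
    if full_alt is None:
        full_alt = fit_alt(engine, None, fg, null)
    full_sign = np.sign(1.0 - full_alt.lam)
    table: list[tuple[str, float, float]] = []
    robust = True
    for species in sorted(fg.fg_tips):
        reduced = foreground_branches(tree, fg.fg_tips - {species})
        alt = fit_alt(engine, None, reduced, null)
        p = lrt(null, alt).pvalue
        table.append((species, alt.lam, p))
        if np.sign(1.0 - alt.lam) != full_sign or p > loo_p_threshold:
            robust = False
    return robust, table
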