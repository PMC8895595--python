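"""Enrichment calling, candidate ranking, profile comparison and mixture-fraction fit.

The measured composition of a deposit-rich (case) fraction is compared with a
matched control: the channel with the uniquely largest case/control fold
change (> 1) is called the enrichment target.  Candidate proteins are then
ranked by their sequence-derived content of that channel, the winner's
profile is compared with the measurement (Pearson r and Jensen-Shannon
divergence), and a two-component candidate + background mixture is fitted to
estimate the candidate's residue-level fraction in the deposit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from depositcomp.composition import (
    CompositionVector,
    HydrolysisScheme,
    protein_composition,
)
from depositcomp.sequence_io import ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-4


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-channel case/control fold changes and the called target channel(s)."""

    fold_change: dict[str, float]
    target_channels: tuple[str, ...]
    epsilon: float
    epsilon_channels: tuple[str, ...] = ()

    def top_channel(self) -> str | None:
        return self.target_channels[0] if self.target_channels else None


@dataclass(frozen=True)
class CandidateRanking:
    """Candidates ordered by descending fraction of one channel.

    ``rows`` are (protein id, channel fraction, rank); ties share the smaller
    rank (competition ranking) and are ordered by id.
    """

    channel: str
    rows: tuple[tuple[str, float, int], ...]
    scheme_name: str
    excluded: tuple[str, ...] = ()

    def top_id(self) -> str:
        return self.rows[0][0]


@dataclass(frozen=True)
class SimilarityScore:
    """Two complementary profile-agreement metrics; neither is privileged."""

    pearson: float | None
    jsd: float


@dataclass(frozen=True)
class MixtureFractionEstimate:
    fraction: float | None
    residual: float
    degenerate: bool = False


def _check_same_scheme(a: CompositionVector, b: CompositionVector) -> None:
    if a.scheme_name != b.scheme_name:
        raise ValueError(
            f"scheme mismatch: {a.scheme_name!r} vs {b.scheme_name!r}"
        )


def fold_change(
    case: CompositionVector,
    control: CompositionVector,
    epsilon: float = DEFAULT_EPSILON,
    call_mode: str = "unique_max",
    fc_cutoff: float = 1.5,
) -> EnrichmentResult:
    """Per-channel case/control ratios with target-channel calling.

    Control fractions below *epsilon* are replaced by *epsilon* (logged), so a
    channel absent from the control cannot produce an infinite ratio.  In the
    default ``unique_max`` mode the target is the single channel with the
    strictly greatest fold change, provided it exceeds 1; ``threshold`` mode
    calls every channel with fold change >= *fc_cutoff* (for dipeptide-like
    biases enriching two channels at once).
    """
    _check_same_scheme(case, control)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    fc: dict[str, float] = {}
    eps_channels = []
    for ch in case.fractions:
        denom = control.fractions[ch]
        if denom < epsilon:
            logger.info(
                "control fraction %.3g for channel %s below epsilon; using %.3g",
                denom, ch, epsilon,
            )
            eps_channels.append(ch)
            denom = epsilon
        fc[ch] = case.fractions[ch] / denom
    if call_mode == "unique_max":
        best = max(fc.values())
        winners = [ch for ch, v in fc.items() if v == best]
        targets = tuple(winners) if (len(winners) == 1 and best > 1.0) else ()
    elif call_mode == "threshold":
        called = [(ch, v) for ch, v in fc.items() if v >= fc_cutoff and v > 1.0]
        targets = tuple(ch for ch, _ in sorted(called, key=lambda t: (-t[1], t[0])))
    else:
        raise ValueError(f"unknown call_mode {call_mode!r}")
    return EnrichmentResult(
        fold_change=fc,
        target_channels=targets,
        epsilon=epsilon,
        epsilon_channels=tuple(eps_channels),
    )


def rank_by_channel(
    candidates: list[ProteinRecord],
    channel: str,
    scheme: HydrolysisScheme,
) -> CandidateRanking:
    """Rank candidate proteins by their mole fraction of *channel*.

    Candidates with no recoverable residues under the scheme are excluded
    with a warning and listed in the result.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    if channel not in scheme.channels:
        raise ValueError(
            f"channel {channel!r} not in scheme {scheme.name!r} channel set"
        )
    scored = []
    excluded = []
    for rec in candidates:
        try:
            comp = protein_composition(rec, scheme)
        except ValueError:
            logger.warning(
                "candidate %r has no recoverable residues under scheme %s; excluded",
                rec.id, scheme.name,
            )
            excluded.append(rec.id)
            continue
        scored.append((rec.id, comp[channel]))
    if not scored:
        raise ValueError("no candidates with recoverable residues")
    scored.sort(key=lambda t: (-t[1], t[0]))
    rows = []
    for i, (pid, frac) in enumerate(scored):
        if i > 0 and frac == scored[i - 1][1]:
            rank = rows[-1][2]  # competition ranking: ties share the smaller rank
        else:
            rank = i + 1
        rows.append((pid, frac, rank))
    return CandidateRanking(
        channel=channel,
        rows=tuple(rows),
        scheme_name=scheme.name,
        excluded=tuple(excluded),
    )


def profile_similarity(
    a: CompositionVector, b: CompositionVector
) -> SimilarityScore:
    """Pearson correlation and base-2 Jensen-Shannon divergence of two profiles.

    JSD lies in [0, 1] and is 0 iff the vectors are equal; Pearson is
    undefined (None) when either vector is constant across channels.
    """
    _check_same_scheme(a, b)
    channels = list(a.fractions)
    x = np.array([a.fractions[ch] for ch in channels])
    y = np.array([b.fractions[ch] for ch in channels])
    if np.array_equal(x, y):
        jsd = 0.0
    else:
        with np.errstate(invalid="ignore"):
            jsd = float(jensenshannon(x, y, base=2) ** 2)
        # near-identical vectors can push the divergence a rounding error
        # below zero inside scipy's sqrt, yielding NaN
        jsd = 0.0 if math.isnan(jsd) else min(max(jsd, 0.0), 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        pearson = None
    else:
        pearson = float(pearsonr(x, y).statistic)
    return SimilarityScore(pearson=pearson, jsd=jsd)


def estimate_mixture_fraction(
    measured: CompositionVector,
    candidate: CompositionVector,
    background: CompositionVector,
) -> MixtureFractionEstimate:
    """Best-fit candidate fraction f in a two-component mixture model.

    Minimises the Euclidean distance between the measured vector and
    f*candidate + (1-f)*background over f in [0, 1] (bounded golden-section /
    Brent search).  If candidate and background coincide the fraction is
    undefined and the estimate is flagged degenerate.
    """
    _check_same_scheme(measured, candidate)
    _check_same_scheme(measured, background)
    channels = list(measured.fractions)
    m = np.array([measured.fractions[ch] for ch in channels])
    c = np.array([candidate.fractions[ch] for ch in channels])
    b = np.array([background.fractions[ch] for ch in channels])
    if np.allclose(c, b):
        return MixtureFractionEstimate(
            fraction=None,
            residual=float(np.linalg.norm(m - b)),
            degenerate=True,
        )

    def objective(f: float) -> float:
        return float(np.linalg.norm(m - (f * c + (1.0 - f) * b)))

    res = minimize_scalar(
        objective, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-7}
    )
    # The objective is convex in f; check the boundary values as well since a
    # bounded search can stop a hair inside the interval.
    best_f = float(res.x)
    for f0 in (0.0, 1.0, best_f):
        if objective(f0) < objective(best_f):
            best_f = f0
    return MixtureFractionEstimate(fraction=best_f, residual=objective(best_f))
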