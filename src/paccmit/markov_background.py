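"""Order-k Markov background model and the seed-match over-representation P-value.

The UTR-mode statistic asks: given the observed number *n* of seed matches
in a transcript of length *L*, how surprising is *n* under a random-sequence
background?  The background is an order-k Markov chain fitted to the
transcript corpus; the per-position occurrence probability *p* of the
length-m motif then yields the upper binomial tail

    P(X >= n),   X ~ Binomial(N, p),   N = L - m + 1.

Overlap dependence between nearby positions is deliberately ignored; for
non-self-overlapping motifs at desk scale the approximation error of the
tail is small (checked against exhaustive enumeration in the test suite).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
from scipy import stats

__all__ = ["MarkovModel", "SiteCountTest", "fit_markov", "motif_probability", "site_count_pvalue"]

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(_ALPHABET)}


def _kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_ALPHABET, repeat=k)]


@dataclass
class MarkovModel:
    """Order-k Markov chain over {A,C,G,T}.

    ``initial_probs`` maps each k-mer context to its stationary/empirical
    probability (for k=0, the single empty context '' maps to 1 and letter
    probabilities live in ``transition_probs['']``).  ``transition_probs``
    maps each context to a length-4 array of P(next letter | context).
    Raw counts are retained so a fitted model can be serialized and refit
    losslessly.
    """

    order: int
    pseudocount: float
    initial_probs: dict[str, float]
    transition_probs: dict[str, np.ndarray]
    context_counts: dict[str, np.ndarray] = field(default_factory=dict)
    initial_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("Markov order must be >= 0")
        total = sum(self.initial_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial_probs must sum to 1, got {total}")
        for ctx, probs in self.transition_probs.items():
            s = float(np.sum(probs))
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"transition probs for context {ctx!r} sum to {s}")

    # -- plain-text serialization -------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Write order, pseudocount and raw counts as key=value lines."""
        lines = [f"order={self.order}", f"pseudocount={self.pseudocount!r}"]
        for ctx in sorted(self.initial_counts):
            lines.append(f"initial_count:{ctx}={self.initial_counts[ctx]}")
        for ctx in sorted(self.context_counts):
            joined = ",".join(str(int(c)) for c in self.context_counts[ctx])
            lines.append(f"transition_counts:{ctx}={joined}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "MarkovModel":
        order = 0
        pseudocount = 0.0
        init_counts: dict[str, int] = {}
        trans_counts: dict[str, np.ndarray] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            if key == "order":
                order = int(val)
            elif key == "pseudocount":
                pseudocount = float(val)
            elif key.startswith("initial_count:"):
                init_counts[key.split(":", 1)[1]] = int(val)
            elif key.startswith("transition_counts:"):
                trans_counts[key.split(":", 1)[1]] = np.array(
                    [int(x) for x in val.split(",")], dtype=float
                )
        return _model_from_counts(order, pseudocount, init_counts, trans_counts)


def _model_from_counts(
    order: int,
    pseudocount: float,
    initial_counts: Mapping[str, int],
    context_counts: Mapping[str, np.ndarray],
) -> MarkovModel:
    contexts = _kmers(order)
    # initial k-mer distribution, smoothed by the same pseudocount
    init_raw = np.array([initial_counts.get(c, 0) for c in contexts], dtype=float)
    init = init_raw + pseudocount
    if init.sum() == 0:
        init = np.ones_like(init)
    init /= init.sum()
    initial_probs = dict(zip(contexts, init.tolist()))

    transition_probs: dict[str, np.ndarray] = {}
    for ctx in contexts:
        counts = np.asarray(context_counts.get(ctx, np.zeros(4)), dtype=float)
        denom = counts.sum() + 4 * pseudocount
        if denom == 0:
            logger.warning(
                "context %r never observed with pseudocount=0; falling back to uniform", ctx
            )
            transition_probs[ctx] = np.full(4, 0.25)
        else:
            transition_probs[ctx] = (counts + pseudocount) / denom
    return MarkovModel(
        order=order,
        pseudocount=pseudocount,
        initial_probs=initial_probs,
        transition_probs=transition_probs,
        context_counts={c: np.asarray(context_counts.get(c, np.zeros(4)), dtype=float)
                        for c in contexts},
        initial_counts={c: int(initial_counts.get(c, 0)) for c in contexts},
    )


def fit_markov(
    sequences: Iterable[str], order: int = 1, pseudocount: float = 1.0
) -> MarkovModel:
    """Fit an order-k model by pooling counts over ``sequences``.

    Transition estimate per context c and letter x:
        (count(c·x) + pseudocount) / (count(c·*) + 4·pseudocount)
    Counts never wrap around record boundaries.  The initial distribution
    is the (smoothed) pooled k-mer frequency.
    """
    seqs = [s for s in sequences]
    if not seqs or sum(len(s) for s in seqs) == 0:
        raise ValueError("cannot fit a Markov model on an empty corpus")
    if order < 0:
        raise ValueError("order must be >= 0")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if sum(len(s) for s in seqs) <= order:
        raise ValueError("pooled sequence length must exceed the model order")

    initial_counts: dict[str, int] = {}
    context_counts: dict[str, np.ndarray] = {}
    for seq in seqs:
        if not set(seq) <= set(_ALPHABET):
            raise ValueError("sequences must be uppercase DNA over A/C/G/T")
        for i in range(len(seq) - order + 1) if order > 0 else range(1):
            if order > 0:
                kmer = seq[i : i + order]
                initial_counts[kmer] = initial_counts.get(kmer, 0) + 1
        for i in range(len(seq) - order):
            ctx = seq[i : i + order]
            x = seq[i + order]
            if ctx not in context_counts:
                context_counts[ctx] = np.zeros(4)
            context_counts[ctx][_IDX[x]] += 1
    if order == 0:
        initial_counts = {"": sum(len(s) for s in seqs)}
    return _model_from_counts(order, pseudocount, initial_counts, context_counts)


def motif_probability(model: MarkovModel, motif: str) -> float:
    """Per-position probability of ``motif`` under the background model.

    p = P(prefix of length k) * prod_{i>k} P(motif[i] | preceding k letters),
    accumulated in log space to avoid underflow for long motifs.
    """
    k = model.order
    if len(motif) < k + 1:
        raise ValueError(f"motif length {len(motif)} must exceed model order {k}")
    if not set(motif) <= set(_ALPHABET):
        raise ValueError("motif must be DNA over A/C/G/T")
    logp = math.log(model.initial_probs[motif[:k]]) if k > 0 else 0.0
    for i in range(k, len(motif)):
        ctx = motif[i - k : i]
        p = float(model.transition_probs[ctx][_IDX[motif[i]]])
        if p == 0.0:
            return 0.0
        logp += math.log(p)
    return math.exp(logp)


@dataclass(frozen=True)
class SiteCountTest:
    """Result of the binomial over-representation test for one pair."""

    observed_count: int
    positions_available: int
    site_prob: float
    p_value: float


def site_count_pvalue(
    model: MarkovModel,
    transcript_length: int,
    motif: str,
    observed_count: int,
    *,
    poisson: bool = False,
) -> SiteCountTest:
    """Upper-tail P-value for the observed seed-match count.

    Exact binomial P(X >= n) with N = L - m + 1 positions and per-position
    probability from the background model.  ``poisson=True`` switches to a
    Poisson(N·p) tail approximation; the binomial is the reference.
    """
    m = len(motif)
    if transcript_length < m:
        raise ValueError(
            f"transcript length {transcript_length} shorter than motif length {m}"
        )
    if observed_count < 0:
        raise ValueError("observed count must be >= 0")
    n_positions = transcript_length - m + 1
    if observed_count > n_positions:
        raise ValueError(
            f"observed count {observed_count} exceeds available positions {n_positions}"
        )
    p = motif_probability(model, motif)
    if observed_count == 0:
        pval = 1.0
    elif poisson:
        pval = float(stats.poisson.sf(observed_count - 1, n_positions * p))
    else:
        pval = float(stats.binom.sf(observed_count - 1, n_positions, p))
    pval = min(max(pval, 0.0), 1.0)
    if pval == 0.0:  # guard against underflow: a tail of an open interval
        pval = 5e-324
    return SiteCountTest(
        observed_count=observed_count,
        positions_available=n_positions,
        site_prob=p,
        p_value=pval,
    )
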