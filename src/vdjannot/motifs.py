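"""Position weight matrices for RSS heptamers/nonamers and leader parts.

A PWM is a per-position nucleotide probability model. Motif scores are
log-likelihoods in natural log units: ``sum_i log p_i(base_i)``, with N
contributing ``log(0.25)``. Each PWM carries a pass threshold (by default
the minimum log-likelihood of its own training sequences, so every training
example passes) and an optional IUPAC consensus string.

The paired search used at gene ends (heptamer + spacer + nonamer, or the
reverse) maximises the *joint* log-likelihood, i.e. the sum of the two
motif log-likelihoods; the spacer contributes only a placement constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .sequence import IUPAC_CLASSES, NUCLEOTIDES, encode


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # (L, 4) probabilities over A, C, G, T
    threshold: float = float("-inf")
    consensus: Optional[str] = None
    pseudocount: float = 0.0
    _logp: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: matrix must be (L, 4)")
        sums = self.matrix.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"PWM {self.name}: row {bad[0]} sums to {sums[bad[0]]:.6f}, not 1"
            )
        if self.consensus is not None and len(self.consensus) != len(self):
            raise ValueError(
                f"PWM {self.name}: consensus length {len(self.consensus)} "
                f"!= matrix length {len(self)}"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def logp(self) -> np.ndarray:
        """(L, 5) log-probability table; column 4 is N at log(0.25)."""
        if self._logp is None:
            with np.errstate(divide="ignore"):
                core = np.log(self.matrix)
            n_col = np.full((len(self), 1), np.log(0.25))
            self._logp = np.hstack([core, n_col])
        return self._logp


@dataclass(frozen=True)
class MotifHit:
    """A scored motif placement. ``matches_consensus`` is None when the PWM
    defines no consensus."""

    position: int
    log_likelihood: float
    passes_threshold: bool
    matches_consensus: Optional[bool]


def build_pwm(
    training_seqs: Sequence[str],
    pseudocount: float = 0.1,
    consensus: Optional[str] = None,
    name: str = "",
) -> PWM:
    """Estimate a PWM from equal-length training sequences.

    Entry (i, b) = (count(b at i) + pseudocount) / (n + 4 * pseudocount).
    The pass threshold is the minimum log-likelihood that any training
    sequence attains under the finished matrix, so no training motif is
    ever rejected by its own model.
    """
    if not training_seqs:
        raise ValueError("at least one training sequence is required")
    length = len(training_seqs[0])
    if any(len(s) != length for s in training_seqs):
        raise ValueError("training sequences must all have the same length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    counts = np.zeros((length, 4))
    for seq in training_seqs:
        enc = encode(seq.upper())
        if (enc > 3).any():
            raise ValueError(f"training sequence {seq!r} contains non-ACGT bases")
        counts[np.arange(length), enc] += 1
    n = len(training_seqs)
    matrix = (counts + pseudocount) / (n + 4 * pseudocount)
    pwm = PWM(name=name, matrix=matrix, consensus=consensus, pseudocount=pseudocount)
    pwm.threshold = min(
        float(score_pwm(pwm, seq).log_likelihood) for seq in training_seqs
    )
    return pwm


def score_pwm(pwm: PWM, window: str, position: int = 0) -> MotifHit:
    """Score one window of exactly PWM length."""
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != PWM {pwm.name} length {len(pwm)}"
        )
    enc = encode(window.upper())
    ll = float(pwm.logp[np.arange(len(pwm)), enc].sum())
    consensus_ok = (
        matches_consensus(window.upper(), pwm.consensus)
        if pwm.consensus is not None
        else None
    )
    return MotifHit(position, ll, ll >= pwm.threshold, consensus_ok)


def score_positions(pwm: PWM, encoded: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Vectorised log-likelihoods of windows starting at *starts* (all of
    which must fit inside *encoded*)."""
    length = len(pwm)
    idx = np.asarray(starts)[:, None] + np.arange(length)[None, :]
    return pwm.logp[np.arange(length)[None, :], encoded[idx]].sum(axis=1)


def matches_consensus(seq: str, pattern: str) -> bool:
    """True iff every base of *seq* lies in the IUPAC class of the
    corresponding *pattern* position. N in *seq* is an ambiguity code, not a
    base, and matches nothing."""
    if len(seq) != len(pattern):
        raise ValueError("sequence and pattern lengths differ")
    for base, code in zip(seq.upper(), pattern.upper()):
        try:
            allowed = IUPAC_CLASSES[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r} in pattern") from None
        if base not in allowed:
            return False
    return True


def find_best_motif_pair(
    seq: str,
    left_pwm: PWM,
    right_pwm: PWM,
    spacer: int,
    tolerance: int = 0,
    window: Optional[tuple[int, int]] = None,
) -> Optional[tuple[MotifHit, MotifHit, int]]:
    """Exhaustive joint search for ``left + gap + right`` placements.

    The left motif start ranges over *window* (half-open; default: the whole
    sequence) and the gap over ``spacer +- tolerance``. Returns the placement
    maximising the joint log-likelihood, ties broken by canonical spacer
    first, then leftmost position; None when no placement fits.
    """
    lo, hi = window if window is not None else (0, len(seq))
    lo = max(lo, 0)
    llen, rlen = len(left_pwm), len(right_pwm)
    encoded = encode(seq.upper())

    best = None
    best_key = None
    for s in range(lo, hi):
        if s + llen > len(seq):
            break
        for gap in range(max(spacer - tolerance, 0), spacer + tolerance + 1):
            rs = s + llen + gap
            if rs + rlen > len(seq):
                continue
            ll = float(
                score_positions(left_pwm, encoded, np.array([s]))[0]
                + score_positions(right_pwm, encoded, np.array([rs]))[0]
            )
            key = (ll, gap == spacer, -s)
            if best_key is None or key > best_key:
                best_key = key
                best = (s, rs, gap)
    if best is None:
        return None
    s, rs, gap = best
    left_hit = score_pwm(left_pwm, seq[s : s + llen], position=s)
    right_hit = score_pwm(right_pwm, seq[rs : rs + rlen], position=rs)
    return left_hit, right_hit, gap
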