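"""Random-fern ensemble classifier with an adaptive posterior prior.

Each base classifier (fern) indexes a posterior table by a binary code of
pixel-intensity comparisons; the pixel pairs are generated randomly at
initialization and stay fixed at runtime.  A fern's posterior for a code is
``#positive / (#positive + #negative)`` over the training samples that landed
on that code, and 0 for codes never seen in training.

The adaptive rule addresses a failure mode of tracking-by-detection on
slender instruments: the annotation rectangle contains background, background
appearance drifts, so at test time many codes have never been trained and the
ensemble sums toward 0 — the object is wrongly declared absent.  A randomly
chosen fifth of the ferns therefore answer *unseen* codes with a running
prior: 0.5 before any training data, thereafter the ratio of positive to
total samples produced by P-N learning, refreshed every frame.  Codes with
observed counts keep their evidence-based posterior, and the non-adaptive
ferns are untouched; with an empty adaptive subset the ensemble is exactly
the classical one.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["FernEnsemble", "fern_code", "ensemble_classify", "adaptive_posterior_update"]


def fern_code(patch: np.ndarray, pixel_pairs: np.ndarray) -> int:
    """Binary code of a patch: bit ``i`` is 1 iff the first pixel of pair ``i``
    is strictly brighter than the second.

    ``pixel_pairs`` is ``(k, 2, 2)`` of ``(row, col)`` indices into ``patch``.
    """
    patch = np.asarray(patch)
    pairs = np.asarray(pixel_pairs, dtype=int)
    if pairs.ndim != 3 or pairs.shape[1:] != (2, 2):
        raise ValueError(f"pixel_pairs must be (k, 2, 2), got {pairs.shape}")
    h, w = patch.shape
    if (pairs[..., 0] < 0).any() or (pairs[..., 0] >= h).any() or (
        pairs[..., 1] < 0
    ).any() or (pairs[..., 1] >= w).any():
        raise ValueError("pixel pair index out of range for patch")
    first = patch[pairs[:, 0, 0], pairs[:, 0, 1]]
    second = patch[pairs[:, 1, 0], pairs[:, 1, 1]]
    bits = (first > second).astype(int)
    return int((bits << np.arange(bits.size)).sum())


class FernEnsemble:
    """Ensemble of ferns over normalized patches.

    ``pairs`` holds the comparison endpoints in normalized patch coordinates
    ``[0, 1)`` so the same ensemble evaluates windows of any pixel size.
    """

    def __init__(
        self,
        n_ferns: int = 10,
        n_pairs: int = 13,
        adaptive: bool = True,
        threshold: float | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.n_ferns = n_ferns
        self.n_pairs = n_pairs
        self.n_leaves = 2**n_pairs
        # (n_ferns, n_pairs, 2 endpoints, 2 coords (x, y)) in [0, 1)
        self.pairs = rng.random((n_ferns, n_pairs, 2, 2))
        # the adaptive subset is drawn either way so the rng stream (and hence
        # everything downstream) is identical with adaptivity toggled off
        subset = rng.choice(n_ferns, size=math.ceil(n_ferns / 5), replace=False)
        self.adaptive_idx = np.sort(subset) if adaptive else subset[:0]
        self.pos_counts = np.zeros((n_ferns, self.n_leaves), dtype=np.float64)
        self.neg_counts = np.zeros((n_ferns, self.n_leaves), dtype=np.float64)
        self.prior = 0.5
        self.threshold = 0.5 * n_ferns if threshold is None else threshold

    # -- training -----------------------------------------------------------
    def update(self, codes: np.ndarray, positive: bool) -> None:
        """Count one or more samples; ``codes`` is ``(n_ferns,)`` or ``(m, n_ferns)``."""
        codes = np.atleast_2d(np.asarray(codes, dtype=int))
        table = self.pos_counts if positive else self.neg_counts
        for f in range(self.n_ferns):
            np.add.at(table[f], codes[:, f], 1.0)

    # -- inference ----------------------------------------------------------
    def posterior_sums(self, codes: np.ndarray) -> np.ndarray:
        """Sum of per-fern posteriors for ``(m, n_ferns)`` codes."""
        codes = np.atleast_2d(np.asarray(codes, dtype=int))
        m = codes.shape[0]
        total = np.zeros(m)
        adaptive = np.zeros(self.n_ferns, dtype=bool)
        adaptive[self.adaptive_idx] = True
        for f in range(self.n_ferns):
            p = self.pos_counts[f, codes[:, f]]
            n = self.neg_counts[f, codes[:, f]]
            tot = p + n
            unseen_value = self.prior if adaptive[f] else 0.0
            total += np.where(tot > 0, p / np.maximum(tot, 1e-300), unseen_value)
        return total

    def posterior_table(self) -> np.ndarray:
        """Dense ``(n_ferns, n_leaves)`` posterior table with the adaptive
        prior filled into unseen entries of the adaptive ferns."""
        tot = self.pos_counts + self.neg_counts
        table = np.where(tot > 0, self.pos_counts / np.maximum(tot, 1e-300), 0.0)
        if self.adaptive_idx.size:
            unseen = tot[self.adaptive_idx] == 0
            table[self.adaptive_idx] = np.where(
                unseen, self.prior, table[self.adaptive_idx]
            )
        return table


def ensemble_classify(codes: np.ndarray, ensemble: FernEnsemble) -> tuple[float, bool]:
    """Posterior sum and label (positive iff sum strictly above threshold)."""
    s = float(ensemble.posterior_sums(np.asarray(codes))[0])
    return s, s > ensemble.threshold


def adaptive_posterior_update(
    ensemble: FernEnsemble, n_positive: int, n_total: int
) -> FernEnsemble:
    """Refresh the adaptive ferns' unseen-code posterior with the P-N sample
    ratio (0.5 before any training data)."""
    if n_total < 0 or n_positive > n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    ensemble.prior = n_positive / n_total if n_total > 0 else 0.5
    return ensemble
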