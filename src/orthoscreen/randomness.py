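"""Monte-Carlo sliding-window count of randomly aligned positions.

Columns of an MSA that align residues no better than chance carry no
homology signal; their count is the single strongest-expected separator
between true homology clusters and random decoys.  This scorer follows
the parametric Monte-Carlo resampling-in-a-sliding-window principle:

* for every unordered pair of rows and every window start, the observed
  window score is the sum of BLOSUM62 scores over the window's columns,
  with any gap-containing column contributing a flat ``gap_score``;
* the pair's null distribution is the set of scores of ``n_resamples``
  windows whose residues are drawn independently from each row's own
  ungapped residue frequencies (no gaps in the null);
* a window is *nonrandom* iff its observed score exceeds the null's
  ``quantile``;
* pooling over all pairs, a column is flagged random iff fewer than half
  of the windows covering it are nonrandom.

Deterministic given the seed, and invariant to row order and sequence
ids: each pair's random stream is derived from the seed and the pair's
(sorted) residue strings.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .cluster_io import Alignment
from .msa_align import BLOSUM62_22, GAP_INDEX, encode


@dataclass(frozen=True)
class RandomnessParams:
    window: int = 6
    n_resamples: int = 100
    quantile: float = 0.95
    gap_score: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.n_resamples < 10:
            raise ValueError("n_resamples must be >= 10")
        if not (0.0 < self.quantile < 1.0):
            raise ValueError("quantile must lie in (0, 1)")


def _pair_rng(seed: int, row_a: str, row_b: str) -> np.random.Generator:
    """RNG stream derived from the seed and the pair's residue content.

    Sorting the two strings makes the stream independent of row order
    and of sequence ids.
    """
    lo, hi = sorted((row_a, row_b))
    digest = hashlib.sha256(
        f"{seed}\x00{lo}\x00{hi}".encode()
    ).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _observed_window_scores(
    ia: np.ndarray, ib: np.ndarray, window: int, gap_score: float
) -> np.ndarray:
    col = BLOSUM62_22[ia, ib].copy()
    gap_col = (ia == GAP_INDEX) | (ib == GAP_INDEX)
    col[gap_col] = gap_score
    kernel = np.ones(window)
    return np.convolve(col, kernel, mode="valid")


def _null_quantile(
    rng: np.random.Generator,
    ia: np.ndarray,
    ib: np.ndarray,
    params: RandomnessParams,
) -> float:
    def freqs(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        resid = idx[idx != GAP_INDEX]
        vals, counts = np.unique(resid, return_counts=True)
        return vals, counts / counts.sum()

    va, pa = freqs(ia)
    vb, pb = freqs(ib)
    shape = (params.n_resamples, params.window)
    draws_a = rng.choice(va, size=shape, p=pa)
    draws_b = rng.choice(vb, size=shape, p=pb)
    scores = BLOSUM62_22[draws_a, draws_b].sum(axis=1)
    return float(np.quantile(scores, params.quantile))


def random_positions(
    aln: Alignment, params: RandomnessParams | None = None
) -> int:
    """Count alignment columns indistinguishable from randomly aligned."""
    params = params or RandomnessParams()
    length = aln.length
    window = min(params.window, length)  # whole-alignment window if too long
    encoded = [encode(r.residues) for r in aln.rows]
    strings = [r.residues for r in aln.rows]
    n_windows = length - window + 1
    nonrandom_cover = np.zeros(length)
    total_cover = np.zeros(length)
    kernel = np.ones(window)
    per_pair_total = np.convolve(np.ones(n_windows), kernel, mode="full")
    for a, b in combinations(range(len(encoded)), 2):
        rng = _pair_rng(params.seed, strings[a], strings[b])
        obs = _observed_window_scores(
            encoded[a], encoded[b], window, params.gap_score
        )
        threshold = _null_quantile(rng, encoded[a], encoded[b], params)
        nonrandom = (obs > threshold).astype(float)
        nonrandom_cover += np.convolve(nonrandom, kernel, mode="full")
        total_cover += per_pair_total
    flagged = nonrandom_cover < 0.5 * total_cover
    return int(flagged.sum())
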