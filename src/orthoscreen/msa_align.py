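"""Multiple sequence alignment for clusters.

Downstream feature extraction needs *an* MSA per cluster, not a
state-of-the-art one: every feature is an alignment-level summary
statistic.  We therefore provide a fast, deterministic, dependency-free
progressive aligner (UPGMA guide tree on k-mer cosine distances,
profile–profile merging with mean-of-pairs scoring over BLOSUM62) plus a
hook for an external aligner such as MAFFT for users who have one.

The Needleman–Wunsch/Gotoh affine-gap dynamic programming kernel is
shared by the pairwise and profile–profile paths and is numba-compiled.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster.hierarchy import linkage

from .cluster_io import (
    GAP,
    STANDARD_AA,
    Alignment,
    Cluster,
    SequenceRecord,
    read_cluster_fasta,
    write_cluster_fasta,
)

#: residue index alphabet used internally: 20 standard AAs, then X, then gap
INDEX_ALPHABET = STANDARD_AA + "X"
GAP_INDEX = len(INDEX_ALPHABET)  # 21
_CHAR_TO_INDEX = {c: i for i, c in enumerate(INDEX_ALPHABET + GAP)}


def _blosum62_submatrix() -> np.ndarray:
    """22×22 scoring matrix over (20 AA, X, gap) from Biopython's BLOSUM62.

    Gap-vs-residue scores a flat −1 (profile columns only; the DP applies
    its own affine penalties), gap-vs-gap scores 0.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(INDEX_ALPHABET)
    mat = np.zeros((n + 1, n + 1), dtype=np.float64)
    for i, a in enumerate(INDEX_ALPHABET):
        for j, b in enumerate(INDEX_ALPHABET):
            mat[i, j] = blosum[a][b]
    mat[GAP_INDEX, :n] = -1.0
    mat[:n, GAP_INDEX] = -1.0
    return mat


BLOSUM62_22 = _blosum62_submatrix()


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters for global affine-gap alignment."""

    substitution_matrix: np.ndarray = None  # type: ignore[assignment]
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.substitution_matrix is None:
            object.__setattr__(self, "substitution_matrix", BLOSUM62_22)
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                f"need gap_open <= gap_extend < 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )
        m = self.substitution_matrix
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")


class ExternalAlignerError(RuntimeError):
    """Raised when the configured external aligner fails."""


@njit(cache=True)
def _gotoh(S, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    """Global affine-gap DP on a precomputed column-score matrix.

    Gap of length k costs gap_open + k*gap_extend.  Tie-break order:
    diagonal, then up (gap in the column sequence), then left.
    Returns (score, path_a, path_b) with -1 marking a gap.
    """
    n, m = S.shape
    NEG = -1e30
    V = np.empty((n + 1, m + 1))
    E = np.empty((n + 1, m + 1))  # gap in a (consumes j, horizontal)
    F = np.empty((n + 1, m + 1))  # gap in b (consumes i, vertical)
    ptrV = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag, 2 up(F), 3 left(E)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 open, 0 extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    V[0, 0] = 0.0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for i in range(1, n + 1):
        F[i, 0] = gap_open + i * gap_extend
        V[i, 0] = F[i, 0]
        E[i, 0] = NEG
        ptrV[i, 0] = 2
    for j in range(1, m + 1):
        E[0, j] = gap_open + j * gap_extend
        V[0, j] = E[0, j]
        F[0, j] = NEG
        ptrV[0, j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = V[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = V[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = V[i - 1, j - 1] + S[i - 1, j - 1]
            best = diag
            ptr = 1
            if F[i, j] > best:
                best = F[i, j]
                ptr = 2
            if E[i, j] > best:
                best = E[i, j]
                ptr = 3
            V[i, j] = best
            ptrV[i, j] = ptr
    # traceback
    path_a = np.empty(n + m, dtype=np.int64)
    path_b = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    state = 0  # 0 = V, 2 = F, 3 = E
    while i > 0 or j > 0:
        if state == 0:
            if i == 0:
                state = 3
                continue
            if j == 0:
                state = 2
                continue
            p = ptrV[i, j]
            if p == 1:
                path_a[k] = i - 1
                path_b[k] = j - 1
                i -= 1
                j -= 1
                k += 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            path_a[k] = i - 1
            path_b[k] = -1
            opened = ptrF[i, j]
            i -= 1
            k += 1
            if opened == 1:
                state = 0
        else:
            path_a[k] = -1
            path_b[k] = j - 1
            opened = ptrE[i, j]
            j -= 1
            k += 1
            if opened == 1:
                state = 0
    return V[n, m], path_a[:k][::-1].copy(), path_b[:k][::-1].copy()


def encode(residues: str) -> np.ndarray:
    """Map a residue string to internal integer indices (gap → 21)."""
    return np.fromiter(
        (_CHAR_TO_INDEX[c] for c in residues), dtype=np.int64, count=len(residues)
    )


def decode(indices: np.ndarray) -> str:
    alphabet = INDEX_ALPHABET + GAP
    return "".join(alphabet[i] for i in indices)


def pairwise_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> tuple[Alignment, float]:
    """Optimal global alignment of two ungapped sequences (Gotoh affine)."""
    params = params or AlignParams()
    if GAP in a.residues or GAP in b.residues:
        raise ValueError("pairwise_align expects ungapped sequences")
    ia, ib = encode(a.residues), encode(b.residues)
    S = params.substitution_matrix[np.ix_(ia, ib)]
    score, pa, pb = _gotoh(S, float(params.gap_open), float(params.gap_extend))
    row_a = "".join(a.residues[i] if i >= 0 else GAP for i in pa)
    row_b = "".join(b.residues[j] if j >= 0 else GAP for j in pb)
    aln = Alignment(
        rows=(
            SequenceRecord(id=a.id, residues=row_a, taxon=a.taxon),
            SequenceRecord(id=b.id, residues=row_b, taxon=b.taxon),
        )
    )
    return aln, float(score)


def _kmer_matrix(seqs: list[np.ndarray], k: int = 3) -> np.ndarray:
    """Dense k-mer count matrix over the 21-letter residue alphabet."""
    n_letters = len(INDEX_ALPHABET)
    dim = n_letters**k
    counts = np.zeros((len(seqs), dim), dtype=np.float64)
    for row, s in enumerate(seqs):
        if len(s) < k:
            counts[row, s[0] if len(s) else 0] += 1.0
            continue
        code = np.zeros(len(s) - k + 1, dtype=np.int64)
        for off in range(k):
            code = code * n_letters + s[off : len(s) - k + 1 + off]
        np.add.at(counts[row], code, 1.0)
    return counts


def _cosine_condensed(counts: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(counts, axis=1)
    norms[norms == 0] = 1.0
    unit = counts / norms[:, None]
    sim = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - sim
    iu = np.triu_indices(len(counts), k=1)
    return np.maximum(dist[iu], 0.0)


class _Profile:
    """Gapped rows of one guide-tree node, as integer index arrays."""

    __slots__ = ("rows", "order")

    def __init__(self, rows: list[np.ndarray], order: list[int]):
        self.rows = rows
        self.order = order  # original member indices, for stable output order

    def freq(self) -> np.ndarray:
        length = len(self.rows[0])
        counts = np.zeros((length, GAP_INDEX + 1), dtype=np.float64)
        for r in self.rows:
            np.add.at(counts, (np.arange(length), r), 1.0)
        return counts / len(self.rows)


def _merge_profiles(
    pa: _Profile, pb: _Profile, params: AlignParams
) -> _Profile:
    fa, fb = pa.freq(), pb.freq()
    S = fa @ params.substitution_matrix @ fb.T
    _, path_a, path_b = _gotoh(S, float(params.gap_open), float(params.gap_extend))
    gap_col_a = np.array([i < 0 for i in path_a])
    gap_col_b = np.array([j < 0 for j in path_b])
    idx_a = np.asarray(path_a)
    idx_b = np.asarray(path_b)
    new_rows: list[np.ndarray] = []
    for r in pa.rows:
        out = np.full(len(idx_a), GAP_INDEX, dtype=np.int64)
        out[~gap_col_a] = r[idx_a[~gap_col_a]]
        new_rows.append(out)
    for r in pb.rows:
        out = np.full(len(idx_b), GAP_INDEX, dtype=np.int64)
        out[~gap_col_b] = r[idx_b[~gap_col_b]]
        new_rows.append(out)
    return _Profile(new_rows, pa.order + pb.order)


def progressive_align(
    cluster: Cluster, params: AlignParams | None = None
) -> Cluster:
    """Populate ``cluster.alignment`` via progressive profile alignment.

    Guide tree: UPGMA over cosine distances between 3-mer count vectors.
    Degapping any output row recovers the corresponding input exactly.
    """
    params = params or AlignParams()
    members = cluster.members
    encoded = [encode(m.ungapped()) for m in members]
    if len(members) == 2:
        aln, _ = pairwise_align(
            SequenceRecord(members[0].id, members[0].ungapped()),
            SequenceRecord(members[1].id, members[1].ungapped()),
            params,
        )
        return cluster.with_alignment(aln)
    condensed = _cosine_condensed(_kmer_matrix(encoded))
    merges = linkage(condensed, method="average")
    nodes: dict[int, _Profile] = {
        i: _Profile([encoded[i]], [i]) for i in range(len(members))
    }
    next_id = len(members)
    for left, right, _, _ in merges:
        pa = nodes.pop(int(left))
        pb = nodes.pop(int(right))
        nodes[next_id] = _merge_profiles(pa, pb, params)
        next_id += 1
    (final,) = nodes.values()
    by_pos = {orig: row for orig, row in zip(final.order, final.rows)}
    rows = tuple(
        SequenceRecord(
            id=members[i].id, residues=decode(by_pos[i]), taxon=members[i].taxon
        )
        for i in range(len(members))
    )
    return cluster.with_alignment(Alignment(rows=rows))


def ensure_aligned(cluster: Cluster, params: AlignParams | None = None) -> Cluster:
    """Return the cluster with an alignment, aligning only if absent."""
    if cluster.alignment is not None:
        return cluster
    return progressive_align(cluster, params)


def external_align(cluster: Cluster, command_template: str) -> Cluster:
    """Align via an external command with ``{in}``/``{out}`` placeholders.

    e.g. ``mafft --auto {in} > {out}`` (the template is run through a shell).
    """
    with tempfile.TemporaryDirectory(prefix="orthoscreen_aln_") as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_cluster_fasta(cluster, fin, aligned=False)
        cmd = command_template.replace("{in}", str(fin)).replace("{out}", str(fout))
        binary = cmd.split()[0]
        if shutil.which(binary) is None:
            raise ExternalAlignerError(f"external aligner not found: {binary!r}")
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0 or not fout.exists():
            raise ExternalAlignerError(
                f"external aligner failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()}"
            )
        try:
            aligned = read_cluster_fasta(
                fout, cluster_id=cluster.cluster_id, force_aligned=True
            )
        except Exception as exc:
            raise ExternalAlignerError(
                f"could not parse external aligner output: {exc}"
            ) from exc
    result = cluster.with_alignment(aligned.alignment)
    return result
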